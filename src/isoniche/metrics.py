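"""Per-individual isotopic summaries, species niche breadth and the
isotopic individuality index (III).

III for a taxon = (average individual d13C range) / (total d13C range of
the taxon, over all serial samples of its qualifying individuals).  Values
near 0 mean individuals are specialized relative to the species niche;
values near 1 mean each individual spans the species niche.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import IndividualRecord, SerialDataset, body_size_category

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndividualSummary:
    individual_id: str
    taxon: str
    diet: str
    n_samples: int
    min: float
    max: float
    range: float
    mean: float
    sd: float  # nan (flagged undefined) for n = 1
    latitude_deg: float | None = None
    body_mass_kg: float | None = None


def summarize_individual(ind: IndividualRecord) -> IndividualSummary:
    """Order statistics and moments over all pooled serial samples.

    sd is the sample (n-1) standard deviation, undefined (NaN) for n = 1.
    """
    vals = ind.d13c
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"individual {ind.individual_id!r} has no finite d13C values")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
    return IndividualSummary(
        individual_id=ind.individual_id,
        taxon=ind.taxon,
        diet=ind.diet,
        n_samples=int(vals.size),
        min=float(vals.min()),
        max=float(vals.max()),
        range=float(vals.max() - vals.min()),
        mean=float(vals.mean()),
        sd=sd,
        latitude_deg=ind.latitude_deg,
        body_mass_kg=ind.body_mass_kg,
    )


def individual_summary_table(dataset: SerialDataset) -> pd.DataFrame:
    """One row per individual: n, min, max, range, mean, sd plus metadata."""
    rows = [summarize_individual(ind).__dict__ for ind in dataset.individuals()]
    if not rows:
        return pd.DataFrame(
            columns=[
                "individual_id", "taxon", "diet", "n_samples", "min", "max",
                "range", "mean", "sd", "latitude_deg", "body_mass_kg",
            ]
        )
    df = pd.DataFrame(rows)
    df["body_size"] = [
        body_size_category(m) for m in df["body_mass_kg"]
    ]
    return df.sort_values("individual_id").reset_index(drop=True)


@dataclass(frozen=True)
class SpeciesNicheSummary:
    taxon: str
    diet: str
    n_individuals: int
    species_total_range: float
    avg_individual_range: float
    iii: float  # NaN when species_total_range == 0


def species_niche(
    dataset: SerialDataset,
    summaries: pd.DataFrame | None = None,
    min_individuals: int = 1,
) -> pd.DataFrame:
    """Species niche table: total range, average individual range and III.

    The species total range is taken over *all* serial samples of the
    taxon's qualifying individuals (not over per-individual means).  Taxa
    with fewer than ``min_individuals`` individuals are omitted.  III is
    NaN (flagged undefined) when the species total range is zero.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if summaries is None:
        summaries = individual_summary_table(dataset)

    rows = []
    grouped = dataset.table.groupby("taxon", sort=True)
    for taxon, grp in grouped:
        sub = summaries[summaries["taxon"] == taxon]
        if len(sub) < min_individuals or len(sub) == 0:
            continue
        total_range = float(grp["d13c"].max() - grp["d13c"].min())
        avg_range = float(sub["range"].mean())
        iii = avg_range / total_range if total_range > 0 else float("nan")
        rows.append(
            SpeciesNicheSummary(
                taxon=str(taxon),
                diet=str(grp["diet"].iloc[0]),
                n_individuals=int(len(sub)),
                species_total_range=total_range,
                avg_individual_range=avg_range,
                iii=iii,
            ).__dict__
        )
    if not rows:
        raise ValueError("no taxon passed the min_individuals threshold")
    return pd.DataFrame(rows)


def mean_iii_by_diet(niche_table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean and sd of III over species, per dietary category.

    Species with undefined III (zero total range) are excluded; diets with
    no species are omitted with a warning.
    """
    usable = niche_table[niche_table["iii"].notna()]
    dropped = set(niche_table["diet"]) - set(usable["diet"])
    for diet in sorted(dropped):
        logger.warning("diet %r has no species with a defined III; omitted", diet)
    out = (
        usable.groupby("diet")["iii"]
        .agg(mean_iii="mean", sd_iii=lambda s: s.std(ddof=1), n_species="size")
        .reset_index()
    )
    return out


def bin_individual_ranges(
    ranges: Sequence[float] | pd.Series,
    groups: Sequence[str] | pd.Series | None = None,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Right-closed binning of individual ranges: (0, w], (w, 2w], ...

    Ranges of exactly 0 (possible for individuals with few samples) are
    placed in the first bin rather than dropped.  Returns per-group counts,
    proportions and cumulative proportions, one row per (group, bin).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    r = np.asarray(ranges, dtype=float)
    if np.any(r < 0):
        raise ValueError("ranges must be non-negative")
    if groups is None:
        groups = np.repeat("all", r.size)
    g = np.asarray(groups, dtype=object)
    if g.size != r.size:
        raise ValueError("groups and ranges must have equal length")

    # bin index i covers ((i)w, (i+1)w]; zeros go to bin 0
    with np.errstate(invalid="ignore"):
        idx = np.ceil(r / bin_width).astype(int) - 1
    idx[r == 0] = 0

    n_zero = int(np.sum(r == 0))
    if n_zero:
        logger.info("%d zero ranges placed in the first bin", n_zero)

    n_bins = int(idx.max()) + 1 if idx.size else 1
    rows = []
    for group in pd.unique(g):
        mask = g == group
        counts = np.bincount(idx[mask], minlength=n_bins)
        props = counts / counts.sum() if counts.sum() else counts.astype(float)
        cum = np.cumsum(props)
        for i in range(n_bins):
            rows.append(
                {
                    "group": group,
                    "bin_low": i * bin_width,
                    "bin_high": (i + 1) * bin_width,
                    "count": int(counts[i]),
                    "proportion": float(props[i]),
                    "cum_proportion": float(cum[i]),
                }
            )
    return pd.DataFrame(rows)


def proportion_le(
    ranges: Sequence[float] | pd.Series, threshold: float
) -> float:
    """Fraction of individuals whose range is <= threshold (per mil)."""
    r = np.asarray(ranges, dtype=float)
    if r.size == 0:
        raise ValueError("no ranges")
    return float(np.mean(r <= threshold))


def group_range_table(
    summaries: pd.DataFrame,
    grouping: str = "diet",
    value_col: str = "range",
) -> pd.DataFrame:
    """Per-group mean/sd/n of individual ranges (the Table-1-style summary).

    ``grouping`` is the summary column to group by ('diet' or 'body_size').
    Requires at least two non-empty groups; pairwise test p-values are the
    business of :mod:`isoniche.groupcmp`.
    """
    if grouping not in summaries.columns:
        raise KeyError(f"no column {grouping!r} in summaries")
    sub = summaries[summaries[grouping].notna() & (summaries[grouping] != "unknown")]
    groups = sub.groupby(grouping)[value_col]
    if groups.ngroups < 2:
        raise ValueError(f"need >= 2 non-empty {grouping} groups, got {groups.ngroups}")
    out = groups.agg(
        mean="mean", sd=lambda s: s.std(ddof=1), n="size"
    ).reset_index()
    return out
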