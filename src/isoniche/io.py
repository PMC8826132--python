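"""Reading, validating and filtering flat serial-sample tables.

The canonical on-disk format is a flat CSV/TSV with one row per enamel
serial sample::

    individual_id, taxon, diet, latitude, body_mass_kg, tooth_id,
    position_mm, d13c, source

``diet`` is one of ``browser``, ``grazer``, ``mixed_feeder``; ``latitude``
is signed degrees; ``position_mm`` is the distance from root along the
tooth's growth axis; ``d13c`` is the per-mil deviation of the sample's
13C/12C ratio from VPDB.  Missing values are empty fields.

A :class:`SerialDataset` wraps the validated table and offers the filters
used throughout the analysis: a minimum serial-sample count per tooth and
a low-latitude restriction (below which C4 grasses and C3 browse are
isotopically separable).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "individual_id",
    "taxon",
    "diet",
    "latitude",
    "body_mass_kg",
    "tooth_id",
    "position_mm",
    "d13c",
    "source",
]

MANDATORY_COLUMNS = ["individual_id", "taxon", "diet", "d13c"]

DIET_CATEGORIES = ("browser", "grazer", "mixed_feeder")

#: Plausibility window for enamel d13C (per mil, VPDB).  Herbivore enamel
#: from pure-C3 closed canopy to pure-C4 grassland spans roughly -20 to +3;
#: values outside this window are flagged, not rejected.
D13C_PLAUSIBLE_RANGE = (-25.0, 10.0)

#: Default column-name aliases accepted on read, lowercased.
DEFAULT_ALIASES: dict[str, str] = {
    "individual": "individual_id",
    "specimen": "individual_id",
    "specimen_id": "individual_id",
    "species": "taxon",
    "taxon_name": "taxon",
    "diet_category": "diet",
    "dietary_category": "diet",
    "lat": "latitude",
    "latitude_deg": "latitude",
    "mass_kg": "body_mass_kg",
    "body_mass": "body_mass_kg",
    "tooth": "tooth_id",
    "position": "position_mm",
    "distance_from_root_mm": "position_mm",
    "d13c_permil": "d13c",
    "d13c_enamel": "d13c",
    "delta13c": "d13c",
    "reference": "source",
}


class SchemaError(ValueError):
    """Input table does not match the documented schema."""


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Delta notation: ((R_sample / R_standard) - 1) * 1000, in per mil.

    Both isotope ratios must be positive.
    """
    r_sample = float(r_sample)
    r_standard = float(r_standard)
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError(
            f"isotope ratios must be positive, got {r_sample!r}, {r_standard!r}"
        )
    return (r_sample / r_standard - 1.0) * 1000.0


@dataclass(frozen=True)
class FilterConfig:
    """Inclusion rules applied before any analysis.

    min_samples
        Minimum serial samples a tooth must have for its individual to be
        analysed (3 for the main analyses, 5 for the standardized and
        variance-partitioning ones).
    latitude_cutoff_deg
        Absolute latitude below which individuals are kept in the
        low-latitude scope.
    body_size_cutoffs_kg
        (small|medium, medium|large) boundaries; half-open intervals
        [0, c1) / [c1, c2) / [c2, inf).
    bin_width_permil
        Width of the right-closed range bins.
    window_size
        Number of consecutive samples per sliding window.
    """

    min_samples: int = 3
    latitude_cutoff_deg: float = 37.0
    body_size_cutoffs_kg: tuple[float, float] = (100.0, 350.0)
    bin_width_permil: float = 1.0
    window_size: int = 5

    def __post_init__(self) -> None:
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.latitude_cutoff_deg <= 0:
            raise ValueError("latitude_cutoff_deg must be positive")
        lo, hi = self.body_size_cutoffs_kg
        if not (0 < lo < hi):
            raise ValueError("body_size_cutoffs_kg must be positive and increasing")
        if self.bin_width_permil <= 0:
            raise ValueError("bin_width_permil must be positive")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


@dataclass
class IndividualRecord:
    """One individual's metadata plus its serial samples (possibly several teeth)."""

    individual_id: str
    taxon: str
    diet: str
    latitude_deg: float | None
    body_mass_kg: float | None
    samples: pd.DataFrame  # columns: tooth_id, position_mm, d13c, source

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def d13c(self) -> np.ndarray:
        return self.samples["d13c"].to_numpy(dtype=float)


def body_size_category(
    mass_kg: float | None, cutoffs: tuple[float, float] = (100.0, 350.0)
) -> str:
    """Small [0, c1), medium [c1, c2), large [c2, inf); 'unknown' if missing."""
    if mass_kg is None or (isinstance(mass_kg, float) and np.isnan(mass_kg)):
        return "unknown"
    if mass_kg <= 0:
        raise ValueError(f"body mass must be positive, got {mass_kg!r}")
    lo, hi = cutoffs
    if mass_kg < lo:
        return "small"
    if mass_kg < hi:
        return "medium"
    return "large"


@dataclass
class ValidationReport:
    """Counts of rows dropped or flagged while assembling a dataset."""

    n_rows_read: int = 0
    n_rows_kept: int = 0
    n_missing_d13c: int = 0
    n_duplicate_position: int = 0
    n_implausible_d13c: int = 0
    n_bad_diet: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


class SerialDataset:
    """A validated serial-sample table plus its validation report.

    The underlying frame always carries the canonical columns; filters
    return new datasets and never mutate in place.
    """

    def __init__(self, table: pd.DataFrame, report: ValidationReport | None = None):
        missing = [c for c in CANONICAL_COLUMNS if c not in table.columns]
        if missing:
            raise SchemaError(f"missing canonical columns: {missing}")
        self.table = table.reset_index(drop=True)
        self.report = report if report is not None else ValidationReport(
            n_rows_read=len(table), n_rows_kept=len(table)
        )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, aliases: Mapping[str, str] | None = None
                   ) -> "SerialDataset":
        """Validate an in-memory frame exactly as :func:`read_dataset` would."""
        return _validate(frame, aliases)

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_individuals(self) -> int:
        return self.table["individual_id"].nunique()

    def individuals(self) -> Iterator[IndividualRecord]:
        """Yield one record per individual, samples pooled across teeth."""
        for ind_id, grp in self.table.groupby("individual_id", sort=True):
            first = grp.iloc[0]
            lat = first["latitude"]
            mass = first["body_mass_kg"]
            yield IndividualRecord(
                individual_id=str(ind_id),
                taxon=str(first["taxon"]),
                diet=str(first["diet"]),
                latitude_deg=None if pd.isna(lat) else float(lat),
                body_mass_kg=None if pd.isna(mass) else float(mass),
                samples=grp[["tooth_id", "position_mm", "d13c", "source"]].reset_index(
                    drop=True
                ),
            )

    # -- filters -----------------------------------------------------------

    def filter_min_samples(self, k: int) -> "SerialDataset":
        """Keep individuals for which at least one tooth has >= k serial samples.

        The inclusion test is per tooth; the retained individual keeps all
        of its samples (summaries pool across teeth).
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        counts = self.table.groupby(["individual_id", "tooth_id"], dropna=False).size()
        qualifying = {ind for (ind, _tooth), n in counts.items() if n >= k}
        mask = self.table["individual_id"].isin(qualifying)
        return SerialDataset(self.table[mask], self.report)

    def filter_latitude(self, cutoff_deg: float) -> "SerialDataset":
        """Keep individuals with |latitude| strictly below the cutoff.

        Individuals with missing latitude are dropped (logged).
        """
        if cutoff_deg <= 0:
            raise ValueError("cutoff must be positive")
        lat = self.table["latitude"]
        n_missing = int(
            self.table.loc[lat.isna(), "individual_id"].nunique()
        )
        if n_missing:
            logger.info("filter_latitude: dropping %d individuals with no latitude",
                        n_missing)
        mask = lat.abs() < cutoff_deg
        return SerialDataset(self.table[mask.fillna(False)], self.report)

    def filter_min_samples_per_tooth(self, k: int) -> "SerialDataset":
        """Keep only samples from teeth that themselves have >= k samples.

        Used by the variance-partitioning scope, where an individual
        contributes only samples from qualifying teeth.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        counts = self.table.groupby(["individual_id", "tooth_id"], dropna=False)[
            "d13c"
        ].transform("size")
        return SerialDataset(self.table[counts >= k], self.report)

    # -- export ------------------------------------------------------------

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, columns=CANONICAL_COLUMNS)


def _canonicalize_columns(
    frame: pd.DataFrame, aliases: Mapping[str, str] | None
) -> pd.DataFrame:
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update({k.lower(): v for k, v in aliases.items()})
    renames = {}
    for col in frame.columns:
        low = str(col).strip().lower()
        renames[col] = alias_map.get(low, low)
    return frame.rename(columns=renames)


def _validate(
    frame: pd.DataFrame, aliases: Mapping[str, str] | None = None
) -> SerialDataset:
    frame = _canonicalize_columns(frame, aliases)
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"mandatory columns absent: {missing}")
    for col in CANONICAL_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    frame = frame[CANONICAL_COLUMNS].copy()

    report = ValidationReport(n_rows_read=len(frame))

    for col in ("latitude", "body_mass_kg", "position_mm", "d13c"):
        bad = pd.to_numeric(frame[col], errors="coerce")
        newly_bad = bad.isna() & frame[col].notna() & (frame[col].astype(str).str.strip() != "")
        for idx in frame.index[newly_bad]:
            raise SchemaError(
                f"unparseable numeric in column {col!r} at row {idx + 2}: "
                f"{frame.at[idx, col]!r}"
            )
        frame[col] = bad

    # rows lacking d13c carry no serial value (e.g. summary-only records)
    n_missing = int(frame["d13c"].isna().sum())
    if n_missing:
        logger.info("dropping %d rows without a d13c value", n_missing)
    report.n_missing_d13c = n_missing
    frame = frame[frame["d13c"].notna()]

    lo, hi = D13C_PLAUSIBLE_RANGE
    implausible = (frame["d13c"] < lo) | (frame["d13c"] > hi)
    report.n_implausible_d13c = int(implausible.sum())
    if report.n_implausible_d13c:
        report.warnings.append(
            f"{report.n_implausible_d13c} d13C values outside [{lo}, {hi}] permil"
        )

    frame["diet"] = frame["diet"].astype(str).str.strip().str.lower().str.replace(
        "-", "_"
    ).str.replace(" ", "_")
    bad_diet = ~frame["diet"].isin(DIET_CATEGORIES)
    if bad_diet.any():
        report.n_bad_diet = int(bad_diet.sum())
        bad_vals = sorted(frame.loc[bad_diet, "diet"].unique())
        raise SchemaError(
            f"diet must be one of {DIET_CATEGORIES}, got {bad_vals}"
        )

    # duplicate (individual, tooth, position) rows: keep first, warn
    has_pos = frame["position_mm"].notna()
    dup = frame[has_pos].duplicated(
        subset=["individual_id", "tooth_id", "position_mm"], keep="first"
    )
    n_dup = int(dup.sum())
    if n_dup:
        report.n_duplicate_position = n_dup
        report.warnings.append(
            f"{n_dup} duplicate (individual, tooth, position) rows dropped"
        )
        logger.warning("dropping %d duplicate (individual, tooth, position) rows", n_dup)
        keep = pd.Series(True, index=frame.index)
        keep.loc[dup.index[dup]] = False
        frame = frame[keep]

    report.n_rows_kept = len(frame)
    return SerialDataset(frame, report)


def read_dataset(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> SerialDataset:
    """Read and validate a serial-sample table (CSV or TSV by extension).

    Rows without a d13C value are dropped with a logged count; duplicated
    (individual, tooth, position) rows keep the first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, dtype={"individual_id": str, "tooth_id": str})
    return _validate(frame, aliases)
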