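"""One-command orchestration of the full analysis grid.

For each scope (global / low-latitude) crossed with each minimum-sample
filter, the pipeline produces: per-individual summaries, the species
niche / III table, raw and window-standardized bin tables, the
Table-1-style group range table with Kruskal-Wallis / Dunn results, and
the variance partition under both estimators; plus a provenance manifest
with row counts and exclusion accounting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import metrics, windows
from .groupcmp import dunn_pairwise
from .io import SerialDataset, read_dataset
from .variance import grouped_values, nested_anova_mom, nested_reml

logger = logging.getLogger(__name__)

CSV_DECIMALS = 4


@dataclass
class AnalysisConfig:
    input_path: str | None = None
    scopes: tuple[str, ...] = ("global", "low_latitude")
    min_samples: tuple[int, ...] = (3, 5)
    latitude_cutoff_deg: float = 37.0
    window_size: int = 5
    window_aggregate: str = "mean"
    groupings: tuple[str, ...] = ("diet", "body_size")
    variance_methods: tuple[str, ...] = ("mom", "reml")
    variance_min_samples_per_tooth: int = 5
    min_individuals_per_species: int = 3
    bin_width_permil: float = 1.0
    dunn_adjustment: str = "holm"
    lump_table: Mapping[str, str] | None = None
    out_dir: str = "results"
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if not self.scopes:
            raise ValueError("select at least one scope")
        if not self.groupings:
            raise ValueError("select at least one grouping")
        for s in self.scopes:
            if s not in ("global", "low_latitude"):
                raise ValueError(f"unknown scope {s!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("scopes", "min_samples", "groupings", "variance_methods"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _apply_lump(dataset: SerialDataset, lump: Mapping[str, str] | None) -> SerialDataset:
    """Replace genus-only taxon labels per a user-supplied lump table."""
    if not lump:
        return dataset
    table = dataset.table.copy()
    table["taxon"] = table["taxon"].map(lambda t: lump.get(t, t))
    return SerialDataset(table, dataset.report)


def _scope_dataset(dataset: SerialDataset, scope: str, cutoff: float) -> SerialDataset:
    if scope == "global":
        return dataset
    return dataset.filter_latitude(cutoff)


def run_full_analysis(
    config: AnalysisConfig, dataset: SerialDataset | None = None
) -> dict:
    """Execute the whole grid; returns the result bundle as a dict of
    DataFrames plus the manifest, and writes CSV/JSON under out_dir.
    """
    if dataset is None:
        if config.input_path is None:
            raise ValueError("either a dataset or config.input_path is required")
        dataset = read_dataset(config.input_path)
    if len(dataset) == 0:
        raise ValueError("input dataset is empty")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dataset = _apply_lump(dataset, config.lump_table)

    summaries_all = []
    niche_all = []
    bins_all = []
    ranges_all = []
    tests_all = []
    var_all = []
    manifest: dict = {
        "seed": config.seed,
        "n_rows_loaded": int(dataset.report.n_rows_read),
        "n_rows_analysed": len(dataset),
        "n_individuals_loaded": dataset.n_individuals,
        "exclusions": asdict(dataset.report),
        "failures": [],
        "cells": [],
    }

    for scope in config.scopes:
        scoped = _scope_dataset(dataset, scope, config.latitude_cutoff_deg)
        if len(scoped) == 0:
            raise ValueError(f"scope {scope!r} emptied the dataset (latitude filter)")
        for k in config.min_samples:
            cell = f"{scope}_min{k}"
            sub = scoped.filter_min_samples(k)
            if len(sub) == 0:
                raise ValueError(
                    f"min_samples={k} emptied the dataset in scope {scope!r}"
                )
            summ = metrics.individual_summary_table(sub)
            summ.insert(0, "scope", scope)
            summ.insert(1, "min_samples", k)
            summaries_all.append(summ)

            niche = metrics.species_niche(
                sub, summ, min_individuals=config.min_individuals_per_species
            )
            niche.insert(0, "scope", scope)
            niche.insert(1, "min_samples", k)
            niche_all.append(niche)

            # raw and standardized bin tables
            raw_bins = metrics.bin_individual_ranges(
                summ["range"], summ["diet"], config.bin_width_permil
            )
            raw_bins.insert(0, "scope", scope)
            raw_bins.insert(1, "min_samples", k)
            raw_bins.insert(2, "kind", "raw")
            bins_all.append(raw_bins)

            std = windows.standardized_individual_ranges(
                sub, config.window_size, config.window_aggregate
            )
            if not std.empty:
                std_bins = metrics.bin_individual_ranges(
                    std["standardized_range"], std["diet"], config.bin_width_permil
                )
                std_bins.insert(0, "scope", scope)
                std_bins.insert(1, "min_samples", k)
                std_bins.insert(2, "kind", "standardized")
                bins_all.append(std_bins)

            # group range tables + rank tests
            for grouping in config.groupings:
                try:
                    rt = metrics.group_range_table(summ, grouping)
                except (ValueError, KeyError) as exc:
                    manifest["failures"].append(
                        {"cell": cell, "step": f"range_table[{grouping}]",
                         "error": str(exc)}
                    )
                    continue
                rt.insert(0, "scope", scope)
                rt.insert(1, "min_samples", k)
                rt.insert(2, "grouping", grouping)
                ranges_all.append(rt)

                grp_vals = {
                    name: g["range"].to_numpy()
                    for name, g in summ[
                        summ[grouping].notna() & (summ[grouping] != "unknown")
                    ].groupby(grouping)
                }
                try:
                    res = dunn_pairwise(grp_vals, config.dunn_adjustment)
                except ValueError as exc:
                    manifest["failures"].append(
                        {"cell": cell, "step": f"dunn[{grouping}]", "error": str(exc)}
                    )
                    continue
                tests_all.append(
                    pd.DataFrame(
                        [
                            {
                                "scope": scope, "min_samples": k,
                                "grouping": grouping, "H": res.h,
                                "df": res.df, "p_kw": res.p_value,
                                "group_a": pc.group_a, "group_b": pc.group_b,
                                "z": pc.z, "p_unadjusted": pc.p_unadjusted,
                                "p_adjusted": pc.p_adjusted,
                            }
                            for pc in res.pairwise
                        ]
                    )
                )

            manifest["cells"].append(
                {
                    "cell": cell,
                    "n_individuals": int(summ.shape[0]),
                    "n_samples": len(sub),
                    "n_species_iii": int(niche.shape[0]),
                }
            )

        # variance partitioning once per scope, on >= k-sample teeth
        vp = scoped.filter_min_samples_per_tooth(
            config.variance_min_samples_per_tooth
        )
        if len(vp) > 0:
            groups = grouped_values(vp.table)
            for method in config.variance_methods:
                try:
                    if method == "mom":
                        _, comps = nested_anova_mom(groups)
                    else:
                        comps = nested_reml(groups)
                except (ValueError, RuntimeError) as exc:
                    manifest["failures"].append(
                        {"cell": scope, "step": f"variance[{method}]",
                         "error": str(exc)}
                    )
                    continue
                p_s, p_i, p_w = comps.proportions
                var_all.append(
                    {
                        "method": method, "scope": scope,
                        "sigma2_species": comps.sigma2_species,
                        "sigma2_individual": comps.sigma2_individual,
                        "sigma2_within": comps.sigma2_within,
                        "p_species": p_s, "p_individual": p_i, "p_within": p_w,
                        "a": len(groups),
                        "sum_b": sum(len(sp) for sp in groups),
                        "N": len(vp),
                        "flags": ";".join(comps.truncated),
                    }
                )

    bundle = {
        "individual_summaries": _concat(summaries_all),
        "species_niche": _concat(niche_all),
        "bin_table": _concat(bins_all),
        "range_table": _concat(ranges_all),
        "group_tests": _concat(tests_all),
        "variance_partition": pd.DataFrame(var_all),
        "manifest": manifest,
    }
    _write_bundle(bundle, out, config)
    return bundle


def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
    frames = [f for f in frames if not f.empty]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _sort_for_output(name: str, df: pd.DataFrame) -> pd.DataFrame:
    keys = [c for c in ("scope", "min_samples", "grouping", "kind", "diet",
                        "taxon", "individual_id", "bin_low", "group",
                        "group_a", "group_b", "method") if c in df.columns]
    if keys:
        df = df.sort_values(keys, kind="mergesort", ignore_index=True)
    return df


def _write_bundle(bundle: dict, out: Path, config: AnalysisConfig) -> None:
    json_bundle = {}
    for name, df in bundle.items():
        if name == "manifest":
            continue
        df = _sort_for_output(name, df)
        bundle[name] = df
        df.to_csv(out / f"{name}.csv", index=False,
                  float_format=f"%.{CSV_DECIMALS}f")
        json_bundle[name] = json.loads(df.to_json(orient="records"))

    cfg = asdict(config)
    cfg["lump_table"] = dict(config.lump_table) if config.lump_table else None
    manifest = bundle["manifest"]
    manifest["config"] = cfg
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "bundle.json").write_text(json.dumps(json_bundle, default=str))
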