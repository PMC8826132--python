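#!/usr/bin/env python
"""Five-sample sliding-window standardization: standardized individual
ranges and bin tables on the default dataset, plus the bias diagnostic
(regression of range on samples-per-tooth for i.i.d. synthetic teeth,
raw vs standardized).

Writes window_ranges.csv, standardized_bins.csv and bias_slopes.csv under
results/windows/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from isoniche.io import SerialDataset, read_dataset
from isoniche.metrics import bin_individual_ranges, individual_summary_table, proportion_le
from isoniche.windows import standardized_individual_ranges, window_table

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "windows"


def bias_check(seed: int = 101, n_teeth: int = 1000) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for k, n in enumerate(rng.integers(5, 21, size=n_teeth)):
        for i, v in enumerate(rng.normal(-8.0, 1.0, size=n)):
            rows.append(
                {"individual_id": f"i{k:04d}", "taxon": "t", "diet": "grazer",
                 "latitude": 10.0, "body_mass_kg": 400.0,
                 "tooth_id": f"i{k:04d}_t", "position_mm": 2.0 * i,
                 "d13c": float(v), "source": "synthetic"}
            )
    ds = SerialDataset.from_frame(pd.DataFrame(rows))
    merged = standardized_individual_ranges(ds, 5).merge(
        individual_summary_table(ds), on="individual_id"
    )
    return pd.DataFrame(
        {
            "statistic": ["raw_range", "standardized_range"],
            "slope_vs_n": [
                float(np.polyfit(merged["n_samples"], merged["range"], 1)[0]),
                float(np.polyfit(merged["n_samples"],
                                 merged["standardized_range"], 1)[0]),
            ],
        }
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds = read_dataset(ROOT / "sim" / "default" / "samples.csv").filter_min_samples(5)

    wt = window_table(ds, window_size=5)
    wt.to_csv(OUT / "window_ranges.csv", index=False)
    std = standardized_individual_ranges(ds, window_size=5)
    bins = bin_individual_ranges(std["standardized_range"], std["diet"])
    bins.to_csv(OUT / "standardized_bins.csv", index=False)
    print(f"{std.shape[0]} individuals standardized "
          f"({wt['tooth_id'].nunique()} teeth, window = 5)")
    for thr in (2.0, 3.0):
        print(f"P(standardized range <= {thr:.0f} permil): "
              f"{proportion_le(std['standardized_range'], thr):.3f}")

    slopes = bias_check()
    slopes.to_csv(OUT / "bias_slopes.csv", index=False)
    print("\nrange vs samples-per-tooth slope (i.i.d. teeth, permil/sample):")
    print(slopes.to_string(index=False, float_format="%.4f"))
    print("(the moving window removes the sampling-intensity bias: the "
          "standardized slope is ~0)")


if __name__ == "__main__":
    main()
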