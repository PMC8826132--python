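#!/usr/bin/env python
"""Generate the synthetic serial-sample datasets used by the downstream
analysis steps: a study-like default design (unbalanced counts, three diet
groups, mostly low-latitude sites) plus the specialist and generalist
scenario presets.

Writes results/sim/{default,specialist,generalist}/{samples.csv,
ground_truth.csv, params.json}.
"""

import sys
from pathlib import Path

from isoniche.simulate import SimulationParams, scenario, write_bundle

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main(seed: int = 0) -> None:
    for name, params in [
        ("default", SimulationParams(seed=seed)),
        ("specialist", scenario("specialist", seed=seed)),
        ("generalist", scenario("generalist", seed=seed)),
    ]:
        ds, truth = write_bundle(params, OUT / name)
        print(
            f"{name}: {len(ds)} samples, {ds.n_individuals} individuals, "
            f"{ds.table['taxon'].nunique()} taxa -> {OUT / name}"
        )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
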