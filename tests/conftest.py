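import numpy as np
import pandas as pd
import pytest

from isoniche.io import SerialDataset


def make_table(rows):
    """Build a canonical serial-sample frame from (ind, taxon, diet, lat,
    mass, tooth, pos, d13c) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id", "taxon", "diet", "latitude", "body_mass_kg",
            "tooth_id", "position_mm", "d13c",
        ],
    ).assign(source="fixture")


@pytest.fixture
def tiny_dataset():
    """3 individuals x 4 samples, 2 taxa, hand-built."""
    rows = []
    specs = [
        ("ind1", "Equus sp", "grazer", 20.0, 400.0, [-1.0, 0.5, -0.2, 1.1]),
        ("ind2", "Equus sp", "grazer", 20.0, 380.0, [-9.0, -8.5, -8.8, -9.2]),
        ("ind3", "Cervus sp", "browser", -34.0, 150.0, [-12.0, -11.5, -12.2, -11.8]),
    ]
    for ind, taxon, diet, lat, mass, vals in specs:
        for i, v in enumerate(vals):
            rows.append((ind, taxon, diet, lat, mass, f"{ind}_t1", 2.0 * i, v))
    return SerialDataset.from_frame(make_table(rows))


@pytest.fixture
def unbalanced_dataset():
    """Individuals with 2, 3 and 7 samples and mixed latitudes."""
    rows = []
    design = [
        ("a1", "Bison sp", "grazer", -34.0, 600.0, 2),
        ("a2", "Bison sp", "grazer", 29.0, 600.0, 3),
        ("a3", "Bison sp", "grazer", 53.0, 600.0, 7),
    ]
    rng = np.random.default_rng(11)
    for ind, taxon, diet, lat, mass, n in design:
        for i in range(n):
            rows.append(
                (ind, taxon, diet, lat, mass, f"{ind}_t1", 2.0 * i,
                 float(rng.normal(-2.0, 1.0)))
            )
    return SerialDataset.from_frame(make_table(rows))
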