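import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isoniche.io import IndividualRecord, SerialDataset
from isoniche.metrics import (
    bin_individual_ranges,
    group_range_table,
    individual_summary_table,
    mean_iii_by_diet,
    proportion_le,
    species_niche,
    summarize_individual,
)
from conftest import make_table


def _record(values, ind="i1", taxon="t", diet="browser"):
    df = pd.DataFrame(
        {
            "tooth_id": "t1",
            "position_mm": np.arange(len(values), dtype=float),
            "d13c": values,
            "source": "fixture",
        }
    )
    return IndividualRecord(ind, taxon, diet, 10.0, 50.0, df)


class TestSummarizeIndividual:
    def test_constant_samples(self):
        s = summarize_individual(_record([-8.0, -8.0, -8.0]))
        assert s.range == 0 and s.sd == 0 and s.mean == -8.0

    def test_arithmetic_oracle(self):
        # mean and (n-1) sd computed by hand: deviations -1.0, 0.1, 0.9
        s = summarize_individual(_record([-9.1, -8.0, -7.2]))
        assert s.min == -9.1 and s.max == -7.2
        assert s.range == pytest.approx(1.9)
        assert s.mean == pytest.approx(-8.1)
        assert s.sd == pytest.approx(math.sqrt((1.0 + 0.01 + 0.81) / 2))

    def test_single_sample_sd_flagged(self):
        s = summarize_individual(_record([-11.4]))
        assert s.range == 0 and math.isnan(s.sd)

    def test_no_finite_values_rejected(self):
        with pytest.raises(ValueError):
            summarize_individual(_record([float("nan")]))


def _species_fixture(values_by_ind, diet="grazer", taxon="Equus sp"):
    rows = []
    for ind, vals in values_by_ind.items():
        for i, v in enumerate(vals):
            rows.append((ind, taxon, diet, 10.0, 400.0, f"{ind}_t1", 2.0 * i, v))
    return SerialDataset.from_frame(make_table(rows))


class TestSpeciesNiche:
    def test_iii_is_range_ratio(self):
        # avg individual range 1.1, species range 13.4 -> III ~ 0.082
        ds = _species_fixture(
            {"i1": [-12.0, -10.9], "i2": [0.3, 1.4], "i3": [-6.0, -4.9]}
        )
        niche = species_niche(ds, min_individuals=1)
        row = niche.iloc[0]
        assert row["avg_individual_range"] == pytest.approx(1.1)
        assert row["species_total_range"] == pytest.approx(13.4)
        assert row["iii"] == pytest.approx(1.1 / 13.4)
        assert row["iii"] == pytest.approx(0.082, abs=5e-4)

    def test_single_individual_iii_is_one(self):
        ds = _species_fixture({"i1": [-9.0, -7.0]})
        niche = species_niche(ds, min_individuals=1)
        assert niche.iloc[0]["iii"] == pytest.approx(1.0)

    def test_all_constant_individuals_iii_zero(self):
        ds = _species_fixture({"i1": [-9.0, -9.0], "i2": [-5.0, -5.0]})
        niche = species_niche(ds, min_individuals=1)
        assert niche.iloc[0]["iii"] == 0.0

    def test_zero_species_range_flagged_undefined(self):
        ds = _species_fixture({"i1": [-8.0, -8.0], "i2": [-8.0, -8.0]})
        niche = species_niche(ds, min_individuals=1)
        assert math.isnan(niche.iloc[0]["iii"])

    def test_empty_dataset_rejected(self):
        ds = _species_fixture({"i1": [-8.0]})
        with pytest.raises(ValueError):
            species_niche(SerialDataset(ds.table.iloc[:0]))

    def test_min_individuals_threshold(self):
        ds = _species_fixture({"i1": [-9.0, -7.0]})
        with pytest.raises(ValueError):
            species_niche(ds, min_individuals=3)

    @given(
        shift=st.floats(-20, 20),
        scale=st.floats(0.1, 5.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_iii_shift_invariant_scale_equivariant_ranges(self, shift, scale):
        # III is a range ratio: invariant under adding a constant and under
        # multiplying all values by a (positive) constant
        base = {"i1": [-12.0, -10.0, -11.0], "i2": [-6.0, -5.0, -5.5]}
        ds0 = _species_fixture(base)
        ds1 = _species_fixture(
            {k: [scale * v + shift for v in vals] for k, vals in base.items()}
        )
        i0 = species_niche(ds0, min_individuals=1).iloc[0]["iii"]
        i1 = species_niche(ds1, min_individuals=1).iloc[0]["iii"]
        assert i1 == pytest.approx(i0, rel=1e-9)

    def test_avg_individual_range_bounded_by_species_range(self, tiny_dataset):
        niche = species_niche(tiny_dataset, min_individuals=1)
        assert (niche["avg_individual_range"] <= niche["species_total_range"] + 1e-12).all()
        assert ((niche["iii"] >= 0) & (niche["iii"] <= 1)).all()

    def test_adding_individual_cannot_shrink_species_range(self):
        small = _species_fixture({"i1": [-9.0, -7.0]})
        bigger = _species_fixture({"i1": [-9.0, -7.0], "i2": [-8.0, -8.5]})
        r0 = species_niche(small, min_individuals=1).iloc[0]["species_total_range"]
        r1 = species_niche(bigger, min_individuals=1).iloc[0]["species_total_range"]
        assert r1 >= r0


class TestMeanIII:
    def test_unweighted_mean_over_species(self):
        niche = pd.DataFrame(
            {
                "taxon": ["a", "b"],
                "diet": ["grazer", "grazer"],
                "n_individuals": [3, 3],
                "species_total_range": [5.0, 5.0],
                "avg_individual_range": [1.0, 2.0],
                "iii": [0.2, 0.4],
            }
        )
        out = mean_iii_by_diet(niche)
        assert out.loc[0, "mean_iii"] == pytest.approx(0.3)
        assert out.loc[0, "n_species"] == 2


class TestBinning:
    def test_one_range_per_bin(self):
        bt = bin_individual_ranges([0.5, 1.5, 2.5, 3.5])
        assert list(bt["count"]) == [1, 1, 1, 1]
        assert bt.loc[2, "cum_proportion"] == pytest.approx(0.75)
        assert proportion_le([0.5, 1.5, 2.5, 3.5], 3.0) == pytest.approx(0.75)

    def test_right_closed_edges(self):
        # a range of exactly 1 belongs to the first bin (0 < x <= 1)
        bt = bin_individual_ranges([1.0, 1.0001])
        assert bt.loc[0, "count"] == 1 and bt.loc[1, "count"] == 1

    def test_all_in_first_bin(self):
        bt = bin_individual_ranges([0.5, 0.5, 0.5])
        assert bt.loc[0, "proportion"] == 1.0

    def test_zero_ranges_counted_in_first_bin(self):
        bt = bin_individual_ranges([0.0, 0.5])
        assert bt.loc[0, "count"] == 2

    @given(
        st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=30, deadline=None)
    def test_proportions_sum_to_one_and_cum_monotone(self, ranges):
        bt = bin_individual_ranges(ranges)
        assert bt["proportion"].sum() == pytest.approx(1.0)
        assert (np.diff(bt["cum_proportion"]) >= -1e-12).all()

    def test_per_group_proportions(self):
        bt = bin_individual_ranges(
            [0.5, 1.5, 0.7], groups=["g", "g", "b"]
        )
        for _, grp in bt.groupby("group"):
            assert grp["proportion"].sum() == pytest.approx(1.0)


class TestGroupRangeTable:
    def test_two_constant_groups(self):
        summ = pd.DataFrame(
            {
                "diet": ["browser"] * 3 + ["grazer"] * 3,
                "range": [1.0] * 6,
            }
        )
        out = group_range_table(summ)
        assert (out["mean"] == 1.0).all() and (out["sd"] == 0.0).all()
        assert out["n"].sum() == 6

    def test_single_group_rejected(self):
        summ = pd.DataFrame({"diet": ["browser"] * 3, "range": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            group_range_table(summ)

    def test_unknown_body_size_excluded(self):
        summ = pd.DataFrame(
            {
                "body_size": ["small", "large", "unknown", "small"],
                "range": [1.0, 2.0, 9.0, 3.0],
            }
        )
        out = group_range_table(summ, grouping="body_size")
        assert out["n"].sum() == 3
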