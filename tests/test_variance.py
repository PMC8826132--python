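import numpy as np
import pytest

from isoniche.simulate import SimulationParams, generate
from isoniche.variance import (
    grouped_values,
    nested_anova_mom,
    nested_reml,
    reml_loglik,
    variance_proportions,
)


def _groups_from_arrays(spec):
    """spec: list of species, each a list of per-individual value lists."""
    return [[np.asarray(ind, dtype=float) for ind in sp] for sp in spec]


def brute_force_coefficients(n_ij):
    """Direct evaluation of the unbalanced expected-MS multipliers."""
    a = len(n_ij)
    b = [len(row) for row in n_ij]
    n_i = [sum(row) for row in n_ij]
    N = sum(n_i)
    s1 = sum(sum(n**2 for n in row) / ni for row, ni in zip(n_ij, n_i))
    s2 = sum(n**2 for row in n_ij for n in row)
    n0 = (N - s1) / (sum(b) - a)
    n0p = (s1 - s2 / N) / (a - 1)
    nb0 = (N - sum(ni**2 for ni in n_i) / N) / (a - 1)
    return n0, n0p, nb0


def brute_force_ss(spec):
    """Naive double-loop sums of squares from definitions."""
    allv = [v for sp in spec for ind in sp for v in ind]
    grand = sum(allv) / len(allv)
    ss_sp = ss_ind = ss_w = 0.0
    for sp in spec:
        spv = [v for ind in sp for v in ind]
        spm = sum(spv) / len(spv)
        ss_sp += len(spv) * (spm - grand) ** 2
        for ind in sp:
            m = sum(ind) / len(ind)
            ss_ind += len(ind) * (m - spm) ** 2
            for v in ind:
                ss_w += (v - m) ** 2
    return ss_sp, ss_ind, ss_w


class TestNestedAnovaMoM:
    def test_all_identical_values(self):
        g = _groups_from_arrays([[[1.0, 1.0], [1.0, 1.0]], [[1.0, 1.0], [1.0, 1.0]]])
        table, comps = nested_anova_mom(g)
        assert table.ss_total == 0.0
        assert comps.total == 0.0
        assert all(np.isnan(p) for p in comps.proportions)

    def test_balanced_toy_closed_form(self):
        # a=2 species, b=2 individuals, n=2 samples, hand-chosen values
        spec = [[[0.0, 2.0], [4.0, 6.0]], [[10.0, 12.0], [20.0, 22.0]]]
        g = _groups_from_arrays(spec)
        table, comps = nested_anova_mom(g)
        # balanced collapse: multipliers are exactly (n, n, b n)
        assert table.n0 == pytest.approx(2.0)
        assert table.n0_prime == pytest.approx(2.0)
        assert table.nb0 == pytest.approx(4.0)
        # SS from the naive definition-based loops
        ss = brute_force_ss(spec)
        assert table.ss_species == pytest.approx(ss[0], rel=1e-12)
        assert table.ss_individual == pytest.approx(ss[1], rel=1e-12)
        assert table.ss_within == pytest.approx(ss[2], rel=1e-12)
        # textbook closed form: sigma_w = MS_w, sigma_I = (MS_I - MS_w)/n,
        # sigma_S = (MS_S - MS_I)/(b n)
        ms_w, ms_i, ms_s = table.ms_within, table.ms_individual, table.ms_species
        assert comps.sigma2_within == pytest.approx(ms_w)
        assert comps.sigma2_individual == pytest.approx((ms_i - ms_w) / 2)
        assert comps.sigma2_species == pytest.approx((ms_s - ms_i) / 4)

    def test_unbalanced_coefficients_against_oracle(self):
        rng = np.random.default_rng(9)
        n_ij = [[2, 3, 5], [3, 5], [2, 2, 5, 3]]
        spec = [[list(rng.normal(i, 1.0, size=n)) for n in row]
                for i, row in enumerate(n_ij)]
        table, _ = nested_anova_mom(_groups_from_arrays(spec))
        n0, n0p, nb0 = brute_force_coefficients(n_ij)
        assert table.n0 == pytest.approx(n0, abs=1e-10)
        assert table.n0_prime == pytest.approx(n0p, abs=1e-10)
        assert table.nb0 == pytest.approx(nb0, abs=1e-10)
        ss = brute_force_ss(spec)
        assert table.ss_total == pytest.approx(sum(ss), rel=1e-9)

    def test_ss_decomposition_equals_total(self):
        rng = np.random.default_rng(4)
        spec = [
            [list(rng.normal(mu, 1.0, size=rng.integers(2, 8)))
             for _ in range(rng.integers(2, 5))]
            for mu in (0.0, 3.0, -2.0)
        ]
        table, _ = nested_anova_mom(_groups_from_arrays(spec))
        allv = np.concatenate([np.concatenate(sp) for sp in
                               _groups_from_arrays(spec)])
        ss_total_direct = float(np.sum((allv - allv.mean()) ** 2))
        assert table.ss_total == pytest.approx(ss_total_direct, rel=1e-9)
        assert table.df_species + table.df_individual + table.df_within == \
            allv.size - 1

    def test_negative_component_truncated_and_flagged(self):
        # individuals within species nearly identical but species far apart,
        # with large within noise -> sigma2_individual estimate negative
        rng = np.random.default_rng(2)
        spec = [
            [list(rng.normal(0.0, 5.0, size=6)) for _ in range(6)],
            [list(rng.normal(0.5, 5.0, size=6)) for _ in range(6)],
        ]
        _, comps = nested_anova_mom(_groups_from_arrays(spec))
        assert comps.sigma2_individual >= 0 and comps.sigma2_species >= 0
        assert comps.truncated  # at least one truncation flagged

    def test_degenerate_nesting_rejected(self):
        g = _groups_from_arrays([[[1.0], [2.0]], [[3.0], [4.0]]])
        with pytest.raises(ValueError, match="single sample"):
            nested_anova_mom(g)
        with pytest.raises(ValueError, match=">= 2 species"):
            nested_anova_mom(_groups_from_arrays([[[1.0, 2.0]]]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        spec = [
            [list(rng.normal(mu, 1.0, size=5)) for _ in range(4)]
            for mu in (0.0, 2.0)
        ]
        g1 = _groups_from_arrays(spec)
        g2 = _groups_from_arrays([sp[::-1] for sp in spec[::-1]])
        _, c1 = nested_anova_mom(g1)
        _, c2 = nested_anova_mom(g2)
        for x, y in zip(c1.proportions, c2.proportions):
            assert x == pytest.approx(y, abs=1e-12)


class TestNestedREML:
    def test_internally_constant_individuals_drive_sigma_within_to_zero(self):
        rng = np.random.default_rng(1)
        spec = [
            [[float(rng.normal(mu, 2.0))] * 4 for _ in range(5)]
            for mu in (0.0, 4.0, -3.0)
        ]
        comps = nested_reml(_groups_from_arrays(spec))
        assert comps.sigma2_within <= 1e-6

    def test_cross_method_agreement_on_balanced_data(self):
        # balanced design: REML and MoM estimate the same quantities
        p = SimulationParams(
            n_species={"browser": 10, "grazer": 10, "mixed_feeder": 10},
            individuals_per_species=5, individuals_poisson_mean=None,
            samples_per_tooth=6, samples_poisson_mean=None,
            diet_means={"browser": -6.0, "grazer": -6.0, "mixed_feeder": -6.0},
            sigma_species=2.0, sigma_individual=np.sqrt(2.0),
            sigma_within=1.0, seed=30,
        )
        ds, _ = generate(p)
        g = grouped_values(ds.table)
        _, mom = nested_anova_mom(g)
        reml = nested_reml(g)
        for m, r in zip(
            (mom.sigma2_species, mom.sigma2_individual, mom.sigma2_within),
            (reml.sigma2_species, reml.sigma2_individual, reml.sigma2_within),
        ):
            assert r == pytest.approx(m, rel=0.10)

    def test_reml_against_statsmodels_mixedlm(self):
        # independent oracle: generic mixed-model REML on the same data
        statsmodels = pytest.importorskip("statsmodels.api")
        p = SimulationParams(
            n_species={"browser": 4, "grazer": 4, "mixed_feeder": 4},
            individuals_per_species=5, individuals_poisson_mean=4.0,
            samples_per_tooth=7, samples_poisson_mean=7.0,
            sigma_species=2.0, sigma_individual=1.5, sigma_within=0.6,
            seed=42,
        )
        ds, _ = generate(p)
        comps = nested_reml(grouped_values(ds.table))
        md = statsmodels.MixedLM.from_formula(
            "d13c ~ 1", groups="taxon", re_formula="1",
            vc_formula={"ind": "0 + C(individual_id)"}, data=ds.table,
        )
        fit = md.fit(reml=True)
        assert comps.sigma2_species == pytest.approx(
            float(fit.cov_re.iloc[0, 0]), rel=1e-3
        )
        assert comps.sigma2_individual == pytest.approx(
            float(fit.vcomp[0]), rel=1e-3
        )
        assert comps.sigma2_within == pytest.approx(float(fit.scale), rel=1e-3)

    def test_reml_at_optimum_beats_perturbations(self):
        rng = np.random.default_rng(12)
        spec = [
            [list(rng.normal(mu + rng.normal(0, 1), 0.7, size=5))
             for _ in range(4)]
            for mu in (0.0, 2.0, -1.0, 4.0)
        ]
        g = _groups_from_arrays(spec)
        comps = nested_reml(g)
        theta = (comps.sigma2_species, comps.sigma2_individual,
                 comps.sigma2_within)
        ll_hat = reml_loglik(theta, g)
        for bump in np.eye(3) * 0.05:
            assert reml_loglik(tuple(np.array(theta) + bump), g) <= ll_hat + 1e-6


class TestVarianceProportions:
    @pytest.mark.parametrize(
        "comps, expected",
        [((1, 1, 2), (0.25, 0.25, 0.5)), ((0, 0, 3), (0.0, 0.0, 1.0))],
    )
    def test_normalization(self, comps, expected):
        assert variance_proportions(*comps) == pytest.approx(expected)

    def test_all_zero_flagged(self):
        assert all(np.isnan(p) for p in variance_proportions(0, 0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            variance_proportions(-1, 1, 1)
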