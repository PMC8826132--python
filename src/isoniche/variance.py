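"""Nested variance partitioning of d13C across three scales: between
species, between individuals within species, within individuals.

Two estimators of the random-effects model

    y_ijk = mu + S_i + I_ij + e_ijk,
    S_i ~ N(0, s2_species),  I_ij ~ N(0, s2_individual),
    e_ijk ~ N(0, s2_within),  all independent,

are provided:

``nested_anova_mom``
    Method-of-moments two-level nested ANOVA for unbalanced data
    (Sokal–Rohlf-style expected mean squares).  With a species, b_i
    individuals in species i, n_ij samples in individual (i, j),
    n_i. = sum_j n_ij and N = sum n_i., the expected-MS multipliers are

        n0  = (N - sum_i (sum_j n_ij^2) / n_i.) / (sum_i b_i - a)
        n0' = (sum_i (sum_j n_ij^2) / n_i. - (sum_ij n_ij^2) / N) / (a - 1)
        nb0 = (N - sum_i n_i.^2 / N) / (a - 1)

    and the components solve E[MS_within] = s2_w,
    E[MS_ind] = s2_w + n0 s2_I, E[MS_sp] = s2_w + n0' s2_I + nb0 s2_S.
    In a balanced design (b individuals of n samples each) the multipliers
    collapse to (n, n, b n).  Negative solutions are truncated to zero and
    flagged; proportions are renormalized.

``nested_reml``
    Restricted maximum likelihood for the same model.  The restricted
    log-likelihood is evaluated in closed form from per-individual
    sufficient statistics (sample count, mean, within-individual SS) using
    a rank-one update for the species level, so each evaluation is
    O(number of individuals); it is maximized with bounded L-BFGS-B
    (non-negativity by construction), warm-started at the truncated
    method-of-moments estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "NestedAnovaTable",
    "VarianceComponents",
    "grouped_values",
    "nested_anova_mom",
    "nested_reml",
    "variance_proportions",
    "reml_loglik",
]


@dataclass(frozen=True)
class NestedAnovaTable:
    ss_species: float
    ss_individual: float
    ss_within: float
    df_species: int
    df_individual: int
    df_within: int
    ms_species: float
    ms_individual: float
    ms_within: float
    n0: float
    n0_prime: float
    nb0: float

    @property
    def ss_total(self) -> float:
        return self.ss_species + self.ss_individual + self.ss_within


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_species: float
    sigma2_individual: float
    sigma2_within: float
    method: str  # "mom" | "reml"
    truncated: tuple[str, ...] = ()
    converged: bool = True

    @property
    def total(self) -> float:
        return self.sigma2_species + self.sigma2_individual + self.sigma2_within

    @property
    def proportions(self) -> tuple[float, float, float]:
        return variance_proportions(
            self.sigma2_species, self.sigma2_individual, self.sigma2_within
        )


def variance_proportions(
    s2_species: float, s2_individual: float, s2_within: float
) -> tuple[float, float, float]:
    """Each non-negative component divided by their sum; NaNs if all zero."""
    comps = (s2_species, s2_individual, s2_within)
    if any(c < 0 for c in comps):
        raise ValueError(f"components must be non-negative, got {comps}")
    total = sum(comps)
    if total == 0:
        return (float("nan"),) * 3
    return tuple(c / total for c in comps)  # type: ignore[return-value]


def grouped_values(
    frame: pd.DataFrame,
    species_col: str = "taxon",
    individual_col: str = "individual_id",
    value_col: str = "d13c",
) -> list[list[np.ndarray]]:
    """Nest a flat table into species -> individual -> value arrays."""
    groups: list[list[np.ndarray]] = []
    for _, sp in frame.groupby(species_col, sort=True):
        inds = [
            grp[value_col].to_numpy(dtype=float)
            for _, grp in sp.groupby(individual_col, sort=True)
        ]
        groups.append(inds)
    return groups


def _check_nesting(groups: list[list[np.ndarray]]) -> None:
    if len(groups) < 2:
        raise ValueError("need >= 2 species")
    if not any(len(sp) >= 2 for sp in groups):
        raise ValueError("need >= 1 species with >= 2 individuals")
    if all(all(len(ind) < 2 for ind in sp) for sp in groups):
        raise ValueError(
            "degenerate nesting: every individual has a single sample "
            "(within-individual variance unidentifiable)"
        )
    for sp in groups:
        if len(sp) == 0:
            raise ValueError("species with zero individuals")
        for ind in sp:
            if len(ind) == 0:
                raise ValueError("individual with zero samples")


def _sums_of_squares(groups: list[list[np.ndarray]]):
    """SS at the three nested levels, from definitions."""
    all_vals = np.concatenate([v for sp in groups for v in sp])
    grand = all_vals.mean()
    ss_sp = ss_ind = ss_w = 0.0
    for sp in groups:
        sp_vals = np.concatenate(sp)
        sp_mean = sp_vals.mean()
        ss_sp += sp_vals.size * (sp_mean - grand) ** 2
        for ind in sp:
            m = ind.mean()
            ss_ind += ind.size * (m - sp_mean) ** 2
            ss_w += float(np.sum((ind - m) ** 2))
    return float(ss_sp), float(ss_ind), float(ss_w)


def nested_anova_mom(
    groups: list[list[np.ndarray]],
) -> tuple[NestedAnovaTable, VarianceComponents]:
    """Unbalanced two-level nested ANOVA by expected mean squares.

    ``groups`` nests species -> individuals -> 1-D value arrays
    (see :func:`grouped_values`).  Raises on degenerate nesting; an input
    with zero total SS yields all-zero components (proportions NaN).
    """
    _check_nesting(groups)

    a = len(groups)
    b = [len(sp) for sp in groups]
    n_ij = [[ind.size for ind in sp] for sp in groups]
    n_i = [sum(row) for row in n_ij]
    n_total = sum(n_i)
    sum_b = sum(b)

    ss_sp, ss_ind, ss_w = _sums_of_squares(groups)
    df_sp = a - 1
    df_ind = sum_b - a
    df_w = n_total - sum_b
    if df_ind == 0 or df_w == 0:
        raise ValueError("zero degrees of freedom at a nested level")

    ms_sp = ss_sp / df_sp
    ms_ind = ss_ind / df_ind
    ms_w = ss_w / df_w

    sum_nij2_over_ni = sum(
        sum(n**2 for n in row) / ni for row, ni in zip(n_ij, n_i)
    )
    sum_nij2 = sum(n**2 for row in n_ij for n in row)
    n0 = (n_total - sum_nij2_over_ni) / df_ind
    n0_prime = (sum_nij2_over_ni - sum_nij2 / n_total) / df_sp
    nb0 = (n_total - sum(ni**2 for ni in n_i) / n_total) / df_sp

    table = NestedAnovaTable(
        ss_species=ss_sp, ss_individual=ss_ind, ss_within=ss_w,
        df_species=df_sp, df_individual=df_ind, df_within=df_w,
        ms_species=ms_sp, ms_individual=ms_ind, ms_within=ms_w,
        n0=n0, n0_prime=n0_prime, nb0=nb0,
    )

    s2_w = ms_w
    s2_i = (ms_ind - ms_w) / n0
    s2_s = (ms_sp - ms_w - n0_prime * s2_i) / nb0

    truncated = []
    if s2_i < 0:
        truncated.append("sigma2_individual")
        s2_i = 0.0
        # re-solve the species equation under the truncated sigma2_individual
        s2_s = (ms_sp - ms_w) / nb0
    if s2_s < 0:
        truncated.append("sigma2_species")
        s2_s = 0.0

    comps = VarianceComponents(
        sigma2_species=float(s2_s),
        sigma2_individual=float(s2_i),
        sigma2_within=float(s2_w),
        method="mom",
        truncated=tuple(truncated),
    )
    return table, comps


# ---------------------------------------------------------------------------
# REML


def _suffstats(groups: list[list[np.ndarray]]):
    """Per-species (n_ij, ybar_ij) arrays plus pooled within-individual SS."""
    stats = []
    ss_w = 0.0
    n_total = 0
    m_total = 0
    for sp in groups:
        n = np.array([ind.size for ind in sp], dtype=float)
        ybar = np.array([ind.mean() for ind in sp], dtype=float)
        ss_w += sum(float(np.sum((ind - ind.mean()) ** 2)) for ind in sp)
        stats.append((n, ybar))
        n_total += int(n.sum())
        m_total += len(sp)
    return stats, ss_w, n_total, m_total


def reml_loglik(
    theta: tuple[float, float, float], groups: list[list[np.ndarray]]
) -> float:
    """Restricted log-likelihood of (s2_species, s2_individual, s2_within).

    Exact closed form: within-individual contrasts contribute
    (N - M) residual degrees of freedom at variance s2_within; the vector
    of scaled individual means per species is normal with a diagonal plus
    rank-one covariance, handled by Sherman-Morrison.  The grand mean is
    profiled out via the REML adjustment log|X' V^-1 X|.
    """
    return _loglik_from_stats(theta, *_suffstats(groups))


def _loglik_from_stats(theta, stats, ss_w, n_total, m_total) -> float:
    s2_s, s2_i, s2_w = (float(t) for t in theta)
    if s2_w <= 0 or s2_s < 0 or s2_i < 0:
        return -math.inf

    logdet = (n_total - m_total) * math.log(s2_w)
    quad = ss_w / s2_w
    xvx = 0.0   # X' V^-1 X with X = 1
    xvy = 0.0   # X' V^-1 y
    for n, ybar in stats:
        # scaled means m_j = sqrt(n_j) ybar_j have cov D + s2_s u u',
        # D_jj = s2_w + n_j s2_i, u_j = sqrt(n_j)
        d = s2_w + n * s2_i
        u2_over_d = n / d          # (u_j)^2 / D_jj
        denom = 1.0 + s2_s * float(u2_over_d.sum())
        logdet += float(np.log(d).sum()) + math.log(denom)
        m_over_d = n * ybar / d    # u_j m_j / D_jj
        quad += float((n * ybar**2 / d).sum()) - s2_s * float(m_over_d.sum()) ** 2 / denom
        xvx += float(u2_over_d.sum()) / denom
        xvy += float(m_over_d.sum()) / denom
    quad -= xvy**2 / xvx
    return -0.5 * (
        (n_total - 1) * math.log(2 * math.pi) + logdet + math.log(xvx) + quad
    )


def nested_reml(
    groups: list[list[np.ndarray]],
    tol: float = 1e-8,
    maxiter: int = 500,
) -> VarianceComponents:
    """REML estimates of the three nested variance components.

    Non-negativity is enforced by bounded search; optimization stops at a
    relative log-likelihood tolerance of ``tol``.  Raises on
    non-convergence, carrying the optimizer message.
    """
    _check_nesting(groups)
    _, mom = nested_anova_mom(groups)
    suff = _suffstats(groups)
    all_vals = np.concatenate([v for sp in groups for v in sp])
    scale = max(float(np.var(all_vals)), 1e-12)

    x0 = np.array(
        [
            max(mom.sigma2_species, 1e-3 * scale),
            max(mom.sigma2_individual, 1e-3 * scale),
            max(mom.sigma2_within, 1e-6 * scale),
        ]
    )
    bounds = [(0.0, None), (0.0, None), (1e-12 * scale, None)]

    def neg(theta):
        return -_loglik_from_stats(theta, *suff)

    res = minimize(
        neg, x0, method="Powell", bounds=bounds,
        options={"ftol": tol, "xtol": 1e-8, "maxiter": maxiter},
    )
    if not res.success:
        # one retry from a neutral start before declaring non-convergence
        x_alt = np.array([scale / 3.0, scale / 3.0, scale / 3.0])
        res = minimize(
            neg, x_alt, method="Powell", bounds=bounds,
            options={"ftol": tol, "xtol": 1e-8, "maxiter": maxiter},
        )
    if not res.success:
        raise RuntimeError(
            f"REML did not converge: {res.message} "
            f"(nit={res.nit}, x={res.x.tolist()})"
        )
    s2_s, s2_i, s2_w = (max(float(v), 0.0) for v in res.x)
    return VarianceComponents(
        sigma2_species=s2_s,
        sigma2_individual=s2_i,
        sigma2_within=s2_w,
        method="reml",
        converged=True,
    )
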