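"""Rank-based group comparisons: Kruskal-Wallis across diet or body-size
groups and Dunn's pairwise post hoc test.

Dunn's z for groups a, b uses pooled mid-ranks with tie correction:

    z_ab = (Rbar_a - Rbar_b) /
           sqrt([N(N+1)/12 - sum(t^3 - t) / (12(N-1))] (1/n_a + 1/n_b))

with two-sided p from the standard normal.  Because the p-value adjustment
convention behind published tables is often unstated, results carry both
unadjusted and adjusted columns side by side.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

ADJUSTMENTS = ("none", "holm", "bonferroni")


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_unadjusted: float
    p_adjusted: float


@dataclass(frozen=True)
class RankTestResult:
    h: float
    df: int
    p_value: float
    rank_means: dict[str, float]
    pairwise: list[PairwiseComparison] = field(default_factory=list)


def _validate_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        out[str(name)] = arr
    pooled = np.concatenate(list(out.values()))
    if np.unique(pooled).size < 2:
        raise ValueError("all values tied; rank statistics undefined")
    return out


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = groups - 1)."""
    g = _validate_groups(groups)
    h, p = stats.kruskal(*g.values())
    pooled = np.concatenate(list(g.values()))
    ranks = stats.rankdata(pooled)
    rank_means = {}
    start = 0
    for name, vals in g.items():
        rank_means[name] = float(ranks[start : start + vals.size].mean())
        start += vals.size
    return RankTestResult(
        h=float(h), df=len(g) - 1, p_value=float(p), rank_means=rank_means
    )


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "holm":
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"adjustment must be one of {ADJUSTMENTS}")


def dunn_pairwise(
    groups: Mapping[str, Sequence[float]], adjustment: str = "holm"
) -> RankTestResult:
    """Kruskal-Wallis plus Dunn's z and p for every unordered pair."""
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"adjustment must be one of {ADJUSTMENTS}")
    kw = kruskal_wallis(groups)
    g = _validate_groups(groups)
    pooled = np.concatenate(list(g.values()))
    n = pooled.size

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term

    names = list(g)
    zs, ps, pairs = [], [], []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / g[a].size + 1.0 / g[b].size))
        z = (kw.rank_means[a] - kw.rank_means[b]) / se if se > 0 else 0.0
        zs.append(z)
        ps.append(2.0 * stats.norm.sf(abs(z)))
        pairs.append((a, b))
    p_arr = np.asarray(ps)
    p_adj = _adjust(p_arr, adjustment)
    pairwise = [
        PairwiseComparison(a, b, float(z), float(p), float(pa))
        for (a, b), z, p, pa in zip(pairs, zs, p_arr, p_adj)
    ]
    return RankTestResult(
        h=kw.h, df=kw.df, p_value=kw.p_value,
        rank_means=kw.rank_means, pairwise=pairwise,
    )
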