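"""Nonparametric statistics shared across the pipeline.

All group contrasts in the package are rank based: two-group comparisons use
the Mann-Whitney U (rank-sum) test, multi-group comparisons use Kruskal-Wallis
with Dunn's post-hoc z-tests on the pooled ranks. Small two-group samples are
tested by exhaustive enumeration of all label assignments, which is exact even
in the presence of ties; larger samples use the tie-corrected normal
approximation (standard single-cell practice).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "rank_sum_test",
    "kruskal_wallis",
    "dunn_posthoc",
    "DunnResult",
    "EXACT_MAX_N",
]

#: largest per-group size for which the rank-sum test enumerates exactly
EXACT_MAX_N = 8


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for group x vs group y, ties counted as 1/2."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _rank_sum_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p by full enumeration of C(n1+n2, n1) group assignments.

    Valid with ties because the permutation distribution is built from the
    observed pooled values themselves.
    """
    pooled = np.concatenate([x, y])
    n = pooled.size
    n1 = x.size
    u_obs = _u_statistic(x, y)
    mu = n1 * (n - n1) / 2.0
    d_obs = abs(u_obs - mu)
    n_extreme = 0
    n_total = 0
    idx_all = frozenset(range(n))
    for idx in combinations(range(n), n1):
        a = pooled[list(idx)]
        b = pooled[list(idx_all - set(idx))]
        n_total += 1
        if abs(_u_statistic(a, b) - mu) >= d_obs - 1e-12:
            n_extreme += 1
    return u_obs, n_extreme / n_total


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = EXACT_MAX_N
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where ``U`` is the statistic for the first group.
    Exact enumeration is used when both groups have at most ``exact_max_n``
    observations; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires two non-empty groups")
    if x.size <= exact_max_n and y.size <= exact_max_n:
        return _rank_sum_exact(x, y)
    res = _sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H and p across ``groups``. Requires >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # every observation tied: no evidence of difference
    h, p = _sps.kruskal(*arrays)
    return float(h), float(p)


@dataclass(frozen=True)
class DunnResult:
    """One pairwise Dunn contrast from a shared pooled ranking."""

    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adj: float
    n_a: int
    n_b: int


def dunn_posthoc(
    groups: dict[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]] | None = None,
    n_tests: int | None = None,
) -> list[DunnResult]:
    """Dunn's post-hoc z-tests on the pooled ranks of ``groups``.

    Mean-rank differences are standardised with the tie-corrected variance of
    the pooled ranking and converted to two-sided normal p-values. ``pairs``
    selects which contrasts to report (default: all pairs); ``n_tests`` is the
    Bonferroni family size (default: the number of reported pairs). Adjusted
    p-values are never smaller than raw ones.
    """
    names = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    pooled = np.concatenate([arrays[k] for k in names])
    n_total = pooled.size
    ranks = _sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    sizes: dict[str, int] = {}
    offset = 0
    for k in names:
        n_k = arrays[k].size
        mean_rank[k] = float(ranks[offset : offset + n_k].mean()) if n_k else np.nan
        sizes[k] = n_k
        offset += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    if pairs is None:
        pairs = list(combinations(names, 2))
    m = n_tests if n_tests is not None else len(pairs)
    out: list[DunnResult] = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p_raw = float(2.0 * _sps.norm.sf(abs(z)))
        p_adj = float(min(1.0, p_raw * m))
        out.append(DunnResult(a, b, float(z), p_raw, p_adj, sizes[a], sizes[b]))
    return out


def mannwhitney_vectorized(
    values: np.ndarray, in_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided Mann-Whitney U (in-group vs rest), tie-corrected.

    ``values`` is an (n_rows, n_obs) array; ``in_mask`` a boolean vector over
    observations. Returns ``(U, p)`` arrays of length n_rows. Uses the normal
    approximation with continuity correction, matching the scalar asymptotic
    path of :func:`rank_sum_test`.
    """
    values = np.asarray(values, dtype=float)
    n1 = int(in_mask.sum())
    n2 = int((~in_mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    ranks = _sps.rankdata(values, axis=1)
    r1 = ranks[:, in_mask].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per row
    tie_term = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(values[i], return_counts=True)
        tie_term[i] = (counts**3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u1 - mu) - 0.5) / sigma
    z = np.where(sigma > 0, np.maximum(z, 0.0), 0.0)
    p = 2.0 * _sps.norm.sf(z)
    return u1, np.minimum(p, 1.0)
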