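"""Shared statistical primitives.

The Wilcoxon rank-sum test here follows the convention used throughout the
pipeline for group comparisons: exact enumeration of the null distribution
for small samples (tie-aware, via mid-ranks), and the normal approximation
with tie and continuity corrections otherwise. SciPy's exact path refuses
tied data, which UMI-derived quantities produce routinely, hence the
enumeration is implemented here and cross-checked against SciPy on
tie-free inputs in the test suite.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

EXACT_LIMIT = 12  # exact enumeration when n1 + n2 <= this


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def rank_sum_test(x, y, exact_limit: int = EXACT_LIMIT) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x``
    (number of (x, y) pairs with x > y, ties counted half).

    For ``n1 + n2 <= exact_limit`` the p value is exact: all C(n1+n2, n1)
    assignments of the pooled mid-ranks to group 1 are enumerated and the
    two-sided p is the fraction of assignments whose rank sum is at least
    as extreme (in absolute deviation from the mean) as the observed one.
    Otherwise the normal approximation with tie correction and a 0.5
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValidationError("rank-sum test needs non-empty groups")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = ranks[:n1].sum()  # rank sum of group 1
    u = w - n1 * (n1 + 1) / 2.0
    mean_w = n1 * (n1 + n2 + 1) / 2.0

    if n1 + n2 <= exact_limit:
        # Enumerate all assignments of ranks to group 1; mid-ranks make the
        # null distribution depend on the observed tie pattern.
        dev = abs(w - mean_w)
        count = 0
        total = comb(n1 + n2, n1)
        for idx in combinations(range(n1 + n2), n1):
            ws = ranks[list(idx)].sum()
            if abs(ws - mean_w) >= dev - 1e-12:
                count += 1
        p = count / total
        return u, min(1.0, p)

    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_w <= 0:
        return u, 1.0
    dev = abs(w - mean_w) - 0.5  # continuity correction
    z = max(dev, 0.0) / sqrt(var_w)
    p = 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))
    return u, min(1.0, p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_upper_tail(overlap: int, universe: int, term_size: int, query_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, term_size, query_size)."""
    if overlap < 0 or term_size > universe or query_size > universe:
        raise ValidationError("inconsistent hypergeometric configuration")
    return float(sps.hypergeom.sf(overlap - 1, universe, term_size, query_size))
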