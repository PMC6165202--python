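"""Group-level nonparametric statistics: Friedman test across regions,
Wilcoxon signed-rank post-hocs, Bonferroni correction.

The Friedman test ranks each subject's scores across the k conditions
and evaluates the tie-corrected statistic

    Q = (k - 1) * sum_j (R_j - n(k+1)/2)^2 / (sum_ij r_ij^2 - n k (k+1)^2 / 4)

(R_j the column rank sums), referred to a chi-square with k-1 degrees of
freedom; an exact within-row permutation enumeration is available for
tiny tables.  The Wilcoxon signed-rank test uses exact 2^n sign
enumeration for n <= 15 paired differences and a tie-corrected normal
approximation beyond.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "friedman_test",
    "wilcoxon_signed_rank",
    "bonferroni",
]


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    p: float
    n: int
    corrected_alpha: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p-value must be in [0, 1]")


def _friedman_q(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman statistic from a subjects x conditions rank table."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    s = np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    denom = np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0
    if denom <= 0:      # every row fully tied
        return 0.0
    return float((k - 1) * s / denom)


def friedman_test(scores: np.ndarray, method: str = "chi2") -> StatResult:
    """Friedman test on a subjects x conditions score table.

    ``method="chi2"`` uses the chi-square approximation with k-1 degrees
    of freedom; ``method="exact"`` enumerates all (k!)^n within-row
    orderings of the observed values (tiny tables only) and returns
    P(Q_perm >= Q_obs).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("scores must be subjects x conditions with both >= 2")
    n, k = scores.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, scores)
    q = _friedman_q(ranks)
    if method == "chi2":
        p = float(sps.chi2.sf(q, k - 1)) if q > 0 else 1.0
        if q == 0.0:
            p = 1.0
    elif method == "exact":
        import math
        n_tables = math.factorial(k) ** n
        if n_tables > 500_000:
            raise ValueError(f"exact enumeration infeasible for ({n}, {k})")
        row_perms = [np.array(list(itertools.permutations(r))) for r in ranks]
        count = total = 0
        for choice in itertools.product(*[range(len(rp)) for rp in row_perms]):
            table = np.stack([row_perms[i][c] for i, c in enumerate(choice)])
            if _friedman_q(table) >= q - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatResult(test="friedman", statistic=q, p=p, n=n)


def wilcoxon_signed_rank(x, y, method: str = "auto") -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped.  The statistic is W = min(W+, W-).
    ``method="exact"`` (default for n <= 15) enumerates all 2^n sign
    patterns of the observed absolute-difference ranks, which remains
    valid under ties; ``method="approx"`` uses the tie-corrected normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if method == "auto":
        method = "exact" if n <= 15 else "approx"
    if method == "exact":
        # all 2^n sign assignments of the observed ranks
        signs = np.array(list(itertools.product([0, 1], repeat=n)), dtype=float)
        wp = signs @ ranks
        total = ranks.sum()
        wm = total - wp
        p = float(np.mean(np.minimum(wp, wm) <= w + 1e-12))
    elif method == "approx":
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
        p = min(p, 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatResult(test="wilcoxon_signed_rank", statistic=w, p=p, n=n)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected significance level alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m
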