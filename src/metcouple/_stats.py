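"""Shared statistical primitives.

Small-sample paths are exact by enumeration (Spearman permutation null,
rank-sum combination null); large samples use the standard asymptotic
approximations.  Midranks are used throughout so every statistic is
well defined under ties.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

# enumeration is used at or below these sizes, asymptotics above
SPEARMAN_EXACT_MAX_N = 9
RANKSUM_EXACT_MAX_N = 10

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def standardized_ranks(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midrank-transform rows of ``a`` and scale so that the dot product of
    two rows is their Spearman rho.

    Returns (standardized ranks, constant-row mask); constant rows are
    returned as all-zeros so their correlation with anything is 0.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    r = stats.rankdata(a, axis=1)
    r = r - r.mean(axis=1, keepdims=True)
    norm = np.sqrt((r ** 2).sum(axis=1))
    const = norm < _EPS
    norm[const] = 1.0
    return r / norm[:, None], const


def spearman_rho_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise Spearman rho between rows of ``x`` and rows of ``y``.

    Returns (rho matrix |x| x |y|, mask of undefined entries where either
    row is constant; those entries hold rho = 0).
    """
    rx, cx = standardized_ranks(x)
    ry, cy = standardized_ranks(y)
    rho = np.clip(rx @ ry.T, -1.0, 1.0)
    undef = cx[:, None] | cy[None, :]
    return rho, undef


def spearman_p_approx(rho, n: int):
    """Two-sided p for Spearman rho via the t approximation (df = n - 2)."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0 - _EPS, 0.0, p)
    return np.minimum(p, 1.0)


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    # rx, ry already standardized 1-row vectors
    return float(np.clip(rx @ ry, -1.0, 1.0))


def spearman_p_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p-value for Spearman rho, enumerating every
    ordering of ``y``.  Ties are handled with midranks; p is the fraction
    of orderings with |rho| at least the observed |rho|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > SPEARMAN_EXACT_MAX_N:
        raise ValueError(f"exact Spearman p limited to n <= {SPEARMAN_EXACT_MAX_N}")
    rx, cx = standardized_ranks(x)
    ry, cy = standardized_ranks(y)
    if cx[0] or cy[0]:
        return 1.0
    obs = abs(_rho_of_ranks(rx[0], ry[0]))
    perms = np.array(list(itertools.permutations(ry[0])))
    rhos = np.abs(np.clip(perms @ rx[0], -1.0, 1.0))
    return float((rhos >= obs - _EPS).sum()) / len(perms)


def spearman(x, y, method: str = "auto") -> tuple[float, float, bool]:
    """Spearman rho and two-sided p.

    method: 'auto' (exact for n <= 9, t approximation above), 'exact',
    or 'approx'.  Returns (rho, p, flagged) where flagged marks an
    undefined correlation (a constant input), reported as (0, 1, True).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("length mismatch")
    rho, undef = spearman_rho_matrix(x[None, :], y[None, :])
    if undef[0, 0]:
        return 0.0, 1.0, True
    r = float(rho[0, 0])
    if method == "auto":
        method = "exact" if n <= SPEARMAN_EXACT_MAX_N else "approx"
    if method == "exact":
        return r, spearman_p_exact(x, y), False
    return r, float(spearman_p_approx(r, n)), False


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney) with midranks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    statistic: float          # z statistic (tie-corrected, no continuity corr.)
    rank_sum: float           # midrank sum of the first sample
    p_value: float
    method: str


def _ranksum_z(w: float, ranks: np.ndarray, n1: int) -> float:
    n = ranks.size
    n2 = n - n1
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie = (counts ** 3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie)
    if var <= 0:
        return 0.0
    return (w - mean) / math.sqrt(var)


def rank_sum_test(x, y, alternative: str = "two-sided", method: str = "auto") -> RankSumResult:
    """Wilcoxon rank-sum test of the first sample against the second.

    alternative 'greater' tests x stochastically greater than y.  The exact
    path enumerates all assignments of the pooled midranks to the two
    groups; the asymptotic path uses the tie-corrected normal z without
    continuity correction (so identical samples give one-sided p = 0.5).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = x.size
    w = float(ranks[:n1].sum())
    z = _ranksum_z(w, ranks, n1)
    if method == "auto":
        method = "exact" if max(x.size, y.size) <= RANKSUM_EXACT_MAX_N else "approx"
    if method == "exact":
        n = pooled.size
        sums = np.array([sum(ranks[list(c)])
                         for c in itertools.combinations(range(n), n1)])
        total = sums.size
        mean = n1 * (n + 1) / 2.0
        if alternative == "greater":
            p = (sums >= w - _EPS).sum() / total
        elif alternative == "less":
            p = (sums <= w + _EPS).sum() / total
        elif alternative == "two-sided":
            p = (np.abs(sums - mean) >= abs(w - mean) - _EPS).sum() / total
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return RankSumResult(z, w, float(min(p, 1.0)), "exact")
    if alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    elif alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return RankSumResult(z, w, float(min(p, 1.0)), "approx")


# ---------------------------------------------------------------------------
# Multiple testing, enrichment, permutation p
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_upper(k: int, population: int, successes: int, draws: int) -> float:
    """Upper-tail hypergeometric P(X >= k) for an overlap of ``k`` between
    ``successes`` marked items and ``draws`` drawn items out of
    ``population``."""
    if draws == 0:
        raise ValueError("empty draw set")
    return float(stats.hypergeom.sf(k - 1, population, successes, draws))


def empirical_p(r: int, n: int) -> float:
    """Add-one permutation p-value (r + 1) / (n + 1)."""
    if n < 1 or r < 0 or r > n:
        raise ValueError("need 0 <= r <= n, n >= 1")
    return (r + 1) / (n + 1)


def empirical_p_two_sided(observed, null_values) -> np.ndarray:
    """Per-observation add-one empirical two-sided p against a null sample:
    (1 + #{|null| >= |obs|}) / (len(null) + 1)."""
    null_abs = np.sort(np.abs(np.asarray(null_values, dtype=float)))
    if null_abs.size == 0:
        raise ValueError("empty null sample")
    obs = np.abs(np.asarray(observed, dtype=float))
    n_ge = null_abs.size - np.searchsorted(null_abs, obs - _EPS, side="left")
    return (1.0 + n_ge) / (null_abs.size + 1.0)
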