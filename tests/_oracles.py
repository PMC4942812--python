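"""Independent brute-force oracles used to cross-check the package's
statistics.  Everything here is written from first principles (explicit
formulas, exhaustive enumeration, rational arithmetic) and must stay
independent of the implementation paths it checks."""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, sqrt

import numpy as np


def midranks(values) -> list[float]:
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    denom = sqrt((a ** 2).sum() * (b ** 2).sum())
    return float((a * b).sum() / denom) if denom > 0 else float("nan")


def spearman_exact(x, y) -> tuple[float, float]:
    """Spearman rho via the explicit rank formula and the exact two-sided
    permutation p over all orderings of y."""
    rx = midranks(x)
    rho = pearson(rx, midranks(y))
    hits = total = 0
    for perm in itertools.permutations(midranks(y)):
        r = pearson(rx, list(perm))
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    return rho, hits / total


def bh_stepup(p_values) -> list[float]:
    """Literal Benjamini-Hochberg step-up adjustment."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adj[i] = running
    return adj


def hypergeom_upper_exact(k: int, population: int, successes: int,
                          draws: int) -> Fraction:
    """P(X >= k) by rational tail summation."""
    total = Fraction(0)
    denom = comb(population, draws)
    for i in range(k, min(successes, draws) + 1):
        total += Fraction(comb(successes, i)
                          * comb(population - successes, draws - i), denom)
    return total


def ranksum_exact(x, y, alternative="two-sided") -> float:
    """Exact rank-sum p by enumerating every assignment of the pooled
    midranks to the first group."""
    pooled = list(x) + list(y)
    ranks = midranks(pooled)
    n1 = len(x)
    n = len(pooled)
    w_obs = sum(ranks[:n1])
    mean = n1 * (n + 1) / 2.0
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        w = sum(ranks[i] for i in combo)
        total += 1
        if alternative == "greater":
            hits += w >= w_obs - 1e-12
        elif alternative == "less":
            hits += w <= w_obs + 1e-12
        else:
            hits += abs(w - mean) >= abs(w_obs - mean) - 1e-12
    return hits / total


def auc_pair_counting(labels, scores) -> Fraction:
    """AUC as the concordant-pair fraction with half-credit ties, in
    rational arithmetic.  labels in {0, 1} (or {-1, +1})."""
    labels = [1 if l > 0 else 0 for l in labels]
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    num = Fraction(0)
    for p in pos:
        for q in neg:
            if p > q:
                num += 1
            elif p == q:
                num += Fraction(1, 2)
    return num / (len(pos) * len(neg))


def logrank_riskset(time, event, group) -> float:
    """Two-group log-rank chi-square via explicit risk-set summation."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var if var > 0 else 0.0


def ols_normal_equations(X, y) -> np.ndarray:
    """(intercept, coefs) from the normal equations on an intercept-
    augmented design."""
    X = np.asarray(X, dtype=float)
    design = np.column_stack([np.ones(len(X)), X])
    return np.linalg.solve(design.T @ design, design.T @ np.asarray(y, float))
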