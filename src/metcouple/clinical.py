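"""Clinical application: survival and receptor-status screening.

Predicted (or measured) metabolite levels are dichotomized at their
cohort median and the low/high groups compared with the two-group
log-rank test; a BH screen across metabolites flags survival-associated
ones.  Each metabolite's survival signal is also compared against the
best signal among its connected genes' expression, and metabolites are
tested for ER+/ER- differential levels with a two-sided rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from ._stats import bh_fdr, rank_sum_test


@dataclass
class SurvivalScreenRow:
    metabolite_id: str
    statistic: float          # log-rank chi-square, 1 df
    logrank_p: float
    direction: str            # median group with better survival: low | high | none
    n_low: int
    n_high: int
    flagged: bool = False     # ties emptied a group


def _observed_minus_expected(time, event, in_group) -> float:
    """O - E of the flagged group under the log-rank risk-set decomposition
    (used only to orient the direction of the effect)."""
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], in_group[order]
    o_minus_e = 0.0
    for tt in np.unique(t[e]):
        at_risk = t >= tt
        d = float((e & (t == tt)).sum())
        n = float(at_risk.sum())
        n1 = float((at_risk & g).sum())
        d1 = float((e & (t == tt) & g).sum())
        o_minus_e += d1 - d * n1 / n
    return o_minus_e


def km_logrank_median_split(
    values: pd.Series,
    time: pd.Series,
    event: pd.Series,
) -> SurvivalScreenRow:
    """Median-split log-rank test of one metabolite's levels.

    Samples at or below the median go to 'low' (the deterministic tie
    rule).  Fewer than 2 samples in a group flags the row with p = 1.
    """
    name = str(values.name) if values.name is not None else "?"
    v = values.to_numpy(dtype=float)
    t = time.loc[values.index].to_numpy(dtype=float)
    e = event.loc[values.index].to_numpy(dtype=bool)
    low = v <= np.median(v)
    n_low, n_high = int(low.sum()), int((~low).sum())
    if min(n_low, n_high) < 2:
        return SurvivalScreenRow(name, 0.0, 1.0, "none", n_low, n_high, True)
    res = logrank_test(t[low], t[~low], event_observed_A=e[low],
                       event_observed_B=e[~low])
    ome = _observed_minus_expected(t, e, low)
    direction = "low" if ome < 0 else ("high" if ome > 0 else "none")
    return SurvivalScreenRow(name, float(res.test_statistic),
                             float(res.p_value), direction, n_low, n_high)


def survival_screen(
    predicted: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One median-split log-rank row per metabolite, BH across metabolites."""
    rows = []
    for met in predicted.index:
        r = km_logrank_median_split(predicted.loc[met], time, event)
        rows.append({"metabolite_id": met, "statistic": r.statistic,
                     "logrank_p": r.logrank_p, "direction": r.direction,
                     "n_low": r.n_low, "n_high": r.n_high, "flagged": r.flagged})
    table = pd.DataFrame(rows, columns=["metabolite_id", "statistic",
                                        "logrank_p", "direction",
                                        "n_low", "n_high", "flagged"])
    table["q"] = bh_fdr(table["logrank_p"].to_numpy()) if len(table) else []
    table["significant"] = table["q"] < alpha
    return table


def gene_vs_metabolite_survival(
    screen: pd.DataFrame,
    expression: pd.DataFrame,
    pairs,
    time: pd.Series,
    event: pd.Series,
    rule: str = "min",
) -> pd.DataFrame:
    """Flag metabolites whose survival association beats that of every
    connected gene's expression.

    Each connected measured gene gets the same median-split log-rank
    treatment; a metabolite is 'stronger' when its p is below the
    minimum (default, most favorable to the genes) or mean gene p.
    Metabolites with no measured connected genes are marked
    incomparable.
    """
    if rule not in ("min", "mean"):
        raise ValueError("rule must be 'min' or 'mean'")
    genes_of: dict[str, set[str]] = {}
    for p in pairs:
        genes_of.setdefault(p.metabolite_id, set()).add(p.gene_id)
    cache: dict[str, float] = {}

    def gene_p(g: str) -> float:
        if g not in cache:
            cache[g] = km_logrank_median_split(expression.loc[g], time, event) \
                .logrank_p
        return cache[g]

    rows = []
    for r in screen.itertuples():
        genes = sorted(g for g in genes_of.get(r.metabolite_id, set())
                       if g in expression.index)
        if not genes:
            rows.append({"metabolite_id": r.metabolite_id, "metabolite_p":
                         r.logrank_p, "gene_p": np.nan, "n_genes": 0,
                         "stronger": False, "incomparable": True})
            continue
        ps = np.array([gene_p(g) for g in genes])
        ref = float(ps.min() if rule == "min" else ps.mean())
        rows.append({"metabolite_id": r.metabolite_id,
                     "metabolite_p": r.logrank_p, "gene_p": ref,
                     "n_genes": len(genes),
                     "stronger": bool(r.logrank_p < ref),
                     "incomparable": False})
    return pd.DataFrame(rows, columns=["metabolite_id", "metabolite_p",
                                       "gene_p", "n_genes", "stronger",
                                       "incomparable"])


def er_differential(
    predicted: pd.DataFrame,
    er_status: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided rank-sum test of each metabolite between ER+ and ER-
    samples, BH across metabolites; the direction column holds the
    median ER+ minus ER- difference."""
    er = er_status.loc[predicted.columns].astype(int).to_numpy()
    if len(np.unique(er)) < 2:
        raise ValueError("both ER groups must be present")
    pos, neg = er == 1, er == 0
    rows = []
    for met in predicted.index:
        v = predicted.loc[met].to_numpy(dtype=float)
        res = rank_sum_test(v[pos], v[neg], alternative="two-sided")
        rows.append({"metabolite_id": met, "statistic": res.statistic,
                     "p": res.p_value,
                     "median_diff": float(np.median(v[pos]) - np.median(v[neg]))})
    table = pd.DataFrame(rows, columns=["metabolite_id", "statistic", "p",
                                        "median_diff"])
    table["q"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    table["significant"] = table["q"] < alpha
    return table
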