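"""Raw-data gene-metabolite association layer.

Spearman tables per condition stratum with BH/FDR control, the
gene-label permutation null for coupling enrichment, and the
results-level contrasts: enrichment of highly expressed genes among
significantly associated ones, the substrate-versus-product correlation
shift, the coupling-versus-differential-expression relation, and the
expression-variance shift of association-carrying genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import (
    bh_fdr, empirical_p, hypergeom_upper, rank_sum_test,
    spearman, spearman_p_approx, spearman_rho_matrix,
)

STRATA = ("all", "noncancerous", "cancer")


def _check_samples(expression: pd.DataFrame, metabolites: pd.DataFrame):
    shared = expression.columns.intersection(metabolites.columns)
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    return shared


def spearman_table(
    expression: pd.DataFrame,
    metabolites: pd.DataFrame,
    pairs,
    stratum: str = "all",
    p_method: str = "auto",
) -> pd.DataFrame:
    """Per-pair Spearman rho, two-sided p and BH q over the shared samples.

    ``expression`` / ``metabolites`` must already be sliced to the
    stratum's samples; the stratum tag is recorded in the table.  Pairs
    whose gene or metabolite is unmeasured are skipped.  A constant
    vector makes the correlation undefined: the row is kept with
    rho = 0, p = 1 and ``flagged`` set.
    """
    shared = _check_samples(expression, metabolites)
    expr = expression[shared]
    mets = metabolites[shared]
    n = len(shared)
    rows = []
    gene_rows = {g: expr.loc[g].to_numpy() for g in expr.index}
    met_rows = {m: mets.loc[m].to_numpy() for m in mets.index}
    for pair in pairs:
        g, m = pair.gene_id, pair.metabolite_id
        if g not in gene_rows or m not in met_rows:
            continue
        rho, p, flagged = spearman(gene_rows[g], met_rows[m], method=p_method)
        rows.append((g, m, stratum, rho, p, n, flagged))
    table = pd.DataFrame(
        rows, columns=["gene_id", "metabolite_id", "stratum",
                       "rho", "p", "n_samples", "flagged"])
    table["q"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    return table[["gene_id", "metabolite_id", "stratum",
                  "rho", "p", "q", "n_samples", "flagged"]]


@dataclass
class PermutationTestResult:
    """Gene-label permutation null for the count of significant GM pairs."""
    n_sig_real: int
    n_sig_perm: np.ndarray
    n_perm: int
    alpha: float
    r: int = field(init=False)
    empiric_p: float = field(init=False)

    def __post_init__(self):
        self.n_sig_perm = np.asarray(self.n_sig_perm)
        self.r = int((self.n_sig_perm > self.n_sig_real).sum())
        self.empiric_p = empirical_p(self.r, self.n_perm)


def coupling_permutation_test(
    expression: pd.DataFrame,
    metabolites: pd.DataFrame,
    pairs,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Are connected GM pairs more associated than random GM pairs?

    The real statistic counts connected pairs with unadjusted Spearman
    p < alpha.  Each permutation round permutes gene labels and draws
    C = len(pairs) random gene-metabolite pairs without replacement
    (equivalently: C pairs drawn uniformly from all measured
    combinations) and counts significant ones; the empirical p-value is
    the add-one fraction of rounds beating the real count.  Both real
    and null counts use the asymptotic Spearman p so they are
    exchangeable.
    """
    if len(pairs) < 1 or n_perm < 1:
        raise ValueError("need at least one pair and one permutation")
    shared = _check_samples(expression, metabolites)
    expr = expression[shared].to_numpy()
    mets = metabolites[shared].to_numpy()
    n = len(shared)
    rho, undef = spearman_rho_matrix(expr, mets)
    pmat = spearman_p_approx(rho, n)
    pmat[undef] = 1.0
    sig = (pmat < alpha)

    gidx = {g: i for i, g in enumerate(expression.index)}
    midx = {m: i for i, m in enumerate(metabolites.index)}
    measured = [(p.gene_id, p.metabolite_id) for p in pairs
                if p.gene_id in gidx and p.metabolite_id in midx]
    c = len(measured)
    total = sig.size
    if c > total:
        raise ValueError("more pairs requested than available combinations")
    real = int(sum(sig[gidx[g], midx[m]] for g, m in measured))

    rng = np.random.default_rng(seed)
    flat = sig.ravel()
    counts = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        pick = rng.choice(total, size=c, replace=False)
        counts[b] = int(flat[pick].sum())
    return PermutationTestResult(real, counts, n_perm, alpha)


def expressed_gene_enrichment(
    expression: pd.DataFrame,
    association_table: pd.DataFrame,
    alpha: float = 0.05,
    expression_quantile: float = 0.75,
) -> float:
    """Hypergeometric upper-tail p for the overlap between genes carrying a
    significant association (q < alpha) and highly expressed genes (mean
    expression above the given quantile, default top quartile)."""
    population = sorted(association_table["gene_id"].unique())
    if not population:
        raise ValueError("empty association table")
    sig_genes = set(association_table.loc[association_table["q"] < alpha, "gene_id"])
    means = expression.loc[population].mean(axis=1)
    cut = means.quantile(expression_quantile)
    high = set(means.index[means > cut])
    if not high:
        raise ValueError("empty highly-expressed draw set")
    k = len(sig_genes & high)
    return hypergeom_upper(k, len(population), len(sig_genes), len(high))


def substrate_product_shift(values, is_substrate) -> float:
    """One-sided rank-sum p for product-role values being stochastically
    greater than substrate-role values (confidences or correlations)."""
    values = np.asarray(values, dtype=float)
    is_substrate = np.asarray(is_substrate, dtype=bool)
    prods = values[~is_substrate]
    subs = values[is_substrate]
    return rank_sum_test(prods, subs, alternative="greater").p_value


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    flagged: bool = False


def diffexp_vs_coupling(
    expression: pd.DataFrame,
    condition: pd.Series,
    association_table: pd.DataFrame,
) -> CorrelationResult:
    """Spearman between per-gene coupling strength (max |rho| over the
    gene's pairs, all-samples stratum) and the magnitude of its
    differential expression (|rank-sum z| between conditions)."""
    labels = condition.loc[expression.columns]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("need exactly two conditions")
    a = expression.loc[:, (labels == groups[0]).to_numpy()]
    b = expression.loc[:, (labels == groups[1]).to_numpy()]
    coupling = association_table.groupby("gene_id")["rho"].agg(
        lambda s: float(np.abs(s).max()))
    genes = [g for g in coupling.index if g in expression.index]
    de = np.array([
        abs(rank_sum_test(a.loc[g].to_numpy(), b.loc[g].to_numpy(),
                          method="approx").statistic)
        for g in genes
    ])
    rho, p, flagged = spearman(coupling.loc[genes].to_numpy(), de)
    return CorrelationResult(rho, p, flagged)


def rgm_gene_variance_shift(
    expression: pd.DataFrame,
    associated_gene_ids,
) -> float:
    """One-sided rank-sum p testing whether association-carrying genes have
    larger expression variance than the remaining genes."""
    assoc = [g for g in associated_gene_ids if g in expression.index]
    other = [g for g in expression.index if g not in set(assoc)]
    if not assoc or not other:
        raise ValueError("both gene groups must be nonempty")
    var = expression.var(axis=1, ddof=1)
    return rank_sum_test(var.loc[assoc].to_numpy(),
                         var.loc[other].to_numpy(),
                         alternative="greater").p_value
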