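import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import _oracles as oracles
from metcouple import association
from metcouple._stats import (
    bh_fdr, empirical_p, hypergeom_upper, rank_sum_test, spearman,
)
from metcouple.network import CYTOSOL, GMPair, connected_gm_pairs
from metcouple.synthetic import (
    CANCER, NONCANCEROUS, generate_network, generate_omics,
)

from conftest import stratum_matrices


class TestSpearman:
    def test_monotone_identity(self):
        x = np.arange(10.0)
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exact_permutation_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=8).astype(float)   # heavy ties
        y = rng.integers(0, 5, size=8).astype(float)
        if np.unique(x).size == 1 or np.unique(y).size == 1:
            x[0] += 1
            y[0] += 1
        rho, p, flagged = spearman(x, y, method="exact")
        o_rho, o_p = oracles.spearman_exact(x, y)
        assert not flagged
        assert rho == pytest.approx(o_rho, abs=1e-10)
        assert p == pytest.approx(o_p, abs=1e-10)

    @given(st.lists(st.integers(-50, 50), min_size=5, max_size=12,
                    unique=True))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transforms(self, xs):
        x = np.asarray(xs, dtype=float)
        y = np.sin(x) + x  # arbitrary paired values, strictly increasing in x
        base = spearman(x, y, method="approx")[0]
        assert spearman(np.exp(x / 50.0), y, method="approx")[0] \
            == pytest.approx(base, abs=1e-12)
        assert spearman(x ** 3, y, method="approx")[0] \
            == pytest.approx(base, abs=1e-12)

    def test_constant_vector_flagged_in_table(self):
        expr = pd.DataFrame([[5.0] * 6], index=["g1"],
                            columns=[f"s{i}" for i in range(6)])
        mets = pd.DataFrame([np.arange(6.0)], index=["m1"],
                            columns=expr.columns)
        pairs = [GMPair("g1", "m1", frozenset({"R1"}))]
        tbl = association.spearman_table(expr, mets, pairs)
        row = tbl.iloc[0]
        assert row["flagged"] and row["rho"] == 0.0 and row["p"] == 1.0

    def test_requires_four_samples(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                            columns=list("abc"))
        with pytest.raises(ValueError):
            association.spearman_table(expr, expr, [])


class TestBH:
    def test_hand_worked_case(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) \
            == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_matches_literal_stepup(self, ps):
        assert bh_fdr(ps) == pytest.approx(oracles.bh_stepup(ps), abs=1e-12)


class TestPermutationTest:
    def test_empirical_p_formula_bounds(self):
        assert empirical_p(0, 1000) == pytest.approx(1 / 1001)
        assert empirical_p(1000, 1000) == 1.0
        with pytest.raises(ValueError):
            empirical_p(-1, 10)

    def test_result_satisfies_addone_identity(self, medium_cohort,
                                              medium_network):
        cohort, _ = medium_cohort
        pairs = connected_gm_pairs(medium_network, CYTOSOL)
        expr, mets = stratum_matrices(cohort, CANCER)
        res = association.coupling_permutation_test(
            expr, mets, pairs, n_perm=99, seed=3)
        assert res.empiric_p == (res.r + 1) / (res.n_perm + 1)
        assert res.r == int((res.n_sig_perm > res.n_sig_real).sum())

    def test_planted_stratum_contrast(self, medium_cohort, medium_network):
        cohort, _ = medium_cohort
        pairs = connected_gm_pairs(medium_network, CYTOSOL)
        expr_c, mets_c = stratum_matrices(cohort, CANCER)
        expr_n, mets_n = stratum_matrices(cohort, NONCANCEROUS)
        p_c = association.coupling_permutation_test(
            expr_c, mets_c, pairs, n_perm=500, seed=4).empiric_p
        p_n = association.coupling_permutation_test(
            expr_n, mets_n, pairs, n_perm=500, seed=5).empiric_p
        assert p_c < 0.01
        assert p_n > 0.05

    def test_type_one_error_calibrated(self):
        """Over 200 null synthetic datasets the fraction with empiric_p <
        0.05 stays near the nominal level."""
        net = generate_network(30, 40, 25, 3, seed=71)
        pairs = connected_gm_pairs(net, CYTOSOL)
        hits = 0
        for seed in range(200):
            cohort, _ = generate_omics(
                net, n_samples_per_condition=20,
                coupling_fraction_by_condition={CANCER: 0.0}, seed=seed)
            res = association.coupling_permutation_test(
                cohort.expression, cohort.metabolites, pairs,
                n_perm=400, seed=seed + 5000)
            hits += res.empiric_p < 0.05
        assert 0.02 <= hits / 200 <= 0.09

    def test_too_many_pairs_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 6)),
                            index=["g1", "g2"],
                            columns=[f"s{i}" for i in range(6)])
        mets = pd.DataFrame(np.random.default_rng(1).normal(size=(1, 6)),
                            index=["m1"], columns=expr.columns)
        pairs = [GMPair(f"g{i % 2 + 1}", "m1", frozenset({"R"}))
                 for i in range(3)]
        with pytest.raises(ValueError):
            association.coupling_permutation_test(expr, mets, pairs,
                                                  n_perm=10, seed=0)


class TestEnrichmentAndShifts:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "metabolite_id",
                                           "stratum", "rho", "p", "q",
                                           "n_samples", "flagged"])

    def test_expressed_gene_enrichment_matches_exact_tail(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        expr = pd.DataFrame(rng.normal(size=(40, 8)) + np.linspace(0, 4, 40)[:, None],
                            index=genes, columns=[f"s{i}" for i in range(8)])
        sig = set(genes[30:])  # the 10 most expressed genes are significant
        tbl = self._table([
            (g, "m", "all", 0.5, 0.001 if g in sig else 0.9,
             0.01 if g in sig else 0.95, 8, False) for g in genes])
        p = association.expressed_gene_enrichment(expr, tbl, alpha=0.05)
        high = expr.mean(axis=1)
        k = len(sig & set(high.index[high > high.quantile(0.75)]))
        expected = float(oracles.hypergeom_upper_exact(k, 40, 10,
                                                       int((high > high.quantile(0.75)).sum())))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_no_significant_genes_gives_p_one(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(12)]
        expr = pd.DataFrame(rng.normal(size=(12, 6)), index=genes,
                            columns=[f"s{i}" for i in range(6)])
        tbl = self._table([(g, "m", "all", 0.1, 0.9, 0.95, 6, False)
                           for g in genes])
        assert association.expressed_gene_enrichment(expr, tbl) \
            == pytest.approx(1.0)

    def test_substrate_product_shift_exact_and_symmetric(self):
        vals = np.array([1.0] * 5 + [-1.0] * 5)
        is_sub = np.array([False] * 5 + [True] * 5)
        p = association.substrate_product_shift(vals, is_sub)
        assert p == pytest.approx(oracles.ranksum_exact(
            vals[~is_sub], vals[is_sub], "greater"), abs=1e-12)
        assert p == pytest.approx(1 / 252)
        same = association.substrate_product_shift(
            np.r_[np.arange(20.0), np.arange(20.0)],
            np.r_[np.zeros(20), np.ones(20)].astype(bool))
        assert same == pytest.approx(0.5)

    def test_shift_recovered_from_role_signed_cohort(self):
        net = generate_network(60, 60, 40, 4, seed=81)
        cohort, truth = generate_omics(
            net, n_samples_per_condition=40, sign_policy="role",
            strength_range=(0.8, 0.8), seed=82)
        pairs = connected_gm_pairs(net, CYTOSOL)
        expr, mets = stratum_matrices(cohort, CANCER)
        tbl = association.spearman_table(expr, mets, pairs, p_method="approx")
        planted = {(cp.gene_id, cp.metabolite_id): cp
                   for cp in truth.coupled_pairs}
        rows = tbl[[(g, m) in planted
                    for g, m in zip(tbl.gene_id, tbl.metabolite_id)]]
        is_sub = np.array([planted[(r.gene_id, r.metabolite_id)].sign < 0
                           for r in rows.itertuples()])
        assert is_sub.any() and (~is_sub).any()
        p = association.substrate_product_shift(rows["rho"].to_numpy(), is_sub)
        assert p < 0.05

    def test_variance_shift_exact_small_and_planted(self):
        # exact enumeration on a 3v3 case
        expr = pd.DataFrame(
            [[0, 1, 2, 3], [0, 2, 4, 6], [0, 3, 6, 9],
             [0, 0.1, 0.2, 0.3], [0, 0.2, 0.4, 0.6], [0, 0.3, 0.6, 0.9]],
            index=[f"g{i}" for i in range(6)], columns=list("abcd"),
            dtype=float)
        p = association.rgm_gene_variance_shift(expr, ["g0", "g1", "g2"])
        var = expr.var(axis=1, ddof=1)
        assert p == pytest.approx(oracles.ranksum_exact(
            var.iloc[:3], var.iloc[3:], "greater"), abs=1e-12)
        # planted: coupled genes carry the variance multiplier; use a
        # cohort where coupled and uncoupled gene groups are comparable
        net = generate_network(60, 120, 30, 4, seed=91)
        cohort, truth = generate_omics(net, n_samples_per_condition=30,
                                       max_secondary=3, seed=0)
        coupled_genes = [cp.gene_id for cp in truth.coupled_pairs]
        p2 = association.rgm_gene_variance_shift(cohort.expression,
                                                 coupled_genes)
        assert p2 < 0.05


class TestDiffexpVsCoupling:
    @staticmethod
    def _build(seed, couple_differential):
        """Two-condition expression where either the condition-shifted genes
        or an unrelated set carries the metabolite couplings."""
        rng = np.random.default_rng(seed)
        n = 30
        samples = [f"s{i}" for i in range(2 * n)]
        condition = pd.Series(["noncancerous"] * n + ["cancer"] * n,
                              index=samples)
        genes = [f"g{i}" for i in range(40)]
        expr = pd.DataFrame(rng.normal(size=(40, 2 * n)), index=genes,
                            columns=samples)
        expr.iloc[:20, n:] += 2.0          # first 20 genes differential
        coupled = genes[:20] if couple_differential else genes[20:]
        mets = {}
        pairs = []
        for j, g in enumerate(genes):
            m = f"m{j}"
            noise = rng.normal(size=2 * n)
            x = expr.loc[g] - expr.loc[g].mean()
            mets[m] = (0.8 * x / x.std() + 0.6 * noise) if g in coupled \
                else noise
            pairs.append(GMPair(g, m, frozenset({"R"})))
        met_df = pd.DataFrame(mets).T
        met_df.columns = samples
        return expr, met_df, condition, pairs

    def test_planted_differential_coupling_recovered(self):
        expr, mets, condition, pairs = self._build(1, True)
        tbl = association.spearman_table(expr, mets, pairs,
                                         p_method="approx")
        res = association.diffexp_vs_coupling(expr, condition, tbl)
        assert res.rho > 0.4

    def test_null_calibration(self):
        ok = 0
        for seed in range(20):
            expr, mets, condition, pairs = self._build(seed + 10, False)
            rng = np.random.default_rng(seed)
            # decouple: permute gene rows so coupling no longer aligns
            # with differential expression in any systematic way
            tbl = association.spearman_table(expr, mets, pairs,
                                            p_method="approx")
            perm = expr.copy()
            perm.index = rng.permutation(expr.index)
            res = association.diffexp_vs_coupling(perm, condition, tbl)
            ok += res.p > 0.05
        assert ok >= 18

    def test_constant_coupling_flagged(self):
        expr, mets, condition, pairs = self._build(3, True)
        tbl = association.spearman_table(expr, mets, pairs,
                                         p_method="approx")
        tbl["rho"] = 0.5
        res = association.diffexp_vs_coupling(expr, condition, tbl)
        assert res.flagged


class TestRankSumAndHypergeom:
    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    def test_exact_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 6, size=6).astype(float)
        y = rng.integers(0, 6, size=7).astype(float)
        res = rank_sum_test(x, y, alternative=alternative, method="exact")
        assert res.p_value == pytest.approx(
            oracles.ranksum_exact(x, y, alternative), abs=1e-12)

    def test_hypergeom_tail_matches_rational_sum(self):
        for (k, M, K, N) in [(3, 25, 10, 8), (0, 12, 5, 4), (5, 20, 5, 10)]:
            assert hypergeom_upper(k, M, K, N) == pytest.approx(
                float(oracles.hypergeom_upper_exact(k, M, K, N)), rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])
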