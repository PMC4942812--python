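"""Pathway-level analyses.

Two complementary views: (a) prediction-based - reactions called
"regulated" in a condition when any of their RGM triplets carries an
FDR-significant confidence, then per-pathway hypergeometric enrichment
of regulated reactions; (b) raw-data - a rank-sum shift test between
the noncancerous and cancer per-pair Spearman p-value sets of each
pathway with at least a minimum number of measured pairs.  Finally, a
cross-dataset agreement correlation of pathway enrichment p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_fdr, hypergeom_upper, rank_sum_test, spearman
from .network import MetabolicNetwork


def regulated_reactions(
    significance: pd.DataFrame,
    triplets=None,
) -> set[str]:
    """Reactions with at least one FDR-significant triplet.

    ``significance`` carries reaction_id plus a boolean ``significant``
    column (confidence_significance output joined onto the triplet
    table)."""
    mask = significance["significant"].astype(bool)
    return set(significance.loc[mask, "reaction_id"])


def prediction_enrichment(
    regulated_by_condition: dict[str, set[str]],
    network: MetabolicNetwork,
) -> pd.DataFrame:
    """Hypergeometric enrichment of regulated reactions per pathway and
    condition; population = reactions with enumerable triplets (those a
    classifier can ever call), BH across pathways within condition."""
    population = sorted(
        r.reaction_id for r in network.reactions.values()
        if r.genes and r.metabolites)
    pw_of = {rid: network.reactions[rid].pathway_id for rid in population}
    pathways = sorted(set(pw_of.values()))
    frames = []
    for condition, regulated in sorted(regulated_by_condition.items()):
        reg = {r for r in regulated if r in pw_of}
        rows = []
        for pw in pathways:
            members = [r for r in population if pw_of[r] == pw]
            if not members:
                continue
            k = len([r for r in members if r in reg])
            p = hypergeom_upper(k, len(population), len(reg), len(members)) \
                if members else 1.0
            rows.append({"pathway_id": pw,
                         "pathway": network.pathway_names.get(pw, str(pw)),
                         "condition": condition,
                         "n_regulated": k, "n_total": len(members), "p": p})
        df = pd.DataFrame(rows)
        df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["pathway_id", "pathway", "condition",
                 "n_regulated", "n_total", "p", "q"])


def _pair_pathways(pairs, network: MetabolicNetwork) -> dict[tuple[str, str], set[int]]:
    out = {}
    for p in pairs:
        pws = {network.reactions[r].pathway_id for r in p.connecting_reaction_ids}
        out[(p.gene_id, p.metabolite_id)] = pws
    return out


def raw_gm_shift(
    table_noncancerous: pd.DataFrame,
    table_cancer: pd.DataFrame,
    pairs,
    network: MetabolicNetwork,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Per-pathway two-sided rank-sum test comparing the noncancerous
    against the cancer GM-association p-value sets.

    Only pathways with at least ``min_pairs`` measured pairs enter (a
    pair belongs to every pathway of its connecting reactions); the
    shift direction is reported as the median p difference
    (cancer - noncancerous; negative = stronger coupling in cancer).
    """
    pw_of_pair = _pair_pathways(pairs, network)
    key_nc = table_noncancerous.set_index(["gene_id", "metabolite_id"])["p"]
    key_ca = table_cancer.set_index(["gene_id", "metabolite_id"])["p"]
    shared = [k for k in pw_of_pair if k in key_nc.index and k in key_ca.index]
    rows = []
    pathways = sorted({pw for k in shared for pw in pw_of_pair[k]})
    for pw in pathways:
        members = [k for k in shared if pw in pw_of_pair[k]]
        if len(members) < min_pairs:
            continue
        p_nc = key_nc.loc[members].to_numpy()
        p_ca = key_ca.loc[members].to_numpy()
        res = rank_sum_test(p_nc, p_ca, alternative="two-sided")
        rows.append({"pathway_id": pw,
                     "pathway": network.pathway_names.get(pw, str(pw)),
                     "n_pairs": len(members), "p": res.p_value,
                     "median_shift": float(np.median(p_ca) - np.median(p_nc))})
    table = pd.DataFrame(rows, columns=["pathway_id", "pathway", "n_pairs",
                                        "p", "median_shift"])
    table["q"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    return table


@dataclass(frozen=True)
class AgreementResult:
    rho: float
    p: float
    n_pathways: int
    flagged: bool


def cross_dataset_agreement(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    sig_threshold: float = 0.05,
) -> AgreementResult:
    """Spearman agreement of -log10 enrichment p-values between two
    datasets over pathways significantly enriched (unadjusted p below
    the threshold) in either dataset; fewer than 4 shared pathways is
    flagged."""
    a = table_a.set_index("pathway_id")["p"]
    b = table_b.set_index("pathway_id")["p"]
    shared = a.index.intersection(b.index)
    keep = [pw for pw in shared
            if a.loc[pw] < sig_threshold or b.loc[pw] < sig_threshold]
    if len(keep) < 4:
        return AgreementResult(0.0, 1.0, len(keep), True)
    la = -np.log10(np.maximum(a.loc[keep].to_numpy(), 1e-300))
    lb = -np.log10(np.maximum(b.loc[keep].to_numpy(), 1e-300))
    rho, p, flagged = spearman(la, lb, method="approx")
    return AgreementResult(rho, p, len(keep), flagged)
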