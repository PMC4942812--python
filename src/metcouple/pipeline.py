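"""End-to-end orchestration of the coupling pipeline.

run_all executes associate -> classify -> graph -> predict-metabolites
-> pathways -> clinical over one cohort + network, writing every stage
artifact (TSV / JSON / GraphML) into a run directory together with a
machine-parseable JSONL log, the config hash and the seed, so a run is
a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from . import association, classifier, clinical, graph, pathways, regression
from .network import (
    CYTOSOL, MetabolicNetwork, connected_gm_pairs, enumerate_rgm_triplets,
    load_network,
)
from .synthetic import (
    CANCER, NONCANCEROUS, OmicsCohort, read_cohort,
)

STRATA = ("all", NONCANCEROUS, CANCER)


@dataclass
class RunConfig:
    network: str
    cohort_dir: str
    alpha: float = 0.05
    n_perm: int = 1000
    k_folds: int = 5
    confidence_threshold: float = 0.5
    degree_threshold: int = 4
    min_pathway_pairs: int = 10
    n_null_permutations: int = 20
    expression_quantile: float = 0.75
    confidence_mapping: str = "calibrated"
    categorical_features: str = "onehot"
    strata: tuple[str, ...] = STRATA
    seed: int = 0

    def __post_init__(self):
        for name in ("alpha", "n_perm", "k_folds", "confidence_threshold",
                     "degree_threshold", "min_pathway_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def event(self, stage: str, **fields) -> None:
        rec = {"stage": stage, "t": round(_time.time(), 3), **fields}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")


def _stratum_slice(cohort: OmicsCohort, stratum: str):
    mask = cohort.sample_mask(stratum)
    cols = cohort.samples[mask]
    return cohort.expression[cols], cohort.metabolites[cols]


def classify_stratum(
    network: MetabolicNetwork,
    cohort: OmicsCohort,
    assoc_table: pd.DataFrame,
    stratum: str,
    config: RunConfig,
    seed: int,
):
    """Train, cross-validate and apply the RGM classifier for one stratum;
    returns (confidence table with significance, CVResult)."""
    expr, _ = _stratum_slice(cohort, stratum)
    triplets = enumerate_rgm_triplets(network)
    features, _excluded = classifier.build_features(network, expr, triplets)
    labels = classifier.build_labels(assoc_table, features, alpha=config.alpha)
    labeled = (labels != 0).to_numpy()
    X_all = classifier.encode_features(features, network,
                                       config.categorical_features)
    X_lab = X_all[labeled]
    y_lab = labels[labeled].to_numpy()
    cv = classifier.cross_validate(
        X_lab, y_lab, k=config.k_folds, seed=seed,
        confidence_mapping=config.confidence_mapping)
    model = classifier.RGMClassifier(
        confidence_mapping=config.confidence_mapping, random_state=seed).fit(
        X_lab, y_lab)
    conf = classifier.predict_confidences(model, features, X_all)
    null = classifier.permutation_null_confidences(
        X_lab, y_lab, X_all,
        n_permutations=config.n_null_permutations, seed=seed + 1,
        confidence_mapping=config.confidence_mapping)
    sig = classifier.confidence_significance(conf["confidence"].to_numpy(),
                                             null, alpha=config.alpha)
    conf = pd.concat([conf.reset_index(drop=True),
                      sig[["p", "q", "significant"]]], axis=1)
    conf["label"] = labels.to_numpy()
    return conf, cv


def run_all(config: RunConfig, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run_log.jsonl")
    (out / "provenance.json").write_text(json.dumps({
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
    }, indent=1, default=str))
    rng = np.random.SeedSequence(config.seed)
    seeds = iter(int(s) for s in rng.generate_state(32) % (2 ** 31 - 1))

    stage = "load"
    try:
        network = load_network(config.network)
        cohort = read_cohort(config.cohort_dir)
        pairs = connected_gm_pairs(network, CYTOSOL)
        log.event(stage, n_reactions=len(network.reactions),
                  n_pairs=len(pairs), n_samples=len(cohort.samples))

        stage = "associate"
        tables: dict[str, pd.DataFrame] = {}
        stats_report = {}
        for stratum in config.strata:
            expr, mets = _stratum_slice(cohort, stratum)
            tbl = association.spearman_table(expr, mets, pairs, stratum=stratum)
            tbl.to_csv(out / f"associations_{stratum}.tsv", sep="\t", index=False)
            tables[stratum] = tbl
            perm = association.coupling_permutation_test(
                expr, mets, pairs, alpha=config.alpha, n_perm=config.n_perm,
                seed=next(seeds))
            enr = association.expressed_gene_enrichment(
                expr, tbl, alpha=config.alpha,
                expression_quantile=config.expression_quantile)
            stats_report[stratum] = {
                "n_pairs": int(len(tbl)),
                "n_significant": int((tbl["q"] < config.alpha).sum()),
                "permutation_empiric_p": perm.empiric_p,
                "n_sig_real": perm.n_sig_real,
                "expressed_gene_enrichment_p": enr,
            }
            log.event(stage, stratum=stratum, **stats_report[stratum])
        (out / "association_stats.json").write_text(
            json.dumps(stats_report, indent=1))

        stage = "classify"
        confidences: dict[str, pd.DataFrame] = {}
        for stratum in config.strata:
            labels_avail = tables[stratum][tables[stratum]["q"] < config.alpha]
            n_pos = int((labels_avail["rho"] > 0).sum())
            n_neg = int((labels_avail["rho"] < 0).sum())
            if min(n_pos, n_neg) < max(config.k_folds,
                                       classifier.MIN_LABELS_PER_CLASS):
                log.event(stage, stratum=stratum, skipped=True,
                          reason=f"too few labels ({n_pos}+/{n_neg}-)")
                continue
            conf, cv = classify_stratum(network, cohort, tables[stratum],
                                        stratum, config, next(seeds))
            conf.to_csv(out / f"confidences_{stratum}.tsv", sep="\t",
                        index=False)
            (out / f"cv_{stratum}.json").write_text(json.dumps({
                "mean_auc": cv.mean_auc,
                "fold_metrics": cv.fold_metrics.to_dict(orient="list"),
                "seed": cv.seed,
            }, indent=1))
            confidences[stratum] = conf
            log.event(stage, stratum=stratum, mean_auc=cv.mean_auc,
                      n_labeled=int((conf["label"] != 0).sum()))

        stage = "graph"
        for stratum in (NONCANCEROUS, CANCER):
            if stratum not in tables:
                continue
            g = graph.build_graph(tables[stratum], pairs, alpha=config.alpha,
                                  stratum=stratum)
            nx.write_graphml(g, out / f"gm_graph_{stratum}.graphml")
            deg = graph.degree_table(g, min_degree=config.degree_threshold)
            deg.to_csv(out / f"degrees_{stratum}.tsv", sep="\t", index=False)
            enr = graph.hub_pathway_enrichment(
                g, network, degree_threshold=config.degree_threshold)
            enr.to_csv(out / f"hub_enrichment_{stratum}.tsv", sep="\t",
                       index=False)
            log.event(stage, stratum=stratum, n_edges=g.number_of_edges())

        stage = "predict-metabolites"
        predicted = None
        selections = None
        reg_stratum = "all" if "all" in confidences else \
            (next(iter(confidences)) if confidences else None)
        if reg_stratum is not None:
            conf = confidences[reg_stratum]
            selections, excluded = regression.select_rgm_extremes(
                conf, network, threshold=config.confidence_threshold)
            expr, mets = _stratum_slice(cohort, reg_stratum)
            instances, _dropped = regression.build_instances(
                selections, expr, network)
            if len(instances) >= 30:
                z, zparams = regression.log_zscore(
                    mets.loc[[m for m in mets.index
                              if m in selections]])
                targets = pd.Series(
                    [z.loc[m, s] for m, s in instances.index],
                    index=instances.index)
                model = regression.fit(instances, targets)
                predicted = regression.predict(model, instances)
                predicted.to_csv(out / "predicted_metabolites.tsv", sep="\t")
                ev = regression.evaluate(predicted, z, selections)
                (out / "regression_evaluation.json").write_text(json.dumps({
                    "stratum": reg_stratum,
                    "overall_rho": ev.overall_rho, "overall_p": ev.overall_p,
                    "n_metabolites": int(len(ev.per_metabolite)),
                    "n_metabolites_significant":
                        int((ev.per_metabolite["q"] < config.alpha).sum()),
                    "n_samples_significant":
                        int((ev.per_sample["q"] < config.alpha).sum()),
                    "meta_rho": ev.meta_rho, "meta_p": ev.meta_p,
                }, indent=1))
                log.event(stage, stratum=reg_stratum,
                          n_selected=len(selections),
                          overall_rho=ev.overall_rho)
            else:
                log.event(stage, skipped=True, reason="too few instances")
        else:
            log.event(stage, skipped=True, reason="no trained classifier")

        stage = "pathways"
        regulated = {
            s: pathways.regulated_reactions(confidences[s])
            for s in (NONCANCEROUS, CANCER) if s in confidences
        }
        if regulated:
            enr = pathways.prediction_enrichment(regulated, network)
            enr.to_csv(out / "pathway_enrichment.tsv", sep="\t", index=False)
            log.event(stage, conditions=sorted(regulated),
                      n_rows=len(enr))
        if NONCANCEROUS in tables and CANCER in tables:
            shift = pathways.raw_gm_shift(
                tables[NONCANCEROUS], tables[CANCER], pairs, network,
                min_pairs=config.min_pathway_pairs)
            shift.to_csv(out / "pathway_shift.tsv", sep="\t", index=False)
            log.event(stage, shift_pathways=len(shift))

        stage = "clinical"
        if predicted is not None and cohort.survival_time is not None:
            cols = predicted.columns
            screen = clinical.survival_screen(
                predicted, cohort.survival_time.loc[cols],
                cohort.event.loc[cols], alpha=config.alpha)
            screen.to_csv(out / "survival_screen.tsv", sep="\t", index=False)
            gvm = clinical.gene_vs_metabolite_survival(
                screen, cohort.expression[cols], pairs,
                cohort.survival_time.loc[cols], cohort.event.loc[cols])
            gvm.to_csv(out / "gene_vs_metabolite.tsv", sep="\t", index=False)
            er = clinical.er_differential(predicted,
                                          cohort.er_status.loc[cols],
                                          alpha=config.alpha)
            er.to_csv(out / "er_differential.tsv", sep="\t", index=False)
            log.event(stage,
                      n_survival_significant=int(screen["significant"].sum()),
                      n_stronger=int(gvm["stronger"].sum()),
                      n_er_significant=int(er["significant"].sum()))
        else:
            log.event(stage, skipped=True,
                      reason="no predictions or no survival data")
    except StageError:
        raise
    except Exception as exc:                      # halt with stage + cause
        log.event(stage, error=str(exc))
        raise StageError(stage, exc) from exc
    log.event("done")
    return out
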