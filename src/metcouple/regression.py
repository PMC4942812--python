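"""Step 2: predicting metabolite levels from enzyme expression.

For every metabolite the two extreme-confidence gene-reaction anchors
GR+ (most positively associated triplet) and GR- (most negatively
associated) are selected from the RGM classifier's confidence table.
Their two 14-feature blocks - with the gene-mean slot replaced by the
gene's expression in the sample at hand - form a 28-feature instance
per (metabolite, sample), and one pooled ordinary-least-squares model
maps instances to z-scored log metabolite levels.  Metabolites whose
best confidence does not clear the reporting threshold (default 0.5 in
absolute value) are excluded from prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression
from sklearn.utils.validation import check_is_fitted

from ._stats import bh_fdr, spearman
from .classifier import FEATURE_COLUMNS
from .network import MetabolicNetwork

GENE_MEAN_SLOT = FEATURE_COLUMNS.index("gene_mean")
INSTANCE_COLUMNS = [f"plus_{c}" for c in FEATURE_COLUMNS] \
    + [f"minus_{c}" for c in FEATURE_COLUMNS]


@dataclass(frozen=True)
class RGMSelection:
    metabolite_id: str
    gr_plus: tuple[str, str, bool]     # (gene_id, reaction_id, is_substrate)
    gr_minus: tuple[str, str, bool]
    confidence_plus: float
    confidence_minus: float

    @property
    def best_confidence(self) -> float:
        return max(abs(self.confidence_plus), abs(self.confidence_minus))


def select_rgm_extremes(
    confidence_table: pd.DataFrame,
    network: MetabolicNetwork,
    threshold: float = 0.5,
) -> tuple[dict[str, RGMSelection], list[str]]:
    """Per metabolite, the argmax / argmin confidence triplets.

    Ties break by (reaction index, gene index) ascending.  Metabolites
    whose best absolute selected confidence does not exceed the
    threshold are excluded; both GR+ and GR- are kept as the extreme
    triplets regardless of whether GR- itself crosses -threshold.
    Returns (selections by metabolite, excluded metabolite ids).
    """
    tbl = confidence_table.copy()
    tbl["_r"] = [network.reactions[r].network_index for r in tbl["reaction_id"]]
    tbl["_g"] = [network.genes[g].network_index for g in tbl["gene_id"]]
    selections: dict[str, RGMSelection] = {}
    excluded: list[str] = []
    for met, sub in tbl.groupby("metabolite_id", sort=True):
        sub = sub.sort_values(["_r", "_g"], kind="stable")
        conf = sub["confidence"].to_numpy()
        i_plus = int(np.argmax(conf))
        i_minus = int(np.argmin(conf))
        rp, rm = sub.iloc[i_plus], sub.iloc[i_minus]
        sel = RGMSelection(
            metabolite_id=str(met),
            gr_plus=(rp["gene_id"], rp["reaction_id"], bool(rp["is_substrate"])),
            gr_minus=(rm["gene_id"], rm["reaction_id"], bool(rm["is_substrate"])),
            confidence_plus=float(rp["confidence"]),
            confidence_minus=float(rm["confidence"]),
        )
        if sel.best_confidence > threshold:
            selections[str(met)] = sel
        else:
            excluded.append(str(met))
    return selections, excluded


def _triplet_features(network, expression, gene_id, reaction_id, is_substrate,
                      metabolite_id):
    r = network.reactions[reaction_id]
    g = expression.loc[gene_id]
    return np.array([
        r.network_index, r.pathway_id, r.delta_g0, int(r.reversible),
        network.genes[gene_id].network_index,
        g.mean(), g.var(ddof=1), g.min(), g.max(),
        network.metabolites[metabolite_id].network_index,
        len(r.metabolites), len(r.substrates), len(r.products),
        int(is_substrate),
    ], dtype=float)


def build_instances(
    selections: dict[str, RGMSelection],
    expression: pd.DataFrame,
    network: MetabolicNetwork,
    samples=None,
) -> tuple[pd.DataFrame, list[str]]:
    """One 28-feature row per (selected metabolite, sample).

    Layout: the GR+ 14-feature block then the GR- block, each in the
    classifier's feature order, with the gene-mean slot holding the
    anchor gene's expression in that sample.  Metabolites whose anchor
    gene is unmeasured in this cohort are dropped (returned in the
    second element).
    """
    if samples is None:
        samples = list(expression.columns)
    rows, index, dropped = [], [], []
    for met in sorted(selections):
        sel = selections[met]
        (gp, rp, sp), (gm, rm, sm) = sel.gr_plus, sel.gr_minus
        if gp not in expression.index or gm not in expression.index:
            dropped.append(met)
            continue
        base_p = _triplet_features(network, expression, gp, rp, sp, met)
        base_m = _triplet_features(network, expression, gm, rm, sm, met)
        xp = expression.loc[gp, samples].to_numpy(dtype=float)
        xm = expression.loc[gm, samples].to_numpy(dtype=float)
        for j, s in enumerate(samples):
            fp = base_p.copy()
            fm = base_m.copy()
            fp[GENE_MEAN_SLOT] = xp[j]
            fm[GENE_MEAN_SLOT] = xm[j]
            rows.append(np.concatenate([fp, fm]))
            index.append((met, s))
    if dropped:
        warnings.warn(f"metabolites dropped (anchor gene unmeasured): {dropped}")
    instances = pd.DataFrame(
        rows, columns=INSTANCE_COLUMNS,
        index=pd.MultiIndex.from_tuples(index, names=["metabolite_id", "sample"]))
    return instances, dropped


def log_zscore(
    metabolites: pd.DataFrame,
    params: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Natural-log transform with a per-metabolite pseudo-offset (half the
    minimum positive value) followed by per-metabolite z-scoring.

    Pass the returned ``params`` back in to apply frozen training
    statistics to an application cohort.
    """
    vals = metabolites.astype(float)
    if params is None:
        minpos = vals.where(vals > 0).min(axis=1)
        offset = (minpos / 2.0).fillna(1.0)
        logged = np.log(vals.add(offset.where(vals.le(0).any(axis=1), 0.0), axis=0))
        mean = logged.mean(axis=1)
        sd = logged.std(axis=1, ddof=1).replace(0.0, 1.0)
        params = pd.DataFrame({"offset": offset, "mean": mean, "sd": sd})
    else:
        offset = params["offset"]
        logged = np.log(vals.add(offset.where(vals.le(0).any(axis=1), 0.0), axis=0))
        mean, sd = params["mean"], params["sd"]
    z = logged.sub(mean, axis=0).div(sd, axis=0)
    return z, params


class MetaboliteLevelRegressor(BaseEstimator, RegressorMixin):
    """Generalized multiple linear regressor over 28-feature instances.

    mode="pooled" (default) fits a single OLS model across every
    (metabolite, sample) instance, reading "generalized" as one shared
    model; mode="per-metabolite" fits one OLS per metabolite instead.
    Rank-deficient designs fall back to the pseudoinverse solution with
    a warning (that is what lstsq computes).
    """

    def __init__(self, mode: str = "pooled"):
        self.mode = mode

    def fit(self, X, y, metabolite_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(X) < 30:
            raise ValueError("need at least 30 training instances")
        if not np.isfinite(y).all():
            raise ValueError("targets must be finite")
        if self.mode == "pooled":
            self._check_rank(X)
            self.model_ = LinearRegression().fit(X, y)
        elif self.mode == "per-metabolite":
            if metabolite_ids is None:
                raise ValueError("per-metabolite mode needs metabolite_ids")
            mids = np.asarray(metabolite_ids)
            self.models_ = {}
            for m in np.unique(mids):
                mask = mids == m
                self.models_[m] = LinearRegression().fit(X[mask], y[mask])
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _check_rank(X):
        design = np.column_stack([np.ones(len(X)), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn("rank-deficient design; coefficients are the "
                          "minimum-norm pseudoinverse solution")

    def predict(self, X, metabolite_ids=None):
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("instance layout mismatch")
        if self.mode == "pooled":
            return self.model_.predict(X)
        if metabolite_ids is None:
            raise ValueError("per-metabolite mode needs metabolite_ids")
        mids = np.asarray(metabolite_ids)
        out = np.empty(len(X))
        for m in np.unique(mids):
            mask = mids == m
            if m not in self.models_:
                raise ValueError(f"no model for metabolite {m!r}")
            out[mask] = self.models_[m].predict(X[mask])
        return out


def fit(instances: pd.DataFrame, targets: pd.Series,
        mode: str = "pooled") -> MetaboliteLevelRegressor:
    """Fit the level regressor on an instance table (MultiIndex
    (metabolite_id, sample)) against z-scored log levels."""
    reg = MetaboliteLevelRegressor(mode=mode)
    mids = instances.index.get_level_values("metabolite_id")
    reg.fit(instances.to_numpy(), targets.loc[instances.index].to_numpy(),
            metabolite_ids=mids)
    return reg


def predict(model: MetaboliteLevelRegressor,
            instances: pd.DataFrame) -> pd.DataFrame:
    """Predicted metabolite x sample matrix on the z-score scale."""
    mids = instances.index.get_level_values("metabolite_id")
    yhat = model.predict(instances.to_numpy(), metabolite_ids=mids)
    series = pd.Series(yhat, index=instances.index)
    return series.unstack("sample")


@dataclass
class EvaluationResult:
    overall_rho: float
    overall_p: float
    per_metabolite: pd.DataFrame
    per_sample: pd.DataFrame
    meta_rho: float | None = None
    meta_p: float | None = None


def evaluate(
    predicted: pd.DataFrame,
    measured_z: pd.DataFrame,
    selections: dict[str, RGMSelection] | None = None,
) -> EvaluationResult:
    """Measured-versus-predicted Spearman at three granularities.

    Overall: all (metabolite, sample) points pooled.  Per metabolite:
    across samples, BH-adjusted across metabolites (rows with < 4
    points are flagged).  Per sample: across metabolites, BH within
    samples.  With selections given, also the meta-correlation between
    per-metabolite performance and the metabolite's best selected
    confidence.
    """
    mets = predicted.index.intersection(measured_z.index)
    cols = predicted.columns.intersection(measured_z.columns)
    pred = predicted.loc[mets, cols]
    meas = measured_z.loc[mets, cols]
    overall_rho, overall_p, _ = spearman(pred.to_numpy().ravel(),
                                         meas.to_numpy().ravel(),
                                         method="approx")

    def _family(axis: int) -> pd.DataFrame:
        keys = mets if axis == 0 else cols
        rows = []
        for k in keys:
            a = (pred.loc[k] if axis == 0 else pred[k]).to_numpy()
            b = (meas.loc[k] if axis == 0 else meas[k]).to_numpy()
            if a.size < 4:
                rows.append((k, 0.0, 1.0, True))
                continue
            rho, p, flagged = spearman(a, b, method="approx")
            rows.append((k, rho, p, flagged))
        df = pd.DataFrame(rows, columns=["key", "rho", "p", "flagged"])
        df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
        return df

    per_met = _family(0)
    per_sample = _family(1)
    result = EvaluationResult(overall_rho, overall_p, per_met, per_sample)
    if selections:
        best = np.array([selections[m].best_confidence for m in per_met["key"]
                         if m in selections])
        perf = per_met.set_index("key").loc[
            [m for m in per_met["key"] if m in selections], "rho"].to_numpy()
        if best.size >= 4:
            result.meta_rho, result.meta_p, _ = spearman(perf, best,
                                                         method="approx")
    return result
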