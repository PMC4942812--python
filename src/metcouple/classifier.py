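"""Step 1: the RGM predictor.

Every (reaction, gene, metabolite, role) triplet of the metabolic
network is represented by 14 features (reaction position, pathway code,
delta G0, reversibility; gene position and expression mean / variance /
min / max; metabolite position, reaction metabolite / substrate /
product counts, and the substrate-or-product flag).  Triplets whose
gene-metabolite pair shows an FDR-significant Spearman correlation are
labeled by the correlation sign, a class-balanced linear-kernel SVM is
trained on them, and a confidence level in [-1, +1] is emitted for
every triplet in the network - including the large majority whose
metabolite was never measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted

from ._stats import bh_fdr, empirical_p_two_sided
from .network import MetabolicNetwork

FEATURE_COLUMNS = [
    "reaction_index",     # (1)  position of the reaction in the model
    "pathway_code",       # (2)  integer code of its pathway
    "delta_g0",           # (3)  predicted standard Gibbs energy, kJ/mol
    "reversible",         # (4)  1 if reversible
    "gene_index",         # (5)  position of the gene in the model
    "gene_mean",          # (6)  mean expression over the stratum
    "gene_var",           # (7)  expression variance
    "gene_min",           # (8)  expression minimum
    "gene_max",           # (9)  expression maximum
    "metabolite_index",   # (10) position of the metabolite in the model
    "n_metabolites",      # (11) metabolites in the reaction
    "n_substrates",       # (12) substrates in the reaction
    "n_products",         # (13) products in the reaction
    "substrate_flag",     # (14) 1 if the triplet's metabolite is a substrate
]

TRIPLET_COLUMNS = ["reaction_id", "gene_id", "metabolite_id", "is_substrate"]

CATEGORICAL_FEATURE_COLUMNS = ["reaction_index", "pathway_code",
                               "gene_index", "metabolite_index"]
NUMERIC_FEATURE_COLUMNS = [c for c in FEATURE_COLUMNS
                           if c not in CATEGORICAL_FEATURE_COLUMNS]

MIN_LABELS_PER_CLASS = 5


def encode_features(
    features: pd.DataFrame,
    network: MetabolicNetwork,
    categorical: str = "onehot",
) -> np.ndarray:
    """Design matrix for the classifier.

    The model-position features (reaction, pathway, gene, metabolite)
    are categorical identifiers; "onehot" (default) expands each into
    indicator columns sized by the network so a linear kernel can use
    them as the categorical proxy they are, "raw" feeds the bare
    integers.
    """
    if categorical == "raw":
        return features[FEATURE_COLUMNS].to_numpy(dtype=float)
    if categorical != "onehot":
        raise ValueError(f"unknown categorical encoding {categorical!r}")
    blocks = [features[NUMERIC_FEATURE_COLUMNS].to_numpy(dtype=float)]
    sizes = {
        "reaction_index": len(network.reactions) + 1,
        "pathway_code": max(network.pathway_names, default=0) + 1,
        "gene_index": len(network.genes) + 1,
        "metabolite_index": len(network.metabolites) + 1,
    }
    for col, n in sizes.items():
        v = features[col].to_numpy(dtype=int)
        m = np.zeros((len(features), n))
        m[np.arange(len(features)), v] = 1.0
        blocks.append(m)
    return np.hstack(blocks)


def build_features(
    network: MetabolicNetwork,
    expression: pd.DataFrame,
    triplets,
) -> tuple[pd.DataFrame, list]:
    """14-feature table for the given triplets; expression statistics are
    taken over the columns of ``expression`` (slice to the stratum
    first).  Triplets whose gene is unmeasured are excluded and returned
    separately."""
    stats = pd.DataFrame({
        "gene_mean": expression.mean(axis=1),
        "gene_var": expression.var(axis=1, ddof=1),
        "gene_min": expression.min(axis=1),
        "gene_max": expression.max(axis=1),
    })
    rows, excluded = [], []
    for t in triplets:
        if t.gene_id not in stats.index:
            excluded.append(t)
            continue
        r = network.reactions[t.reaction_id]
        g = stats.loc[t.gene_id]
        rows.append((
            t.reaction_id, t.gene_id, t.metabolite_id, t.is_substrate,
            r.network_index, r.pathway_id, r.delta_g0, int(r.reversible),
            network.genes[t.gene_id].network_index,
            g["gene_mean"], g["gene_var"], g["gene_min"], g["gene_max"],
            network.metabolites[t.metabolite_id].network_index,
            len(r.metabolites), len(r.substrates), len(r.products),
            int(t.is_substrate),
        ))
    features = pd.DataFrame(rows, columns=TRIPLET_COLUMNS + FEATURE_COLUMNS)
    return features, excluded


def build_labels(
    association_table: pd.DataFrame,
    features: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.Series:
    """Label each triplet row: +1 (q < alpha, rho > 0), -1 (q < alpha,
    rho < 0), 0 otherwise (unlabeled / unmeasured).  The pair's label
    propagates to every RGM triplet of that pair."""
    key = association_table.set_index(["gene_id", "metabolite_id"])
    labels = np.zeros(len(features), dtype=int)
    for i, (g, m) in enumerate(zip(features["gene_id"], features["metabolite_id"])):
        if (g, m) not in key.index:
            continue
        row = key.loc[(g, m)]
        if float(row["q"]) < alpha and not bool(row["flagged"]):
            labels[i] = 1 if float(row["rho"]) > 0 else (-1 if float(row["rho"]) < 0 else 0)
    return pd.Series(labels, index=features.index, name="label")


class ContinuousScaler(TransformerMixin, BaseEstimator):
    """Standardize continuous columns, pass binary indicator columns
    through unscaled.

    Rescaling a rare one-hot indicator to unit variance makes its
    weight artificially cheap for an L2-regularized margin, letting the
    SVM memorize single triplets for free; leaving indicators at {0, 1}
    prices identity evidence honestly against the shared numeric
    features.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        is_binary = np.array([np.isin(np.unique(col), (0.0, 1.0)).all()
                              for col in X.T])
        self.scale_mask_ = ~is_binary
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        self.mean_ = np.where(self.scale_mask_, mean, 0.0)
        self.std_ = np.where(self.scale_mask_, std, 1.0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.std_


def _make_scaler(kind: str):
    if kind == "standard":
        return StandardScaler()
    if kind == "continuous":
        return ContinuousScaler()
    raise ValueError(f"unknown scaler {kind!r}")


def _fit_platt_cv(X, y, C: float, n_splits: int,
                  scaler: str = "standard") -> tuple[float, float]:
    """Platt scaling fitted on internal training folds.

    Returns (a, b) for P(+1 | margin f) = sigmoid(a f + b), with the
    slope constrained non-negative: a refitted sigmoid must never invert
    the SVM's own ranking (on very small folds an unconstrained fit
    can), so an uninformative calibration collapses toward confidence 0
    rather than flipping signs.  A small L2 penalty stabilizes the fit
    when the fold margins are separable.
    """
    margins, labels = [], []
    skf = StratifiedKFold(n_splits=n_splits)
    for tr, te in skf.split(X, y):
        fold = make_pipeline(_make_scaler(scaler), SVC(kernel="linear", C=C))
        fold.fit(X[tr], y[tr])
        margins.append(fold.decision_function(X[te]))
        labels.append(y[te])
    f = np.concatenate(margins)
    yy = np.concatenate(labels)
    # Platt's smoothed targets keep the slope finite on separable folds
    n_pos, n_neg = float((yy == 1).sum()), float((yy == -1).sum())
    t_pos = (n_pos + 1.0) / (n_pos + 2.0)
    t_neg = 1.0 / (n_neg + 2.0)
    t = np.where(yy == 1, t_pos, t_neg)

    def nll(theta):
        a, b = theta
        z = a * f + b
        p_log = -np.logaddexp(0.0, -z)      # log sigmoid(z)
        q_log = -np.logaddexp(0.0, z)       # log (1 - sigmoid(z))
        return float(-np.sum(t * p_log + (1 - t) * q_log)
                     + 1e-3 * (a * a + b * b))

    res = minimize(nll, x0=np.array([1.0, 0.0]), method="L-BFGS-B",
                   bounds=[(0.0, None), (None, None)])
    return float(res.x[0]), float(res.x[1])


class RGMClassifier(BaseEstimator, ClassifierMixin):
    """Class-balanced linear-kernel SVM over RGM feature vectors.

    Parameters
    ----------
    C : float
        SVM regularization strength (conventional default, not tuned).
    confidence_mapping : {"calibrated", "margin"}
        "calibrated" maps Platt-calibrated P(+1|x) to 2p - 1; "margin"
        clips the raw decision margin into [-1, +1].
    random_state : int or None
        Seeds the majority-class subsampling and the internal
        calibration folds.

    Fitted attributes: ``pipeline_`` (scaler + SVM), ``platt_`` (the
    (a, b) sigmoid coefficients, calibrated mapping only), ``classes_``,
    ``n_balanced_`` (per-class training size after subsampling).
    """

    def __init__(self, C: float = 1.0, confidence_mapping: str = "calibrated",
                 scaler: str = "standard", random_state=None):
        self.C = C
        self.confidence_mapping = confidence_mapping
        self.scaler = scaler
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        if self.confidence_mapping not in ("calibrated", "margin"):
            raise ValueError(f"unknown confidence_mapping "
                             f"{self.confidence_mapping!r}")
        classes = np.unique(y)
        if not np.array_equal(classes, [-1, 1]):
            raise ValueError("need both +1 and -1 labels")
        n_pos, n_neg = int((y == 1).sum()), int((y == -1).sum())
        if min(n_pos, n_neg) < 2:
            raise ValueError(
                f"need >= 2 labels of each sign "
                f"(got {n_pos} positive, {n_neg} negative)")
        rng = check_random_state(self.random_state)
        n_min = min(n_pos, n_neg)
        keep = []
        for cls in (-1, 1):
            idx = np.flatnonzero(y == cls)
            if len(idx) > n_min:
                idx = rng.choice(idx, size=n_min, replace=False)
            keep.append(idx)
        keep = np.sort(np.concatenate(keep))
        self.pipeline_ = make_pipeline(_make_scaler(self.scaler),
                                       SVC(kernel="linear", C=self.C))
        self.pipeline_.fit(X[keep], y[keep])
        if self.confidence_mapping == "calibrated":
            self.platt_ = _fit_platt_cv(X[keep], y[keep], C=self.C,
                                        n_splits=min(MIN_LABELS_PER_CLASS,
                                                     n_min),
                                        scaler=self.scaler)
        self.classes_ = np.array([-1, 1])
        self.n_balanced_ = n_min
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Raw SVM margin (unbounded)."""
        check_is_fitted(self, "pipeline_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        return self.pipeline_.decision_function(X)

    def confidence(self, X) -> np.ndarray:
        """Per-triplet confidence in the closed interval [-1, +1]."""
        margin = self.decision_function(X)
        if self.confidence_mapping == "calibrated":
            a, b = self.platt_
            return 2.0 * expit(a * margin + b) - 1.0
        return np.clip(margin, -1.0, 1.0)

    def predict(self, X):
        return np.where(self.confidence(X) >= 0, 1, -1)


@dataclass
class CVResult:
    fold_metrics: pd.DataFrame        # auc / sensitivity / specificity / accuracy per fold
    fold_assignments: np.ndarray
    heldout_confidence: np.ndarray    # aligned with the labeled set
    heldout_score: np.ndarray         # held-out decision scores, same alignment
    seed: int | None

    @property
    def mean_auc(self) -> float:
        return float(self.fold_metrics["auc"].mean())

    @property
    def means(self) -> pd.Series:
        return self.fold_metrics.mean()


def cross_validate(X, y, k: int = 5, seed: int | None = 0,
                   **classifier_params) -> CVResult:
    """Stratified k-fold cross-validation of the RGM classifier.

    Balancing and standardization happen inside each training fold (no
    leakage).  Discrimination metrics are computed from the held-out
    decision scores (the confidence mapping is monotone in them, so AUC
    is identical either way and does not degrade if a calibration
    collapses); sensitivity, specificity and accuracy use the zero
    threshold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = {cls: int((y == cls).sum()) for cls in (-1, 1)}
    if min(counts.values()) < k:
        raise ValueError(f"fewer labeled triplets than folds: {counts}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.full(len(y), -1, dtype=int)
    heldout = np.full(len(y), np.nan)
    heldout_score = np.full(len(y), np.nan)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        clf = RGMClassifier(random_state=None if seed is None else seed + fold,
                            **classifier_params)
        clf.fit(X[tr], y[tr])
        assignments[te] = fold
        heldout[te] = clf.confidence(X[te])
        score = clf.decision_function(X[te])
        heldout_score[te] = score
        y_te = y[te]
        pred = np.where(score >= 0, 1, -1)
        tp = int(((pred == 1) & (y_te == 1)).sum())
        tn = int(((pred == -1) & (y_te == -1)).sum())
        fp = int(((pred == 1) & (y_te == -1)).sum())
        fn = int(((pred == -1) & (y_te == 1)).sum())
        auc = roc_auc_score((y_te == 1).astype(int), score) \
            if len(np.unique(y_te)) == 2 else np.nan
        rows.append({
            "auc": auc,
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
            "accuracy": (tp + tn) / len(y_te),
        })
    return CVResult(pd.DataFrame(rows), assignments, heldout, heldout_score, seed)


def predict_confidences(
    model: RGMClassifier,
    features: pd.DataFrame,
    feature_matrix: np.ndarray | None = None,
) -> pd.DataFrame:
    """Confidence table over every triplet in ``features``.

    ``feature_matrix`` is the encoded design matrix aligned with the
    rows (see encode_features); when omitted, the raw 14 columns are
    used."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    if feature_matrix is None:
        feature_matrix = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    if len(feature_matrix) != len(features):
        raise ValueError("feature matrix not aligned with triplet table")
    out = features[TRIPLET_COLUMNS].copy()
    out["confidence"] = model.confidence(feature_matrix)
    return out


def permutation_null_confidences(
    X_labeled, y_labeled, X_all,
    n_permutations: int = 20,
    seed: int = 0,
    **classifier_params,
) -> np.ndarray:
    """Pooled null confidences from classifiers retrained on label-permuted
    data (same pipeline, seeded); the reference distribution for
    confidence significance."""
    X_labeled = np.asarray(X_labeled, dtype=float)
    y_labeled = np.asarray(y_labeled, dtype=int)
    X_all = np.asarray(X_all, dtype=float)
    rng = np.random.default_rng(seed)
    pool = []
    for b in range(n_permutations):
        y_perm = rng.permutation(y_labeled)
        clf = RGMClassifier(random_state=int(rng.integers(2 ** 31 - 1)),
                            **classifier_params)
        clf.fit(X_labeled, y_perm)
        pool.append(clf.confidence(X_all))
    return np.concatenate(pool)


def confidence_significance(
    confidences,
    null_confidences,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided add-one empirical p per triplet against the permutation
    null of |confidence|, BH-adjusted across triplets."""
    conf = np.asarray(confidences, dtype=float)
    p = empirical_p_two_sided(conf, null_confidences)
    q = bh_fdr(p)
    return pd.DataFrame({"confidence": conf, "p": p, "q": q,
                         "significant": q < alpha})
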