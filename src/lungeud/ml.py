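"""Classifier comparison with and without EUD-based predictors.

Four models are compared - multiple logistic regression (MLR), a
radial-basis-function support vector machine (SVM), a depth-limited CART
decision tree (DT) and k-nearest neighbours (KNN) - on two nested predictor
sets: a "without EUD" set of conventional dose summaries (physical composite,
PTV-to-lung ratio, LKB NTCP of the affected and whole lung) and a "with EUD"
set that adds the whole-lung EUD at alpha = 0.3 and the EUD-calibrated NTCP
of the affected lung.

The cohort is split 70/30 stratified by outcome; model selection uses 5-fold
stratified cross-validation within the training split, features are
z-standardized with training-fold statistics only, and performance is the
ROC AUC on both splits. Decision-curve (net benefit) and calibration curves
evaluate the chosen model's clinical usefulness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "WITHOUT_EUD",
    "WITH_EUD",
    "MODEL_NAMES",
    "ModelResult",
    "DecisionCurve",
    "split_cohort",
    "train_and_evaluate",
    "compare_feature_sets",
    "auc_matrix",
    "decision_curve",
    "calibration_curve",
]

#: Conventional predictor set (no EUD-derived quantities).
WITHOUT_EUD = [
    "physical_composite",
    "ptv_to_lung_ratio",
    "ntcp_lkb_sick",
    "ntcp_lkb_total",
]

#: Predictor set augmented with lung EUD(0.3) and EUD-calibrated NTCP.
WITH_EUD = WITHOUT_EUD + ["lung_eud_cgy", "ntcp_eud_sick"]

MODEL_NAMES = ("MLR", "SVM", "DT", "KNN")


def _make_pipeline(name: str, seed: int, hyper: dict | None = None) -> Pipeline:
    """Standardizer + classifier pipeline with fixed, logged hyperparameters."""
    hyper = hyper or {}
    if name == "MLR":
        # unpenalized fit: C = inf disables regularization
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    elif name == "SVM":
        clf = SVC(
            kernel=hyper.get("kernel", "rbf"),
            C=hyper.get("C", 1.0),
            gamma=hyper.get("gamma", "scale"),
        )
    elif name == "DT":
        clf = DecisionTreeClassifier(
            max_depth=hyper.get("max_depth", 3), random_state=seed
        )
    elif name == "KNN":
        clf = KNeighborsClassifier(n_neighbors=hyper.get("k", 5))
    else:
        raise ValueError(f"unknown model name {name!r}; expected one of {MODEL_NAMES}")
    return Pipeline([("standardize", StandardScaler()), ("clf", clf)])


def _scores(pipe: Pipeline, X: np.ndarray) -> np.ndarray:
    """Continuous ranking scores: decision function if available, else P(class 1)."""
    clf = pipe.named_steps["clf"]
    if hasattr(clf, "decision_function"):
        return pipe.decision_function(X)
    return pipe.predict_proba(X)[:, 1]


def split_cohort(
    features: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
    label_col: str = "rp2",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified train/validation split preserving class ratio."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    y = features[label_col]
    counts = y.value_counts()
    if counts.size < 2 or counts.min() < 2:
        raise ValueError("both classes need at least two members to split")
    train, validation = train_test_split(
        features,
        train_size=train_fraction,
        stratify=y,
        random_state=seed,
        shuffle=True,
    )
    return train, validation


@dataclass
class ModelResult:
    """Fitted-model performance on one feature set."""

    model_name: str
    seed: int
    fold_aucs: list
    auc_train: float
    auc_validation: float
    roc_train: pd.DataFrame
    roc_validation: pd.DataFrame


def train_and_evaluate(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    model_name: str,
    seed: int,
    feature_cols: list | None = None,
    label_col: str = "rp2",
    folds: int = 5,
    hyper: dict | None = None,
) -> ModelResult:
    """Cross-validate on the training split, refit, and score both splits.

    Fold AUCs come from stratified k-fold CV inside the training split (the
    standardizer is refit on each fold's training part, so no information
    leaks from held-out folds); the reported train/validation AUCs use the
    model refit on the full training split.
    """
    if feature_cols is None:
        feature_cols = [c for c in train.columns if c != label_col]
    X_tr = train[feature_cols].to_numpy(dtype=float)
    y_tr = train[label_col].to_numpy(dtype=int)
    X_va = validation[feature_cols].to_numpy(dtype=float)
    y_va = validation[label_col].to_numpy(dtype=int)
    if np.unique(y_tr).size < 2:
        raise ValueError("training split must contain both classes")
    if np.unique(y_va).size < 2:
        raise ValueError("validation split must contain both classes")
    class_counts = np.bincount(y_tr)
    if class_counts[class_counts > 0].min() < folds:
        raise ValueError(
            f"each training class needs >= {folds} members for "
            f"{folds}-fold stratified cross-validation"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs = []
    for fit_idx, hold_idx in skf.split(X_tr, y_tr):
        pipe = _make_pipeline(model_name, seed, hyper)
        pipe.fit(X_tr[fit_idx], y_tr[fit_idx])
        fold_aucs.append(
            float(roc_auc_score(y_tr[hold_idx], _scores(pipe, X_tr[hold_idx])))
        )
    final = _make_pipeline(model_name, seed, hyper)
    final.fit(X_tr, y_tr)
    s_tr = _scores(final, X_tr)
    s_va = _scores(final, X_va)
    fpr_tr, tpr_tr, _ = roc_curve(y_tr, s_tr)
    fpr_va, tpr_va, _ = roc_curve(y_va, s_va)
    return ModelResult(
        model_name=model_name,
        seed=seed,
        fold_aucs=fold_aucs,
        auc_train=float(roc_auc_score(y_tr, s_tr)),
        auc_validation=float(roc_auc_score(y_va, s_va)),
        roc_train=pd.DataFrame({"fpr": fpr_tr, "tpr": tpr_tr}),
        roc_validation=pd.DataFrame({"fpr": fpr_va, "tpr": tpr_va}),
    )


def compare_feature_sets(
    features: pd.DataFrame,
    seed: int,
    models: tuple = MODEL_NAMES,
    train_fraction: float = 0.7,
    folds: int = 5,
    feature_sets: dict | None = None,
    hyper: dict | None = None,
) -> dict:
    """Train every model on both predictor sets from one stratified split.

    Returns ``{(feature_set_tag, model_name): ModelResult}``. The same split
    and CV folds are reused across feature sets, so the comparison isolates
    the effect of adding the EUD-based predictors.
    """
    if feature_sets is None:
        feature_sets = {"without_eud": WITHOUT_EUD, "with_eud": WITH_EUD}
    hyper = hyper or {}
    for tag, cols in feature_sets.items():
        missing = set(cols) - set(features.columns)
        if missing:
            raise ValueError(f"feature set {tag!r} missing columns {sorted(missing)}")
    train, validation = split_cohort(features, train_fraction, seed)
    results = {}
    for tag, cols in feature_sets.items():
        for name in models:
            results[(tag, name)] = train_and_evaluate(
                train,
                validation,
                name,
                seed,
                feature_cols=list(cols),
                folds=folds,
                hyper=hyper.get(name),
            )
    return results


def auc_matrix(results: dict) -> pd.DataFrame:
    """Long-form AUC table (feature set x model x split) from comparison results."""
    rows = []
    for (tag, name), res in results.items():
        rows.append(
            {
                "feature_set": tag,
                "model": name,
                "auc_train": res.auc_train,
                "auc_validation": res.auc_validation,
                "cv_auc_mean": float(np.mean(res.fold_aucs)),
            }
        )
    return pd.DataFrame(rows).set_index(["feature_set", "model"])


# ---------------------------------------------------------------------------
# Decision and calibration curves
# ---------------------------------------------------------------------------


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "net_benefit": self.net_benefit,
                "treat_all": self.treat_all,
                "treat_none": self.treat_none,
            }
        )


def decision_curve(
    predicted,
    labels,
    thresholds=None,
) -> DecisionCurve:
    """Decision-curve analysis: net benefit across threshold probabilities.

    ``NB(p_t) = TP/N - (FP/N) * p_t / (1 - p_t)`` for the rule "treat when
    predicted probability >= p_t", with treat-all and treat-none references.
    Thresholds >= 1 are excluded from the grid.
    """
    predicted = np.asarray(predicted, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.any(predicted < 0) or np.any(predicted > 1):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    thresholds = thresholds[(thresholds >= 0) & (thresholds < 1.0)]
    n = labels.size
    prevalence = labels.mean()
    odds = thresholds / (1.0 - thresholds)
    nb = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        treat = predicted >= t
        tp = np.sum(treat & (labels == 1))
        fp = np.sum(treat & (labels == 0))
        nb[i] = tp / n - (fp / n) * odds[i]
    treat_all = prevalence - (1.0 - prevalence) * odds
    return DecisionCurve(
        thresholds=thresholds,
        net_benefit=nb,
        treat_all=treat_all,
        treat_none=np.zeros(thresholds.size),
    )


def calibration_curve(
    predicted,
    labels,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Quantile-binned agreement between predicted probabilities and outcomes.

    Bins are formed at prediction quantiles; bins emptied by ties collapse
    into their neighbours. Returns per-bin mean prediction, observed event
    rate and count; the identity line is the ideal reference.
    """
    predicted = np.asarray(predicted, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if predicted.size != labels.size or predicted.size == 0:
        raise ValueError("predicted and labels must be equal-length, non-empty")
    edges = np.unique(np.quantile(predicted, np.linspace(0.0, 1.0, n_bins + 1)))
    if edges.size <= 2:  # ties collapsed everything into one bin
        return pd.DataFrame(
            {
                "mean_predicted": [float(predicted.mean())],
                "observed_rate": [float(labels.mean())],
                "n": [int(predicted.size)],
            }
        )
    inner = edges[1:-1]
    idx = np.searchsorted(inner, predicted, side="right")
    rows = []
    for b in range(edges.size - 1):
        mask = idx == b
        if not np.any(mask):
            continue
        rows.append(
            {
                "mean_predicted": float(predicted[mask].mean()),
                "observed_rate": float(labels[mask].mean()),
                "n": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)
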