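"""The eight-classifier supervised comparison under 10-fold cross-validation.

Models: decision tree (DT), linear discriminant analysis (LDA), logistic
regression (LR), four SVM kernels (linear, quadratic, cubic, fine
Gaussian), and 1-nearest-neighbour with Euclidean distance. Features are
standardised inside each fold's pipeline. Preterm is the positive class.

Metrics are pooled over folds: the confusion matrices are summed and the
per-sample scores concatenated before accuracy, sensitivity, specificity
and ROC-AUC are computed (all reported as percentages); per-fold metrics
are retained alongside. For 1-NN the AUC score of a sample is the distance
margin d(nearest term neighbour) - d(nearest preterm neighbour).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .balance import BalanceConfig, smote
from .features import FEATURE_NAMES

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "EvalReport",
    "compute_metrics",
    "crossval_eval",
    "run_model_suite",
]

MODEL_NAMES = ("DT", "LDA", "LR", "LSVM", "QSVM", "CSVM", "FGSVM", "KNN")

POSITIVE_LABEL = "preterm"  # clinical aim: detect preterm labour

# small, documented hyperparameter grids for tuning="grid"
_GRIDS: dict[str, dict] = {
    "DT": {"clf__max_depth": [3, 5, None]},
    "LDA": {},
    "LR": {"clf__C": [0.1, 1.0, 10.0]},
    "LSVM": {"clf__C": [0.1, 1.0, 10.0]},
    "QSVM": {"clf__C": [0.1, 1.0, 10.0]},
    "CSVM": {"clf__C": [0.1, 1.0, 10.0]},
    "FGSVM": {"clf__C": [1.0, 10.0], "clf__gamma": [4.0, 16.0]},
    "KNN": {},
}


@dataclass
class ModelSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)
    tuning: str = "fixed"  # or "grid"

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"model name must be one of {MODEL_NAMES}")
        if self.tuning not in ("fixed", "grid"):
            raise ValueError("tuning must be 'fixed' or 'grid'")


@dataclass
class EvalReport:
    model: str
    acc: float
    sens: float
    spec: float
    auc: float
    per_fold: list[dict]
    confusion: np.ndarray  # [[TN, FP], [FN, TP]], positive = preterm


def _build_estimator(spec: ModelSpec, seed: int, n_features: int) -> Pipeline:
    hp = dict(spec.hyperparameters)
    name = spec.name
    if name == "DT":
        clf = DecisionTreeClassifier(random_state=seed, **hp)
    elif name == "LDA":
        clf = LinearDiscriminantAnalysis(**hp)
    elif name == "LR":
        clf = LogisticRegression(max_iter=2000, **hp)
    elif name == "LSVM":
        clf = SVC(kernel="linear", C=hp.pop("C", 1.0), **hp)
    elif name == "QSVM":
        clf = SVC(kernel="poly", degree=2, coef0=1.0, C=hp.pop("C", 1.0), **hp)
    elif name == "CSVM":
        clf = SVC(kernel="poly", degree=3, coef0=1.0, C=hp.pop("C", 1.0), **hp)
    elif name == "FGSVM":
        # "fine" Gaussian: a narrow kernel, scale sqrt(P)/4 -> gamma = 16/P
        gamma = hp.pop("gamma", 16.0 / max(n_features, 1))
        clf = SVC(kernel="rbf", gamma=gamma, C=hp.pop("C", 1.0), **hp)
    elif name == "KNN":
        clf = KNeighborsClassifier(
            n_neighbors=hp.pop("n_neighbors", 1), metric="euclidean", **hp
        )
    pipe = Pipeline([("scale", StandardScaler()), ("clf", clf)])
    if spec.tuning == "grid" and _GRIDS[name]:
        return GridSearchCV(pipe, _GRIDS[name], cv=3, scoring="accuracy")
    return pipe


def _scores(fitted, spec: ModelSpec, X_train, y_train, X_test) -> np.ndarray:
    """Continuous preterm-leaning score per test sample (larger = preterm)."""
    est = fitted.best_estimator_ if isinstance(fitted, GridSearchCV) else fitted
    if spec.name == "KNN":
        Xt_train = est.named_steps["scale"].transform(X_train)
        Xt_test = est.named_steps["scale"].transform(X_test)
        d_pos, _ = NearestNeighbors(n_neighbors=1).fit(
            Xt_train[y_train == 1]
        ).kneighbors(Xt_test)
        d_neg, _ = NearestNeighbors(n_neighbors=1).fit(
            Xt_train[y_train == 0]
        ).kneighbors(Xt_test)
        return d_neg.ravel() - d_pos.ravel()
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X_test), dtype=float)
    return np.asarray(est.predict_proba(X_test)[:, 1], dtype=float)


def compute_metrics(
    confusion: np.ndarray, scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, float]:
    """(acc, sens, spec, auc), each x100. Positive class is row/column 1.

    AUC is the trapezoidal area under the ROC of the scores, which with
    midrank tie handling equals the Mann-Whitney pair-counting statistic.
    """
    conf = np.asarray(confusion, dtype=float)
    if conf.shape != (2, 2) or conf.sum() == 0 or np.any(conf < 0):
        raise ValueError("confusion must be a non-negative, non-empty 2x2 table")
    (tn, fp), (fn, tp) = conf
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present")
    acc = (tp + tn) / conf.sum()
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC undefined with a single class")
    auc = roc_auc_score(labels, np.asarray(scores, dtype=float))
    return 100.0 * acc, 100.0 * sens, 100.0 * spec, 100.0 * auc


def encode_labels(labels) -> np.ndarray:
    """Map term/preterm (or 0/1) labels to ints with preterm = 1."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iub":
        return arr.astype(int)
    return (arr == POSITIVE_LABEL).astype(int)


def _impute_nonfinite(X_train: np.ndarray, X_test: np.ndarray):
    """Replace non-finite cells by the training-fold column mean."""
    X_train = X_train.copy()
    X_test = X_test.copy()
    for j in range(X_train.shape[1]):
        col = X_train[:, j]
        finite = np.isfinite(col)
        fill = col[finite].mean() if finite.any() else 0.0
        col[~finite] = fill
        test_col = X_test[:, j]
        test_col[~np.isfinite(test_col)] = fill
    return X_train, X_test


def crossval_eval(
    X: np.ndarray,
    y,
    spec: ModelSpec,
    k_folds: int = 10,
    seed: int = 0,
    balance: BalanceConfig | None = None,
    groups: np.ndarray | None = None,
) -> EvalReport:
    """Stratified k-fold evaluation of one model.

    Balancing (if configured) is applied inside each training fold, or once
    before splitting when ``balance.mode == 'before_split'``. ``groups``
    switches to patient-grouped stratified folds, keeping all windows of a
    patient in the same fold.
    """
    X = np.asarray(X, dtype=float)
    y = encode_labels(y)
    if min(np.bincount(y, minlength=2)) < k_folds:
        raise ValueError("each class needs at least k_folds samples")

    if balance is not None and balance.mode == "before_split":
        X, y, _ = smote(X, y, balance)
        groups = None if groups is None else None  # synthetic rows have no patient

    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y)

    conf = np.zeros((2, 2))
    all_scores, all_labels = [], []
    per_fold = []
    for fold, (tr, te) in enumerate(split):
        X_tr, y_tr = X[tr], y[tr]
        X_te, y_te = X[te], y[te]
        if len(set(y_te.tolist())) < 2 or len(set(y_tr.tolist())) < 2:
            raise ValueError("a class is absent from a fold; use fewer folds")
        if balance is not None and balance.mode == "within_train_folds":
            X_tr, y_tr, _ = smote(
                X_tr, y_tr, BalanceConfig(balance.k_neighbors, balance.seed + fold)
            )
        X_tr, X_te = _impute_nonfinite(X_tr, X_te)
        est = _build_estimator(spec, seed, X.shape[1])
        est.fit(X_tr, y_tr)
        pred = est.predict(X_te)
        scores = _scores(est, spec, X_tr, y_tr, X_te)
        fold_conf = np.zeros((2, 2))
        for truth, p in zip(y_te, pred):
            fold_conf[truth, p] += 1
        conf += fold_conf
        all_scores.append(scores)
        all_labels.append(y_te)
        per_fold.append(
            {
                "fold": fold,
                "n": int(te.size),
                "acc": 100.0 * float((pred == y_te).mean()),
            }
        )

    acc, sens, spc, auc = compute_metrics(
        conf, np.concatenate(all_scores), np.concatenate(all_labels)
    )
    return EvalReport(spec.name, acc, sens, spc, auc, per_fold, conf)


def run_model_suite(
    features_raw: pd.DataFrame,
    features_lsdl: pd.DataFrame | None,
    seed: int = 0,
    specs: list[ModelSpec] | None = None,
    k_folds: int = 10,
    balance: BalanceConfig | None = None,
    grouped: bool = False,
) -> tuple[pd.DataFrame, dict[str, dict[str, EvalReport]]]:
    """Evaluate every model on the raw and LSDL-decomposed feature tables.

    Returns (table, reports): the table mirrors the published layout with
    paired Raw-/LSDL- columns per metric; ``reports`` holds the full
    EvalReport per model and arm.
    """
    specs = specs or [ModelSpec(name) for name in MODEL_NAMES]
    arms: dict[str, pd.DataFrame] = {"Raw": features_raw}
    if features_lsdl is not None:
        arms["LSDL"] = features_lsdl

    reports: dict[str, dict[str, EvalReport]] = {}
    for arm, table in arms.items():
        X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
        y = table["label"].to_numpy()
        groups = table["patient_id"].to_numpy() if grouped else None
        for spec in specs:
            rep = crossval_eval(
                X, y, spec, k_folds=k_folds, seed=seed, balance=balance, groups=groups
            )
            reports.setdefault(spec.name, {})[arm] = rep

    rows = []
    for spec in specs:
        row: dict[str, object] = {"Model": spec.name}
        for metric in ("Acc", "Sens", "Spec", "AUC"):
            for arm in arms:
                rep = reports[spec.name][arm]
                row[f"{arm}-{metric} (%)"] = round(
                    getattr(rep, metric.lower()), 1
                )
        rows.append(row)
    columns = ["Model"]
    for metric in ("Acc", "Sens", "Spec", "AUC"):
        for arm in arms:
            columns.append(f"{arm}-{metric} (%)")
    return pd.DataFrame(rows, columns=columns), reports
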