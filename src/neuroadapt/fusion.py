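"""Multimodal feature fusion and disorder classification.

The feature table joins EEG, cardiac, and gaze features per (participant,
condition) row, named ``<modality>.<metric>[.<site|band>]``. Classification
is evaluated with stratified nested cross-validation: an outer 10-fold loop
estimates generalization; within each outer-training set, an inner 5-fold
loop selects the margin-classifier regularization ``C``, and univariate
ANOVA-F top-k feature selection (default k = 124, capped at the available
feature count) plus z-scaling are fitted on training rows only — test rows
never influence imputation, scaling, selection, or hyperparameters.

The classifier is a weighted soft-voting ensemble of three probabilistic
learners — an RBF-kernel SVM (weight 0.40), a two-hidden-layer feed-forward
network with dropout-style regularization via early stopping (0.35), and a
random forest (0.25). The ensemble score is affine in the base
probabilities; ties break by the fixed class order (ASD, ADHD, SLD, TD).

A temporal hold-out withholds the last 20% of rows by recruitment order:
nested CV runs on the development split, then one final model fitted on all
development rows is scored once on the hold-out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

CLASS_ORDER = ("ASD", "ADHD", "SLD", "TD")
DEFAULT_WEIGHTS = (0.40, 0.35, 0.25)
SVM_C_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0)
META_COLUMNS = ("participant", "condition", "group", "recruitment_order")


# ------------------------------------------------------------ feature table

@dataclass
class FeatureTable:
    """Rows = (participant, condition) sessions; columns = named features."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("participant", "group") if c not in self.frame]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        if self.frame["group"].isna().any():
            raise ValueError("missing labels")
        names = self.feature_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in META_COLUMNS]

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["group"].to_numpy()

    @property
    def n_rows(self) -> int:
        return len(self.frame)


def assemble_features(rows: list[dict]) -> FeatureTable:
    """Join per-row modality dicts into a feature table.

    Each row dict carries ``participant``, ``group`` (and optionally
    ``condition`` / ``recruitment_order``) plus ``eeg``, ``ecg``, ``gaze``
    metric dicts. Rows missing any modality are dropped with a warning
    naming the participant.
    """
    records = []
    for row in rows:
        missing = [m for m in ("eeg", "ecg", "gaze") if not row.get(m)]
        if missing:
            warnings.warn(
                f"participant {row.get('participant')!r} missing modality "
                f"{missing}; row dropped", stacklevel=2)
            continue
        rec = {k: row.get(k) for k in META_COLUMNS if k in row}
        for modality in ("eeg", "ecg", "gaze"):
            for name, value in row[modality].items():
                rec[f"{modality}.{name}"] = value
        records.append(rec)
    if not records:
        raise ValueError("no rows with all three modalities")
    return FeatureTable(frame=pd.DataFrame.from_records(records))


# ------------------------------------------------------------------- folds

@dataclass
class FoldPlan:
    outer: list[tuple[np.ndarray, np.ndarray]]
    inner: list[list[tuple[np.ndarray, np.ndarray]]]  # relative to outer train
    seed: int
    k_outer: int
    k_inner: int


def stratified_folds(labels: np.ndarray, k_outer: int = 10, k_inner: int = 5,
                     seed: int = 0) -> FoldPlan:
    """Deterministic stratified outer/inner fold assignments."""
    labels = np.asarray(labels)
    if k_outer < 2 or k_inner < 2:
        raise ValueError("fold counts must be at least 2")
    classes, counts = np.unique(labels, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < k_outer:
            raise ValueError(f"class {cls!r} has {cnt} rows < k_outer={k_outer}")
    outer_cv = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
    outer = [(tr, te) for tr, te in outer_cv.split(np.zeros(labels.size), labels)]
    inner = []
    for i, (tr, _) in enumerate(outer):
        inner_cv = StratifiedKFold(n_splits=k_inner, shuffle=True,
                                   random_state=seed + 1000 + i)
        inner.append([(a, b) for a, b in
                      inner_cv.split(np.zeros(tr.size), labels[tr])])
    return FoldPlan(outer=outer, inner=inner, seed=seed,
                    k_outer=k_outer, k_inner=k_inner)


# ---------------------------------------------------------------- selection

@dataclass
class Selector:
    """In-fold fitted preprocessing: median imputation, ANOVA-F top-k
    selection, and z-scaling — all statistics from training rows only."""

    indices: np.ndarray
    medians: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    scores: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float).copy()
        for j in range(X.shape[1]):
            bad = ~np.isfinite(X[:, j])
            X[bad, j] = self.medians[j]
        Z = X[:, self.indices]
        return (Z - self.means) / self.sds


def select_topk(X: np.ndarray, y: np.ndarray, k: int = 124) -> Selector:
    """Rank features by one-way ANOVA F on training rows; retain top k."""
    X = np.asarray(X, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    k = min(k, X.shape[1])
    medians = np.nanmedian(np.where(np.isfinite(X), X, np.nan), axis=0)
    medians = np.where(np.isfinite(medians), medians, 0.0)
    Xi = X.copy()
    for j in range(Xi.shape[1]):
        bad = ~np.isfinite(Xi[:, j])
        Xi[bad, j] = medians[j]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features yield F=nan
        F, _ = f_classif(Xi, y)
    F = np.where(np.isfinite(F), F, -np.inf)
    order = np.argsort(-F, kind="stable")
    indices = np.sort(order[:k])
    Z = Xi[:, indices]
    means = Z.mean(axis=0)
    sds = Z.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    return Selector(indices=indices, medians=medians, means=means, sds=sds,
                    scores=F)


# ----------------------------------------------------------------- ensemble

@dataclass
class EnsembleModel:
    models: list
    weights: tuple[float, float, float]
    selector: Selector
    classes: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = self.selector.transform(X)
        proba = np.zeros((Z.shape[0], self.classes.size))
        for w, model in zip(self.weights, self.models):
            p = model.predict_proba(Z)
            cols = {c: i for i, c in enumerate(model.classes_)}
            aligned = np.zeros_like(proba)
            for i, c in enumerate(self.classes):
                if c in cols:
                    aligned[:, i] = p[:, cols[c]]
            proba += w * aligned
        return proba

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes[np.argmax(proba, axis=1)]


def _class_sorted(y: np.ndarray) -> np.ndarray:
    present = set(np.unique(y))
    ordered = [c for c in CLASS_ORDER if c in present]
    ordered += sorted(present - set(CLASS_ORDER))
    return np.array(ordered)


def fit_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    selector: Selector,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    seed: int = 0,
    svm_c: float = 1.0,
    n_trees: int = 500,
) -> EnsembleModel:
    """Fit the three base learners on selected, z-scored training features."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("single-class training set")
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        warnings.warn("ensemble weights do not sum to 1; renormalizing",
                      stacklevel=2)
        w = w / w.sum()
    Z = selector.transform(X)
    svm = SVC(C=svm_c, kernel="rbf", gamma="scale", probability=True,
              random_state=seed)
    net = MLPClassifier(hidden_layer_sizes=(64, 32), alpha=1e-3,
                        early_stopping=True, n_iter_no_change=20,
                        validation_fraction=0.15, max_iter=400,
                        random_state=seed)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter
        for model in (svm, net, forest):
            model.fit(Z, y)
    return EnsembleModel(models=[svm, net, forest], weights=tuple(w),
                         selector=selector, classes=_class_sorted(y))


# ------------------------------------------------------------------ reports

@dataclass
class ClassificationReport:
    accuracy: float
    per_class: pd.DataFrame          # sensitivity/specificity/PPV/NPV (%)
    macro_auc: float
    confusion: pd.DataFrame
    fold_accuracies: list[float] = field(default_factory=list)
    predictions: np.ndarray | None = None

    @property
    def fold_sd(self) -> float:
        if len(self.fold_accuracies) < 2:
            return float("nan")
        return float(np.std(self.fold_accuracies, ddof=1))

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": 100.0 * self.accuracy,
            "macro_auc": self.macro_auc,
            "fold_accuracy_sd_pct": 100.0 * self.fold_sd,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.to_dict(orient="index"),
        }


def _report(y_true: np.ndarray, y_pred: np.ndarray, proba: np.ndarray,
            classes: np.ndarray,
            fold_accs: list[float] | None = None) -> ClassificationReport:
    """Pooled metrics over out-of-fold predictions."""
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    rows = {}
    total = cm.sum()
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        rows[cls] = {
            "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
            "ppv": 100.0 * tp / (tp + fp) if tp + fp else float("nan"),
            "npv": 100.0 * tn / (tn + fn) if tn + fn else float("nan"),
        }
    try:
        y_bin = np.array([np.flatnonzero(classes == v)[0] for v in y_true])
        auc = float(roc_auc_score(y_bin, proba, multi_class="ovr",
                                  average="macro", labels=range(classes.size)))
    except ValueError:
        auc = float("nan")
    return ClassificationReport(
        accuracy=float(np.mean(y_true == y_pred)),
        per_class=pd.DataFrame.from_dict(rows, orient="index"),
        macro_auc=auc,
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        fold_accuracies=fold_accs or [],
        predictions=np.asarray(y_pred),
    )


def _tune_svm_c(X: np.ndarray, y: np.ndarray,
                inner_folds: list[tuple[np.ndarray, np.ndarray]],
                k: int, seed: int) -> float:
    """Inner-CV selection of the SVM cost parameter."""
    best_c, best_acc = SVM_C_GRID[0], -1.0
    for c in SVM_C_GRID:
        accs = []
        for tr, va in inner_folds:
            sel = select_topk(X[tr], y[tr], k=k)
            svm = SVC(C=c, kernel="rbf", gamma="scale", random_state=seed)
            svm.fit(sel.transform(X[tr]), y[tr])
            accs.append(np.mean(svm.predict(sel.transform(X[va])) == y[va]))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_acc, best_c = acc, c
    return best_c


def nested_cv(table: FeatureTable, plan: FoldPlan, k_features: int = 124,
              weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
              n_trees: int = 500) -> ClassificationReport:
    """Leakage-free nested cross-validation of the fusion ensemble."""
    X, y = table.X, table.y
    if any(len(tr) + len(te) != table.n_rows for tr, te in plan.outer):
        raise ValueError("fold plan inconsistent with table size")
    classes = _class_sorted(y)
    y_pred = np.empty(table.n_rows, dtype=object)
    proba_all = np.zeros((table.n_rows, classes.size))
    fold_accs = []
    for (tr, te), inner in zip(plan.outer, plan.inner):
        c = _tune_svm_c(X[tr], y[tr], inner, k=k_features, seed=plan.seed)
        selector = select_topk(X[tr], y[tr], k=k_features)
        model = fit_ensemble(X[tr], y[tr], selector, weights=weights,
                             seed=plan.seed, svm_c=c, n_trees=n_trees)
        proba = model.predict_proba(X[te])
        pred = model.classes[np.argmax(proba, axis=1)]
        y_pred[te] = pred
        cols = {c_: i for i, c_ in enumerate(model.classes)}
        for i, c_ in enumerate(classes):
            if c_ in cols:
                proba_all[te, i] = proba[:, cols[c_]]
        fold_accs.append(float(np.mean(pred == y[te])))
    return _report(y, y_pred.astype(str), proba_all, classes, fold_accs)


def temporal_holdout(table: FeatureTable, holdout_fraction: float = 0.2,
                     k_outer: int = 10, k_inner: int = 5, seed: int = 0,
                     k_features: int = 124, n_trees: int = 500,
                     ) -> tuple[ClassificationReport, ClassificationReport]:
    """Sequester the last ``holdout_fraction`` of rows by recruitment order;
    nested CV on the rest, then one final fit scored once on the hold-out."""
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout fraction must lie in (0, 1)")
    if "recruitment_order" not in table.frame:
        raise ValueError("rows need a recruitment_order key")
    frame = table.frame.sort_values("recruitment_order", kind="stable")
    # split on recruitment order so all rows of a participant stay together
    orders = np.sort(frame["recruitment_order"].unique())
    n_hold = max(int(round(holdout_fraction * orders.size)), 1)
    cut = orders[-n_hold]
    dev = FeatureTable(frame=frame[frame["recruitment_order"] < cut]
                       .reset_index(drop=True))
    hold = FeatureTable(frame=frame[frame["recruitment_order"] >= cut]
                        .reset_index(drop=True))
    assert not set(dev.frame["participant"]) & set(hold.frame["participant"]), \
        "hold-out overlaps development ids"
    plan = stratified_folds(dev.y, k_outer=k_outer, k_inner=k_inner, seed=seed)
    dev_report = nested_cv(dev, plan, k_features=k_features, n_trees=n_trees)
    selector = select_topk(dev.X, dev.y, k=k_features)
    final = fit_ensemble(dev.X, dev.y, selector, seed=seed, n_trees=n_trees)
    proba = final.predict_proba(hold.X)
    pred = final.classes[np.argmax(proba, axis=1)]
    hold_report = _report(hold.y, pred, proba, final.classes)
    return dev_report, hold_report
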