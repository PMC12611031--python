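"""Cross-validation and confusion-matrix metrics.

Folds partition *subjects* (never individual records or windows), stratified
by group by default since a 15/10 cohort split 10 ways would otherwise
regularly produce single-class folds.  The MS group is the positive class
throughout.  Per-fold metrics are averaged across folds (mean +/- sd), the
protocol used for the reported tables; pooled-count metrics over the summed
confusion matrix are also provided for transparency.  Metrics with a zero
denominator are flagged as NaN, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .classify import WindowSet, make_classifier, predict_subjects, train_cnn
from .cnn import CNNSpec
from .features import FEATURE_NAMES

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "FoldPlan",
    "make_folds",
    "compute_metrics",
    "cross_validate",
    "cross_validate_cnn",
    "repeated_cv",
]

POSITIVE = "ms"

METRIC_NAMES = ("fpr", "fnr", "ppv", "npv", "se", "sp", "acc")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred, positive: str = POSITIVE) -> "ConfusionMatrix":
        yt = np.asarray(y_true) == positive
        yp = np.asarray(y_pred) == positive
        return cls(
            tp=int(np.sum(yt & yp)),
            tn=int(np.sum(~yt & ~yp)),
            fp=int(np.sum(~yt & yp)),
            fn=int(np.sum(yt & ~yp)),
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricsReport:
    """FPR, FNR, PPV, NPV, Se, Sp, Acc as proportions; NaN where undefined."""

    fpr: float
    fnr: float
    ppv: float
    npv: float
    se: float
    sp: float
    acc: float

    def as_series(self) -> pd.Series:
        return pd.Series({m: getattr(self, m) for m in METRIC_NAMES})

    def as_percent(self) -> pd.Series:
        return 100.0 * self.as_series()


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The standard confusion-matrix metric set.

    FPR = FP/(FP+TN), FNR = FN/(TP+FN), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
    Se = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total.  A zero
    denominator yields NaN for that metric.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricsReport(
        fpr=_ratio(cm.fp, cm.fp + cm.tn),
        fnr=_ratio(cm.fn, cm.tp + cm.fn),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        se=_ratio(cm.tp, cm.tp + cm.fn),
        sp=_ratio(cm.tn, cm.tn + cm.fp),
        acc=_ratio(cm.tp + cm.tn, cm.total),
    )


@dataclass
class FoldPlan:
    k: int
    assignment: dict[str, int]  # subject_id -> fold index
    stratified: bool
    seed: int

    def fold_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)

    def train_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f != fold)


def make_folds(
    subject_ids, labels, k: int = 10, seed: int = 0, stratified: bool = True
) -> FoldPlan:
    """Deterministic subject-level k-fold plan (stratified by default)."""
    subject_ids = list(subject_ids)
    labels = list(labels)
    uniq = list(dict.fromkeys(subject_ids))
    lab = {s: l for s, l in zip(subject_ids, labels)}
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(uniq):
        raise ValueError(f"k={k} exceeds the {len(uniq)} available subjects")
    y = np.array([lab[s] for s in uniq])
    # stratification is infeasible once k exceeds the minority-class count
    # (e.g. leave-one-out); fall back to a plain shuffled split there
    _, class_counts = np.unique(y, return_counts=True)
    if stratified and k > class_counts.min():
        stratified = False
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(uniq)), y)):
        for i in test_idx:
            assignment[uniq[i]] = fold
    return FoldPlan(k=k, assignment=assignment, stratified=stratified, seed=seed)


@dataclass
class CVResult:
    fold_metrics: list[MetricsReport]
    fold_matrices: list[ConfusionMatrix]
    predictions: pd.DataFrame = field(repr=False)

    @property
    def pooled_matrix(self) -> ConfusionMatrix:
        cm = self.fold_matrices[0]
        for other in self.fold_matrices[1:]:
            cm = cm + other
        return cm

    def summary(self) -> pd.DataFrame:
        """Per-metric mean +/- sd across folds, plus pooled-count metrics."""
        table = pd.DataFrame([m.as_series() for m in self.fold_metrics])
        pooled = compute_metrics(self.pooled_matrix).as_series()
        return pd.DataFrame(
            {
                "mean": table.mean(),
                "sd": table.std(ddof=1),
                "n_folds_defined": table.notna().sum(),
                "pooled": pooled,
            }
        )

    @property
    def mean_accuracy(self) -> float:
        return float(np.nanmean([m.acc for m in self.fold_metrics]))


def _feature_matrix(df: pd.DataFrame) -> np.ndarray:
    cols = [c for c in FEATURE_NAMES if c in df.columns]
    return df[cols].to_numpy(dtype=float)


def cross_validate(
    features: pd.DataFrame,
    method: str = "svm",
    plan: FoldPlan | None = None,
    k: int = 10,
    seed: int = 0,
    **classifier_kwargs,
) -> CVResult:
    """Subject-wise k-fold CV of a feature-space classifier.

    ``features`` is a cohort feature table (rows = subject-stage records).
    All rows of a subject stay on the same side of every split; the model is
    fitted on training-fold rows only (standardisation included) and scored
    on the held-out rows.
    """
    subjects = features["subject_id"].to_numpy()
    groups = features["group"].to_numpy()
    if plan is None:
        plan = make_folds(subjects, groups, k=k, seed=seed)
    x = _feature_matrix(features)
    y = groups
    fold_metrics, fold_cms, preds = [], [], []
    for fold in range(plan.k):
        test_s = set(plan.fold_subjects(fold))
        test_mask = np.isin(subjects, list(test_s))
        model = make_classifier(method, seed=seed + fold, **classifier_kwargs)
        model.fit(x[~test_mask], y[~test_mask])
        y_pred = model.predict(x[test_mask])
        cm = ConfusionMatrix.from_labels(y[test_mask], y_pred)
        fold_cms.append(cm)
        fold_metrics.append(compute_metrics(cm))
        preds.append(
            pd.DataFrame(
                {
                    "subject_id": subjects[test_mask],
                    "fold": fold,
                    "true": y[test_mask],
                    "pred": y_pred,
                }
            )
        )
    return CVResult(fold_metrics, fold_cms, pd.concat(preds, ignore_index=True))


def cross_validate_cnn(
    windows: WindowSet,
    spec: CNNSpec | None = None,
    plan: FoldPlan | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[CVResult, CVResult]:
    """Subject-wise k-fold CV of the CNN on raw windows.

    Returns ``(subject_level, window_level)`` results: subject labels come
    from the majority vote over each held-out subject's windows; window-level
    metrics are computed over the same held-out windows directly.
    """
    sub_labels = windows.subject_labels()
    subjects = sorted(sub_labels)
    if plan is None:
        plan = make_folds(subjects, [sub_labels[s] for s in subjects], k=k, seed=seed)
    s_metrics, s_cms, w_metrics, w_cms, preds = [], [], [], [], []
    for fold in range(plan.k):
        test_s = plan.fold_subjects(fold)
        train = windows.subset(plan.train_subjects(fold))
        test = windows.subset(test_s)
        model = train_cnn(train, spec=spec, seed=seed + fold, test_subjects=test_s)
        votes = predict_subjects(model, test)
        y_true = [sub_labels[s] for s in test_s]
        y_pred = [votes[s] for s in test_s]
        cm = ConfusionMatrix.from_labels(y_true, y_pred)
        s_cms.append(cm)
        s_metrics.append(compute_metrics(cm))
        win_pred = model.predict(test.x)
        wcm = ConfusionMatrix.from_labels(test.labels, win_pred)
        w_cms.append(wcm)
        w_metrics.append(compute_metrics(wcm))
        preds.append(pd.DataFrame({"subject_id": test_s, "fold": fold, "true": y_true, "pred": y_pred}))
    pred_df = pd.concat(preds, ignore_index=True)
    return CVResult(s_metrics, s_cms, pred_df), CVResult(w_metrics, w_cms, pred_df)


def repeated_cv(
    features: pd.DataFrame,
    method: str = "svm",
    n_reps: int = 500,
    k: int = 10,
    seed: int = 0,
    n_bins: int = 20,
    **classifier_kwargs,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Accuracy distribution over repeated independent k-fold runs.

    Each repetition re-randomises both the fold assignment and the classifier
    seed (seeded ``seed + rep``).  Returns the ``n_reps`` pooled (fold-mean)
    accuracies and a relative-frequency histogram table.
    """
    accs = np.empty(n_reps)
    subjects = features["subject_id"].to_numpy()
    groups = features["group"].to_numpy()
    for rep in range(n_reps):
        plan = make_folds(subjects, groups, k=k, seed=seed + rep)
        res = cross_validate(features, method=method, plan=plan, seed=seed + rep, **classifier_kwargs)
        accs[rep] = res.mean_accuracy
    counts, edges = np.histogram(accs, bins=n_bins, range=(0.0, 1.0))
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "relative_frequency": counts / n_reps}
    )
    return accs, hist
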