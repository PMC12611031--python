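"""Classifier back-ends: RBF-SVM, RobustBoost, and the raw-signal CNN.

The SVM and boosting models operate on the 30-entry feature vectors; the CNN
operates on raw multi-lead signal windows (each record split into 300
contiguous segments).  Feature standardisation always uses training-fold
statistics only (the scaler is fitted inside each model's ``fit``), and CNN
training refuses outright to proceed if any training window belongs to a
declared test subject — subject-wise isolation is an error-level contract,
not a warning.

RobustBoost follows the boost-by-majority approximation: example weights are
Gaussian-potential weights about a target margin trajectory mu(t) over a
"robust time" t in [0, 1]; each cycle fits a tree to the weighted sample and
jointly solves for the time advance dt and the vote weight alpha such that
the average potential is conserved and the new weights decorrelate from the
fitted tree.  Training self-terminates when t reaches 1.  The calibration
constant rho is set so that the potential at (t=0, margin=0) equals the
requested error goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as _opt
from scipy import stats as _ss
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import AdaBoostClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cnn import CNNSpec, NumpyCNN
from .synthetic import BeatAnnotations, ECGRecord

__all__ = [
    "BoostConfig",
    "SVMRBF",
    "RobustBoostClassifier",
    "WindowSet",
    "train_svm_rbf",
    "train_robustboost",
    "window_signal",
    "windows_from_cohort",
    "train_cnn",
    "predict",
    "predict_subjects",
    "make_classifier",
]


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if len(classes) > 2:
        raise ValueError("binary classification only")
    return classes


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------


class SVMRBF(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM with median-heuristic kernel scale.

    Features are z-scored with training statistics; the kernel scale, unless
    given, is the median pairwise Euclidean distance of the z-scored training
    points (gamma = 1 / (2 * scale^2)); the box constraint defaults to 1.
    """

    def __init__(self, kernel_scale: float | None = None, box_constraint: float = 1.0):
        self.kernel_scale = kernel_scale
        self.box_constraint = box_constraint

    def fit(self, x: np.ndarray, y: np.ndarray) -> "SVMRBF":
        x = np.asarray(x, dtype=float)
        self.classes_ = _check_two_classes(y)
        self.scaler_ = StandardScaler().fit(x)
        xz = self.scaler_.transform(x)
        scale = self.kernel_scale
        if scale is None:
            d = np.sqrt(((xz[:, None, :] - xz[None, :, :]) ** 2).sum(-1))
            med = np.median(d[np.triu_indices(len(xz), k=1)])
            scale = med if med > 0 else 1.0
        self.kernel_scale_ = float(scale)
        self.svc_ = SVC(C=self.box_constraint, kernel="rbf", gamma=1.0 / (2.0 * scale**2))
        self.svc_.fit(xz, y)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if len(x) == 0:
            return np.asarray([], dtype=self.classes_.dtype)
        return self.svc_.predict(self.scaler_.transform(np.asarray(x, dtype=float)))

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return self.svc_.decision_function(self.scaler_.transform(np.asarray(x, dtype=float)))


def train_svm_rbf(
    features: np.ndarray, labels: np.ndarray, kernel_scale: float | None = None, box_constraint: float = 1.0
) -> SVMRBF:
    return SVMRBF(kernel_scale=kernel_scale, box_constraint=box_constraint).fit(features, labels)


# ---------------------------------------------------------------------------
# RobustBoost
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoostConfig:
    """Boosting configuration: 100 tree cycles by default.

    ``robustness_target`` is the error-rate goal in [0, 1) that calibrates
    the potential schedule; ``sigma_margin`` the final margin-distribution
    width; ``algorithm`` may be "robustboost" or the plain "adaboost"
    fallback behind the same interface.
    """

    n_cycles: int = 100
    base_learner: str = "tree"
    robustness_target: float = 0.1
    sigma_margin: float = 0.1
    theta: float = 0.0
    max_depth: int = 3
    algorithm: str = "robustboost"

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0 <= self.robustness_target < 1:
            raise ValueError("robustness_target must be in [0, 1)")
        if self.base_learner != "tree":
            raise ValueError("only tree base learners are supported")
        if self.algorithm not in ("robustboost", "adaboost"):
            raise ValueError("algorithm must be 'robustboost' or 'adaboost'")


class RobustBoostClassifier(BaseEstimator, ClassifierMixin):
    """Boost-by-majority approximation over decision-tree learners."""

    def __init__(self, config: BoostConfig | None = None, seed: int = 0):
        self.config = config or BoostConfig()
        self.seed = seed

    # --- potential schedule -------------------------------------------------
    def _sigma(self, t: float) -> float:
        sf2 = self.config.sigma_margin**2
        return float(np.sqrt(max((sf2 + 1.0) * np.exp(2.0 * (1.0 - t)) - 1.0, sf2)))

    def _mu(self, t: float) -> float:
        return float((self.config.theta - 2.0 * self._rho) * np.exp(1.0 - t) + 2.0 * self._rho)

    def _weights(self, m: np.ndarray, t: float) -> np.ndarray:
        return np.exp(-0.5 * ((m - self._mu(t)) / self._sigma(t)) ** 2)

    def _potential(self, m: np.ndarray, t: float) -> float:
        return float(np.mean(_ss.norm.sf((m - self._mu(t)) / self._sigma(t))))

    def fit(self, x: np.ndarray, y: np.ndarray) -> "RobustBoostClassifier":
        x = np.asarray(x, dtype=float)
        self.classes_ = _check_two_classes(y)
        ypm = np.where(np.asarray(y) == self.classes_[1], 1.0, -1.0)
        cfg = self.config
        # rho calibrated so the initial potential at margin 0 equals the
        # error goal: mu(0) = -sigma(0) * z_{1-eps}
        z = _ss.norm.ppf(1.0 - max(cfg.robustness_target, 1e-6))
        s0 = self._sigma0 = np.sqrt((cfg.sigma_margin**2 + 1.0) * np.e**2 - 1.0)
        self._rho = (s0 * z + cfg.theta * np.e) / (2.0 * (np.e - 1.0))

        n = len(ypm)
        margins = np.zeros(n)
        t = 0.0
        self.estimators_: list[DecisionTreeClassifier] = []
        self.alphas_: list[float] = []
        rng = np.random.default_rng(self.seed)
        for _ in range(cfg.n_cycles):
            if t >= 1.0 - 1e-9:
                break
            w = self._weights(margins, t)
            if w.sum() <= 0 or not np.all(np.isfinite(w)):
                break
            tree = DecisionTreeClassifier(
                max_depth=cfg.max_depth, random_state=int(rng.integers(2**31 - 1))
            )
            tree.fit(x, ypm, sample_weight=w / w.sum())
            h = tree.predict(x)
            agree = ypm * h
            edge = float(np.sum(w * agree) / np.sum(w))
            if edge <= 1e-12:
                break  # no usable weak hypothesis left
            alpha, dt = self._solve_step(margins, agree, t, edge)
            if alpha <= 0:
                break
            margins = margins + alpha * agree
            t = min(1.0, t + dt)
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
        if not self.estimators_:
            # degenerate data: fall back to a single unweighted tree
            tree = DecisionTreeClassifier(max_depth=cfg.max_depth, random_state=self.seed)
            tree.fit(x, ypm)
            self.estimators_ = [tree]
            self.alphas_ = [1.0]
        self.final_time_ = t
        return self

    def _solve_step(
        self, margins: np.ndarray, agree: np.ndarray, t: float, edge: float
    ) -> tuple[float, float]:
        """Solve for (alpha, dt): decorrelation + potential conservation."""
        if edge >= 1.0 - 1e-12:
            return 1.0, 1.0 - t  # perfect hypothesis: jump to the end

        def decorr(alpha: float, tn: float) -> float:
            m2 = margins + alpha * agree
            return float(np.sum(self._weights(m2, tn) * agree))

        def alpha_for(tn: float) -> float | None:
            lo, hi = 0.0, 0.5
            flo = decorr(lo, tn)
            if flo <= 0:
                return None
            while decorr(hi, tn) > 0 and hi < 64:
                hi *= 2
            if decorr(hi, tn) > 0:
                return None
            return float(_opt.brentq(lambda a: decorr(a, tn), lo, hi, xtol=1e-10))

        pot0 = self._potential(margins, t)

        def g(dt: float) -> float | None:
            a = alpha_for(t + dt)
            if a is None:
                return None
            return self._potential(margins + a * agree, t + dt) - pot0

        dt_max = 1.0 - t
        # the potential target rises with dt; find the largest dt keeping the
        # conservation residual non-positive, by bisection on g
        g_max = g(dt_max)
        if g_max is not None and g_max <= 0:
            return alpha_for(1.0) or 0.0, dt_max
        lo, hi = 0.0, dt_max
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            gm = g(mid)
            if gm is None or gm > 0:
                hi = mid
            else:
                lo = mid
        if lo <= 0:
            # cannot advance time while conserving potential: take a minimal
            # step with the AdaBoost vote weight so training still progresses
            alpha = 0.5 * np.log((1.0 + edge) / (1.0 - edge))
            return float(alpha), dt_max / max(self.config.n_cycles, 1)
        return alpha_for(t + lo) or 0.0, lo

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        score = np.zeros(len(x))
        for tree, a in zip(self.estimators_, self.alphas_):
            score += a * tree.predict(x)
        return score

    def predict(self, x: np.ndarray) -> np.ndarray:
        if len(x) == 0:
            return np.asarray([], dtype=self.classes_.dtype)
        return np.where(self.decision_function(x) >= 0, self.classes_[1], self.classes_[0])


def train_robustboost(
    features: np.ndarray, labels: np.ndarray, config: BoostConfig | None = None, seed: int = 0
):
    """Train the boosting ensemble ("robustboost" or the AdaBoost fallback)."""
    config = config or BoostConfig()
    if config.algorithm == "adaboost":
        _check_two_classes(labels)
        model = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=config.max_depth),
            n_estimators=config.n_cycles,
            random_state=seed,
        )
        return model.fit(np.asarray(features, dtype=float), labels)
    return RobustBoostClassifier(config=config, seed=seed).fit(features, labels)


# ---------------------------------------------------------------------------
# windowing + CNN
# ---------------------------------------------------------------------------


@dataclass
class WindowSet:
    """Raw-signal windows with per-window subject traceability."""

    x: np.ndarray  # (n_windows, n_leads, window_length)
    subject_ids: np.ndarray
    labels: np.ndarray
    stages: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.labels = np.asarray(self.labels)
        if self.stages is None:
            self.stages = np.full(len(self.subject_ids), "", dtype=object)
        if not (len(self.x) == len(self.subject_ids) == len(self.labels)):
            raise ValueError("windows, subject_ids and labels must align")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)

    def subset(self, subjects) -> "WindowSet":
        mask = np.isin(self.subject_ids, list(subjects))
        return WindowSet(
            x=self.x[mask],
            subject_ids=self.subject_ids[mask],
            labels=self.labels[mask],
            stages=self.stages[mask],
        )

    def subject_labels(self) -> dict[str, str]:
        return {s: self.labels[self.subject_ids == s][0] for s in self.subjects}


def window_signal(record: ECGRecord, n_windows: int = 300) -> WindowSet:
    """Split one record into ``n_windows`` equal contiguous windows.

    Window length is floor(n_samples / n_windows); the trailing remainder is
    discarded, so concatenating the windows reproduces the truncated signal
    exactly.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    length = record.n_samples // n_windows
    if length < 1:
        raise ValueError(
            f"record has {record.n_samples} samples; too short for {n_windows} windows"
        )
    used = record.samples[:, : n_windows * length]
    x = used.reshape(used.shape[0], n_windows, length).transpose(1, 0, 2)
    return WindowSet(
        x=np.ascontiguousarray(x),
        subject_ids=np.full(n_windows, record.subject_id, dtype=object),
        labels=np.full(n_windows, record.group, dtype=object),
        stages=np.full(n_windows, record.stage, dtype=object),
    )


def windows_from_cohort(
    cohort: list[tuple[ECGRecord, BeatAnnotations]], n_windows: int = 300, stage: str | None = None
) -> WindowSet:
    parts = [
        window_signal(rec, n_windows)
        for rec, _ in cohort
        if stage is None or rec.stage == stage
    ]
    if not parts:
        raise ValueError("no records matched the requested stage")
    return WindowSet(
        x=np.concatenate([p.x for p in parts]),
        subject_ids=np.concatenate([p.subject_ids for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        stages=np.concatenate([p.stages for p in parts]),
    )


def train_cnn(
    train_windows: WindowSet,
    spec: CNNSpec | None = None,
    seed: int = 0,
    test_subjects=(),
) -> NumpyCNN:
    """Train the CNN on a window set with subject-isolation enforcement.

    Any overlap between the training subjects and the declared held-out
    ``test_subjects`` raises immediately — per-subject leakage through shared
    windows is the failure mode this guard exists for.
    """
    overlap = set(train_windows.subjects) & set(test_subjects)
    if overlap:
        raise ValueError(f"subject overlap between train and test sets: {sorted(overlap)}")
    model = NumpyCNN(spec=spec, seed=seed)
    model.fit(train_windows.x, train_windows.labels)
    return model


def predict(model, inputs) -> np.ndarray:
    """Uniform prediction across back-ends; empty input yields empty output."""
    if isinstance(inputs, WindowSet):
        inputs = inputs.x
    if len(inputs) == 0:
        return np.asarray([], dtype=object)
    return model.predict(inputs)


def predict_subjects(model: NumpyCNN, windows: WindowSet) -> dict[str, str]:
    """Subject-level CNN labels: majority vote over each subject's windows."""
    win_pred = predict(model, windows)
    out = {}
    for s in windows.subjects:
        votes = win_pred[windows.subject_ids == s]
        vals, counts = np.unique(votes, return_counts=True)
        out[s] = vals[np.argmax(counts)]
    return out


def make_classifier(method: str, seed: int = 0, **kwargs):
    """Factory for feature-space classifiers ('svm', 'robustboost', 'adaboost')."""
    if method == "svm":
        return SVMRBF(**kwargs)
    if method in ("robustboost", "adaboost"):
        config = kwargs.pop("config", None) or BoostConfig(algorithm=method, **kwargs)
        return RobustBoostClassifier(config=config, seed=seed) if method == "robustboost" else _AdaWrapper(config, seed)
    raise ValueError(f"unknown method {method!r}")


class _AdaWrapper(BaseEstimator, ClassifierMixin):
    """AdaBoost fallback behind the BoostConfig interface."""

    def __init__(self, config: BoostConfig, seed: int = 0):
        self.config = config
        self.seed = seed

    def fit(self, x, y):
        self.model_ = train_robustboost(x, y, config=self.config, seed=self.seed)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, x):
        return self.model_.predict(x)
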