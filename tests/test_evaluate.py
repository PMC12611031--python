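"""Fold plans, confusion-matrix metrics, cross-validation protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecgms.evaluate as ev
from ecgms.evaluate import (
    ConfusionMatrix,
    compute_metrics,
    cross_validate,
    make_folds,
    repeated_cv,
)


class TestMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix(tp=10, tn=10, fp=0, fn=0))
        assert (m.acc, m.se, m.sp, m.ppv, m.npv, m.fpr, m.fnr) == (1, 1, 1, 1, 1, 0, 0)

    def test_hand_computed_example(self):
        m = compute_metrics(ConfusionMatrix(tp=93, fn=7, tn=96, fp=4))
        assert m.se == pytest.approx(0.93)
        assert m.sp == pytest.approx(0.96)
        assert m.acc == pytest.approx(189 / 200)
        assert m.ppv == pytest.approx(93 / 97)

    def test_zero_denominator_flagged_not_zeroed(self):
        m = compute_metrics(ConfusionMatrix(tp=0, fn=0, tn=5, fp=5))
        assert np.isnan(m.se) and np.isnan(m.fnr)
        assert m.sp == pytest.approx(0.5)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(0, 0, 0, 0))

    @settings(deadline=None, derandomize=True, max_examples=1000)
    @given(st.tuples(*[st.integers(0, 500)] * 4).filter(lambda t: sum(t) > 0))
    def test_identities(self, counts):
        tp, tn, fp, fn = counts
        m = compute_metrics(ConfusionMatrix(tp, tn, fp, fn))
        if tp + fn > 0:
            assert m.se + m.fnr == pytest.approx(1.0)
        if tn + fp > 0:
            assert m.sp + m.fpr == pytest.approx(1.0)
        assert m.acc == pytest.approx((tp + tn) / (tp + tn + fp + fn))
        if tp + fp > 0:
            assert m.ppv * (tp + fp) == pytest.approx(tp)


class TestFolds:
    def _subjects(self):
        ids = [f"ms{i}" for i in range(15)] + [f"c{i}" for i in range(10)]
        labels = ["ms"] * 15 + ["control"] * 10
        return ids, labels

    def test_default_cohort_folds_partition(self):
        ids, labels = self._subjects()
        plan = make_folds(ids, labels, k=10, seed=0)
        sizes = [len(plan.fold_subjects(f)) for f in range(10)]
        assert all(s in (2, 3) for s in sizes)
        all_subjects = [s for f in range(10) for s in plan.fold_subjects(f)]
        assert sorted(all_subjects) == sorted(ids)
        assert len(set(all_subjects)) == len(ids)

    def test_deterministic_and_seed_sensitive(self):
        ids, labels = self._subjects()
        a = make_folds(ids, labels, k=10, seed=1)
        b = make_folds(ids, labels, k=10, seed=1)
        assert a.assignment == b.assignment
        assert any(
            make_folds(ids, labels, k=10, seed=s).assignment != a.assignment
            for s in range(2, 22)
        )

    def test_stratification_bounds_class_imbalance(self):
        ids, labels = self._subjects()
        plan = make_folds(ids, labels, k=5, seed=3)
        lab = dict(zip(ids, labels))
        for f in range(5):
            fold = plan.fold_subjects(f)
            n_ms = sum(lab[s] == "ms" for s in fold)
            assert abs(n_ms / len(fold) - 0.6) <= 1 / len(fold)

    def test_too_many_folds_rejected(self):
        ids, labels = self._subjects()
        with pytest.raises(ValueError):
            make_folds(ids, labels, k=26, seed=0)


class _Oracle:
    """Test double: returns the true labels it saw at fit time, keyed by row."""

    def fit(self, x, y):
        self.lookup = {tuple(row): lab for row, lab in zip(x, y)}
        return self

    def predict(self, x):
        return np.array([self.lookup[tuple(row)] for row in x])


class _Majority:
    def fit(self, x, y):
        vals, counts = np.unique(y, return_counts=True)
        self.label = vals[np.argmax(counts)]
        return self

    def predict(self, x):
        return np.full(len(x), self.label)


def _toy_features(n_per_class=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per_class):
        group = "ms" if i < n_per_class else "control"
        rows.append(
            {"subject_id": f"s{i:02d}", "group": group, "stage": "basal", "f01_rr_mean_di": float(i)}
        )
    return pd.DataFrame(rows)


class TestCrossValidate:
    def test_oracle_classifier_scores_one(self, monkeypatch):
        df = _toy_features()
        lookup = {float(i): ("ms" if i < 10 else "control") for i in range(20)}

        class Oracle:
            def fit(self, x, y):
                return self

            def predict(self, x):
                return np.array([lookup[v] for v in x[:, 0]])

        monkeypatch.setattr(ev, "make_classifier", lambda *a, **k: Oracle())
        res = cross_validate(df, k=5, seed=0)
        assert all(m.acc == 1.0 for m in res.fold_metrics)

    def test_majority_classifier_scores_chance(self, monkeypatch):
        df = _toy_features()
        monkeypatch.setattr(ev, "make_classifier", lambda *a, **k: _Majority())
        res = cross_validate(df, k=5, seed=0)
        assert res.mean_accuracy == pytest.approx(0.5, abs=0.15)

    def test_svm_on_default_cohort(self, small_features):
        res = cross_validate(small_features, method="svm", k=10, seed=0)
        assert res.mean_accuracy >= 0.9
        summary = res.summary()
        assert set(summary.columns) >= {"mean", "sd", "pooled"}


class TestRepeatedCV:
    def test_emits_exactly_n_accuracies(self, small_features):
        accs, hist = repeated_cv(small_features, method="svm", n_reps=25, k=10, seed=0)
        assert accs.shape == (25,)
        assert hist["relative_frequency"].sum() == pytest.approx(1.0)

    def test_degenerate_leave_one_out_has_zero_variance(self, monkeypatch):
        """With k = n subjects the fold plan is unique up to ordering, so a
        deterministic classifier yields identical accuracy in every rep."""
        df = _toy_features(n_per_class=3)
        lookup = {float(i): ("ms" if i < 3 else "control") for i in range(6)}

        class Oracle:
            def fit(self, x, y):
                return self

            def predict(self, x):
                return np.array([lookup[v] for v in x[:, 0]])

        monkeypatch.setattr(ev, "make_classifier", lambda *a, **k: Oracle())
        accs, _ = repeated_cv(df, n_reps=10, k=6, seed=0)
        assert np.ptp(accs) == 0.0

    def test_small_rep_mean_is_stable(self, small_features):
        a50, _ = repeated_cv(small_features, method="svm", n_reps=20, k=10, seed=0)
        a10, _ = repeated_cv(small_features, method="svm", n_reps=5, k=10, seed=100)
        sd = a50.std(ddof=1)
        assert abs(a10.mean() - a50.mean()) <= max(2 * sd, 0.05)
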