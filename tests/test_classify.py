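"""Classifier back-ends: SVM, RobustBoost, windowing and the CNN."""

import numpy as np
import pytest

from ecgms.classify import (
    BoostConfig,
    RobustBoostClassifier,
    train_cnn,
    train_robustboost,
    train_svm_rbf,
    predict,
    predict_subjects,
    window_signal,
    windows_from_cohort,
)
from ecgms.cnn import CNNSpec, NumpyCNN
from ecgms.synthetic import CohortSpec, generate_cohort, generate_record


class TestSVM:
    def test_separable_clouds_fit_perfectly(self, separable_xy):
        x, y = separable_xy
        model = train_svm_rbf(x, y)
        assert (model.predict(x) == y).mean() == 1.0

    def test_conflicting_duplicates_cap_accuracy(self):
        x = np.zeros((20, 2))
        y = np.array(["control"] * 10 + ["ms"] * 10)
        model = train_svm_rbf(x, y)
        assert (model.predict(x) == y).mean() <= 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm_rbf(np.random.default_rng(0).normal(size=(10, 2)), np.array(["ms"] * 10))


class TestRobustBoost:
    def test_separable_data_reaches_zero_training_error(self, separable_xy):
        x, y = separable_xy
        model = train_robustboost(x, y)
        assert (model.predict(x) == y).mean() == 1.0
        assert len(model.estimators_) < 100

    def test_one_cycle_equals_single_tree(self, separable_xy):
        x, y = separable_xy
        model = train_robustboost(x, y, BoostConfig(n_cycles=1))
        assert len(model.estimators_) == 1
        tree_pred = model.estimators_[0].predict(x)
        expect = np.where(tree_pred >= 0, model.classes_[1], model.classes_[0])
        assert np.array_equal(model.predict(x), expect)

    def test_label_noise_tolerance(self):
        """20% flipped labels cost at most 5 points of test accuracy when the
        robustness target matches the contamination rate."""
        cfg = BoostConfig(max_depth=1, robustness_target=0.2)
        deltas = []
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            x = np.vstack([rng.normal(-1, 0.1, (40, 2)), rng.normal(1, 0.1, (40, 2))])
            y = np.array(["a"] * 40 + ["b"] * 40)
            xt = np.vstack([rng.normal(-1, 0.1, (50, 2)), rng.normal(1, 0.1, (50, 2))])
            yt = np.array(["a"] * 50 + ["b"] * 50)
            clean = (RobustBoostClassifier(cfg, seed=rep).fit(x, y).predict(xt) == yt).mean()
            yn = y.copy()
            flip = rng.choice(80, 16, replace=False)
            yn[flip] = np.where(yn[flip] == "a", "b", "a")
            noisy = (RobustBoostClassifier(cfg, seed=rep).fit(x, yn).predict(xt) == yt).mean()
            deltas.append(clean - noisy)
        assert np.mean(deltas) <= 0.05

    def test_adaboost_fallback_behind_same_interface(self, separable_xy):
        x, y = separable_xy
        model = train_robustboost(x, y, BoostConfig(algorithm="adaboost"), seed=0)
        assert (model.predict(x) == y).mean() == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_robustboost(np.zeros((5, 2)), np.array(["ms"] * 5))


class TestWindowing:
    def test_partition_identity(self, clean_record):
        rec, _ = clean_record
        ws = window_signal(rec, n_windows=100)
        length = rec.n_samples // 100
        rebuilt = np.concatenate([w for w in ws.x], axis=1)
        assert np.array_equal(rebuilt, rec.samples[:, : 100 * length])

    def test_floor_and_remainder(self):
        spec = CohortSpec(duration=1.001, sample_rate=1000.0, seed=0)
        rec, _ = generate_record(spec, "s01", "control", "basal")
        assert rec.n_samples == 1001
        ws = window_signal(rec, n_windows=300)
        assert ws.x.shape == (300, 2, 3)

    def test_study_scale_window_length(self):
        # 15 min at 1 kHz split into 300 windows -> 3000 samples each
        assert (15 * 60 * 1000) // 300 == 3000

    def test_too_short_record_rejected(self, clean_record):
        rec, _ = clean_record
        with pytest.raises(ValueError):
            window_signal(rec, n_windows=rec.n_samples + 1)


@pytest.fixture(scope="module")
def tiny_windows():
    spec = CohortSpec(
        duration=10.0, sample_rate=120.0, stages=("basal",), n_ms=4, n_control=4, seed=31
    )
    return windows_from_cohort(generate_cohort(spec), n_windows=40)


class TestCNN:
    def test_conv1_parameter_count_unclipped(self):
        model = NumpyCNN(seed=0)
        model._build(h=12, w=40)  # 12-lead-style input: 5x5 kernel unclipped
        assert model.conv1.w.size + model.conv1.b.size == (5 * 5 * 1) * 100 + 100

    def test_layer_count_is_ten(self):
        assert len(CNNSpec().layer_names) == 10

    def test_lr_schedule(self):
        spec = CNNSpec()
        assert all(spec.learning_rate(e) == pytest.approx(1e-4) for e in range(1, 9))
        assert spec.learning_rate(9) == pytest.approx(1e-5)

    def test_softmax_outputs_sum_to_one(self, tiny_windows):
        spec = CNNSpec(max_epochs=1)
        model = train_cnn(tiny_windows, spec=spec, seed=0)
        probs = model.predict_proba(tiny_windows.x[:50])
        assert probs.shape == (50, 2)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_subject_overlap_is_hard_error(self, tiny_windows):
        with pytest.raises(ValueError, match="overlap"):
            train_cnn(tiny_windows, spec=CNNSpec(max_epochs=1), seed=0, test_subjects=["ms01"])

    def test_training_is_seed_deterministic(self, tiny_windows):
        spec = CNNSpec(max_epochs=1)
        a = train_cnn(tiny_windows, spec=spec, seed=3)
        b = train_cnn(tiny_windows, spec=spec, seed=3)
        assert np.array_equal(a.conv1.w, b.conv1.w)
        assert np.array_equal(
            a.predict_proba(tiny_windows.x[:20]), b.predict_proba(tiny_windows.x[:20])
        )


class TestPredict:
    def test_empty_input_gives_empty_output(self, separable_xy):
        x, y = separable_xy
        model = train_svm_rbf(x, y)
        assert len(predict(model, np.empty((0, 2)))) == 0

    def test_majority_vote_aggregation(self, tiny_windows):
        model = train_cnn(tiny_windows, spec=CNNSpec(max_epochs=1), seed=0)
        votes = predict_subjects(model, tiny_windows)
        win_pred = model.predict(tiny_windows.x)
        for subject, label in votes.items():
            sub = win_pred[tiny_windows.subject_ids == subject]
            vals, counts = np.unique(sub, return_counts=True)
            assert label == vals[np.argmax(counts)]
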