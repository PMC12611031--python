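"""Statistical battery: oracles, calibration, PCA and agreement analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ecgms.stats import (
    bland_altman,
    feature_screen,
    ks_normality,
    mann_whitney,
    pca_relevance,
)


def mw_permutation_oracle(a, b):
    """Exhaustive two-sided Mann-Whitney p by enumerating rank assignments."""
    pooled = np.concatenate([a, b])
    n = len(pooled)
    na = len(a)

    def u_stat(idx_a):
        sa = pooled[list(idx_a)]
        sb = pooled[[i for i in range(n) if i not in idx_a]]
        return sum((x > y) + 0.5 * (x == y) for x in sa for y in sb)

    observed = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    us = [u_stat(c) for c in itertools.combinations(range(n), na)]
    mean_u = na * (n - na) / 2.0
    count = sum(abs(u - mean_u) >= abs(observed - mean_u) - 1e-12 for u in us)
    return count / len(us)


class TestMannWhitney:
    def test_textbook_example(self):
        # fully separated samples of 3: one-sided 1/20 -> two-sided 0.1
        assert mann_whitney([1, 2, 3], [10, 20, 30]) == pytest.approx(0.1)

    def test_identical_samples_give_p_near_one(self):
        p = mann_whitney([1.0, 2.0, 3.0, 4.0] * 4, [1.0, 2.0, 3.0, 4.0] * 4)
        assert p >= 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_matches_exhaustive_permutation_oracle(self):
        """Exact-path p equals brute-force enumeration to 1e-9 on a grid of
        tie-free samples with group sizes up to 5."""
        rng = np.random.default_rng(123)
        checked = 0
        for na in (3, 4, 5):
            for nb in (3, 4, 5):
                for _ in range(6):
                    pooled = rng.permutation(np.arange(1.0, na + nb + 1.0))
                    a, b = pooled[:na], pooled[na:]
                    assert mann_whitney(a, b) == pytest.approx(
                        mw_permutation_oracle(a, b), abs=1e-9
                    )
                    checked += 1
        assert checked >= 50


class TestKSNormality:
    def test_calibrated_on_normal_draws(self):
        rng = np.random.default_rng(0)
        hits = sum(ks_normality(rng.standard_normal(1000)) > 0.05 for _ in range(100))
        assert hits >= 90

    def test_detects_bimodal(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(-5, 1, 100), rng.normal(5, 1, 100)])
        assert ks_normality(x) < 1e-3
        assert ks_normality(x, lilliefors=True) < 1e-3

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.ones(10))

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = ks_normality(rng.exponential(size=50))
            assert 0.0 <= p <= 1.0


def _screen_table(effect=0.0, seed=0, n_ms=15, n_control=10):
    rng = np.random.default_rng(seed)
    rows = []
    for stage in ("basal", "30min"):
        for i in range(n_ms + n_control):
            group = "ms" if i < n_ms else "control"
            shift = effect if group == "ms" else 0.0
            row = {"subject_id": f"s{i}", "group": group, "stage": stage}
            row["f01_rr_mean_di"] = rng.normal(shift)
            row["f05_axis_mean"] = rng.normal(3 * shift)
            row["f09_rr_var_di"] = 1.0  # constant feature: r undefined
            rows.append(row)
    return pd.DataFrame(rows)


class TestFeatureScreen:
    def test_perfect_association(self):
        df = _screen_table()
        df["f01_rr_mean_di"] = (df["group"] == "ms").astype(float)
        out = feature_screen(df)
        f1 = out[out["feature"] == "f01_rr_mean_di"]
        assert np.allclose(f1["pearson_r"], 1.0)
        assert np.all(f1["mw_p"] < 1e-4)

    def test_constant_feature_flagged_not_raised(self):
        out = feature_screen(_screen_table(seed=3))
        f9 = out[out["feature"] == "f09_rr_var_di"]
        assert not f9["r_defined"].any()
        assert f9["r_bin"].eq("undefined").all()

    def test_injected_effect_is_detected(self):
        out = feature_screen(_screen_table(effect=3.0, seed=4))
        f5 = out[out["feature"] == "f05_axis_mean"]
        assert f5["mw_significant"].all()

    def test_grid_is_complete(self):
        out = feature_screen(_screen_table(seed=5))
        assert len(out) == 3 * 2  # 3 features x 2 stages
        assert ((out["mw_p"] >= 0) & (out["mw_p"] <= 1)).all()


class TestPCARelevance:
    def _table(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        shared = rng.standard_normal(n)
        df = pd.DataFrame(
            {
                "f01_rr_mean_di": shared + 0.01 * rng.standard_normal(n),
                "f02_rs_mean_di": -shared + 0.01 * rng.standard_normal(n),
                "f03_qs_mean_di": rng.standard_normal(n),  # pure independent noise
            }
        )
        return df

    def test_noise_feature_loads_weakly_on_dominant_axis(self):
        res = pca_relevance(self._table(), n_components=1)
        load = dict(zip(["f01_rr_mean_di", "f02_rs_mean_di", "f03_qs_mean_di"], res.loadings[0]))
        assert abs(load["f03_qs_mean_di"]) < 0.2
        assert "f03_qs_mean_di" not in res.retained_features
        assert {"f01_rr_mean_di", "f02_rs_mean_di"} <= set(res.retained_features)

    def test_loadings_are_orthonormal(self):
        res = pca_relevance(self._table(seed=1), n_components=3)
        gram = res.loadings @ res.loadings.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_zero_threshold_retains_everything(self):
        res = pca_relevance(self._table(seed=2), coefficient_threshold=0.0)
        assert len(res.retained_features) == 3

    def test_reconstruction_from_all_components(self):
        df = self._table(seed=3)
        res = pca_relevance(df, n_components=3)
        x = df.to_numpy()
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        proj = (z - z.mean(0)) @ res.loadings.T @ res.loadings + z.mean(0)
        assert np.allclose(proj, z, atol=1e-8)


class TestBlandAltman:
    def test_identical_marks(self):
        marks = np.array([100, 600, 1100])
        res = bland_altman(marks, marks)
        assert res.mean_difference == 0.0
        assert res.limits_of_agreement == (0.0, 0.0)

    def test_hand_computed_limits(self):
        ref = np.array([0, 1000, 2000, 3000])
        tst = ref + np.array([1, -1, 1, -1])
        res = bland_altman(ref, tst, sample_rate=1000.0)
        assert res.mean_difference == pytest.approx(0.0)
        sd = np.sqrt(4.0 / 3.0)
        assert res.limits_of_agreement[1] == pytest.approx(1.96 * sd, abs=1e-4)
        assert res.limits_of_agreement[1] == pytest.approx(2.2632, abs=1e-3)

    def test_unmatched_marks_counted(self):
        res = bland_altman([100, 600, 1100], [102, 604, 5000], matching_tolerance=50.0)
        assert res.n_matched == 2
        assert res.n_reference_unmatched == 1
        assert res.n_test_unmatched == 1

    def test_no_matches_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([0], [10000])

    def test_limits_widen_with_jitter(self):
        rng = np.random.default_rng(6)
        ref = np.arange(0, 60000, 800)
        widths = []
        for sd in (1.0, 4.0, 10.0):
            tst = ref + rng.normal(0, sd, ref.size)
            res = bland_altman(ref, tst)
            widths.append(res.limits_of_agreement[1] - res.limits_of_agreement[0])
        assert widths[0] < widths[1] < widths[2]
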