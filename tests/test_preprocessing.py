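import numpy as np
import pytest
from scipy.spatial import Delaunay

from fedtab import (
    AugmentConfig,
    OutlierPolicy,
    SmoteConfig,
    augment_noise,
    compute_iqr,
    iqr_table,
    remove_outliers,
    smote,
)
from fedtab.data_model import ConfigError, DegenerateDataError, FedtabError

from conftest import make_table


class TestComputeIqr:
    def test_constant_sequence(self):
        s = compute_iqr([5.0] * 10)
        assert s.iqr == 0.0
        assert s.lower_bound == s.upper_bound == 5.0

    def test_hand_computed_interpolation(self):
        # sorted [1,2,3,100]: q1 at rank 0.75 -> 1.75, q3 at rank 2.25 -> 27.25
        s = compute_iqr([1.0, 2.0, 3.0, 100.0])
        assert s.q1 == pytest.approx(1.75)
        assert s.q3 == pytest.approx(27.25)
        assert s.iqr == pytest.approx(25.5)
        assert s.lower_bound == pytest.approx(1.75 - 1.5 * 25.5)
        assert s.upper_bound == pytest.approx(27.25 + 1.5 * 25.5)

    def test_wbcd_radius_mean_quartiles(self, wbcd):
        # linear-interpolation quartiles of the actual radius_mean column
        col = wbcd.features[:, wbcd.feature_names.index("radius_mean")]
        s = compute_iqr(col)
        assert s.q1 == pytest.approx(np.percentile(col, 25))
        assert s.iqr == pytest.approx(4.08, abs=0.005)

    def test_empty_errors(self):
        with pytest.raises(FedtabError):
            compute_iqr([])

    def test_iqr_table_covers_all_features(self, wbcd):
        df = iqr_table(wbcd)
        assert list(df["feature"]) == list(wbcd.feature_names)
        assert (df["q3"] >= df["q1"]).all()


class TestRemoveOutliers:
    def test_all_inside_bounds_unchanged(self):
        t = make_table([[1.0], [2.0], [3.0], [2.5]], [0, 1, 0, 1])
        out, removed = remove_outliers(t, OutlierPolicy())
        assert len(out) == 4 and len(removed) == 0

    def test_single_feature_toy_removes_extreme(self):
        t = make_table([[1.0], [2.0], [3.0], [100.0]], [0, 1, 0, 1])
        out, removed = remove_outliers(t, OutlierPolicy(multiplier=1.5, min_violations=1))
        assert removed.tolist() == ["3"]
        assert out.features.ravel().tolist() == [1.0, 2.0, 3.0]

    def test_huge_multiplier_removes_nothing(self, wbcd):
        out, removed = remove_outliers(wbcd, OutlierPolicy(multiplier=1e9))
        assert len(out) == len(wbcd) and len(removed) == 0

    def test_strictness_monotonicity(self, wbcd):
        # any-feature rule removes a superset of the two-feature rule
        _, removed1 = remove_outliers(wbcd, OutlierPolicy(min_violations=1))
        _, removed2 = remove_outliers(wbcd, OutlierPolicy(min_violations=2))
        assert set(removed2.tolist()) <= set(removed1.tolist())

    def test_all_removed_is_degenerate(self):
        # feature j is 100 at row j and 0 elsewhere: every row breaches the
        # fence of its own feature, so the any-feature rule removes everything
        X = 100.0 * np.eye(4)
        t = make_table(X, [0, 1, 0, 1])
        with pytest.raises(DegenerateDataError):
            remove_outliers(t, OutlierPolicy(min_violations=1))


class TestAugmentNoise:
    def test_reaches_paper_targets(self, wbcd):
        table, _ = remove_outliers(wbcd, OutlierPolicy(min_violations=6))
        out = augment_noise(
            table, AugmentConfig(per_class_targets={0: 3212, 1: 2530}, seed=0)
        )
        assert len(out) == 5742
        assert out.class_counts() == {0: 3212, 1: 2530}

    def test_zero_noise_identity_targets(self):
        t = make_table([[1.0, 2.0], [3.0, 4.0]], [0, 1])
        out = augment_noise(
            t, AugmentConfig(noise_low=0.0, noise_high=0.0, per_class_targets={0: 1, 1: 1})
        )
        np.testing.assert_array_equal(out.features, t.features)

    def test_originals_unchanged_and_noise_bounded(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.normal(size=(20, 3)), [0, 1] * 10)
        cfg = AugmentConfig(noise_low=-0.01, noise_high=0.01,
                            per_class_targets={0: 50, 1: 40}, seed=1)
        out = augment_noise(t, cfg)
        np.testing.assert_array_equal(out.features[:20], t.features)
        assert out.class_counts() == {0: 50, 1: 40}
        # every appended row sits within the noise box of some same-class original
        for i in range(20, len(out)):
            cls = out.labels[i]
            originals = t.features[t.labels == cls]
            dist = np.abs(originals - out.features[i]).max(axis=1).min()
            assert dist <= 0.01 + 1e-12

    def test_target_below_count_errors(self):
        t = make_table([[1.0], [2.0], [3.0]], [0, 0, 1])
        with pytest.raises(ConfigError):
            augment_noise(t, AugmentConfig(per_class_targets={0: 1, 1: 1}))


class TestSmote:
    def test_paper_balance_counts(self, wbcd_preprocessed):
        assert len(wbcd_preprocessed) == 6424
        assert wbcd_preprocessed.class_counts() == {0: 3212, 1: 3212}

    def test_already_balanced_unchanged(self):
        rng = np.random.default_rng(3)
        t = make_table(rng.normal(size=(20, 2)), [0, 1] * 10)
        out = smote(t, SmoteConfig(k_neighbors=3))
        assert len(out) == len(t)

    def test_two_point_minority_on_segment(self):
        maj = np.random.default_rng(4).normal(5.0, 0.1, size=(10, 2))
        a, b = np.array([0.0, 0.0]), np.array([1.0, 2.0])
        X = np.vstack([maj, a, b])
        y = [0] * 10 + [1, 1]
        out = smote(make_table(X, y), SmoteConfig(k_neighbors=1, seed=0))
        assert out.class_counts() == {0: 10, 1: 10}
        synth = out.features[12:]
        # each synthetic point is a + u * (b - a): collinear, u in [0, 1]
        u = (synth - a) @ (b - a) / ((b - a) @ (b - a))
        recon = a + u[:, None] * (b - a)
        np.testing.assert_allclose(synth, recon, atol=1e-12)
        assert ((u >= 0) & (u <= 1)).all()

    def test_synthetic_points_inside_convex_hull(self):
        rng = np.random.default_rng(5)
        minority = rng.normal(size=(15, 2))
        majority = rng.normal(3.0, 1.0, size=(40, 2))
        t = make_table(np.vstack([majority, minority]), [0] * 40 + [1] * 15)
        out = smote(t, SmoteConfig(k_neighbors=5, seed=2))
        synth = out.features[55:]
        hull = Delaunay(minority)
        assert (hull.find_simplex(synth) >= 0).all()

    def test_single_class_errors(self):
        t = make_table(np.ones((6, 1)), [1] * 6)
        with pytest.raises(FedtabError):
            smote(t)

    def test_k_too_large_errors(self):
        t = make_table(np.arange(8.0).reshape(8, 1), [0] * 5 + [1] * 3)
        with pytest.raises(ConfigError):
            smote(t, SmoteConfig(k_neighbors=3))


def test_full_chain_preserves_labels_and_arity(wbcd_preprocessed, wbcd):
    assert set(np.unique(wbcd_preprocessed.labels)) == {0, 1}
    assert wbcd_preprocessed.n_features == wbcd.n_features
    assert wbcd_preprocessed.feature_names == wbcd.feature_names
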