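"""SVM training, grid search, feature masks and the per-class-subset
one-vs-rest model."""

import itertools

import numpy as np
import pytest
from sklearn.svm import SVC

import claudigait as cg
from claudigait.classifier import (
    DEFAULT_FEATURE_MASKS,
    KernelSpec,
    _fast_rbf_decision,
    grid_search,
    train_binary_svm,
)
from claudigait.features import FEATURE_NAMES


def four_blob_cohort(rng, n_per_class=6, spread=0.3):
    """Well-separated 9-feature blobs, one per class."""
    centers = rng.normal(scale=3.0, size=(4, 9))
    X, y = [], []
    for c, label in enumerate(cg.CLASS_ORDER):
        X.append(centers[c] + spread * rng.normal(size=(n_per_class, 9)))
        y += [label] * n_per_class
    return np.vstack(X), np.array(y, dtype=object)


class TestNormalization:
    def test_two_point_symmetry(self):
        stats = cg.normalize_fit(np.array([[0.0], [2.0]]))
        assert stats.mean[0] == 1.0 and stats.scale[0] == 1.0  # population SD
        assert cg.normalize_apply(stats, np.array([[1.0]]))[0, 0] == 0.0

    def test_zscore_by_hand(self):
        X = np.array([[1.0, 10.0], [3.0, 10.0], [5.0, 40.0]])
        stats = cg.normalize_fit(X)
        Z = cg.normalize_apply(stats, X)
        np.testing.assert_allclose(Z.mean(0), 0.0, atol=1e-12)
        np.testing.assert_allclose(
            Z[0], (X[0] - X.mean(0)) / X.std(0, ddof=0), atol=1e-12
        )

    def test_constant_feature_maps_to_zero(self):
        X = np.full((5, 2), 7.0)
        Z = cg.normalize_apply(cg.normalize_fit(X), X)
        assert np.all(Z == 0.0)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            cg.normalize_fit(np.empty((0, 3)))


class TestBinarySVM:
    def test_separable_pair_signs(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([-1, 1])
        model = train_binary_svm(X, y, C=1e3, kernel=KernelSpec("rbf", gamma=1.0))
        f = model.decision_function(X)
        assert np.all(np.sign(f) == y)

    def test_xor_with_rbf(self):
        """An RBF kernel separates the XOR pattern a linear boundary cannot."""
        X = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]])
        y = np.array([1, 1, -1, -1])
        model = train_binary_svm(X, y, C=1e3, kernel=KernelSpec("rbf", gamma=1.0))
        assert np.all(np.sign(model.decision_function(X)) == y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_binary_svm(np.zeros((3, 2)), np.ones(3), C=1.0)

    def test_fast_path_matches_svc_decision_values(self):
        """The low-level libsvm scoring path used inside grid search must
        reproduce SVC's decision function exactly."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(8, 30))
            X = rng.normal(size=(n, 4))
            y = np.where(rng.random(n) > 0.5, 1.0, -1.0)
            if len(np.unique(y)) < 2:
                continue
            C = float(2.0 ** rng.integers(-5, 16))
            g = float(2.0 ** rng.integers(-15, 4))
            Xt = rng.normal(size=(5, 4))
            ref = SVC(C=C, gamma=g).fit(X, y).decision_function(Xt)
            got = _fast_rbf_decision(X, y, Xt, C, g)
            np.testing.assert_allclose(got, ref, atol=1e-10)


class TestGridSearch:
    def test_singleton_grid(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        y = np.array([1, -1] * 6)
        assert grid_search(X, y, C_grid=[4.0], gamma_grid=[0.25], seed=0) == (4.0, 0.25)

    def test_tie_breaks_to_smallest_pair(self):
        """Perfectly separated data is classified correctly by every grid
        point, so the tie rule must return the smallest (C, gamma)."""
        X = np.vstack([np.full((6, 2), -5.0), np.full((6, 2), 5.0)])
        X += 0.01 * np.random.default_rng(2).normal(size=X.shape)
        y = np.array([-1] * 6 + [1] * 6)
        C, g = grid_search(X, y, C_grid=[1.0, 4.0, 16.0], gamma_grid=[0.1, 1.0], seed=0)
        assert (C, g) == (1.0, 0.1)

    def test_selected_pair_is_grid_optimal(self):
        """The returned pair attains CV accuracy >= every other grid pair
        (verified by exhaustive re-scoring with an independent loop)."""
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-1.2, 1.0, (15, 2)), rng.normal(1.2, 1.0, (15, 2))])
        y = np.array([-1] * 15 + [1] * 15)
        C_grid, g_grid = [0.125, 2.0, 32.0], [0.03125, 0.5, 8.0]
        best = grid_search(X, y, C_grid, g_grid, seed=0)

        from sklearn.model_selection import StratifiedKFold

        folds = list(StratifiedKFold(5, shuffle=True, random_state=0).split(X, y))

        def cv_correct(C, g):
            total = 0
            for tr, te in folds:
                m = SVC(C=C, gamma=g).fit(X[tr], y[tr])
                total += int(np.sum(m.predict(X[te]) == y[te]))
            return total

        best_score = cv_correct(*best)
        for C, g in itertools.product(C_grid, g_grid):
            assert cv_correct(C, g) <= best_score

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(np.zeros((4, 2)), np.array([1, 1, -1, -1]), C_grid=[], seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 3))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=20) > 0, 1, -1)
        a = grid_search(X, y, seed=5)
        assert a == grid_search(X, y, seed=5)


class TestMasks:
    def test_default_masks_match_selection_table(self):
        sel = lambda label: {n for n, m in zip(FEATURE_NAMES, DEFAULT_FEATURE_MASKS[label]) if m}
        assert sel("normal") == {
            "mean_ankle_angle", "femur_amplitude", "gastroc_max_contracted",
            "gastroc_rom", "quad_max_relaxed",
        }
        assert sel("L4") == {
            "mean_ankle_angle", "knee_angle_at_stance_start", "gastroc_max_relaxed",
            "gastroc_max_contracted", "quad_max_contracted", "quad_rom",
        }
        assert sel("PAD") == sel("L5") == {
            "mean_ankle_angle", "gastroc_max_relaxed", "gastroc_max_contracted",
            "quad_rom",
        }
        assert [int(DEFAULT_FEATURE_MASKS[c].sum()) for c in cg.CLASS_ORDER] == [5, 4, 4, 6]


class TestPresentedModel:
    def test_argmax_and_tie_rule(self):
        model = cg.SubsetOVRModel()
        decisions = np.array([[-1.0, 2.0, -1.0, -1.0], [0.5, 0.5, 0.5, 0.5]])
        picked = np.asarray(model.classes, dtype=object)[np.argmax(decisions, axis=1)]
        assert picked.tolist() == ["PAD", "normal"]

    def test_trainset_consistency_on_blobs(self):
        rng = np.random.default_rng(5)
        X, y = four_blob_cohort(rng)
        model = cg.train_presented(X, y, seed=0)
        labels, f = cg.predict_presented(model, X)
        assert f.shape == (24, 4)
        assert np.all(labels == y)

    def test_missing_class_rejected(self):
        rng = np.random.default_rng(6)
        X, y = four_blob_cohort(rng)
        keep = y != "L4"
        with pytest.raises(ValueError, match="L4"):
            cg.train_presented(X[keep], y[keep], seed=0)

    def test_equivalent_to_plain_ovr_with_shared_hyperparameters(self):
        """With all-ones masks and a shared (C, gamma) the presented
        model must predict exactly like the plain one-vs-rest SVM."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            X, y = four_blob_cohort(rng, n_per_class=5, spread=1.5)
            masks = {c: np.ones(9, dtype=bool) for c in cg.CLASS_ORDER}
            grid = {"C_grid": [8.0], "gamma_grid": [0.125]}
            presented = cg.train_presented(X, y, masks=masks, seed=0, **grid)
            ovr = cg.train_baseline(X, y, "ovr_svm", seed=0, **grid)
            Xt = X + 0.3 * rng.normal(size=X.shape)
            assert np.all(presented.predict(Xt) == ovr.predict(Xt))

    def test_serialization_roundtrip_preserves_decisions(self, tmp_path):
        rng = np.random.default_rng(8)
        X, y = four_blob_cohort(rng)
        model = cg.train_presented(X, y, C_grid=[2.0, 8.0], gamma_grid=[0.1, 1.0], seed=0)
        path = tmp_path / "model.json"
        model.save(path)
        back = cg.SubsetOVRModel.load(path)
        np.testing.assert_allclose(back.decision_values(X), model.decision_values(X), atol=1e-12)

    def test_nonfinite_features_rejected(self):
        rng = np.random.default_rng(9)
        X, y = four_blob_cohort(rng)
        model = cg.train_presented(X, y, C_grid=[1.0], gamma_grid=[0.1], seed=0)
        bad = X[0].copy()
        bad[3] = np.nan
        with pytest.raises(ValueError):
            model.predict(bad)


class TestBaselines:
    def test_ovo_trains_six_binary_classifiers(self):
        rng = np.random.default_rng(10)
        X, y = four_blob_cohort(rng)
        model = cg.train_baseline(X, y, "ovo_svm", C_grid=[2.0], gamma_grid=[0.5], seed=0)
        assert len(model.binaries) == 6

    def test_lda_perfect_on_separated_blobs(self):
        rng = np.random.default_rng(11)
        X, y = four_blob_cohort(rng, spread=0.1)
        model = cg.train_baseline(X, y, "lda", seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_tree_deterministic(self):
        rng = np.random.default_rng(12)
        X, y = four_blob_cohort(rng)
        a = cg.train_baseline(X, y, "tree", seed=3).predict(X)
        b = cg.train_baseline(X, y, "tree", seed=3).predict(X)
        assert np.all(a == b)

    def test_unknown_method_rejected(self):
        rng = np.random.default_rng(13)
        X, y = four_blob_cohort(rng)
        with pytest.raises(ValueError, match="unknown method"):
            cg.train_baseline(X, y, "forest", seed=0)


def test_binary_argmax_consistent_with_sign_decision():
    """For two classes, the argmax over the OVR pair {f, -f} agrees with
    the binary sign decision."""
    rng = np.random.default_rng(14)
    X = np.vstack([rng.normal(-2, 0.5, (8, 2)), rng.normal(2, 0.5, (8, 2))])
    y = np.array([-1] * 8 + [1] * 8)
    model = train_binary_svm(X, y, C=10.0, kernel=KernelSpec("rbf", gamma=0.5))
    f = model.decision_function(X)
    argmax_pick = np.where(f >= -f, 1, -1)
    assert np.all(argmax_pick == np.sign(f).astype(int))
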