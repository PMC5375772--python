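import numpy as np
import pytest

import vigileeg as v
from conftest import make_features
from oracles import qp_dual_solve
from vigileeg.svm import (
    KernelSpec, cross_validate, decision_values, dual_objective,
    kernel_matrix, contiguous_folds,
)


def smo_alpha(features, config):
    """Recover the alpha vector of a trained model for oracle comparison."""
    model = v.train(features, config)
    # dual_coefs = y_i a_i at support vectors; rebuild the full alpha
    alpha = np.zeros(features.m)
    for sv, coef in zip(model.support_vectors, model.dual_coefs):
        idx = np.where((features.X == sv).all(axis=1))[0]
        # duplicated rows share the coefficient mass; assign to first free slot
        for i in idx:
            if alpha[i] == 0:
                alpha[i] = abs(coef)
                break
    return model, alpha


class TestKernelEval:
    def test_rbf_zero_distance(self):
        spec = KernelSpec("rbf", g=3.7)
        assert v.kernel_eval([1.0, 2.0], [1.0, 2.0], spec) == 1.0

    def test_rbf_degenerate_width(self):
        spec = KernelSpec("rbf", g=0.0)
        assert v.kernel_eval([0.0], [100.0], spec) == 1.0

    def test_rbf_arithmetic(self):
        spec = KernelSpec("rbf", g=0.1)
        got = v.kernel_eval([0.0, 0.0], [3.0, 4.0], spec)
        assert got == pytest.approx(np.exp(-2.5), abs=1e-6)

    def test_linear_and_polynomial(self):
        assert v.kernel_eval([1, 2], [3, 4], KernelSpec("linear")) == 11.0
        got = v.kernel_eval([1, 0], [2, 0], KernelSpec("polynomial", coef=1, degree=2))
        assert got == 9.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            v.kernel_eval([1.0], [1.0, 2.0], KernelSpec("rbf"))

    def test_rbf_gram_positive_semidefinite(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        K = kernel_matrix(X, X, KernelSpec("rbf", g=1.0))
        eigs = np.linalg.eigvalsh(K)
        assert eigs.min() >= -1e-8


class TestTrain:
    def test_separable_toy_margin(self, toy_separable):
        cfg = v.TrainingConfig(C=1000.0, kernel="linear")
        model = v.train(toy_separable, cfg)
        f = decision_values(model, toy_separable.X)
        np.testing.assert_allclose(f, toy_separable.y, atol=1e-2)
        # midpoint of the classes lies on the separating plane x1 = 1.5
        assert v.decision_value(model, [1.5, 0.5]) == pytest.approx(0.0, abs=1e-2)
        # geometric margin = 2/||w||: unit level sets at x1=0 and x1=3
        w = model.dual_coefs @ model.support_vectors
        assert 2.0 / np.linalg.norm(w) == pytest.approx(3.0, rel=1e-2)

    def test_xor_rbf_fits_training(self, xor_features):
        cfg = v.TrainingConfig(C=10.0, g=1.0)
        model = v.train(xor_features, cfg)
        pred = v.predict(model, xor_features.X)
        np.testing.assert_array_equal(pred, xor_features.y)

    def test_single_class_rejected(self):
        feats = make_features([[0.0], [1.0]], [1, 1])
        with pytest.raises(ValueError, match="single-class"):
            v.train(feats, v.TrainingConfig())

    def test_dual_feasibility_and_kkt(self, contrast_recording):
        rec, labels = contrast_recording
        feats = v.extract_features(v.denoise(rec), labels, "O1", r=2)
        scaled, _, _ = v.scale_features(feats)
        cfg = v.TrainingConfig(C=8.0, g=2.0)
        model, alpha = smo_alpha(scaled, cfg)
        y = scaled.y.astype(float)
        assert np.all(alpha >= -1e-9) and np.all(alpha <= cfg.C + 1e-9)
        assert abs(np.sum(alpha * y)) < 1e-6
        # KKT: margin violations only at bound alphas (within tolerance)
        f = decision_values(model, scaled.X)
        free = (alpha > 1e-6) & (alpha < cfg.C - 1e-6)
        assert np.all(np.abs(y[free] * f[free] - 1.0) < 5e-2)

    def test_flipped_labels_negate_decision(self, xor_features):
        cfg = v.TrainingConfig(C=10.0, g=1.0, seed=5)
        m1 = v.train(xor_features, cfg)
        flipped = make_features(xor_features.X, -xor_features.y)
        m2 = v.train(flipped, cfg)
        probes = np.array([[0.2, 0.7], [0.9, 0.4], [0.5, 0.5]])
        np.testing.assert_allclose(
            decision_values(m1, probes), -decision_values(m2, probes), atol=1e-6
        )

    def test_monotone_capacity_in_C(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(-0.8, 1.0, size=(20, 2)),
                       rng.normal(+0.8, 1.0, size=(20, 2))])
        y = np.r_[np.full(20, -1), np.full(20, 1)]
        feats = make_features(X, y)
        accs = []
        for C in (0.1, 1.0, 10.0, 100.0, 1000.0):
            model = v.train(feats, v.TrainingConfig(C=C, g=1.0))
            accs.append(np.mean(v.predict(model, X) == y))
        assert all(b >= a - 1e-9 for a, b in zip(accs, accs[1:]))


class TestOracleEquivalence:
    """SMO dual objective vs an independent SLSQP QP solve on m <= 8 fixtures."""

    def fixtures(self):
        rng = np.random.default_rng(7)
        yield "toy-linear", make_features(
            [[0.0, 0.3], [0.0, 0.8], [3.0, 0.2], [3.0, 0.9]], [-1, -1, 1, 1]
        ), v.TrainingConfig(C=1000.0, kernel="linear")
        yield "xor-rbf", make_features(
            [[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]], [1, 1, -1, -1]
        ), v.TrainingConfig(C=10.0, g=1.0)
        for k in range(3):
            X = rng.normal(size=(8, 2))
            y = np.array([1, 1, 1, 1, -1, -1, -1, -1])
            yield f"random-{k}", make_features(X, y), v.TrainingConfig(C=5.0, g=0.5)

    def test_objective_matches_qp_oracle(self):
        for name, feats, cfg in self.fixtures():
            _, alpha = smo_alpha(feats, cfg)
            K = kernel_matrix(feats.X, feats.X, cfg.kernel_spec())
            y = feats.y.astype(float)
            obj_smo = dual_objective(K, y, alpha)
            _, obj_qp = qp_dual_solve(feats.X, feats.y, cfg.C, cfg.kernel_spec())
            assert obj_smo == pytest.approx(obj_qp, abs=1e-3), name

    def test_against_sklearn_svc(self, contrast_recording):
        """Independent cross-check: libsvm (sklearn) agrees on held-out labels."""
        from sklearn.svm import SVC
        rec, labels = contrast_recording
        feats = v.extract_features(v.denoise(rec), labels, "O1", r=2)
        scaled, _, _ = v.scale_features(feats)
        half = scaled.m // 2
        cfg = v.TrainingConfig(C=8.0, g=2.0)
        model = v.train(scaled.subset(np.arange(half)), cfg)
        ours = v.predict(model, scaled.X[half:])
        ref = SVC(C=8.0, gamma=2.0).fit(scaled.X[:half], scaled.y[:half])
        theirs = ref.predict(scaled.X[half:])
        assert np.mean(ours == theirs) >= 0.98


class TestPredict:
    def test_sign_rule_and_tie(self):
        model = v.SvmModel(
            kernel=KernelSpec("rbf", g=1.0), C=1.0,
            support_vectors=np.empty((0, 1)), dual_coefs=np.empty(0), bias=0.5,
        )
        assert v.predict(model, [[0.0]])[0] == 1
        model.bias = 0.0
        assert v.predict(model, [[0.0]])[0] == -1   # tie goes to drowsy
        model.bias = -0.5
        assert v.predict(model, [[0.0]])[0] == -1

    def test_no_support_vectors_returns_bias(self):
        model = v.SvmModel(
            kernel=KernelSpec("rbf", g=1.0), C=1.0,
            support_vectors=np.empty((0, 2)), dual_coefs=np.empty(0), bias=0.3,
        )
        assert v.decision_value(model, [1.0, 2.0]) == 0.3


class TestCrossValidate:
    def test_contiguous_blocks(self):
        blocks = contiguous_folds(10, 3)
        np.testing.assert_array_equal(np.concatenate(blocks), np.arange(10))
        assert [len(b) for b in blocks] == [4, 3, 3]

    def test_separable_data_perfect(self):
        X = np.r_[np.zeros((15, 1)), np.ones((15, 1)),
                  np.zeros((15, 1)), np.ones((15, 1))]
        y = np.r_[np.full(15, 1), np.full(15, -1),
                  np.full(15, 1), np.full(15, -1)]
        feats = make_features(X, y)
        acc = cross_validate(feats, v.TrainingConfig(C=10.0, g=1.0), folds=3)
        assert acc == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(300, 3))
        y = rng.permutation(np.r_[np.full(150, 1), np.full(150, -1)])
        feats = make_features(X, y)
        acc = cross_validate(feats, v.TrainingConfig(C=1.0, g=1.0), folds=3)
        assert 0.4 <= acc <= 0.6

    def test_single_class_fold_warns_and_skips(self):
        X = np.arange(9, dtype=float).reshape(-1, 1)
        y = np.array([1, 1, 1, 1, 1, 1, -1, 1, -1])
        feats = make_features(X, y)
        with pytest.warns(UserWarning, match="single class"):
            cross_validate(feats, v.TrainingConfig(C=1.0, g=1.0), folds=3)


class TestGridSearch:
    def test_1x1_grid_returns_pair(self, contrast_recording):
        rec, labels = contrast_recording
        feats = v.extract_features(v.denoise(rec), labels, "O1", r=4)
        C, g, surface = v.grid_search(feats, [2.0], [0.5], folds=3)
        assert (C, g) == (2.0, 0.5)
        assert surface.shape == (1, 1)
        assert 0.0 <= surface[0, 0] <= 1.0

    def test_surface_bounded_and_best_accuracy(self, contrast_recording):
        rec, labels = contrast_recording
        feats = v.extract_features(v.denoise(rec), labels, "O1", r=4)
        grid_C = [2.0 ** e for e in range(-1, 8, 2)]
        grid_g = [2.0 ** e for e in range(-7, 2, 2)]
        C, g, surface = v.grid_search(feats, grid_C, grid_g, folds=3)
        assert np.all((surface >= 0) & (surface <= 1))
        assert surface.max() >= 0.95
        assert C in grid_C and g in grid_g

    def test_tie_breaks_to_smallest(self):
        # trivially separable: every grid point reaches the same accuracy
        X2 = np.r_[np.zeros((6, 1)), np.ones((6, 1)), np.zeros((6, 1)),
                   np.ones((6, 1))]
        y2 = np.r_[np.full(6, 1), np.full(6, -1), np.full(6, 1), np.full(6, -1)]
        feats = make_features(X2, y2)
        C, g, surface = v.grid_search(feats, [1.0, 4.0], [0.5, 2.0], folds=2)
        assert (C, g) == (1.0, 0.5)

    def test_empty_grid_rejected(self, toy_separable):
        with pytest.raises(ValueError, match="empty"):
            v.grid_search(toy_separable, [], [1.0])


class TestPersistence:
    def test_save_load_preserves_decisions(self, xor_features, tmp_path):
        model = v.train(xor_features, v.TrainingConfig(C=10.0, g=1.0))
        path = tmp_path / "model.json"
        model.save(path)
        back = v.SvmModel.load(path)
        probes = np.random.default_rng(1).uniform(0, 1, size=(10, 2))
        np.testing.assert_allclose(
            decision_values(model, probes), decision_values(back, probes),
            atol=1e-9,
        )

    def test_reject_foreign_document(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="not a vigileeg"):
            v.SvmModel.load(p)
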