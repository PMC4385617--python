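"""SVM dual solves, reduced-gradient MKL, decision function, model I/O."""

import numpy as np
import pytest

from pairmkl import (BaseKernelSpec, CompositeModel, DataError, NodeKernel,
                     PairSet, PairwiseKernelKind, build_base_grams, compute_bias,
                     decision_function, fit_composite, load_model, mkl_train,
                     predict_labels, save_model, train_svm, uniform_composite)
from pairmkl.synthetic import BENCHMARK_C, make_dataset
from conftest import qp_oracle_alphas, random_psd


def separable_problem(rng, n=16, gap=4.0):
    """Two well-separated Gaussian blobs, linear kernel, labels by blob."""
    X = np.vstack([rng.normal(size=(n // 2, 3)) + [gap, 0, 0],
                   rng.normal(size=(n - n // 2, 3)) - [gap, 0, 0]])
    y = np.concatenate([np.ones(n // 2), -np.ones(n - n // 2)]).astype(int)
    return X @ X.T, y


class TestTrainSvm:
    def test_two_point_closed_form(self):
        """Identity Gram, one point per class: alpha = (1, 1), b = 0."""
        alphas, bias, obj = train_svm(np.eye(2), np.array([1, -1]), c=10.0)
        np.testing.assert_allclose(alphas, [1.0, 1.0], atol=1e-6)
        assert bias == pytest.approx(0.0, abs=1e-9)
        assert obj == pytest.approx(1.0, abs=1e-6)

    def test_label_symmetric_problem_has_zero_bias(self, rng):
        K0 = random_psd(rng, 4, jitter=0.1)
        # block structure invariant under swapping the two classes
        Z = np.zeros_like(K0)
        K = np.block([[K0, Z], [Z, K0]])
        y = np.array([1] * 4 + [-1] * 4)
        _, bias, _ = train_svm(K, y, c=1.0)
        assert bias == pytest.approx(0.0, abs=1e-6)

    def test_agreement_with_reference_qp(self, rng):
        for _ in range(5):
            K = random_psd(rng, 20, rank=6)
            y = np.array([1] * 10 + [-1] * 10)
            rng.shuffle(y)
            alphas, bias, _ = train_svm(K, y, c=1.0)
            ref = qp_oracle_alphas(K, y, 1.0)
            ref_bias = compute_bias(ref, y, K, 1.0)
            f = K @ (alphas * y) + bias
            f_ref = K @ (ref * y) + ref_bias
            np.testing.assert_allclose(f, f_ref, atol=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(DataError, match="both classes"):
            train_svm(np.eye(3), np.array([1, 1, 1]), c=1.0)

    def test_margin_on_separable_support_vectors(self, rng):
        K, y = separable_problem(rng)
        alphas, bias, _ = train_svm(K, y, c=100.0)
        f = K @ (alphas * y) + bias
        sv = alphas > 1e-8
        assert (y[sv] * f[sv] >= 1 - 1e-6).all()
        assert (predict_labels(f) == y).all()


class TestComputeBias:
    def test_matches_midpoint_formula_and_translation_equivariance(self, rng):
        K = random_psd(rng, 10, jitter=0.1)
        y = np.array([1] * 5 + [-1] * 5)
        alphas, bias, _ = train_svm(K, y, c=1.0)
        f0 = K @ (alphas * y)
        free = alphas < 1.0 * (1 - 1e-6)
        neg = f0[(y == -1) & free] if ((y == -1) & free).any() else f0[y == -1]
        pos = f0[(y == 1) & free] if ((y == 1) & free).any() else f0[y == 1]
        manual = -0.5 * (neg.max() + pos.min())
        assert bias == pytest.approx(manual, abs=1e-12)
        # shifting every bias-free value by +delta shifts b by -delta
        delta = 0.7
        shifted = -0.5 * ((neg + delta).max() + (pos + delta).min())
        assert shifted == pytest.approx(manual - delta)


class TestMklTrain:
    def test_single_gram_reduces_to_train_svm(self, rng):
        K = random_psd(rng, 14, jitter=0.1)
        y = np.array([1] * 7 + [-1] * 7)
        res = mkl_train([K], y, c=1.0)
        np.testing.assert_allclose(res.weights, [1.0])
        alphas, bias, obj = train_svm(K, y, c=1.0)
        assert res.objective == pytest.approx(obj, rel=1e-8)
        np.testing.assert_allclose(res.alphas, alphas, atol=1e-8)
        assert res.bias == pytest.approx(bias, abs=1e-8)

    def test_duplicated_kernels_leave_objective_invariant(self, rng):
        K = random_psd(rng, 16, jitter=0.1)
        y = np.array([1] * 8 + [-1] * 8)
        single = mkl_train([K], y, c=1.0)
        duplicated = mkl_train([K, K.copy()], y, c=1.0)
        assert duplicated.objective == pytest.approx(single.objective, rel=1e-6)

    def test_simplex_and_box_invariants_hold(self, rng):
        grams = [random_psd(rng, 20, jitter=0.1) for _ in range(3)]
        y = np.array([1] * 10 + [-1] * 10)
        res = mkl_train(grams, y, c=0.7)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert (res.weights >= 0).all()
        assert (res.alphas >= -1e-12).all() and (res.alphas <= 0.7 + 1e-9).all()
        assert abs(res.alphas @ y) <= 1e-6 * 0.7 * len(y)

    def test_outer_objective_monotone_nonincreasing(self, rng):
        grams = [random_psd(rng, 24, jitter=0.1) for _ in range(4)]
        y = np.array([1] * 12 + [-1] * 12)
        res = mkl_train(grams, y, c=1.0)
        objs = [h["objective"] for h in res.history]
        assert all(b <= a + 1e-10 for a, b in zip(objs, objs[1:]))

    def test_mkl_objective_never_exceeds_uniform_weighting(self, rng):
        for _ in range(5):
            grams = [random_psd(rng, 18, jitter=0.1) for _ in range(3)]
            y = np.array([1] * 9 + [-1] * 9)
            res = mkl_train(grams, y, c=1.0)
            from pairmkl.mkl_svm import _svm_solve
            _, uni_obj = _svm_solve(uniform_composite(grams), y, 1.0)
            assert res.objective <= uni_obj + 1e-6 * max(abs(uni_obj), 1.0)

    def test_informative_vs_permuted_noise_weight_recovery(self):
        """A label-decorrelated (pair-permuted) copy of the Gram gets
        essentially no weight; verified against a weight-grid oracle."""
        from pairmkl.mkl_svm import _svm_solve

        ds = make_dataset(seed=3, n_pairs=200, informativeness=(0.9,))
        spec = [BaseKernelSpec(PairwiseKernelKind.P1, ds.node_kernels[0].name)]
        g = build_base_grams(ds.node_kernels, spec, ds.pair_set)[0]
        perm = np.random.default_rng(11).permutation(len(ds.pair_set))
        g_noise = g[np.ix_(perm, perm)]
        y = ds.pair_set.labels
        res = mkl_train([g, g_noise], y, c=1.0)
        assert res.weights[0] >= 0.9
        # grid oracle over lambda in {0, 0.05, ..., 1}
        grid_best = min(
            _svm_solve(lam * g + (1 - lam) * g_noise, y, 1.0)[1]
            for lam in np.linspace(0, 1, 21))
        assert res.objective <= grid_best + 1e-3 * abs(grid_best)

    def test_scale_sanity(self, rng):
        """Scaling all grams by gamma and C by 1/gamma preserves labels."""
        K, y = separable_problem(rng)
        gamma = 7.5
        res1 = mkl_train([K], y, c=2.0)
        res2 = mkl_train([gamma * K], y, c=2.0 / gamma)
        f1 = K @ (res1.alphas * y) + res1.bias
        f2 = gamma * K @ (res2.alphas * y) + res2.bias
        np.testing.assert_array_equal(predict_labels(f1), predict_labels(f2))
        np.testing.assert_array_equal(predict_labels(f1), y)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(DataError, match="shape"):
            mkl_train([np.eye(4), np.eye(5)], np.array([1, 1, -1, -1]), c=1.0)


class TestUniformComposite:
    def test_single_gram_is_itself(self, rng):
        K = random_psd(rng, 4)
        np.testing.assert_array_equal(uniform_composite([K]), K)

    def test_mean_identity(self, rng):
        K = random_psd(rng, 4)
        np.testing.assert_allclose(uniform_composite([K, -K + 2 * K]), K)


class TestCompositeModelAndDecision:
    def _fit(self, seed=0, n_pairs=120):
        ds = make_dataset(seed=seed, n_pairs=n_pairs)
        specs = [BaseKernelSpec(PairwiseKernelKind.P1, k.name)
                 for k in ds.node_kernels]
        model = fit_composite(ds.node_kernels, specs, ds.pair_set, c=BENCHMARK_C)
        return ds, model

    def test_decision_matches_dense_composite_multiplication(self):
        ds, model = self._fit()
        test_pairs = model.train_pairs.subset(np.arange(30))
        phi = decision_function(model, test_pairs, ds.node_kernels)
        grams = build_base_grams(ds.node_kernels, model.base_specs,
                                 test_pairs, model.train_pairs)
        dense = sum(w * g for w, g in zip(model.weights, grams))
        expected = dense @ (model.alphas * model.train_pairs.labels) + model.bias
        np.testing.assert_allclose(phi, expected, atol=1e-10)

    def test_all_zero_alphas_give_constant_bias(self):
        ds, model = self._fit()
        zero = CompositeModel(
            base_specs=model.base_specs, weights=model.weights,
            alphas=np.zeros_like(model.alphas), bias=0.25,
            box_bound=model.box_bound, train_pairs=model.train_pairs,
            node_ids=model.node_ids, objective=0.0, normalize=model.normalize)
        phi = decision_function(zero, model.train_pairs.subset(np.arange(10)),
                                ds.node_kernels)
        np.testing.assert_allclose(phi, 0.25)

    def test_model_round_trip_is_exact(self, tmp_path):
        ds, model = self._fit()
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.weights, model.weights)
        np.testing.assert_array_equal(back.alphas, model.alphas)
        assert back.bias == model.bias
        assert back.base_specs == model.base_specs
        np.testing.assert_array_equal(back.train_pairs.pairs,
                                      model.train_pairs.pairs)
        phi1 = decision_function(model, model.train_pairs, ds.node_kernels)
        phi2 = decision_function(back, back.train_pairs, ds.node_kernels)
        np.testing.assert_array_equal(phi1, phi2)

    def test_invariant_violations_rejected(self):
        ds, model = self._fit()
        with pytest.raises(DataError, match="simplex"):
            CompositeModel(base_specs=model.base_specs,
                           weights=model.weights * 2, alphas=model.alphas,
                           bias=model.bias, box_bound=model.box_bound,
                           train_pairs=model.train_pairs, node_ids=model.node_ids,
                           objective=model.objective)
        with pytest.raises(DataError, match="box"):
            CompositeModel(base_specs=model.base_specs, weights=model.weights,
                           alphas=model.alphas + 10 * model.box_bound,
                           bias=model.bias, box_bound=model.box_bound,
                           train_pairs=model.train_pairs, node_ids=model.node_ids,
                           objective=model.objective)
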