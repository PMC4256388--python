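import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import jointcodes as jc


def _finite_difference_gradient(w, x, lam, h=1e-6):
    grad = np.zeros_like(w)
    for idx in np.ndindex(w.shape):
        wp, wm = w.copy(), w.copy()
        wp[idx] += h
        wm[idx] -= h
        grad[idx] = (
            jc.rica_objective(wp, x, lam)[0] - jc.rica_objective(wm, x, lam)[0]
        ) / (2 * h)
    return grad


class TestWhitener:
    def test_known_diagonal_covariance(self, rng):
        x = np.diag([2.0, 1.0]) @ rng.standard_normal((2, 20000))
        w = jc.fit_whitener(x, eps=1e-12)
        z = w.apply(x)
        cov = z @ z.T / z.shape[1]
        np.testing.assert_allclose(cov, np.eye(2), atol=0.05)

    def test_whitened_fitting_set_has_unit_variance(self, rng):
        x = rng.standard_normal((6, 6)) @ rng.standard_normal((6, 300))
        z = jc.fit_whitener(x, eps=1e-10).apply(x)
        cov = z @ z.T / z.shape[1]
        np.testing.assert_allclose(np.diag(cov), 1.0, rtol=0.05)
        assert np.linalg.cond(jc.fit_whitener(x).transform) < 1e12  # invertible

    def test_large_eps_shrinks_output(self, rng):
        x = rng.standard_normal((4, 500))
        z = jc.fit_whitener(x, eps=1e3).apply(x)
        assert np.var(z) < 1e-2

    def test_needs_two_samples(self):
        with pytest.raises(jc.ValidationError):
            jc.fit_whitener(np.zeros((3, 1)))


class TestRicaObjective:
    def test_zero_data_gives_zero(self):
        value, grad = jc.rica_objective(np.ones((3, 4)), np.zeros((4, 5)), 0.7)
        assert value == 0.0
        np.testing.assert_array_equal(grad, np.zeros((3, 4)))

    def test_orthonormal_complete_reconstruction_is_zero(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        x = rng.standard_normal((5, 30))
        value_pen, _ = jc.rica_objective(q, x, 1.0)
        value_rec, _ = jc.rica_objective(q, x, 0.0)
        assert value_rec <= 1e-20
        penalty = np.sum(np.log(np.cosh(q @ x))) / x.shape[1]
        np.testing.assert_allclose(value_pen, penalty, rtol=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        w = rng.standard_normal((4, 6))
        x = rng.standard_normal((6, 8))
        _, grad = jc.rica_objective(w, x, 0.5)
        num = _finite_difference_gradient(w, x, 0.5)
        rel = np.abs(grad - num) / np.maximum(np.abs(num), 1e-8)
        assert rel.max() <= 1e-5

    def test_value_invariant_under_row_permutation(self, rng):
        w = rng.standard_normal((5, 7))
        x = rng.standard_normal((7, 11))
        v1, _ = jc.rica_objective(w, x, 0.3)
        v2, _ = jc.rica_objective(w[::-1], x, 0.3)
        assert v1 == v2

    def test_shape_mismatch_rejected(self):
        with pytest.raises(jc.ValidationError):
            jc.rica_objective(np.zeros((2, 3)), np.zeros((4, 5)), 0.1)


class TestLearnDictionary:
    def test_descent_from_init_and_monotone_trace(self, rng):
        x = rng.standard_normal((6, 80))
        d = jc.learn_dictionary(x, 4, 0.5, seed=3)
        assert d.trace[-1] < d.trace[0]
        assert np.all(np.diff(d.trace) <= 1e-8)

    def test_lambda_zero_complete_case_reaches_orthonormal(self, rng):
        x = rng.standard_normal((6, 200))
        white = jc.fit_whitener(x, eps=1e-10).apply(x)
        d = jc.learn_dictionary(white, 6, 0.0, seed=0, max_iter=500)
        rec, _ = jc.rica_objective(d.words, white, 0.0)
        assert rec <= 1e-6

    def test_planted_two_atom_recovery(self):
        rng = np.random.default_rng(11)
        signs = rng.choice([-1.0, 1.0], size=200)
        axes = rng.integers(0, 2, size=200)
        x = np.zeros((2, 200))
        x[axes, np.arange(200)] = signs
        x += 0.01 * rng.standard_normal(x.shape)
        d = jc.learn_dictionary(x, 2, 0.5, seed=0)
        rows = d.words / np.linalg.norm(d.words, axis=1, keepdims=True)
        cos = np.abs(rows @ np.eye(2))
        r, c = linear_sum_assignment(-cos)
        assert np.all(cos[r, c] >= 0.99)

    def test_same_seed_is_bit_identical(self, rng):
        x = rng.standard_normal((5, 60))
        d1 = jc.learn_dictionary(x, 3, 0.5, seed=9)
        d2 = jc.learn_dictionary(x, 3, 0.5, seed=9)
        np.testing.assert_array_equal(d1.words, d2.words)

    def test_warns_when_underdetermined(self, rng):
        x = rng.standard_normal((4, 3))
        with pytest.warns(UserWarning, match="overfit"):
            jc.learn_dictionary(x, 5, 0.5, seed=0, max_iter=5)


class TestKmeansDictionary:
    def test_separated_blobs_recover_means(self, rng):
        means = np.array([[5.0, 0.0, 0.0], [-5.0, 0.0, 0.0]])
        x = np.hstack(
            [means[i][:, None] + 0.05 * rng.standard_normal((3, 100)) for i in range(2)]
        )
        d = jc.kmeans_dictionary(x, 2, seed=0)
        cost = np.linalg.norm(d.words[:, None] - means[None], axis=2)
        r, c = linear_sum_assignment(cost)
        assert cost[r, c].max() < 0.1

    def test_k_equals_n_returns_points(self, rng):
        x = rng.standard_normal((3, 4))
        d = jc.kmeans_dictionary(x, 4, seed=0)
        cost = np.linalg.norm(d.words[:, None] - x.T[None], axis=2)
        r, c = linear_sum_assignment(cost)
        assert cost[r, c].max() < 1e-8

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(jc.ValidationError):
            jc.kmeans_dictionary(rng.standard_normal((3, 4)), 5)

    def test_same_seed_reproducible(self, rng):
        x = rng.standard_normal((4, 50))
        np.testing.assert_array_equal(
            jc.kmeans_dictionary(x, 3, seed=2).words,
            jc.kmeans_dictionary(x, 3, seed=2).words,
        )


class TestPoolCodebook:
    def _dict(self, words, label):
        return jc.Dictionary(words=np.asarray(words, float), activity_label=label)

    def test_two_class_stacking_and_slices(self, rng):
        wa, wb = rng.standard_normal((2, 2, 3))
        whitener = jc.fit_whitener(rng.standard_normal((3, 10)))
        cb = jc.pool_codebook([self._dict(wb, "b"), self._dict(wa, "a")], whitener)
        assert cb.words.shape == (4, 3)
        assert cb.class_slices == {"a": (0, 2), "b": (2, 4)}
        np.testing.assert_array_equal(cb.words[:2], wa)  # label order

    def test_word_count_bookkeeping(self, rng):
        whitener = jc.fit_whitener(rng.standard_normal((4, 10)))
        dicts = [
            self._dict(rng.standard_normal((3, 4)), f"class_{i}") for i in range(5)
        ]
        cb = jc.pool_codebook(dicts, whitener)
        assert cb.n_words == 15

    def test_single_dictionary_identity(self, rng):
        whitener = jc.fit_whitener(rng.standard_normal((3, 10)))
        d = self._dict(rng.standard_normal((5, 3)), "only")
        cb = jc.pool_codebook([d], whitener)
        np.testing.assert_array_equal(cb.words, d.words)

    def test_duplicate_labels_rejected(self, rng):
        whitener = jc.fit_whitener(rng.standard_normal((3, 10)))
        dicts = [self._dict(np.ones((2, 3)), "x"), self._dict(np.ones((2, 3)), "x")]
        with pytest.raises(jc.ValidationError, match="duplicate"):
            jc.pool_codebook(dicts, whitener)

    def test_mismatched_dimension_rejected(self, rng):
        whitener = jc.fit_whitener(rng.standard_normal((3, 10)))
        dicts = [self._dict(np.ones((2, 3)), "x"), self._dict(np.ones((2, 4)), "y")]
        with pytest.raises(jc.ValidationError, match="dimension"):
            jc.pool_codebook(dicts, whitener)
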