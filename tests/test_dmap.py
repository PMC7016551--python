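import numpy as np
import pytest
import scipy.linalg

import qsdmap as q
from qsdmap.dmap import (PointCloud, build_kernel, kernel_density,
                         build_generator, build_tmdmap, spectral_decompose)


def _cloud(points):
    return PointCloud(np.asarray(points, dtype=float))


class TestKernel:
    def test_unit_diagonal_and_exact_symmetry(self, rng):
        c = _cloud(rng.normal(size=(40, 3)))
        K = build_kernel(c, 0.7).values
        np.testing.assert_array_equal(np.diag(K), np.ones(40))
        np.testing.assert_array_equal(K, K.T)
        assert K.min() >= 0 and K.max() <= 1

    def test_pair_value_from_distance(self):
        K = build_kernel(_cloud([[0.0], [2.0]]), epsilon=1.0).values
        assert K[0, 1] == pytest.approx(np.exp(-1.0), rel=1e-14)

    def test_cutoff_sparsifies_symmetrically(self, rng):
        pts = rng.normal(size=(60, 2))
        dense = build_kernel(_cloud(pts), 0.05).values
        sparse = build_kernel(_cloud(pts), 0.05, cutoff=1e-3).values
        assert sparse.nnz < 60 * 60
        S = sparse.toarray()
        np.testing.assert_array_equal(S, S.T)
        mask = dense >= 1e-3
        np.testing.assert_allclose(S[mask], dense[mask], rtol=1e-13)
        assert np.all(S[~mask] == 0)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            _cloud([[0.0], [np.nan]])


class TestDensity:
    def test_coincident_pair(self):
        K = build_kernel(_cloud([[1.0], [1.0]]), 0.5)
        np.testing.assert_allclose(kernel_density(K).q, [2.0, 2.0])

    def test_isolated_points_approach_one(self):
        K = build_kernel(_cloud([[0.0], [1e3]]), 0.5)
        np.testing.assert_allclose(kernel_density(K).q, [1.0, 1.0])

    def test_permutation_equivariance(self, rng):
        pts = rng.normal(size=(25, 2))
        qv = kernel_density(build_kernel(_cloud(pts), 0.3)).q
        perm = rng.permutation(25)
        qp = kernel_density(build_kernel(_cloud(pts[perm]), 0.3)).q
        np.testing.assert_allclose(qp, qv[perm], rtol=1e-12)


class TestGenerator:
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_rows_sum_to_zero_and_offdiag_nonneg(self, rng, alpha):
        c = _cloud(rng.normal(size=(30, 2)))
        K = build_kernel(c, 0.4)
        gen = build_generator(K, kernel_density(K), alpha)
        L = gen.values
        np.testing.assert_allclose(L @ np.ones(30), 0.0, atol=1e-12)
        off = L - np.diag(np.diag(L))
        assert off.min() >= 0

    def test_markov_matrix_is_stochastic(self, rng):
        c = _cloud(rng.normal(size=(20, 1)))
        K = build_kernel(c, 0.2)
        gen = build_generator(K, kernel_density(K), 0.5)
        P = gen.epsilon * gen.values + np.eye(20)
        assert P.min() >= 0
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_two_point_closed_form_alpha_zero(self):
        eps = 0.3
        c = _cloud([[0.0], [1.2]])
        K = build_kernel(c, eps)
        k12 = np.exp(-1.2**2 / (4 * eps))
        gen = build_generator(K, kernel_density(K), alpha=0.0)
        p = 1.0 / (1.0 + k12)
        expected = np.array([[p - 1, 1 - p], [1 - p, p - 1]]) / eps
        np.testing.assert_allclose(gen.values, expected, atol=1e-12)

    def test_duplicate_points_do_not_crash(self):
        c = _cloud([[0.0], [0.0], [1.0], [1.0], [2.0]])
        K = build_kernel(c, 0.5)
        gen = build_generator(K, kernel_density(K), 0.5)
        np.testing.assert_allclose(gen.values.sum(axis=1), 0, atol=1e-11)

    def test_disconnected_graph_raises(self, rng):
        pts = np.concatenate([rng.normal(scale=0.1, size=(10, 1)),
                              rng.normal(loc=100.0, scale=0.1, size=(10, 1))])
        K = build_kernel(_cloud(pts), 0.05, cutoff=1e-8)
        with pytest.raises(ValueError, match="disconnected"):
            build_generator(K, kernel_density(K), 0.5)


class TestSpectralDecompose:
    def test_zero_mode_and_nonpositive_spectrum(self, ou_cloud):
        res = q.DiffusionMap(ou_cloud, epsilon=0.05).fit(k=4)
        ev = res.eigenvalues
        assert abs(ev[0]) < 1e-10
        assert np.all(ev <= 1e-10)
        phi0 = res.eigenvectors[:, 0]
        assert np.std(phi0) / abs(np.mean(phi0)) < 1e-6

    def test_ou_spectrum_ratio(self, ou_cloud):
        """alpha = 1/2 on Boltzmann samples of V = x^2/2 approximates the
        OU generator: eigenvalue ladder -k, so lambda2/lambda1 = 2."""
        res = q.DiffusionMap(ou_cloud, epsilon=0.05).fit(k=3)
        ratio = res.eigenvalues[2] / res.eigenvalues[1]
        assert 1.8 < ratio < 2.2

    def test_small_cloud_matches_dense_full_spectrum_oracle(self, rng):
        for m in (4, 5, 6):
            c = _cloud(rng.normal(size=(m, 2)))
            K = build_kernel(c, 0.5)
            gen = build_generator(K, kernel_density(K), 0.5)
            dec = spectral_decompose(gen, k=m - 1)
            w = np.sort(scipy.linalg.eig(gen.values)[0].real)[::-1]
            np.testing.assert_allclose(dec.eigenvalues, w[:m], atol=1e-9)

    def test_eigen_residuals(self, rng):
        c = _cloud(rng.normal(size=(300, 2)))
        K = build_kernel(c, 0.3)
        gen = build_generator(K, kernel_density(K), 0.5)
        dec = spectral_decompose(gen, k=4)
        Lnorm = np.linalg.norm(gen.values, ord=np.inf)
        for j in range(5):
            r = gen.values @ dec.eigenvectors[:, j] \
                - dec.eigenvalues[j] * dec.eigenvectors[:, j]
            assert np.linalg.norm(r) <= 1e-8 * Lnorm

    def test_sign_and_norm_convention(self, rng):
        c = _cloud(rng.normal(size=(100, 1)))
        dec = q.DiffusionMap(c, epsilon=0.1).fit(k=3).decomposition
        for j in range(4):
            v = dec.eigenvectors[:, j]
            assert np.linalg.norm(v) == pytest.approx(1.0, rel=1e-10)
            assert v[np.argmax(np.abs(v))] > 0

    def test_sparse_matches_dense(self, rng):
        pts = rng.normal(size=(400, 1))
        dense = q.DiffusionMap(pts, epsilon=0.05).fit(k=3)
        sparse = q.DiffusionMap(pts, epsilon=0.05, cutoff=1e-12).fit(k=3)
        np.testing.assert_allclose(sparse.eigenvalues, dense.eigenvalues,
                                   rtol=1e-6, atol=1e-8)

    def test_invalid_k(self, rng):
        gen = q.DiffusionMap(rng.normal(size=(10, 1)), epsilon=0.1)._generator()
        with pytest.raises(ValueError):
            spectral_decompose(gen, k=10)


class TestTMDmap:
    def test_rows_sum_to_zero(self, rng):
        pts = rng.normal(size=(50, 1))
        pi = np.exp(-pts[:, 0] ** 2)
        gen = q.TargetMeasureDiffusionMap(pts, 0.2, pi)._generator()
        np.testing.assert_allclose(gen.values @ np.ones(50), 0, atol=1e-12)

    def test_reduces_to_row_normalised_when_factor_constant(self, rng):
        """If pi is chosen so sqrt(pi)/q is constant, the right scaling
        cancels and TMDmap equals the plain alpha = 0 construction."""
        pts = rng.normal(size=(40, 2))
        c = _cloud(pts)
        K = build_kernel(c, 0.3)
        qd = kernel_density(K)
        pi = qd.q**2  # sqrt(pi)/q = 1
        tmd = build_tmdmap(K, qd, pi)
        plain = build_generator(K, qd, alpha=0.0)
        np.testing.assert_allclose(tmd.values, plain.values, atol=1e-12)

    def test_target_scale_invariance(self, rng):
        pts = rng.normal(size=(30, 1))
        c = _cloud(pts)
        K = build_kernel(c, 0.2)
        qd = kernel_density(K)
        pi = np.exp(-pts[:, 0] ** 2 / 2)
        a = build_tmdmap(K, qd, pi)
        b = build_tmdmap(K, qd, 37.5 * pi)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_uniform_samples_gaussian_target_ou_ratio(self):
        """Uniform cloud reweighted to a standard Gaussian target recovers
        the OU spectrum: lambda2/lambda1 = 2."""
        rng = np.random.default_rng(7)
        x = rng.uniform(-3, 3, size=(4000, 1))
        pi = np.exp(-x[:, 0] ** 2 / 2)
        res = q.TargetMeasureDiffusionMap(x, 0.05, pi).fit(k=2)
        ratio = res.eigenvalues[2] / res.eigenvalues[1]
        assert 1.8 < ratio < 2.2

    def test_nonpositive_target_rejected(self, rng):
        pts = rng.normal(size=(10, 1))
        c = _cloud(pts)
        K = build_kernel(c, 0.2)
        with pytest.raises(ValueError, match="positive"):
            build_tmdmap(K, kernel_density(K), np.zeros(10))

    def test_matches_alpha_half_when_sampling_equals_target(self):
        """When the sampling density equals the target density, TMDmap and
        the alpha = 1/2 generator estimate the same operator.

        The two constructions carry different finite-bandwidth corrections
        (TMDmap uses the exact density, alpha-normalisation a kernel
        estimate); the correction grows with the mode index, so the third
        eigenvalue is only required to agree within 25%.
        """
        t = q.simulate_overdamped(q.Quadratic(1), 1.0, 0.1, 60_000, [0.0], 5,
                                  scheme="lm")
        pts = t.points[10::10][:6000]
        pi = np.exp(-pts[:, 0] ** 2 / 2)
        a = q.DiffusionMap(pts, 0.03).fit(k=3).eigenvalues[1:]
        b = q.TargetMeasureDiffusionMap(pts, 0.03, pi).fit(k=3).eigenvalues[1:]
        np.testing.assert_allclose(b[:2], a[:2], rtol=0.10)
        np.testing.assert_allclose(b[2], a[2], rtol=0.25)


class TestNystrom:
    def _fit(self, rng, m=200):
        pts = rng.normal(size=(m, 1))
        model = q.DiffusionMap(pts, epsilon=0.1)
        return model, model.fit(k=3)

    def test_exact_at_training_points(self, rng):
        model, res = self._fit(rng)
        for j in (1, 2):
            ext = res.nystrom(model.cloud.points, j)
            ref = res.eigenvectors[:, j]
            assert np.max(np.abs(ext - ref)) / np.max(np.abs(ref)) < 1e-8

    def test_constant_mode_extends_constant(self, rng):
        model, res = self._fit(rng)
        ext = res.nystrom(np.linspace(-2, 2, 7)[:, None], 0)
        assert np.ptp(ext) / np.max(np.abs(ext)) < 1e-10

    def test_antisymmetric_vector_vanishes_at_midpoint(self):
        pts = np.array([[-1.0], [1.0]])
        res = q.DiffusionMap(pts, epsilon=1.0).fit(k=1)
        # the second eigenvector of a symmetric two-point cloud is odd
        assert res.eigenvectors[0, 1] == pytest.approx(-res.eigenvectors[1, 1])
        ext = res.nystrom(np.array([[0.0]]), 1)
        assert abs(ext[0]) < 1e-12

    def test_zero_markov_eigenvalue_rejected(self, rng):
        model, res = self._fit(rng)
        res.decomposition.eigenvalues = res.decomposition.eigenvalues.copy()
        res.decomposition.eigenvalues[1] = -1.0 / res.decomposition.epsilon
        with pytest.raises(ZeroDivisionError):
            res.nystrom(np.array([[0.0]]), 1)


class TestModelLayer:
    def test_from_trajectory_carries_provenance(self):
        t = q.simulate_overdamped(q.Quadratic(1), 2.0, 0.05, 500, [0.0], 11)
        model = q.DiffusionMap.from_trajectory(t, epsilon=0.1, subsample=5)
        assert model.cloud.m == 101
        assert model.cloud.metadata["beta"] == 2.0
        assert model.cloud.metadata["seed"] == 11

    def test_summary_mentions_key_parameters(self, rng):
        res = q.DiffusionMap(rng.normal(size=(50, 2)), epsilon=0.2).fit(k=2)
        s = res.summary()
        assert "epsilon" in s and "0.2" in s and "alpha" in s
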