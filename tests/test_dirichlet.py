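import numpy as np
import pytest
from scipy.integrate import quad

import qsdmap as q
from qsdmap.dirichlet import (barycentric_interpolate, chebyshev_committor,
                              chebyshev_dirichlet, chebyshev_lobatto,
                              clenshaw_curtis_weights, qsd_density,
                              qsd_generator_spectrum_1d, solve_committor,
                              solve_dirichlet_eigen)


class TestChebyshevPrimitives:
    def test_differentiation_of_polynomial_is_exact(self):
        D, x = chebyshev_lobatto(24, -2.0, 3.0)
        f = x**5 - 2 * x**2 + 1
        np.testing.assert_allclose(D @ f, 5 * x**4 - 4 * x, atol=1e-8)

    def test_clenshaw_curtis_integrates_smooth_function(self):
        for n in (32, 33):
            w = clenshaw_curtis_weights(n, 0.0, np.pi)
            _, x = chebyshev_lobatto(n, 0.0, np.pi)
            assert np.sum(w * np.sin(x)) == pytest.approx(2.0, abs=1e-12)

    def test_barycentric_hits_nodes_exactly(self):
        _, x = chebyshev_lobatto(16, -1, 1)
        vals = np.cos(3 * x)
        out = barycentric_interpolate(x, vals, x[5])
        assert out == vals[5]


class TestChebyshevSolvers:
    def test_flat_dirichlet_eigenvalue_closed_form(self):
        """V = 0 on (-L, L): first eigenvalue -(pi / 2L)^2."""
        for L in (1.0, 2.5):
            lam, _, _ = chebyshev_dirichlet(q.Flat(1), 1.0, -L, L, 128, k=2)
            assert lam[0] == pytest.approx(-((np.pi / (2 * L)) ** 2), abs=1e-8)
            assert lam[1] == pytest.approx(-((np.pi / L) ** 2), abs=1e-8)

    def test_flat_committor_is_linear_ramp(self):
        g, c = chebyshev_committor(q.Flat(1), 1.0, -1.0, 1.0, 64)
        np.testing.assert_allclose(c, (g + 1) / 2, atol=1e-8)

    def test_committor_matches_quadrature_closed_form(self):
        """1-D committor closed form q(x) = int_a^x e^{beta V} / int_a^b."""
        pot = q.Quadratic(1)
        g, c = chebyshev_committor(pot, 1.0, -1.0, 1.0, 256)
        den = quad(lambda t: np.exp(t**2 / 2), -1, 1)[0]
        ref = np.array([quad(lambda t: np.exp(t**2 / 2), -1, xv)[0] / den
                        for xv in g])
        np.testing.assert_allclose(c, ref, atol=1e-6)

    def test_first_eigenvalue_stable_under_grid_doubling(self):
        lam1, _, _ = chebyshev_dirichlet(q.Quadratic(1), 1.0, -1, 1, 128, k=1)
        lam2, _, _ = chebyshev_dirichlet(q.Quadratic(1), 1.0, -1, 1, 256, k=1)
        assert abs(lam1[0] - lam2[0]) < 1e-8

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="n must be"):
            chebyshev_dirichlet(q.Flat(1), 1.0, -1, 1, 8)


class TestQSD:
    def test_constant_v_gives_restricted_boltzmann(self):
        pot = q.Quadratic(1)
        _, grid = chebyshev_lobatto(64, -1.5, 1.5)
        res = qsd_density(np.ones(65), pot, beta=2.0, L=1.5, grid=grid)
        w = clenshaw_curtis_weights(64, -1.5, 1.5)
        boltz = np.exp(-2.0 * pot.value_many(grid[:, None]))
        boltz /= np.sum(w * boltz)
        np.testing.assert_allclose(res.nu, boltz, atol=1e-12)
        assert np.sum(w * res.nu) == pytest.approx(1.0, abs=1e-8)

    def test_flat_qsd_density_value_at_origin(self):
        """Ground state of the Dirichlet Laplacian on (-1, 1):
        nu(x) = (pi/4) cos(pi x / 2)."""
        res = q.chebyshev_solve_1d(q.Flat(1), 1.0, L=1.0, n=64)
        assert res.nu_at(0.0) == pytest.approx(np.pi / 4, abs=1e-10)
        assert res.rate == pytest.approx((np.pi / 2) ** 2, abs=1e-8)

    def test_qsd_integrates_to_one(self):
        res = q.chebyshev_solve_1d(q.ShiftedDoubleWell1D(), 1.0, L=3.0, n=128)
        n = res.grid.size - 1
        w = clenshaw_curtis_weights(n, res.grid.min(), res.grid.max())
        assert np.sum(w * res.nu) == pytest.approx(1.0, abs=1e-8)
        assert np.all(res.v[1:-1] >= 0)

    def test_qsd_approaches_boltzmann_as_domain_grows(self):
        """As the domain widens, the QSD of the shifted double well converges
        to the Boltzmann density on a fixed compact (monotone L1 distance),
        and v at the minimum tends to 1."""
        pot = q.ShiftedDoubleWell1D()
        xs = np.linspace(-0.5, 2.5, 301)
        # Boltzmann density normalised over the whole line
        xfull = np.linspace(-10, 12, 4001)
        z = np.trapezoid(np.exp(-pot.value_many(xfull[:, None])), xfull)
        boltz = np.exp(-pot.value_many(xs[:, None])) / z
        l1s, v1s = [], []
        for L in (2, 3, 5, 8):
            res = q.chebyshev_solve_1d(pot, 1.0, L=L, n=128)
            nu = res.nu_at(xs)
            l1s.append(np.trapezoid(np.abs(nu - boltz), xs))
            v1s.append(res.v_at(1.0))
        floor = 1e-8  # barycentric/quadrature noise once converged
        assert all(b < a or b < floor for a, b in zip(l1s, l1s[1:]))
        assert abs(v1s[-1] - 1.0) < 0.05

    def test_negative_v_rejected(self):
        _, grid = chebyshev_lobatto(32, -1, 1)
        v = np.sin(2 * np.pi * grid)  # mixed signs
        with pytest.raises(ValueError, match="positive"):
            qsd_density(v, q.Flat(1), 1.0, 1.0, grid=grid)


class TestPointCloudCommittor:
    def test_boundary_values_exact(self, dw1d_cloud):
        x = dw1d_cloud.points[:, 0]
        idxA = np.nonzero((x >= -1.1) & (x <= -1.0))[0]
        idxB = np.nonzero((x >= 1.0) & (x <= 1.1))[0]
        sub = q.PointCloud(dw1d_cloud.points[:3000])
        xs = sub.points[:, 0]
        a = np.nonzero((xs >= -1.1) & (xs <= -1.0))[0]
        b = np.nonzero((xs >= 1.0) & (xs <= 1.1))[0]
        gen = q.DiffusionMap(sub, epsilon=0.05)._generator()
        f = solve_committor(gen, a, b)
        assert np.all(f.values[a] == 0.0)
        assert np.all(f.values[b] == 1.0)
        assert f.values.min() > -0.05 and f.values.max() < 1.05

    def test_three_point_chain_is_half(self):
        gen = q.DiffusionMap(np.array([[0.0], [1.0], [2.0]]),
                             epsilon=0.3)._generator()
        f = solve_committor(gen, [0], [2])
        assert f.values[0] == 0.0 and f.values[2] == 1.0
        assert f.values[1] == pytest.approx(0.5, abs=1e-12)

    def test_overlapping_sets_rejected(self, rng):
        gen = q.DiffusionMap(rng.normal(size=(20, 1)), epsilon=0.3)._generator()
        with pytest.raises(ValueError, match="disjoint"):
            solve_committor(gen, [0, 1], [1, 2])

    def test_empty_free_set_rejected(self, rng):
        gen = q.DiffusionMap(rng.normal(size=(4, 1)), epsilon=0.3)._generator()
        with pytest.raises(ValueError, match="empty"):
            solve_committor(gen, [0, 1], [2, 3])

    def test_oracle_agreement_double_well(self, dw1d_cloud):
        """Point-cloud committor of V = (x^2-1)^2 between A = [-1.1, -1] and
        B = [1, 1.1] tracks the pseudo-spectral solution uniformly."""
        pts = dw1d_cloud.points
        x = pts[:, 0]
        idxA = np.nonzero((x >= -1.1) & (x <= -1.0))[0]
        idxB = np.nonzero((x >= 1.0) & (x <= 1.1))[0]
        target = np.exp(-q.DoubleWell1D().value_many(pts))
        gen = q.TargetMeasureDiffusionMap(pts, 0.025, target)._generator()
        f = solve_committor(gen, idxA, idxB)
        grid, qc = chebyshev_committor(q.DoubleWell1D(), 1.0, -1.0, 1.0, 256)
        free = np.nonzero((x > -1.0) & (x < 1.0))[0]
        oracle = barycentric_interpolate(grid, qc, x[free])
        assert np.max(np.abs(f.values[free] - oracle)) < 0.1


class TestPointCloudDirichlet:
    @pytest.fixture(scope="class")
    def flat_spec(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-1.3, 1.3, size=(4000, 1))
        gen = q.DiffusionMap(pts, epsilon=0.005)._generator()
        idx = np.nonzero(np.abs(pts[:, 0]) < 1)[0]
        return solve_dirichlet_eigen(gen, idx, k=3), idx, pts.shape[0]

    def test_eigenvalues_strictly_negative(self, flat_spec):
        spec, _, _ = flat_spec
        assert np.all(spec.eigenvalues < 0)

    def test_eigenvectors_vanish_outside_domain(self, flat_spec):
        spec, idx, m = flat_spec
        outside = np.setdiff1d(np.arange(m), idx)
        assert np.all(spec.eigenvectors[outside] == 0.0)

    def test_flat_spectrum_matches_dirichlet_laplacian(self, flat_spec):
        """V = 0, Omega = (-1, 1): eigenvalues -(pi (j+1)/2)^2.  Absolute
        values carry the O(sqrt(eps)) absorbing-boundary smearing of the
        point-cloud Dirichlet realisation, so they are checked at 20%;
        eigenvalue ratios cancel the smearing and are checked at 10%."""
        spec, _, _ = flat_spec
        exact = np.array([-((np.pi * (j + 1) / 2) ** 2) for j in range(3)])
        np.testing.assert_allclose(spec.eigenvalues, exact, rtol=0.20)
        ratios = spec.eigenvalues / spec.eigenvalues[0]
        np.testing.assert_allclose(ratios, exact / exact[0], rtol=0.10)

    def test_domain_must_exceed_k(self, rng):
        gen = q.DiffusionMap(rng.normal(size=(20, 1)), epsilon=0.3)._generator()
        with pytest.raises(ValueError, match="Omega"):
            solve_dirichlet_eigen(gen, [0, 1], k=2)


class TestQSDGeneratorSpectrum:
    def test_trapped_spectrum_matches_qsd_generator(self):
        """A diffusion map built on quasi-stationary samples (Fleming–Viot in
        one well of the 1-D double well) approximates the QSD-tilted
        generator: its first nonzero eigenvalue matches the Sturm–Liouville
        oracle within 20%."""
        pot = q.DoubleWell1D()
        res = q.chebyshev_solve_1d(pot, 1.0, n=256, interval=(-2.5, 0.0))
        oracle = qsd_generator_spectrum_1d(res, k=2, n_grid=1500)
        assert abs(oracle[0]) < 1e-8
        ens = q.fleming_viot(pot, 1.0, 0.002,
                             lambda x: -2.5 < x[0] < 0.0, 200, 6000, [-1.0],
                             21, history_stride=10)
        samp = ens.history[ens.history.shape[0] // 2:]
        samp = samp[:: max(1, samp.shape[0] // 3000)]
        fit = q.DiffusionMap(samp, epsilon=0.005).fit(k=2)
        assert fit.eigenvalues[1] == pytest.approx(oracle[1], rel=0.20)
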