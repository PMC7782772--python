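import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chirplift as cl

from .conftest import kernel_quadrature

finite = st.floats(-5.0, 5.0, allow_nan=False)


class TestClosedForm:
    def test_quadratic_form_reference_points(self):
        assert cl.g_delta(1.0, 0.0, 1.0, 0.0, 1.0) == 0.0  # same point, nu = 0
        assert cl.g_delta(0.0, 1.0, 0.0, 1.0, 1.0) == pytest.approx(3.0)
        assert cl.g_delta(1.0, 0.0, 0.0, 0.0, 1.0) == pytest.approx(3.0)

    @settings(derandomize=True, max_examples=50)
    @given(finite, finite, finite, finite, st.floats(0.01, 2.0))
    def test_quadratic_form_is_positive_semidefinite(self, om, nu, omp, nup, d):
        assert cl.g_delta(om, nu, omp, nup, d) >= -1e-12

    def test_maximum_value(self):
        p = cl.KernelParams(b=1.0, delta=1.0)
        assert p.max_value == pytest.approx(math.sqrt(3.0) / (2.0 * math.pi))
        assert cl.kernel_value(0.7, 0.0, 0.7, 0.0, p) == p.max_value

    @settings(derandomize=True, max_examples=50)
    @given(finite, finite, finite, finite)
    def test_kernel_bounded_by_its_maximum(self, om, nu, omp, nup):
        p = cl.KernelParams(b=0.3, delta=0.5)
        v = cl.kernel_value(om, nu, omp, nup, p)
        # strictly positive in exact arithmetic; underflows to 0 far away
        assert 0.0 <= v <= p.max_value

    @settings(derandomize=True, max_examples=50)
    @given(finite, finite, finite, finite)
    def test_mirror_symmetry_is_exact(self, om, nu, omp, nup):
        p = cl.KernelParams(b=0.1, delta=0.25)
        left = cl.kernel_value(-om, -nu, omp, nup, p)
        right = cl.kernel_value(om, nu, -omp, -nup, p)
        assert left == right  # bit-for-bit: same floating-point operations

    @pytest.mark.parametrize("b", [0.01, 0.05, 0.2])
    @pytest.mark.parametrize("delta", [0.03125, 0.0625, 0.125])
    def test_normalisation(self, b, delta):
        assert kernel_quadrature(cl.KernelParams(b=b, delta=delta)) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_gaussian_moments_match_quadrature(self):
        # nu marginal of the closed form integrates to N(nu', 2 b delta)
        p = cl.KernelParams(b=0.4, delta=0.7)
        mean, cov = cl.kernel_mean_cov(p, (0.3, -0.2))
        so, sn = np.sqrt(np.diag(cov))
        x, w = np.polynomial.legendre.leggauss(160)
        om = mean[0] + 8 * so * x
        nu = mean[1] + 8 * sn * x
        vals = cl.kernel_value(om[:, None], nu[None, :], 0.3, -0.2, p)
        wts = (8 * so * w)[:, None] * (8 * sn * w)[None, :] * vals
        assert np.sum(wts * nu[None, :]) == pytest.approx(mean[1], abs=1e-9)
        assert np.sum(wts * (nu[None, :] - mean[1]) ** 2) == pytest.approx(
            2 * p.b * p.delta, rel=1e-6
        )


class TestSupport:
    def test_region_degenerates_at_maximal_threshold(self):
        p = cl.KernelParams(b=1.0, delta=1.0, eps=math.sqrt(3.0) / (2.0 * math.pi))
        bounds = cl.support_bounds(2.0, 0.5, p)
        assert bounds.c_eps == pytest.approx(0.0, abs=1e-12)
        lo, hi = bounds.nu_interval
        assert lo == pytest.approx(0.5, abs=1e-7) and hi == pytest.approx(0.5, abs=1e-7)
        oi = bounds.omega_interval(0.5)
        # the surviving point is the transport point omega - delta * nu
        assert oi[0] == pytest.approx(2.0 - 1.0 * 0.5, abs=1e-7)
        assert oi[1] == pytest.approx(2.0 - 1.0 * 0.5, abs=1e-7)

    def test_nu_band_halfwidth_for_log_one_threshold(self):
        p = cl.KernelParams(b=1.0, delta=1.0, eps=math.sqrt(3.0) / (2.0 * math.pi) / math.e)
        bounds = cl.support_bounds(0.0, 0.0, p)
        assert bounds.c_eps == pytest.approx(4.0)
        lo, hi = bounds.nu_interval
        assert (lo, hi) == (pytest.approx(-2.0), pytest.approx(2.0))

    def test_above_maximum_region_is_empty(self):
        p = cl.KernelParams(b=1.0, delta=1.0, eps=1.0)
        bounds = cl.support_bounds(0.0, 0.0, p)
        assert bounds.is_empty
        assert not bounds.contains(0.0, 0.0)

    @pytest.mark.parametrize("draw", range(5))
    def test_region_equals_brute_force_thresholding(self, draw):
        rng = np.random.default_rng(100 + draw)
        p = cl.KernelParams(
            b=10.0 ** rng.uniform(-2, 0),
            delta=10.0 ** rng.uniform(-1.5, 0),
            eps_rel=10.0 ** rng.uniform(-5, -1),
        )
        om, nu = rng.normal(size=2)
        bounds = cl.support_bounds(om, nu, p)
        lo, hi = bounds.nu_interval
        span = hi - lo
        nus = np.linspace(lo - 0.3 * span, hi + 0.3 * span, 41)
        oi = bounds.omega_interval(nu)
        w = oi[1] - oi[0]
        oms = np.linspace(om - p.delta * abs(nu) - 3 * w - 0.1 * span,
                          om + p.delta * abs(nu) + 3 * w + 0.1 * span, 41)
        O, N = np.meshgrid(oms, nus, indexing="ij")
        brute = cl.kernel_value(om, nu, O, N, p) >= p.epsilon
        assert np.array_equal(bounds.contains(O, N), brute)


@pytest.fixture(scope="module")
def lattice():
    """Lattice resolving the kernel: spacings well below the kernel widths.

    With b = delta = 1 the kernel has sigma_omega = sqrt(2/3) ~ 0.82 and
    sigma_nu = sqrt(2) ~ 1.41; spacings 0.125 and 0.3 resolve both, and the
    spans comfortably contain the support of the interior rows.
    """
    freqs = np.linspace(0.0, 20.0, 161)
    grid = cl.ChirpinessGrid.symmetric(9.0, 61)
    params = cl.KernelParams(b=1.0, delta=1.0)
    return freqs, grid, params, cl.build_interaction(freqs, grid, params)


class TestInteraction:
    def test_row_mass_near_one_on_ample_lattice(self, lattice):
        freqs, grid, params, K = lattice
        mass = K.row_mass()
        # interior rows: support fully inside the lattice
        inner = mass[np.ix_((freqs > 8) & (freqs < 12), np.abs(grid.nu_values) <= 2)]
        assert np.all(np.abs(inner - 1.0) < 0.02)
        assert mass.max() <= 1.0 + 0.02

    def test_stored_values_respect_the_threshold(self, lattice):
        _, _, params, K = lattice
        for mat in (K.direct, K.mirror):
            if mat.nnz:
                assert mat.data.min() / K.cell_area >= params.epsilon

    def test_row_support_centre_is_the_transport_point(self, lattice):
        freqs, grid, params, K = lattice
        i, j = 80, 40  # omega = 10, nu = 3
        om, nu = freqs[i], grid.nu_values[j]
        row = K.direct.getrow(i * grid.count + j)
        same_nu = row.indices % grid.count == j  # entries with nu' = nu
        cols = row.indices[same_nu]
        vals = row.data[same_nu]
        centre = np.sum(freqs[cols // grid.count] * vals) / vals.sum()
        df = freqs[1] - freqs[0]
        assert abs(centre - (om - params.delta * nu)) < df

    def test_apply_matches_dense_quadrature(self, lattice):
        freqs, grid, params, K = lattice
        rng = np.random.default_rng(5)
        field = np.zeros((len(freqs), grid.count), dtype=complex)
        field[60:100, 20:42] = rng.normal(size=(40, 22)) + 1j * rng.normal(size=(40, 22))
        out = K.apply(field)
        # dense oracle: untruncated midpoint sum over the whole lattice,
        # evaluated on interior rows where no band-edge folding occurs
        O, N = np.meshgrid(freqs, grid.nu_values, indexing="ij")
        rows_i = range(70, 91)
        rows_j = range(10, 51)
        bounds = cl.support_bounds(0.0, 0.0, params)
        lo, hi = bounds.nu_interval
        area = (hi - lo) * 2 * (params.delta / (2 * math.sqrt(3.0))) * math.sqrt(bounds.c_eps)
        tol = params.epsilon * area * np.max(np.abs(field)) + 1e-12
        for i in rows_i:
            for j in rows_j:
                kv = cl.kernel_value(freqs[i], grid.nu_values[j], O, N, params)
                dense = np.sum(kv * field) * K.cell_area
                assert abs(out[i, j] - dense) <= tol

    def test_zero_and_constant_fields(self, lattice):
        _, grid, _, K = lattice
        zero = np.zeros(K.shape, dtype=complex)
        assert np.all(K.apply(zero) == 0.0)
        ones = np.ones(K.shape, dtype=complex)
        np.testing.assert_allclose(K.apply(ones).real, K.row_mass(), rtol=1e-12)

    def test_shape_mismatch_rejected(self, lattice):
        _, _, _, K = lattice
        with pytest.raises(ValueError, match="shape"):
            K.apply(np.zeros((3, 3)))

    def test_overlarge_threshold_gives_empty_tables(self):
        freqs = np.linspace(0.0, 1.0, 9)
        grid = cl.ChirpinessGrid.symmetric(0.5, 5)
        params = cl.KernelParams(b=0.05, delta=0.0625, eps=1e9)
        K = cl.build_interaction(freqs, grid, params)
        assert K.direct.nnz == 0 and K.mirror.nnz == 0

    def test_hdf5_round_trip(self, tmp_path, lattice):
        from chirplift import io_hdf5

        _, _, _, K = lattice
        path = tmp_path / "K.h5"
        io_hdf5.save_interaction(path, K)
        back = io_hdf5.load_interaction(path)
        assert (back.direct != K.direct).nnz == 0
        assert (back.mirror != K.mirror).nnz == 0
        assert back.cell_area == K.cell_area


class TestSDE:
    def test_drift_only_endpoint_is_exact(self):
        p = cl.KernelParams(b=1e-15, delta=0.5)
        om, nu = cl.simulate_sde((0.2, 0.1), p, n_paths=3, n_steps=8, seed=0)
        np.testing.assert_allclose(om, 0.2 + 0.1 * 0.5, atol=1e-6)
        np.testing.assert_allclose(nu, 0.1, atol=1e-6)

    def test_endpoint_moments_match_closed_form(self):
        p = cl.KernelParams(b=0.05, delta=0.0625)
        n = 40000
        om, nu = cl.simulate_sde((0.1, -0.3), p, n_paths=n, n_steps=200, seed=11)
        mean, cov = cl.kernel_mean_cov(p, (0.1, -0.3))
        se_var = cov[1, 1] * math.sqrt(2.0 / n)
        assert abs(np.var(nu) - cov[1, 1]) < 3 * se_var
        assert abs(np.mean(om) - mean[0]) < 4 * math.sqrt(cov[0, 0] / n)
        assert abs(np.mean(nu) - mean[1]) < 4 * math.sqrt(cov[1, 1] / n)

    def test_reproducible_under_seed(self):
        p = cl.KernelParams()
        a = cl.simulate_sde((0.0, 0.0), p, 100, 10, seed=3)
        b = cl.simulate_sde((0.0, 0.0), p, 100, 10, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestFokkerPlanck:
    def test_residual_vanishes_under_refinement(self):
        res, orders = cl.fokker_planck_residual(cl.KernelParams(b=0.05, delta=0.0625))
        assert res[-1] < res[0]
        assert np.all(orders >= 0.9)
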