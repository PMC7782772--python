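import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chirplift as cl
from chirplift.wc import hermitian_defect, lowpass_reference


@pytest.fixture(scope="module")
def small_lattice():
    freqs = np.linspace(0.0, 1.0, 33)
    grid = cl.ChirpinessGrid.symmetric(0.5, 11)
    params = cl.KernelParams(b=0.05, delta=0.0625)
    return freqs, grid, cl.build_interaction(freqs, grid, params)


def _hermitian_random(rng, nf, nn):
    """Random complex field whose DC and Nyquist rows are conjugate-symmetric in nu."""
    f = rng.normal(size=(nf, nn)) + 1j * rng.normal(size=(nf, nn))
    for r in (0, nf - 1):
        f[r] = 0.5 * (f[r] + np.conj(f[r][::-1]))
    return f


class TestSigmoid:
    def test_reference_values(self):
        z = 2.0 * np.exp(1j * np.pi / 4)
        assert cl.sigmoid(z, 1.0) == pytest.approx(np.exp(1j * np.pi / 4))
        assert cl.sigmoid(0.5 + 0j, 1.0) == pytest.approx(0.5)
        assert cl.sigmoid(-3.0 + 0j, 1.0) == pytest.approx(-1.0)
        assert cl.sigmoid(0j, 1.0) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-10, 10), st.floats(-10, 10), st.floats(0.1, 3.0))
    def test_modulus_bounded_phase_preserved(self, re, im, kappa):
        z = complex(re, im)
        out = complex(cl.sigmoid(z, kappa))
        assert abs(out) <= 1.0 + 1e-12
        if z != 0:
            assert np.angle(out) == pytest.approx(np.angle(z), abs=1e-12) or abs(out) == 0

    def test_commutes_with_conjugation(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=16) + 1j * rng.normal(size=16)
        np.testing.assert_allclose(
            cl.sigmoid(np.conj(z), 0.7), np.conj(cl.sigmoid(z, 0.7)), rtol=1e-14
        )


class TestStep:
    def test_pure_decay(self):
        p = cl.WCParams(alpha=10.0, gamma=0.0, delta=0.01, dt=0.01)
        a = np.full((4, 5), 2.0 + 1.0j)
        nxt = cl.wc_step(a, np.zeros_like(a), np.zeros_like(a), p, None)
        np.testing.assert_allclose(nxt, a * (1.0 - 10.0 * 0.01), rtol=1e-14)

    def test_zero_delayed_field_kills_interaction(self, small_lattice):
        freqs, grid, K = small_lattice
        p = cl.WCParams(alpha=10.0, gamma=30.0, delta=0.015625, dt=0.015625)
        rng = np.random.default_rng(0)
        a = rng.normal(size=K.shape) + 0j
        I = rng.normal(size=K.shape) + 0j
        with_K = cl.wc_step(a, np.zeros(K.shape, complex), I, p, K)
        without = cl.wc_step(a, np.zeros(K.shape, complex), I, p, None)
        np.testing.assert_array_equal(with_K, without)

    def test_step_equals_term_by_term_sum(self, small_lattice):
        freqs, grid, K = small_lattice
        p = cl.WCParams(alpha=20.0, beta=1.5, gamma=30.0, kappa=0.6,
                        delta=0.015625, dt=0.015625)
        rng = np.random.default_rng(1)
        a = rng.normal(size=K.shape) + 1j * rng.normal(size=K.shape)
        a_del = rng.normal(size=K.shape) + 1j * rng.normal(size=K.shape)
        I = rng.normal(size=K.shape) + 0j
        out = cl.wc_step(a, a_del, I, p, K)
        # oracle: recompute the right-hand side from dense matrices
        sig = cl.sigmoid(a_del, p.kappa).ravel()
        inter = (K.direct.toarray() @ sig + K.mirror.toarray() @ np.conj(sig)).reshape(K.shape)
        expected = a + p.dt * (-p.alpha * a + p.beta * I + p.gamma * inter)
        np.testing.assert_allclose(out, expected, rtol=1e-12, atol=1e-14)

    def test_nonfinite_inputs_rejected(self):
        p = cl.WCParams(gamma=0.0, delta=0.015625, dt=0.015625)
        a = np.zeros((2, 3), complex)
        bad = a.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cl.wc_step(bad, a, a, p, None)


class TestEvolve:
    def test_zero_input_stays_zero(self, small_lattice):
        freqs, grid, K = small_lattice
        p = cl.WCParams(delta=0.0625, dt=0.015625)
        I = np.zeros((20, *K.shape), complex)
        act = cl.wc_evolve(I, p, K, grid=grid, freqs=freqs)
        assert np.all(act.values == 0.0)

    def test_causality_exact(self, small_lattice):
        freqs, grid, K = small_lattice
        p = cl.WCParams(delta=0.0625, dt=0.015625)
        rng = np.random.default_rng(4)
        I = rng.normal(size=(24, *K.shape)) + 1j * rng.normal(size=(24, *K.shape))
        full = cl.wc_evolve(I, p, K, grid=grid, freqs=freqs)
        cut = I.copy()
        cut[15:] = 0.0
        trunc = cl.wc_evolve(cut, p, K, grid=grid, freqs=freqs)
        # a at step n uses inputs up to n-1 only
        np.testing.assert_array_equal(full.values[:16], trunc.values[:16])

    def test_interaction_term_bounded_by_row_mass(self, small_lattice):
        freqs, grid, K = small_lattice
        rng = np.random.default_rng(6)
        a = 10.0 * (rng.normal(size=K.shape) + 1j * rng.normal(size=K.shape))
        term = K.apply(cl.sigmoid(a, 1.0))
        assert np.max(np.abs(term)) <= K.row_mass().max() * 1.0 + 1e-12

    def test_lowpass_limit_converges_first_order(self):
        alpha, beta = 55.0, 1.0
        errs = []
        for dt in (1 / 1600, 1 / 3200):
            n = int(round(0.5 / dt))
            t = np.arange(n) * dt
            I = (np.sin(2 * np.pi * 3 * t)[:, None, None] * np.ones((1, 3, 3))).astype(complex)
            p = cl.WCParams(alpha=alpha, beta=beta, gamma=0.0, delta=4 * dt, dt=dt)
            act = cl.wc_evolve(I, p, None, grid=cl.ChirpinessGrid.symmetric(1.0, 3))
            ref = lowpass_reference(I, alpha, beta, dt)
            errs.append(np.max(np.abs(act.values - ref)))
        assert 1.8 <= errs[0] / errs[1] <= 2.2

    def test_lowpass_impulse_response(self):
        alpha, dt = 7.0, 0.01
        I = np.zeros((50, 1, 1))
        I[0] = 1.0 / dt  # discrete Dirac
        r = lowpass_reference(I, alpha, beta=1.0, dt=dt)
        np.testing.assert_allclose(
            r[:, 0, 0], np.exp(-alpha * np.arange(50) * dt), rtol=1e-12
        )

    def test_hermitian_consistency_preserved_at_every_step(self, small_lattice):
        freqs, grid, K = small_lattice
        p = cl.WCParams(alpha=20.0, gamma=30.0, kappa=0.6, delta=0.0625, dt=0.015625)
        rng = np.random.default_rng(8)
        I = np.stack([_hermitian_random(rng, *K.shape) for _ in range(16)])
        act = cl.wc_evolve(I, p, K, grid=grid, freqs=freqs)
        scale = np.max(np.abs(act.values))
        for n in range(act.values.shape[0]):
            assert hermitian_defect(act.values[n]) <= 1e-13 * max(scale, 1.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="stability"):
            cl.WCParams(alpha=100.0, dt=0.015625, delta=0.0625)
        with pytest.raises(ValueError, match="whole number"):
            cl.WCParams(delta=0.0625, dt=0.016)
        snapped = cl.WCParams(delta=0.0625, dt=0.015625).snapped(0.016)
        assert snapped.delay_steps == 4 and snapped.delta == pytest.approx(0.064)
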