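"""Delayed Wilson-Cowan evolution on the lifted image.

The complex activation a(t, omega, nu) on the frequency-chirpiness lattice
obeys

    d_t a = -alpha a + beta I
            + gamma * Integral k_delta(omega, nu || omega', nu')
                               sigma(a(t - delta, omega', nu')) d omega' d nu'

with a == 0 for t <= 0: exponential decay towards the driving input, plus a
delayed interaction in which every neuron excites the neurons its diffusion
reaches after one delay.  The saturation sigma acts on the modulus only and
preserves the phase, which (together with the kernel's mirror symmetry) keeps
the evolution of a Hermitian-consistent input Hermitian-consistent, so the
reconstructed waveform stays real.

Time stepping is forward Euler with the delay an exact whole number of
steps; with dt equal to the STFT hop, each step consumes one spectrogram
frame.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np

from .kernel import SparseInteraction
from .lift import ChirpinessGrid, LiftedImage

__all__ = [
    "WCParams",
    "ActivationField",
    "sigmoid",
    "wc_step",
    "wc_evolve",
    "lowpass_reference",
    "hermitian_defect",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class WCParams:
    """Parameters of the delayed Wilson-Cowan equation.

    alpha: decay rate [1/s]; beta: input gain; gamma: interaction gain;
    kappa: sigmoid slope; delta: delay [s]; dt: Euler step [s].  The delay
    must be a whole number of steps and alpha*dt < 1 for stability of the
    explicit linear part.

    The default kappa keeps the delayed recurrent loop subcritical: with
    interaction rows of quadrature mass ~1 the linearised gain of the
    feedback is kappa * gamma / alpha, and the canonical parameter sets use
    gamma slightly above alpha, so kappa >= alpha/gamma would make the zero
    state unstable and the field self-sustaining independently of the
    input.  kappa = 0.6 leaves the interaction a leading-order term while
    activity remains input-driven.
    """

    alpha: float = 55.0
    beta: float = 1.0
    gamma: float = 55.0
    kappa: float = 0.6
    delta: float = 0.0625
    dt: float = 0.015625

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.kappa, self.delta, self.dt) <= 0:
            raise ValueError("alpha, beta, kappa, delta, dt must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.alpha * self.dt >= 1.0:
            raise ValueError(
                f"alpha*dt = {self.alpha * self.dt:g} >= 1 breaks explicit-Euler "
                "stability of the decay term"
            )
        ratio = self.delta / self.dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"delay delta = {self.delta} s must be a positive whole number of "
                f"steps dt = {self.dt} s (got {ratio:g}); snap it first"
            )

    @property
    def delay_steps(self) -> int:
        return int(round(self.delta / self.dt))

    def snapped(self, dt: float) -> "WCParams":
        """Copy with step ``dt`` and the delay snapped to a whole number of steps."""
        steps = max(1, int(round(self.delta / dt)))
        delta = steps * dt
        if abs(delta - self.delta) > 1e-12:
            logger.warning(
                "delay %.6g s is not a multiple of dt=%.6g s; snapped to %.6g s "
                "(%d steps)",
                self.delta,
                dt,
                delta,
                steps,
            )
        return dataclasses.replace(self, dt=dt, delta=delta)


@dataclasses.dataclass(frozen=True)
class ActivationField:
    """Trajectory a(t, omega, nu) of the Wilson-Cowan state.

    ``values[n]`` is the activation at time step n (t = n*dt counted from
    the first input frame); the zero history for t <= 0 holds by
    construction.
    """

    values: np.ndarray  # complex, (n_steps, n_freq, n_nu)
    times: np.ndarray
    freqs: np.ndarray
    grid: ChirpinessGrid
    params: WCParams


def sigmoid(z: np.ndarray, kappa: float = 1.0) -> np.ndarray:
    """Modulus-saturating sigmoid, sigma(rho e^{i theta}) = min(1, kappa rho) e^{i theta}.

    The phase is untouched (and sigma(0) = 0), so sigma commutes with
    complex conjugation.
    """
    z = np.asarray(z, dtype=complex)
    rho = np.abs(z)
    factor = np.ones_like(rho)
    np.divide(np.minimum(1.0, kappa * rho), rho, out=factor, where=rho > 0)
    factor[rho == 0] = 0.0
    return z * factor


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr.view(float) if np.iscomplexobj(arr) else arr)):
        raise ValueError(f"{name} contains NaN or Inf")


def wc_step(
    a_now: np.ndarray,
    a_delayed: np.ndarray,
    I_now: np.ndarray,
    params: WCParams,
    K: Optional[SparseInteraction],
) -> np.ndarray:
    """One forward-Euler step of the delayed Wilson-Cowan equation."""
    for name, arr in (("a_now", a_now), ("a_delayed", a_delayed), ("I_now", I_now)):
        _check_finite(name, np.asarray(arr))
    rhs = -params.alpha * a_now + params.beta * I_now
    if params.gamma != 0.0 and K is not None:
        rhs = rhs + params.gamma * K.apply(sigmoid(a_delayed, params.kappa))
    return a_now + params.dt * rhs


def wc_evolve(
    I: "LiftedImage | np.ndarray",
    params: WCParams,
    K: Optional[SparseInteraction],
    extra_steps: int = 0,
    times: Optional[np.ndarray] = None,
    freqs: Optional[np.ndarray] = None,
    grid: Optional[ChirpinessGrid] = None,
) -> ActivationField:
    """Integrate the evolution through the input frames (plus a zero-input tail).

    ``I`` provides one input slice per Euler step; after the last frame the
    input is zero for ``extra_steps`` more steps (free rundown).  The result
    is causal -- a at step n depends only on input frames < n and on a up to
    n - delay_steps -- and fully deterministic.
    """
    if isinstance(I, LiftedImage):
        frames = I.values
        times = I.times
        freqs = I.freqs
        grid = I.grid
    else:
        frames = np.asarray(I)
        if grid is None:
            grid = ChirpinessGrid.symmetric(1.0, frames.shape[-1] if frames.shape[-1] % 2 else 3)
    _check_finite("input", frames)
    n_in, nf, nn = frames.shape
    n_steps = n_in + extra_steps
    d = params.delay_steps
    a = np.zeros((n_steps, nf, nn), dtype=complex)
    zero = np.zeros((nf, nn), dtype=complex)
    for n in range(n_steps - 1):
        a_delayed = a[n - d] if n - d >= 0 else zero
        I_now = frames[n] if n < n_in else zero
        a[n + 1] = wc_step(a[n], a_delayed, I_now, params, K)
    if times is None:
        t = np.arange(n_steps) * params.dt
    else:
        t0 = float(times[0])
        t = t0 + np.arange(n_steps) * params.dt
    return ActivationField(values=a, times=t, freqs=freqs, grid=grid, params=params)


def lowpass_reference(
    I: np.ndarray, alpha: float, beta: float, dt: float
) -> np.ndarray:
    """Causal discrete convolution of beta*I with the filter e^{-alpha t}.

    Quadrature of the gamma = 0 solution a(t) = Integral_0^t
    e^{-alpha (t - s)} beta I(s) ds with I held piecewise constant:
    r[n] = dt * sum_{m <= n} e^{-alpha (n - m) dt} beta I[m], evaluated by
    the exact recursion r[n] = e^{-alpha dt} r[n-1] + beta dt I[n].  A unit
    Dirac impulse at t = 0 is represented by I[0] = 1/dt and yields the
    sampled filter e^{-alpha n dt}.
    """
    I = np.asarray(I)
    out = np.zeros(I.shape, dtype=I.dtype if np.iscomplexobj(I) else float)
    decay = np.exp(-alpha * dt)
    acc = np.zeros(I.shape[1:], dtype=out.dtype)
    for n in range(I.shape[0]):
        acc = decay * acc + beta * dt * I[n]
        out[n] = acc
    return out


def hermitian_defect(field: np.ndarray) -> float:
    """Deviation of the DC and Nyquist rows from Hermitian consistency.

    On the stored half-lattice the full-plane symmetry a(t, -omega, -nu) =
    conj(a(t, omega, nu)) only constrains the omega = 0 and Nyquist rows:
    a(t, 0, nu) must equal conj(a(t, 0, -nu)) (and likewise at Nyquist).
    Returns the sup-norm of the defect over those rows.
    """
    field = np.asarray(field)
    dc = field[..., 0, :]
    ny = field[..., -1, :]
    defect = 0.0
    for row in (dc, ny):
        defect = max(defect, float(np.max(np.abs(row - np.conj(row[..., ::-1])))))
    return defect
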