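"""Neuronal interaction kernel: the Kolmogorov transition density.

Neural excitation in the frequency-chirpiness plane is modelled by the
degenerate diffusion

    d(omega) = nu dt,      d(nu) = sqrt(2 b) dW,

whose generator is L = nu d_omega + b d_nu^2: frequency is transported at
the current chirpiness while chirpiness itself diffuses with strength b.
The influence of neuron (omega', nu') on neuron (omega, nu) after a delay
delta is the transition density of this process, which is known in closed
form:

    k_delta(omega, nu || omega', nu')
        = sqrt(3) / (2 pi b delta^2) * exp(-g_delta / (b delta^3)),

    g_delta = 3 (omega - omega')^2
              - 3 delta (omega - omega') (nu + nu')
              + delta^2 (nu^2 + nu nu' + nu'^2).

k_delta is a probability density in (omega, nu) (and, by symmetry of
g_delta, in (omega', nu')), Gaussian with mean (omega' + delta nu', nu')
and covariance [[2 b delta^3 / 3, b delta^2], [b delta^2, 2 b delta]].
It is *not* a convolution kernel in (omega, nu).

Since k decays as a Gaussian, the set K^eps(omega, nu) where k >= eps is a
compact region described by two explicit inequalities; tabulating kernel
values only there yields one small sparse row per lattice neuron.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .lift import ChirpinessGrid

__all__ = [
    "KernelParams",
    "AxisScaling",
    "SupportBounds",
    "g_delta",
    "kernel_value",
    "kernel_max",
    "kernel_mean_cov",
    "support_bounds",
    "SparseInteraction",
    "build_interaction",
    "apply_interaction",
    "simulate_sde",
    "fokker_planck_residual",
]

logger = logging.getLogger(__name__)

_SQRT3 = math.sqrt(3.0)


@dataclasses.dataclass(frozen=True)
class KernelParams:
    """Diffusion strength ``b``, delay ``delta`` [s] and truncation ``eps``.

    ``b`` has units chirpiness^2 / s in whatever (possibly rescaled) axis
    units the kernel is evaluated in.  The truncation threshold is usually
    given relative to the kernel maximum via ``eps_rel`` (default 1e-4,
    keeping row masses >= 0.999); an absolute ``eps`` overrides it.
    """

    b: float = 0.05
    delta: float = 0.0625
    eps_rel: float = 1e-4
    eps: Optional[float] = None

    def __post_init__(self) -> None:
        if self.b <= 0 or self.delta <= 0:
            raise ValueError("b and delta must be positive")
        if self.epsilon < 0:
            raise ValueError("truncation threshold must be non-negative")
        if self.epsilon > self.max_value:
            logger.warning(
                "truncation eps=%g exceeds the kernel maximum %g: all support "
                "sets will be empty",
                self.epsilon,
                self.max_value,
            )

    @property
    def max_value(self) -> float:
        """sup of k_delta, attained on the degenerate set g_delta = 0."""
        return _SQRT3 / (2.0 * math.pi * self.b * self.delta**2)

    @property
    def epsilon(self) -> float:
        return self.eps if self.eps is not None else self.eps_rel * self.max_value


@dataclasses.dataclass(frozen=True)
class AxisScaling:
    """Common rescaling of the frequency and chirpiness axes.

    Frequencies [Hz] and chirpinesses [Hz/s] are divided by the same factor
    ``scale`` (time stays in seconds) before kernel evaluation, so the
    kinematic relation nu = d(omega)/dt survives the change of units and
    the kernel drift transports mass along a chirp ridge at exactly the
    ridge's own rate.  With ``scale`` equal to the Nyquist frequency the
    frequency axis maps to [0, 1] and O(0.01-0.2) diffusion strengths are
    meaningful.
    """

    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def g_delta(omega, nu, omega_p, nu_p, delta: float):
    """Quadratic exponent of the transition density (positive semi-definite).

    Vanishes exactly on the transport line nu' = nu, omega' = omega -
    delta * nu, and factors as 3*(x - delta*(nu+nu')/2)**2 +
    (delta**2/4)*(nu-nu')**2 with x = omega - omega'.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    x = np.asarray(omega) - np.asarray(omega_p)
    nu = np.asarray(nu)
    nu_p = np.asarray(nu_p)
    return (
        3.0 * x**2
        - 3.0 * delta * x * (nu + nu_p)
        + delta**2 * (nu**2 + nu * nu_p + nu_p**2)
    )


def kernel_value(omega, nu, omega_p, nu_p, params: KernelParams):
    """Closed-form transition density k_delta(omega, nu || omega', nu')."""
    b, d = params.b, params.delta
    g = g_delta(omega, nu, omega_p, nu_p, d)
    return params.max_value * np.exp(-g / (b * d**3))


def kernel_max(params: KernelParams) -> float:
    return params.max_value


def kernel_mean_cov(
    params: KernelParams, start: Tuple[float, float]
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the Gaussian (omega, nu) law after ``delta``."""
    b, d = params.b, params.delta
    omega_p, nu_p = start
    mean = np.array([omega_p + d * nu_p, nu_p])
    cov = np.array([[2.0 * b * d**3 / 3.0, b * d**2], [b * d**2, 2.0 * b * d]])
    return mean, cov


@dataclasses.dataclass(frozen=True)
class SupportBounds:
    """The compact region K^eps(omega, nu) = {k_delta >= eps}.

    Membership:  |nu - nu'|^2 <= C_eps  and
    |omega' - omega + delta (nu + nu') / 2| <= delta / (2 sqrt 3) *
    sqrt(C_eps - |nu - nu'|^2).  ``c_eps < 0`` encodes the empty region
    (eps above the kernel maximum).
    """

    omega: float
    nu: float
    params: KernelParams
    c_eps: float

    @property
    def is_empty(self) -> bool:
        return self.c_eps < 0.0

    @property
    def nu_interval(self) -> Optional[Tuple[float, float]]:
        if self.is_empty:
            return None
        r = math.sqrt(self.c_eps)
        return (self.nu - r, self.nu + r)

    def omega_interval(self, nu_p: float) -> Optional[Tuple[float, float]]:
        """omega' interval at fixed nu', or None outside the nu band."""
        if self.is_empty:
            return None
        rem = self.c_eps - (self.nu - nu_p) ** 2
        if rem < 0:
            return None
        d = self.params.delta
        center = self.omega - d * (self.nu + nu_p) / 2.0
        half = d / (2.0 * _SQRT3) * math.sqrt(rem)
        return (center - half, center + half)

    def contains(self, omega_p, nu_p) -> np.ndarray:
        """Vectorised membership test for points (omega', nu')."""
        omega_p = np.asarray(omega_p, dtype=float)
        nu_p = np.asarray(nu_p, dtype=float)
        if self.is_empty:
            return np.zeros(np.broadcast(omega_p, nu_p).shape, dtype=bool)
        d = self.params.delta
        dn2 = (self.nu - nu_p) ** 2
        in_band = dn2 <= self.c_eps
        rem = np.where(in_band, self.c_eps - dn2, 0.0)
        half = d / (2.0 * _SQRT3) * np.sqrt(rem)
        center = self.omega - d * (self.nu + nu_p) / 2.0
        return in_band & (np.abs(omega_p - center) <= half)


def support_bounds(omega: float, nu: float, params: KernelParams) -> SupportBounds:
    """Explicit bounds of the eps-superlevel set of k_delta at (omega, nu).

    With eps equal to the kernel maximum the region degenerates to the
    single transport point (omega - delta nu, nu); for larger eps it is
    empty (returned as such, not an error).
    """
    b, d = params.b, params.delta
    eps = params.epsilon
    if eps <= 0.0:
        raise ValueError("support bounds require eps > 0")
    # C = -4 b delta log(2 pi b delta^2 eps / sqrt 3); the argument of the
    # log is eps / max k, so eps equal to the maximum gives exactly 0
    c = -4.0 * b * d * math.log(eps / params.max_value)
    return SupportBounds(omega=float(omega), nu=float(nu), params=params, c_eps=c)


@dataclasses.dataclass(frozen=True)
class SparseInteraction:
    """Truncated kernel tables over a frequency x chirpiness lattice.

    Rows are lattice neurons (omega, nu); entries are kernel values times
    the (scaled) cell area, so applying the operator approximates the
    interaction integral by a midpoint sum.  The lattice only covers
    omega >= 0: support points with omega' < 0 are folded onto the stored
    half-lattice through the mirror symmetry of real signals, and support
    points beyond the Nyquist row through the equivalent symmetry of the
    sampled spectrum about Nyquist; both folds negate nu' and apply to the
    complex conjugate of the field (``mirror`` matrix), which keeps the
    evolution exactly Hermitian-consistent at the DC and Nyquist rows and
    hence the reconstructed waveform real.
    """

    direct: sp.csr_matrix
    mirror: sp.csr_matrix
    freqs: np.ndarray
    grid: ChirpinessGrid
    params: KernelParams
    scaling: AxisScaling
    cell_area: float  # scaled units

    @property
    def shape(self) -> Tuple[int, int]:
        return (len(self.freqs), self.grid.count)

    def row_mass(self) -> np.ndarray:
        """Quadrature mass of each row, shape (n_freq, n_nu); <= ~1."""
        m = np.asarray(self.direct.sum(axis=1)).ravel() + np.asarray(
            self.mirror.sum(axis=1)
        ).ravel()
        return m.reshape(self.shape)

    def apply(self, field: np.ndarray) -> np.ndarray:
        """Approximate the interaction integral of ``field`` (complex, on G)."""
        field = np.asarray(field)
        if field.shape != self.shape:
            raise ValueError(f"field shape {field.shape}, lattice is {self.shape}")
        flat = field.ravel()
        out = self.direct @ flat + self.mirror @ np.conj(flat)
        return out.reshape(self.shape)


def apply_interaction(K: SparseInteraction, field: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`SparseInteraction.apply`."""
    return K.apply(field)


def build_interaction(
    freqs: np.ndarray,
    grid: ChirpinessGrid,
    params: KernelParams,
    scaling: Optional[AxisScaling] = None,
) -> SparseInteraction:
    """Tabulate the truncated kernel on the lattice ``freqs x grid``.

    For fixed (nu, nu') the kernel depends on omega - omega' only, so each
    (nu, nu') pair contributes a band of constant diagonals (Toeplitz
    blocks); candidate frequency offsets come from the closed-form support
    bounds and are then filtered exactly by k >= eps.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0 or grid.count == 0:
        raise ValueError("empty lattice")
    if freqs.size > 1:
        dfs = np.diff(freqs)
        if not np.allclose(dfs, dfs[0]):
            raise ValueError("frequency lattice must be uniform")
    scaling = scaling or AxisScaling(1.0)
    b, d = params.b, params.delta
    eps = params.epsilon
    f = freqs / scaling.scale
    nu = grid.nu_values / scaling.scale
    nf, nn = f.size, nu.size
    df = float(f[1] - f[0]) if nf > 1 else 1.0
    dnu = float(nu[1] - nu[0]) if nn > 1 else 1.0
    cell = df * dnu
    pref = params.max_value
    c_eps = -4.0 * b * d * math.log(eps / pref)

    rows_d, cols_d, vals_d = [], [], []
    rows_m, cols_m, vals_m = [], [], []
    if c_eps < 0.0:
        logger.warning("eps=%g above kernel max %g: interaction tables are empty", eps, pref)
    else:
        slack = 1e-9
        for j in range(nn):
            for jp in range(nn):
                dn2 = (nu[j] - nu[jp]) ** 2
                if dn2 > c_eps * (1.0 + 1e-12):
                    continue
                half = d / (2.0 * _SQRT3) * math.sqrt(max(c_eps - dn2, 0.0))
                center = d * (nu[j] + nu[jp]) / 2.0  # x = omega - omega' band centre
                o_lo = math.ceil((center - half) / df - slack)
                o_hi = math.floor((center + half) / df + slack)
                if o_hi < o_lo:
                    continue
                offs = np.arange(o_lo, o_hi + 1)
                x = offs * df
                g = (
                    3.0 * x**2
                    - 3.0 * d * x * (nu[j] + nu[jp])
                    + d**2 * (nu[j] ** 2 + nu[j] * nu[jp] + nu[jp] ** 2)
                )
                kv = pref * np.exp(-g / (b * d**3))
                keep = kv >= eps
                for o, v in zip(offs[keep], kv[keep] * cell):
                    # direct part: columns i' = i - o on the stored half-lattice
                    i_lo, i_hi = max(0, o), min(nf - 1, nf - 1 + o)
                    if i_hi >= i_lo:
                        i = np.arange(i_lo, i_hi + 1)
                        rows_d.append(i * nn + j)
                        cols_d.append((i - o) * nn + jp)
                        vals_d.append(np.full(i.size, v))
                    # mirror part: i' < 0 folds to (-i', -nu') with conjugation
                    if o >= 1:
                        i = np.arange(max(0, o - (nf - 1)), min(o - 1, nf - 1) + 1)
                        if i.size:
                            rows_m.append(i * nn + j)
                            cols_m.append((o - i) * nn + (nn - 1 - jp))
                            vals_m.append(np.full(i.size, v))
                    # i' > nf-1 folds across Nyquist to (2(nf-1) - i', -nu')
                    if o <= -1:
                        i = np.arange(max(0, nf + o), min(nf - 1, 2 * (nf - 1) + o) + 1)
                        if i.size:
                            rows_m.append(i * nn + j)
                            cols_m.append((2 * (nf - 1) - i + o) * nn + (nn - 1 - jp))
                            vals_m.append(np.full(i.size, v))

    n = nf * nn

    def _assemble(rows, cols, vals):
        if not rows:
            return sp.csr_matrix((n, n))
        return sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )

    return SparseInteraction(
        direct=_assemble(rows_d, cols_d, vals_d),
        mirror=_assemble(rows_m, cols_m, vals_m),
        freqs=freqs,
        grid=grid,
        params=params,
        scaling=scaling,
        cell_area=cell,
    )


def simulate_sde(
    start: Tuple[float, float],
    params: KernelParams,
    n_paths: int,
    n_steps: int,
    seed: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama endpoints at time ``delta`` of the kernel's diffusion.

    Integrates d(omega) = nu dt, d(nu) = sqrt(2 b) dW from ``start``; the
    endpoint sample is distributed (up to O(1/n_steps) discretisation in
    the omega marginal) according to ``kernel_value(.,.||start)``.
    Returns ``(omega, nu)`` arrays of length ``n_paths``.
    """
    if n_paths < 1 or n_steps < 1:
        raise ValueError("n_paths and n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    dt = params.delta / n_steps
    amp = math.sqrt(2.0 * params.b * dt)
    omega = np.full(n_paths, float(start[0]))
    nu = np.full(n_paths, float(start[1]))
    for _ in range(n_steps):
        omega += nu * dt
        nu += amp * rng.standard_normal(n_paths)
    return omega, nu


def fokker_planck_residual(
    params: KernelParams,
    levels: int = 3,
    n_base: int = 24,
    half_width_sigmas: float = 3.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Finite-difference residual of d_t k = (-nu d_omega + b d_nu^2) k.

    Evaluates the closed form at t = delta on grids refined dyadically
    (all steps, including the one for d_t, halve together) and returns
    ``(residuals, observed_orders)`` where residuals are relative sup-norms
    against the transport+diffusion term.  Central differences are used
    throughout, so the observed order approaches 2.
    """
    b, d = params.b, params.delta
    sig_o = math.sqrt(2.0 * b * d**3 / 3.0)
    sig_n = math.sqrt(2.0 * b * d)

    def k_at(t, om, nu):
        p = KernelParams(b=b, delta=t, eps_rel=params.eps_rel)
        return kernel_value(om[:, None], nu[None, :], 0.0, 0.0, p)

    res = []
    for lvl in range(levels):
        n = n_base * 2**lvl + 1
        om = np.linspace(-half_width_sigmas * sig_o, half_width_sigmas * sig_o, n)
        nu = np.linspace(-half_width_sigmas * sig_n, half_width_sigmas * sig_n, n)
        h_o = om[1] - om[0]
        h_n = nu[1] - nu[0]
        h_t = 0.02 * d / 2**lvl
        k0 = k_at(d, om, nu)
        dt_k = (k_at(d + h_t, om, nu) - k_at(d - h_t, om, nu)) / (2.0 * h_t)
        d_om = (k0[2:, 1:-1] - k0[:-2, 1:-1]) / (2.0 * h_o)
        d_nn = (k0[1:-1, 2:] - 2.0 * k0[1:-1, 1:-1] + k0[1:-1, :-2]) / h_n**2
        rhs = -nu[None, 1:-1] * d_om + b * d_nn
        r = dt_k[1:-1, 1:-1] - rhs
        res.append(float(np.max(np.abs(r)) / np.max(np.abs(rhs))))
    res = np.asarray(res)
    orders = np.log2(res[:-1] / res[1:])
    return res, orders
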