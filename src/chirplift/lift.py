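"""Lift of a time-frequency image to the time-frequency-chirpiness space.

Each point (tau, omega) of the spectrogram is assigned the chirpiness
nu* = -d_tau|S| / d_omega|S|, the slope for which the level line of |S|
through the point is stationary (nu * d_omega|S| + d_tau|S| = 0).  The
complex value S(tau, omega) is then deposited in the nearest bin of a
bounded, symmetric chirpiness grid N = [-nu_max, nu_max]; points whose
level line is vertical (d_omega|S| ~ 0, nu* -> +-inf) or whose nu* falls
outside N carry no lifted mass.  Summing the lifted image back over nu
(projection) recovers S exactly on the points that were kept.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np

from .tfr import STFTConfig, TFImage

__all__ = [
    "ChirpinessGrid",
    "LiftedImage",
    "spectrogram_gradient",
    "chirpiness_field",
    "auto_nu_max",
    "lift",
    "project",
]


@dataclasses.dataclass(frozen=True)
class ChirpinessGrid:
    """Uniform chirpiness samples on [-nu_max, nu_max], symmetric about 0.

    The count is odd so nu = 0 is a grid point and the grid is exactly
    closed under negation (nu_values[::-1] == -nu_values bit for bit).
    """

    nu_values: np.ndarray  # Hz/s

    @classmethod
    def symmetric(cls, nu_max: float, count: int = 41) -> "ChirpinessGrid":
        if count < 3 or count % 2 == 0:
            raise ValueError(f"count must be an odd integer >= 3, got {count}")
        if nu_max <= 0:
            raise ValueError("nu_max must be positive")
        half = np.linspace(0.0, float(nu_max), (count + 1) // 2)
        nu = np.concatenate([-half[:0:-1], half])
        return cls(nu)

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu_values, dtype=np.float64)
        object.__setattr__(self, "nu_values", nu)
        if nu.size == 0:
            raise ValueError("empty chirpiness grid")
        if nu.size > 1:
            d = np.diff(nu)
            if not np.allclose(d, d[0]) or d[0] <= 0:
                raise ValueError("chirpiness grid must be uniformly increasing")
            if not np.array_equal(nu[::-1], -nu):
                raise ValueError("chirpiness grid must be symmetric about 0")

    @property
    def count(self) -> int:
        return self.nu_values.size

    @property
    def spacing(self) -> float:
        return float(self.nu_values[1] - self.nu_values[0]) if self.count > 1 else 0.0

    @property
    def nu_max(self) -> float:
        return float(self.nu_values[-1])


@dataclasses.dataclass(frozen=True)
class LiftedImage:
    """Complex field I(tau, omega, nu) on the augmented grid.

    For each (tau, omega) at most one nu bin is nonzero (single-valued
    lift); ``dropped_fraction`` records the share of |S| magnitude that was
    discarded because its chirpiness was undefined or outside the grid.
    """

    values: np.ndarray  # complex, (n_frames, n_bins, n_nu)
    times: np.ndarray
    freqs: np.ndarray
    grid: ChirpinessGrid
    config: STFTConfig
    rate: float
    n_samples: int
    dropped_fraction: float = 0.0

    def __post_init__(self) -> None:
        v = self.values
        expected = (len(self.times), len(self.freqs), self.grid.count)
        if v.shape != expected:
            raise ValueError(f"values shape {v.shape}, expected {expected}")

    def nu_mass(self) -> np.ndarray:
        """Magnitude mass per chirpiness bin, summed over time and frequency."""
        return np.abs(self.values).sum(axis=(0, 1))


def spectrogram_gradient(
    image: TFImage | np.ndarray,
    times: Optional[np.ndarray] = None,
    freqs: Optional[np.ndarray] = None,
    even_omega: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """Finite-difference gradient (d_tau|S|, d_omega|S|) of the magnitude.

    Central differences on interior points, one-sided at the borders.  With
    ``even_omega=True`` the frequency axis is treated as the non-negative
    half of an even function (the magnitude of a real signal's spectrum),
    so the frequency derivative at the first and last bins is computed on
    the mirror extension and comes out exactly 0.  Units: per second and
    per Hz.
    """
    if isinstance(image, TFImage):
        mag, times, freqs = image.magnitude, image.times, image.freqs
    else:
        mag = np.abs(np.asarray(image))
        if times is None or freqs is None:
            raise ValueError("times and freqs are required for a bare array")
    if mag.shape[0] < 3 or mag.shape[1] < 3:
        raise ValueError(f"grid {mag.shape} too small for gradients (need >= 3x3)")
    dt = float(times[1] - times[0])
    df = float(freqs[1] - freqs[0])
    d_tau = np.gradient(mag, dt, axis=0)
    if even_omega:
        padded = np.pad(mag, ((0, 0), (1, 1)), mode="reflect")
        d_omega = np.gradient(padded, df, axis=1)[:, 1:-1]
    else:
        d_omega = np.gradient(mag, df, axis=1)
    return d_tau, d_omega


def chirpiness_field(
    d_tau: np.ndarray,
    d_omega: np.ndarray,
    tol_grad: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Level-line chirpiness nu* = -d_tau|S| / d_omega|S| with a defined-mask.

    Where |d_omega|S|| <= tol_grad the level line is (numerically) vertical
    and nu* diverges; those points are masked rather than clamped.
    ``tol_grad`` defaults to 1e-3 times the sup-norm of the frequency
    component d_omega|S| (the two components carry different units, so only
    the frequency one sets the verticality scale).

    Returns ``(nu_star, defined)``; ``nu_star`` is 0 where undefined.
    """
    if d_tau.shape != d_omega.shape:
        raise ValueError("gradient components must share a grid")
    if tol_grad is None:
        tol_grad = 1e-3 * float(np.max(np.abs(d_omega)))
    defined = np.abs(d_omega) > tol_grad
    nu_star = np.zeros_like(d_tau)
    np.divide(-d_tau, d_omega, out=nu_star, where=defined)
    return nu_star, defined


def auto_nu_max(
    image: TFImage,
    tol_grad: Optional[float] = None,
    mass_fraction: float = 0.01,
    percentile: float = 99.0,
    margin: float = 1.5,
    min_bins: int = 200,
) -> float:
    """Data-driven bound for the admissible chirpiness interval.

    Takes the smallest set of highest-magnitude bins holding ``mass_fraction``
    of the total |S| mass (the ridge neighbourhood), computes the
    ``percentile``-th percentile of |nu*| over the defined ones, and widens
    it by ``margin`` so the interval also contains the diffusion
    neighbourhood of the extreme slopes rather than cutting them at the
    boundary bin.  At least ``min_bins`` bins enter the percentile (capped
    at the number of defined bins): on a strongly peaked spectrogram the
    mass rule alone selects a handful of near-crest bins whose 0/0
    chirpiness ratio is unreliable.
    """
    d_tau, d_omega = spectrogram_gradient(image, even_omega=True)
    nu_star, defined = chirpiness_field(d_tau, d_omega, tol_grad)
    mag = image.magnitude.ravel()
    def_idx = np.nonzero(defined.ravel())[0]
    if def_idx.size == 0:
        raise ValueError("no defined chirpiness anywhere on the image")
    # rank the defined bins (crest centres themselves are 0/0 points and carry
    # no chirpiness) by magnitude and keep those holding the top mass share
    order = def_idx[np.argsort(mag[def_idx])[::-1]]
    cum = np.cumsum(mag[order])
    k = int(np.searchsorted(cum, mass_fraction * cum[-1])) + 1
    k = min(max(k, min_bins), order.size)
    sel = order[:k]
    nu = float(np.percentile(np.abs(nu_star.ravel()[sel]), percentile))
    if nu <= 0:
        raise ValueError("degenerate chirpiness range (stationary spectrogram)")
    return margin * nu


def lift(
    image: TFImage,
    grid: ChirpinessGrid,
    tol_grad: Optional[float] = None,
) -> LiftedImage:
    """Lift ``image`` to the augmented grid by nearest-bin assignment.

    Each (tau, omega) with a defined chirpiness inside [-nu_max, nu_max]
    contributes its full complex value S(tau, omega) to the nearest nu bin;
    all other points are dropped.  The frequency gradient is computed on
    the even extension across the DC and Nyquist rows, so those rows (where
    the true derivative of the two-sided magnitude vanishes) are masked and
    the lifted field is exactly consistent with Hermitian mirror symmetry.
    """
    d_tau, d_omega = spectrogram_gradient(image, even_omega=True)
    nu_star, defined = chirpiness_field(d_tau, d_omega, tol_grad)
    nu0 = grid.nu_values[0]
    inside = defined & (nu_star >= nu0) & (nu_star <= grid.nu_values[-1])
    if grid.count > 1:
        idx = np.rint((nu_star - nu0) / grid.spacing).astype(np.intp)
    else:
        idx = np.zeros_like(nu_star, dtype=np.intp)
    nt, nf = image.values.shape
    out = np.zeros((nt, nf, grid.count), dtype=complex)
    it, iw = np.nonzero(inside)
    out[it, iw, idx[inside]] = image.values[it, iw]
    total = float(np.abs(image.values).sum())
    kept = float(np.abs(image.values[inside]).sum())
    dropped = 0.0 if total == 0.0 else 1.0 - kept / total
    return LiftedImage(
        values=out,
        times=image.times,
        freqs=image.freqs,
        grid=grid,
        config=image.config,
        rate=image.rate,
        n_samples=image.n_samples,
        dropped_fraction=dropped,
    )


def project(field: "LiftedImage | np.ndarray") -> "TFImage | np.ndarray":
    """Integrate over the chirpiness axis (plain sum over nu bins).

    Linear; the inverse of :func:`lift` on the points that were not
    dropped.  Accepts a :class:`LiftedImage` (returns a :class:`TFImage`)
    or a bare array whose last axis is nu (returns an array).
    """
    if isinstance(field, LiftedImage):
        return TFImage(
            values=field.values.sum(axis=2),
            times=field.times,
            freqs=field.freqs,
            config=field.config,
            rate=field.rate,
            n_samples=field.n_samples,
        )
    return np.asarray(field).sum(axis=-1)
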