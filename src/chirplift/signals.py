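"""Synthetic chirp signals and WAV input/output.

Every experiment in this package runs on sounds with a single (or a pair of)
time-varying dominant frequencies, s(t) = A sin(phi(t)) with instantaneous
frequency f(t) = phi'(t) / 2*pi.  Four families are provided:

``linear``
    f(t) = f0 + slope * t, a linear chirp.
``interrupted``
    the same linear chirp with its samples zeroed on a gap interval,
    producing two disjoint ridge segments in the spectrogram.
``crossing``
    the pointwise sum of two linear chirps whose ridges intersect.
``sine_fm``
    sinusoidal frequency modulation, f(t) = carrier + depth * sin(m * t).
"""
from __future__ import annotations

import dataclasses
import math
import os
from typing import Optional

import numpy as np
from scipy.io import wavfile

__all__ = [
    "SoundSignal",
    "ChirpSpec",
    "make_chirp",
    "instantaneous_frequency",
    "read_wav",
    "write_wav",
]


@dataclasses.dataclass(frozen=True)
class SoundSignal:
    """A uniformly sampled real-valued waveform.

    Parameters
    ----------
    samples
        Dimensionless amplitude values (float64).
    rate
        Sampling rate in samples per second (Hz), > 0.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate

    def energy(self) -> float:
        return float(np.sum(self.samples**2))


@dataclasses.dataclass(frozen=True)
class ChirpSpec:
    """Parameters of a synthetic chirp.

    Only the fields relevant to ``kind`` are read; the defaults place all
    ridges well inside the Nyquist band of an 8 kHz signal and make them span
    many analysis windows.

    Fields (units): ``f0`` start frequency [Hz] and ``slope`` [Hz/s] for the
    linear kinds; ``gap_start``/``gap_len`` [s] for ``interrupted``;
    ``f1``/``slope2`` second branch of ``crossing``; ``carrier``/``depth``
    [Hz] and ``m`` [rad/s] for ``sine_fm``; ``amplitude`` (dimensionless),
    ``duration`` [s], ``rate`` [Hz].  ``noise_std`` adds white Gaussian noise
    (seeded) when > 0.
    """

    kind: str = "linear"
    f0: float = 500.0
    slope: float = 1000.0
    gap_start: float = 0.9375
    gap_len: float = 0.125
    f1: float = 2500.0
    slope2: float = -1000.0
    carrier: float = 1500.0
    depth: float = 800.0
    m: float = 2.0 * math.pi
    amplitude: float = 1.0
    duration: float = 2.0
    rate: float = 8000.0
    noise_std: float = 0.0

    _KINDS = ("linear", "interrupted", "crossing", "sine_fm")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown chirp kind {self.kind!r}; choose from {self._KINDS}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be > 0")
        if self.kind == "interrupted":
            if self.gap_len < 0:
                raise ValueError("gap length must be non-negative")
            if not (0.0 <= self.gap_start and self.gap_start + self.gap_len <= self.duration):
                raise ValueError("gap interval must lie inside [0, duration]")


def instantaneous_frequency(spec: ChirpSpec, t: np.ndarray) -> np.ndarray:
    """Instantaneous frequency f(t) [Hz] of the (first branch of the) chirp."""
    t = np.asarray(t, dtype=np.float64)
    if spec.kind in ("linear", "interrupted", "crossing"):
        return spec.f0 + spec.slope * t
    if spec.kind == "sine_fm":
        return spec.carrier + spec.depth * np.sin(spec.m * t)
    raise ValueError(spec.kind)


def _phase(f0: float, slope: float, t: np.ndarray) -> np.ndarray:
    # phase = 2*pi * integral of the instantaneous frequency
    return 2.0 * np.pi * (f0 * t + 0.5 * slope * t**2)


def _check_band(fmin: float, fmax: float, rate: float) -> None:
    if fmax >= rate / 2:
        raise ValueError(
            f"aliasing: maximum instantaneous frequency {fmax:g} Hz reaches the "
            f"Nyquist frequency {rate / 2:g} Hz"
        )
    if fmin <= 0:
        raise ValueError(
            f"instantaneous frequency must stay positive, reaches {fmin:g} Hz"
        )


def make_chirp(spec: ChirpSpec, seed: Optional[int] = None) -> SoundSignal:
    """Generate the waveform described by ``spec``.

    The phase is the exact integral of the instantaneous frequency, so it is
    continuous everywhere except across the interruption gap, whose samples
    are exactly zero.  ``seed`` only matters when ``spec.noise_std > 0``.
    """
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    T = spec.duration

    if spec.kind in ("linear", "interrupted"):
        f_ends = (spec.f0, spec.f0 + spec.slope * T)
        _check_band(min(f_ends), max(f_ends), spec.rate)
        s = spec.amplitude * np.sin(_phase(spec.f0, spec.slope, t))
        if spec.kind == "interrupted":
            gap = (t >= spec.gap_start) & (t < spec.gap_start + spec.gap_len)
            s[gap] = 0.0
    elif spec.kind == "crossing":
        for f0, sl in ((spec.f0, spec.slope), (spec.f1, spec.slope2)):
            f_ends = (f0, f0 + sl * T)
            _check_band(min(f_ends), max(f_ends), spec.rate)
        s = spec.amplitude * (
            np.sin(_phase(spec.f0, spec.slope, t)) + np.sin(_phase(spec.f1, spec.slope2, t))
        )
    elif spec.kind == "sine_fm":
        _check_band(spec.carrier - abs(spec.depth), spec.carrier + abs(spec.depth), spec.rate)
        # phase integral of carrier + depth*sin(m t)
        phase = 2.0 * np.pi * (
            spec.carrier * t + spec.depth / spec.m * (1.0 - np.cos(spec.m * t))
        )
        s = spec.amplitude * np.sin(phase)
    else:  # pragma: no cover - rejected in ChirpSpec
        raise ValueError(spec.kind)

    if spec.noise_std > 0.0:
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, spec.noise_std, size=n)
    return SoundSignal(s, spec.rate)


def read_wav(path: str | os.PathLike) -> SoundSignal:
    """Read a WAV file as a :class:`SoundSignal`.

    Integer encodings are rescaled to [-1, 1]; multichannel files are reduced
    to their first channel.  Empty or corrupt files raise ``IOError``.
    """
    try:
        rate, data = wavfile.read(os.fspath(path))
    except Exception as exc:  # wavfile raises ValueError on corrupt input
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.atleast_1d(np.asarray(data))
    if data.size == 0:
        raise IOError(f"WAV file {path} contains no samples")
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return SoundSignal(data, float(rate))


def write_wav(path: str | os.PathLike, signal: SoundSignal, encoding: str = "float32") -> None:
    """Write a :class:`SoundSignal` to a WAV file.

    ``encoding='float32'`` (default) round-trips samples to ~1e-7; ``'pcm16'``
    quantises to 16 bits.
    """
    if encoding == "float32":
        data = signal.samples.astype(np.float32)
    elif encoding == "pcm16":
        clipped = np.clip(signal.samples, -1.0, 1.0 - 2.0**-15)
        data = np.round(clipped * 32768.0).astype(np.int16)
    else:
        raise ValueError(f"unknown encoding {encoding!r}; use 'float32' or 'pcm16'")
    wavfile.write(os.fspath(path), int(round(signal.rate)), data)
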