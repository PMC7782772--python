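"""Forward and inverse short-time Fourier transform with a Hann window.

The analysis uses a periodic Hann window W(x) = (1 + cos(2*pi*x/L))/2 for
|x| < L/2 (0 otherwise), hop <= L/2 so the constant-overlap-add (COLA)
condition holds, and a unitary per-frame DFT (scaled by 1/sqrt(N_fft)).
Synthesis goes through the canonical dual window, making istft(stft(s))
numerically the identity.

Only the non-negative frequency bins are stored; for a real signal the
negative half is the Hermitian mirror, S(tau, -omega) = conj(S(tau, omega)).
The inverse transform reconstructs the full spectrum from that symmetry and
can report how far a processed image is from representing a real signal
(the imaginary residual of the synthesised waveform).
"""
from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
from scipy.signal import ShortTimeFFT

from .signals import SoundSignal

__all__ = ["STFTConfig", "TFImage", "hann_window", "stft", "istft"]


def hann_window(L_samples: int) -> np.ndarray:
    """Periodic Hann window of length ``L_samples``.

    Sampled as w[n] = (1 - cos(2*pi*n/L))/2, n = 0..L-1, i.e. the zero
    endpoint is included exactly once, which gives exact COLA at hop = L/2
    and L/4.  The centre sample (n = L/2 for even L) equals 1.
    """
    if L_samples < 2:
        raise ValueError(f"window needs at least 2 samples, got {L_samples}")
    n = np.arange(L_samples)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * n / L_samples))


@dataclasses.dataclass(frozen=True)
class STFTConfig:
    """STFT geometry.

    Parameters
    ----------
    window_len
        Hann window length L in seconds (default 62.5 ms).
    hop
        Hop in seconds; defaults to L/4.  Must satisfy 0 < hop <= L/2 for
        overlap-add invertibility.
    fft_size
        FFT length; defaults to the next power of two >= the window sample
        count.
    """

    window_len: float = 0.0625
    hop: Optional[float] = None
    fft_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.window_len <= 0:
            raise ValueError("window_len must be positive")
        hop = self.hop if self.hop is not None else self.window_len / 4.0
        if not (0.0 < hop <= self.window_len / 2.0 + 1e-12):
            raise ValueError(
                f"hop = {hop} s violates 0 < hop <= window_len/2 = "
                f"{self.window_len / 2} s (overlap-add invertibility)"
            )

    @property
    def hop_seconds(self) -> float:
        return self.hop if self.hop is not None else self.window_len / 4.0

    def sample_geometry(self, rate: float) -> tuple[int, int, int]:
        """(window samples, hop samples, fft size) at sampling rate ``rate``."""
        L = int(round(self.window_len * rate))
        h = int(round(self.hop_seconds * rate))
        if L < 2:
            raise ValueError("window shorter than 2 samples at this rate")
        if h < 1 or h > L // 2:
            raise ValueError(
                f"hop of {h} samples violates 1 <= hop <= L/2 = {L // 2} samples"
            )
        mfft = self.fft_size if self.fft_size is not None else 2 ** math.ceil(math.log2(L))
        if mfft < L:
            raise ValueError(f"fft_size {mfft} smaller than window sample count {L}")
        return L, h, mfft


@dataclasses.dataclass(frozen=True)
class TFImage:
    """Complex time-frequency image S(tau, omega) on a regular grid.

    ``values`` is indexed (frame, frequency bin); ``freqs`` holds the
    non-negative bins only, uniformly spaced from 0 to rate/2.
    """

    values: np.ndarray  # complex, (n_frames, n_bins)
    times: np.ndarray  # s, per frame
    freqs: np.ndarray  # Hz, per bin
    config: STFTConfig
    rate: float
    n_samples: int  # length of the analysed signal, for exact inversion

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape != (len(self.times), len(self.freqs)):
            raise ValueError(
                f"values shape {v.shape} inconsistent with {len(self.times)} frames "
                f"x {len(self.freqs)} bins"
            )
        if not np.all(np.isfinite(v.view(np.float64))):
            raise ValueError("TFImage contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def energy(self) -> float:
        """Total spectrogram energy, counting the mirrored negative bins."""
        w = np.full(len(self.freqs), 2.0)
        w[0] = 1.0
        if len(self.freqs) > 1:
            w[-1] = 1.0  # Nyquist bin is not mirrored
        return float(np.sum(np.abs(self.values) ** 2 * w))


def _transformer(cfg: STFTConfig, rate: float, two_sided: bool = False) -> ShortTimeFFT:
    L, h, mfft = cfg.sample_geometry(rate)
    return ShortTimeFFT(
        hann_window(L),
        hop=h,
        fs=rate,
        mfft=mfft,
        fft_mode="twosided" if two_sided else "onesided",
    )


def stft(signal: SoundSignal, cfg: Optional[STFTConfig] = None) -> TFImage:
    """Short-time Fourier transform of ``signal`` (non-negative bins)."""
    cfg = cfg or STFTConfig()
    L, _, mfft = cfg.sample_geometry(signal.rate)
    if signal.samples.size <= L:
        raise ValueError(
            f"signal of {signal.samples.size} samples is not longer than one "
            f"window ({L} samples)"
        )
    sft = _transformer(cfg, signal.rate)
    S = sft.stft(signal.samples) / math.sqrt(mfft)  # unitary per-frame DFT
    times = sft.t(signal.samples.size)
    return TFImage(
        values=S.T.copy(),
        times=times,
        freqs=sft.f.copy(),
        config=cfg,
        rate=signal.rate,
        n_samples=signal.samples.size,
    )


def istft(
    image: TFImage,
    n_samples: Optional[int] = None,
    return_imag_ratio: bool = False,
):
    """Inverse STFT via Hermitian extension and dual-window overlap-add.

    The stored half-spectrum is extended to the full spectrum by the mirror
    symmetry of real signals and inverted with complex arithmetic.  The
    imaginary part of the result measures how far the image is from
    representing a real signal; it is discarded from the returned waveform
    but its relative sup-norm ``max|Im| / max|Re|`` is available through
    ``return_imag_ratio``.

    ``n_samples`` defaults to the length recorded at analysis time, extended
    by one hop per extra frame if the image has grown in time.
    """
    cfg = image.config
    L, h, mfft = cfg.sample_geometry(image.rate)
    n_bins = mfft // 2 + 1
    if image.values.shape[1] != n_bins:
        raise ValueError(
            f"image has {image.values.shape[1]} frequency bins, config implies {n_bins}"
        )
    sft = _transformer(cfg, image.rate, two_sided=True)
    if n_samples is None:
        base_frames = sft.p_max(image.n_samples) - sft.p_min
        extra = image.values.shape[0] - base_frames
        if extra < 0:
            raise ValueError(
                f"image has {image.values.shape[0]} frames, fewer than the "
                f"{base_frames} frames of its recorded signal length"
            )
        n_samples = image.n_samples + extra * h
    S = image.values.T * math.sqrt(mfft)
    full = np.concatenate([S, np.conj(S[-2:0:-1])], axis=0)
    x = sft.istft(full, k1=n_samples)
    re_max = float(np.max(np.abs(x.real)))
    im_max = float(np.max(np.abs(x.imag)))
    ratio = 0.0 if re_max == 0.0 else im_max / re_max
    out = SoundSignal(np.ascontiguousarray(x.real), image.rate)
    if return_imag_ratio:
        return out, ratio
    return out
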