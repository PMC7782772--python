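"""End-to-end sound reconstruction and experiment reproduction.

The pipeline chains the three stages:

A. *Preprocessing* -- STFT of the input waveform, then lift of the
   time-frequency image to the frequency-chirpiness lattice along the level
   lines of |S|.
B. *Processing* -- delayed Wilson-Cowan evolution of the lifted input with
   the Kolmogorov interaction kernel, run once causally through the frames
   (plus a short zero-input rundown so decaying activation remains visible).
C. *Postprocessing* -- sum over the chirpiness axis and inverse STFT back
   to a waveform, which is real up to numerical roundoff.

Four canonical experiments probe the model's qualitative behaviour on
synthetic chirps: persistence of a linear chirp beyond its end
(``linear``), bridging of an interruption gap (``interrupted``), the near
decoupling of two crossing chirps that live in different chirpiness strata
(``crossing``), and stronger diffusion for the more linear stretches of a
sinusoidally modulated chirp (``sine_fm``).
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any, Dict, Optional, Tuple

import numpy as np
import yaml

from .kernel import AxisScaling, KernelParams, build_interaction
from .lift import ChirpinessGrid, LiftedImage, auto_nu_max, lift, project
from .signals import ChirpSpec, SoundSignal, instantaneous_frequency, make_chirp
from .tfr import STFTConfig, TFImage, istft, stft
from .wc import ActivationField, WCParams, wc_evolve

__all__ = [
    "LiftConfig",
    "ReconstructionConfig",
    "save_config",
    "load_config",
    "reconstruct",
    "run_experiment",
    "EXPERIMENTS",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class LiftConfig:
    """Chirpiness grid parameters.

    ``nu_max`` is either a bound in Hz/s or ``"auto"`` (data-driven: the
    99th percentile of |nu*| over the highest-magnitude bins, widened by
    ``nu_margin``).  ``tol_grad`` of ``None`` uses 1e-3 of the gradient
    sup-norm.
    """

    nu_max: "float | str" = "auto"
    nu_count: int = 41
    tol_grad: Optional[float] = None
    nu_margin: float = 1.5


@dataclasses.dataclass(frozen=True)
class ReconstructionConfig:
    """Full parameter set of the reconstruction pipeline."""

    stft: STFTConfig = dataclasses.field(default_factory=STFTConfig)
    lift: LiftConfig = dataclasses.field(default_factory=LiftConfig)
    kernel: KernelParams = dataclasses.field(default_factory=KernelParams)
    wc: WCParams = dataclasses.field(default_factory=WCParams)
    axis_scale: "float | str" = "nyquist"  # common omega/nu scale, or Nyquist
    tail: float = 0.5  # seconds of zero-input rundown after the signal

    def to_dict(self) -> Dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "ReconstructionConfig":
        return cls(
            stft=STFTConfig(**d.get("stft", {})),
            lift=LiftConfig(**d.get("lift", {})),
            kernel=KernelParams(**d.get("kernel", {})),
            wc=WCParams(**d.get("wc", {})),
            axis_scale=d.get("axis_scale", "nyquist"),
            tail=d.get("tail", 0.5),
        )


def save_config(path: "str | Path", cfg: ReconstructionConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_config(path: "str | Path") -> ReconstructionConfig:
    with open(path) as fh:
        return ReconstructionConfig.from_dict(yaml.safe_load(fh))


def reconstruct(
    signal: SoundSignal,
    cfg: Optional[ReconstructionConfig] = None,
    keep_fields: bool = False,
) -> Tuple[SoundSignal, Dict[str, Any]]:
    """Run the full A -> B -> C pipeline on ``signal``.

    Returns the reconstructed waveform (longer than the input by the
    configured rundown tail) and a diagnostics dict with the input/output
    time-frequency images, the imaginary residual of the output before it
    was discarded, lifted-mass summaries and interaction row-mass range.
    With ``keep_fields`` the lifted input and the activation trajectory are
    included as well.
    """
    cfg = cfg or ReconstructionConfig()
    S = stft(signal, cfg.stft)

    if cfg.lift.nu_max == "auto":
        try:
            nu_max = auto_nu_max(S, tol_grad=cfg.lift.tol_grad, margin=cfg.lift.nu_margin)
        except ValueError:
            # featureless (e.g. silent) input: no level lines to follow; any
            # bound works since nothing is lifted
            nu_max = 1000.0
            logger.warning("no usable chirpiness statistics; nu_max fixed at %g", nu_max)
    else:
        nu_max = float(cfg.lift.nu_max)
    grid = ChirpinessGrid.symmetric(nu_max, cfg.lift.nu_count)
    lifted = lift(S, grid, tol_grad=cfg.lift.tol_grad)

    scale = float(signal.rate) / 2.0 if cfg.axis_scale == "nyquist" else float(cfg.axis_scale)
    scaling = AxisScaling(scale)

    dt = cfg.stft.hop_seconds
    wc_params = cfg.wc.snapped(dt)
    kernel_params = dataclasses.replace(cfg.kernel, delta=wc_params.delta)
    K = build_interaction(S.freqs, grid, kernel_params, scaling)
    row_mass = K.row_mass()

    extra = int(round(cfg.tail / dt))
    activation = wc_evolve(lifted, wc_params, K, extra_steps=extra)

    S_hat = TFImage(
        values=project(activation.values),
        times=activation.times,
        freqs=S.freqs,
        config=cfg.stft,
        rate=signal.rate,
        n_samples=signal.samples.size,
    )
    out, imag_ratio = istft(S_hat, return_imag_ratio=True)

    diagnostics: Dict[str, Any] = {
        "input_tf": S,
        "output_tf": S_hat,
        "imag_ratio": imag_ratio,
        "nu_max": nu_max,
        "axis_scale": scale,
        "delta_effective": wc_params.delta,
        "delay_steps": wc_params.delay_steps,
        "dropped_fraction": lifted.dropped_fraction,
        "lifted_mass": float(np.abs(lifted.values).sum()),
        "row_mass_min": float(row_mass.min()),
        "row_mass_max": float(row_mass.max()),
    }
    if keep_fields:
        diagnostics["lifted"] = lifted
        diagnostics["activation"] = activation
        diagnostics["interaction"] = K
    return out, diagnostics


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

#: Canonical experiment definitions: chirp kind and evolution parameters.
#: All use delta = 0.0625 s and beta = 1.
EXPERIMENTS: Dict[str, Dict[str, Any]] = {
    "fig4": {"kind": "linear", "alpha": 55.0, "gamma": 55.0, "b": 0.05},
    "fig5": {"kind": "interrupted", "alpha": 55.0, "gamma": 55.0, "b": 0.05},
    "fig6": {"kind": "crossing", "alpha": 53.0, "gamma": 55.0, "b": 0.01},
    "fig7": {"kind": "sine_fm", "alpha": 53.0, "gamma": 55.0, "b": 0.2},
}


def _experiment_config(name: str, overrides: Optional[Dict[str, Any]] = None
                       ) -> Tuple[ChirpSpec, ReconstructionConfig]:
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}")
    exp = dict(EXPERIMENTS[name])
    exp.update(overrides or {})
    spec_fields = {f.name for f in dataclasses.fields(ChirpSpec)}
    spec = ChirpSpec(**{k: v for k, v in exp.items() if k in spec_fields})
    cfg = ReconstructionConfig(
        kernel=KernelParams(b=exp["b"], delta=exp.get("delta", 0.0625)),
        wc=WCParams(
            alpha=exp["alpha"],
            beta=exp.get("beta", 1.0),
            gamma=exp["gamma"],
            kappa=exp.get("kappa", WCParams.kappa),
            delta=exp.get("delta", 0.0625),
        ),
        tail=exp.get("tail", 0.5),
    )
    return spec, cfg


def _box_energy(tf: TFImage, t_lo: float, t_hi: float, f_lo: float, f_hi: float) -> float:
    """Spectrogram energy inside a time-frequency box."""
    ti = (tf.times >= t_lo) & (tf.times <= t_hi)
    fi = (tf.freqs >= f_lo) & (tf.freqs <= f_hi)
    return float(np.sum(np.abs(tf.values[np.ix_(ti, fi)]) ** 2))


def _total_energy(tf: TFImage) -> float:
    return float(np.sum(np.abs(tf.values) ** 2))


def ridge_duration(tf: TFImage, rel_db: float = -20.0) -> float:
    """Duration [s] over which the per-frame ridge peak stays within
    ``rel_db`` of its global maximum."""
    peak = np.max(np.abs(tf.values), axis=1)
    thr = peak.max() * 10.0 ** (rel_db / 20.0)
    frames = int(np.sum(peak >= thr))
    hop = tf.times[1] - tf.times[0] if len(tf.times) > 1 else 0.0
    return frames * float(hop)


def _gap_box(spec: ChirpSpec, tf: TFImage, pad_bins: float = 4.0) -> Tuple[float, float, float, float]:
    df = float(tf.freqs[1] - tf.freqs[0])
    t_lo = spec.gap_start
    t_hi = spec.gap_start + spec.gap_len
    f_edges = instantaneous_frequency(spec, np.array([t_lo, t_hi]))
    pad = pad_bins * df
    return t_lo, t_hi, float(f_edges.min()) - pad, float(f_edges.max()) + pad


def gap_energy_ratio(before: TFImage, after: TFImage, spec: ChirpSpec) -> float:
    """Relative energy concentration in the interruption's time-frequency box,
    after / before.

    Each spectrogram's box energy is normalised by its own total energy (the
    two images live on different amplitude scales), so a ratio > 1 means the
    processed sound fills the gap more than the degraded input did.
    """
    box = _gap_box(spec, before)
    num = _box_energy(after, *box) / _total_energy(after)
    den = _box_energy(before, *box) / _total_energy(before)
    return num / den


def crosstalk_index(
    combined: TFImage, branch1: TFImage, branch2: TFImage, spec: ChirpSpec,
    t_half: float = 0.125, f_half: float = 250.0,
) -> float:
    """Energy of the jointly processed crossing region over the sum of the
    separately processed branches, in a box centred at the ridge crossing.

    A value near 1 means the two chirps evolve as if decoupled (they occupy
    different chirpiness strata, so the nonlinear interaction does not mix
    them).
    """
    t_star = (spec.f1 - spec.f0) / (spec.slope - spec.slope2)
    f_star = spec.f0 + spec.slope * t_star
    box = (t_star - t_half, t_star + t_half, f_star - f_half, f_star + f_half)
    e_comb = _box_energy(combined, *box)
    e_sep = _box_energy(branch1, *box) + _box_energy(branch2, *box)
    return e_comb / e_sep


def diffusion_spread(lifted: LiftedImage, activation: ActivationField) -> float:
    """Increase [Hz/s] of the magnitude-weighted chirpiness spread from the
    lifted input to the processed activation."""

    def _std(values: np.ndarray, nu: np.ndarray) -> float:
        w = np.abs(values).sum(axis=(0, 1))
        w = w / w.sum()
        mean = float(np.sum(w * nu))
        return float(np.sqrt(np.sum(w * (nu - mean) ** 2)))

    nu = lifted.grid.nu_values
    return _std(activation.values, nu) - _std(lifted.values, nu)


def run_experiment(
    name: str,
    overrides: Optional[Dict[str, Any]] = None,
    out_dir: "str | Path | None" = None,
    seed: Optional[int] = None,
) -> Dict[str, float]:
    """Reproduce one of the canonical experiments and compute its metric.

    Returns a dict of metrics; with ``out_dir`` set, also writes before and
    after spectrogram renderings (PNG) and a ``metrics.csv``.
    """
    spec, cfg = _experiment_config(name, overrides)
    signal = make_chirp(spec, seed=seed)
    out, diag = reconstruct(signal, cfg, keep_fields=True)
    before: TFImage = diag["input_tf"]
    after: TFImage = diag["output_tf"]

    metrics: Dict[str, float] = {
        "imag_ratio": diag["imag_ratio"],
        "nu_max": diag["nu_max"],
        "dropped_fraction": diag["dropped_fraction"],
        "output_max_abs": float(np.max(np.abs(out.samples))),
    }
    if name == "fig4":
        dur_in = ridge_duration(before)
        dur_out = ridge_duration(after)
        metrics["ridge_duration_before"] = dur_in
        metrics["ridge_duration_after"] = dur_out
        metrics["tail_extension"] = dur_out - dur_in
        metrics["tail_extension_ratio"] = dur_out / dur_in
    elif name == "fig5":
        metrics["gap_energy_ratio"] = gap_energy_ratio(before, after, spec)
    elif name == "fig6":
        b1 = dataclasses.replace(spec, kind="linear")
        b2 = dataclasses.replace(spec, kind="linear", f0=spec.f1, slope=spec.slope2)
        out1, d1 = reconstruct(make_chirp(b1, seed=seed), cfg)
        out2, d2 = reconstruct(make_chirp(b2, seed=seed), cfg)
        metrics["crosstalk_index"] = crosstalk_index(
            after, d1["output_tf"], d2["output_tf"], spec
        )
    elif name == "fig7":
        metrics["diffusion_spread"] = diffusion_spread(diag["lifted"], diag["activation"])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _render_spectrograms(out_dir / f"{name}.png", before, after, title=name)
        with open(out_dir / f"{name}_metrics.csv", "w") as fh:
            fh.write("metric,value\n")
            for k, v in metrics.items():
                fh.write(f"{k},{v}\n")
    return metrics


def _render_spectrograms(path: Path, before: TFImage, after: TFImage, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, tf, label in ((axes[0], before, "input"), (axes[1], after, "processed")):
        mag = tf.magnitude.T
        ref = mag.max()
        db = 20.0 * np.log10(np.maximum(mag, ref * 1e-6) / ref)
        ax.imshow(
            db,
            origin="lower",
            aspect="auto",
            extent=(tf.times[0], tf.times[-1], tf.freqs[0], tf.freqs[-1]),
            vmin=-80.0,
            vmax=0.0,
            cmap="magma",
        )
        ax.set_title(f"{title}: {label}")
        ax.set_xlabel("time [s]")
    axes[0].set_ylabel("frequency [Hz]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
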