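"""HDF5 persistence for intermediate fields and CSV magnitude dumps."""
from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import scipy.sparse as sp

from .kernel import AxisScaling, KernelParams, SparseInteraction
from .lift import ChirpinessGrid, LiftedImage
from .tfr import STFTConfig, TFImage
from .wc import ActivationField, WCParams

__all__ = [
    "save_tfimage",
    "load_tfimage",
    "save_lifted",
    "load_lifted",
    "save_activation",
    "save_interaction",
    "load_interaction",
    "export_magnitude_csv",
]


def _write_cfg(group: h5py.Group, cfg: STFTConfig) -> None:
    group.attrs["window_len"] = cfg.window_len
    group.attrs["hop"] = -1.0 if cfg.hop is None else cfg.hop
    group.attrs["fft_size"] = -1 if cfg.fft_size is None else cfg.fft_size


def _read_cfg(group: h5py.Group) -> STFTConfig:
    hop = float(group.attrs["hop"])
    fft = int(group.attrs["fft_size"])
    return STFTConfig(
        window_len=float(group.attrs["window_len"]),
        hop=None if hop < 0 else hop,
        fft_size=None if fft < 0 else fft,
    )


def save_tfimage(path: "str | Path", image: TFImage) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=image.values)
        fh.create_dataset("times", data=image.times)
        fh.create_dataset("freqs", data=image.freqs)
        fh.attrs["rate"] = image.rate
        fh.attrs["n_samples"] = image.n_samples
        _write_cfg(fh, image.config)


def load_tfimage(path: "str | Path") -> TFImage:
    with h5py.File(path, "r") as fh:
        return TFImage(
            values=fh["values"][()],
            times=fh["times"][()],
            freqs=fh["freqs"][()],
            config=_read_cfg(fh),
            rate=float(fh.attrs["rate"]),
            n_samples=int(fh.attrs["n_samples"]),
        )


def save_lifted(path: "str | Path", lifted: LiftedImage) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=lifted.values)
        fh.create_dataset("times", data=lifted.times)
        fh.create_dataset("freqs", data=lifted.freqs)
        fh.create_dataset("nu_values", data=lifted.grid.nu_values)
        fh.attrs["rate"] = lifted.rate
        fh.attrs["n_samples"] = lifted.n_samples
        fh.attrs["dropped_fraction"] = lifted.dropped_fraction
        _write_cfg(fh, lifted.config)


def load_lifted(path: "str | Path") -> LiftedImage:
    with h5py.File(path, "r") as fh:
        return LiftedImage(
            values=fh["values"][()],
            times=fh["times"][()],
            freqs=fh["freqs"][()],
            grid=ChirpinessGrid(fh["nu_values"][()]),
            config=_read_cfg(fh),
            rate=float(fh.attrs["rate"]),
            n_samples=int(fh.attrs["n_samples"]),
            dropped_fraction=float(fh.attrs["dropped_fraction"]),
        )


def save_activation(path: "str | Path", act: ActivationField) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=act.values)
        fh.create_dataset("times", data=act.times)
        fh.create_dataset("freqs", data=act.freqs)
        fh.create_dataset("nu_values", data=act.grid.nu_values)
        for k, v in dataclasses.asdict(act.params).items():
            fh.attrs[f"wc_{k}"] = v


def save_interaction(path: "str | Path", K: SparseInteraction) -> None:
    with h5py.File(path, "w") as fh:
        for name, mat in (("direct", K.direct), ("mirror", K.mirror)):
            g = fh.create_group(name)
            coo = mat.tocoo()
            g.create_dataset("row", data=coo.row)
            g.create_dataset("col", data=coo.col)
            g.create_dataset("data", data=coo.data)
            g.attrs["shape"] = coo.shape
        fh.create_dataset("freqs", data=K.freqs)
        fh.create_dataset("nu_values", data=K.grid.nu_values)
        fh.attrs["b"] = K.params.b
        fh.attrs["delta"] = K.params.delta
        fh.attrs["eps"] = K.params.epsilon
        fh.attrs["scale"] = K.scaling.scale
        fh.attrs["cell_area"] = K.cell_area


def load_interaction(path: "str | Path") -> SparseInteraction:
    with h5py.File(path, "r") as fh:

        def _mat(name: str) -> sp.csr_matrix:
            g = fh[name]
            return sp.csr_matrix(
                (g["data"][()], (g["row"][()], g["col"][()])),
                shape=tuple(g.attrs["shape"]),
            )

        return SparseInteraction(
            direct=_mat("direct"),
            mirror=_mat("mirror"),
            freqs=fh["freqs"][()],
            grid=ChirpinessGrid(fh["nu_values"][()]),
            params=KernelParams(
                b=float(fh.attrs["b"]),
                delta=float(fh.attrs["delta"]),
                eps=float(fh.attrs["eps"]),
            ),
            scaling=AxisScaling(float(fh.attrs["scale"])),
            cell_area=float(fh.attrs["cell_area"]),
        )


def export_magnitude_csv(path: "str | Path", image: TFImage) -> None:
    """Magnitude-only dump for quick inspection: frames as rows."""
    header = "time_s," + ",".join(f"{f:g}Hz" for f in image.freqs)
    data = np.column_stack([image.times, image.magnitude])
    np.savetxt(path, data, delimiter=",", header=header, comments="")
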