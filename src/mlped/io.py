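"""Standard-format persistence: multi-coil HDF5 volumes and YAML run configs.

Volumes use the public accelerated-MRI HDF5 dialect — a complex dataset
named ``kspace`` with layout (slices, coils, rows, columns) and an optional
real dataset ``reconstruction_rss`` holding the fully sampled RSS reference
per slice — so real scanner exports drop in without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .network import NetworkConfig
from .phantom import PhantomSpec
from .training import TrainConfig
from .transforms import KSpaceVolume

__all__ = [
    "VolumeRecord",
    "MaskSettings",
    "RunConfig",
    "read_volume",
    "write_volume",
    "load_run_config",
    "save_run_config",
]


class VolumeFormatError(ValueError):
    """Raised when an HDF5 file does not follow the expected volume layout."""


@dataclass
class VolumeRecord:
    """A k-space volume with optional RSS reference and free-form attributes."""

    kspace: KSpaceVolume
    rss_reference: np.ndarray | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rss_reference is not None:
            self.rss_reference = np.asarray(self.rss_reference, dtype=np.float64)
            if self.rss_reference.ndim != 3:
                raise ValueError("rss_reference must be (slices, rows, columns)")
            if self.rss_reference.shape[0] != self.kspace.data.shape[0]:
                raise ValueError("rss_reference slice count must match kspace")


def read_volume(path) -> VolumeRecord:
    """Read a multi-coil volume from the HDF5 dialect described above."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "kspace" not in f:
            raise VolumeFormatError(
                f"{path.name}: missing dataset 'kspace' "
                "(expected complex layout (slices, coils, rows, columns))"
            )
        raw = f["kspace"][()]
        if raw.ndim != 4:
            raise ValueError(
                f"{path.name}: 'kspace' must be 4-D (slices, coils, rows, columns), "
                f"got ndim={raw.ndim}"
            )
        rss = f["reconstruction_rss"][()] if "reconstruction_rss" in f else None
        attrs = {k: (v.item() if isinstance(v, np.generic) else v)
                 for k, v in f.attrs.items()}
    return VolumeRecord(KSpaceVolume(raw), rss_reference=rss, attributes=attrs)


def write_volume(record: VolumeRecord, path) -> None:
    """Write a volume in the same dialect ``read_volume`` expects."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=record.kspace.data.astype(np.complex64))
        if record.rss_reference is not None:
            f.create_dataset("reconstruction_rss",
                             data=record.rss_reference.astype(np.float32))
        for key, value in record.attributes.items():
            f.attrs[key] = value


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class MaskSettings:
    acceleration: int = 4
    center_fraction: float | None = None
    kind: str = "random"

    def to_dict(self) -> dict:
        return {"acceleration": self.acceleration,
                "center_fraction": self.center_fraction, "kind": self.kind}

    @classmethod
    def from_dict(cls, d: dict) -> "MaskSettings":
        return cls(**d)


@dataclass
class RunConfig:
    """Union of the phantom, network, training and masking settings."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    mask: MaskSettings = field(default_factory=MaskSettings)
    n_train: int = 20
    n_val: int = 4
    n_coils: int = 15
    noise_sd: float = 0.0
    checkpoint: str = "model.npz"
    history: str = "history.json"
    metrics: str = "metrics.tsv"

    def to_dict(self) -> dict:
        return {
            "phantom": {
                "size": list(self.phantom.size),
                "n_ellipses": self.phantom.n_ellipses,
                "contrast": self.phantom.contrast,
                "speckle_sd": self.phantom.speckle_sd,
                "seed": self.phantom.seed,
            },
            "network": self.network.to_dict(),
            "train": self.train.to_dict(),
            "mask": self.mask.to_dict(),
            "n_train": self.n_train,
            "n_val": self.n_val,
            "n_coils": self.n_coils,
            "noise_sd": self.noise_sd,
            "checkpoint": self.checkpoint,
            "history": self.history,
            "metrics": self.metrics,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ph = dict(d.pop("phantom", {}))
        if "size" in ph:
            ph["size"] = tuple(ph["size"])
        net = d.pop("network", {})
        if "channel_schedule" in net and net["channel_schedule"] is not None:
            net = dict(net)
            net["channel_schedule"] = tuple(net["channel_schedule"])
        if "rmp_kernels" in net:
            net = dict(net)
            net["rmp_kernels"] = tuple(net["rmp_kernels"])
        return cls(
            phantom=PhantomSpec(**ph),
            network=NetworkConfig(**net),
            train=TrainConfig(**d.pop("train", {})),
            mask=MaskSettings(**d.pop("mask", {})),
            **d,
        )


def save_run_config(config: RunConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)


def load_run_config(path) -> RunConfig:
    with open(path) as f:
        return RunConfig.from_dict(yaml.safe_load(f))
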