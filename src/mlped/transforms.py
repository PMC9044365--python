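"""Deterministic parallel-imaging signal processing.

Everything upstream and downstream of the network lives here: the centered
orthonormal 2-D Fourier pair, the multi-coil acquisition model
``k_i = F(S_i x) + alpha_i``, Cartesian column under-sampling masks, the
root-sum-of-squares (RSS) coil combination, centre cropping, and the
zero-filled reconstruction that forms the aliased network input.

Conventions
-----------
* k-space arrays are indexed ``(slice, coil, row, column)``; columns are the
  phase-encoding direction and are the axis that under-sampling removes.
* Fourier transforms are centered (DC at the array centre) and orthonormally
  scaled, so Parseval's identity holds without size factors.
* Every stochastic operation takes an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "KSpaceVolume",
    "CoilImageSet",
    "CoilSensitivitySet",
    "SamplingMask",
    "MagnitudeImage",
    "NoiseModel",
    "fft2c",
    "ifft2c",
    "apply_sensitivities",
    "rss_combine",
    "make_mask",
    "apply_mask",
    "center_crop",
    "zero_filled_recon",
    "default_center_fraction",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class KSpaceVolume:
    """Complex frequency-domain samples, indexed (slice, coil, row, column)."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"k-space volume must be (slice, coil, row, column); got ndim={self.data.ndim}"
            )
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("k-space volume contains non-finite values")
        if self.coil_count < 1:
            raise ValueError("k-space volume needs at least one coil")

    @property
    def coil_count(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, columns) of each slice."""
        return self.data.shape[2], self.data.shape[3]


@dataclass
class CoilImageSet:
    """Complex spatial-domain coil images, indexed (coil, row, column)."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("coil image set must be (coil, row, column)")
        if self.data.shape[0] < 1:
            raise ValueError("coil image set needs at least one coil")


@dataclass
class CoilSensitivitySet:
    """Smooth complex per-coil weighting maps S_i, indexed (coil, row, column)."""

    maps: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        if self.maps.ndim != 3:
            raise ValueError("sensitivity maps must be (coil, row, column)")
        if self.normalized:
            power = np.sum(np.abs(self.maps) ** 2, axis=0)
            if not np.allclose(power, 1.0, atol=1e-6):
                raise ValueError("normalized sensitivities must satisfy sum_i |S_i|^2 = 1")

    @property
    def coil_count(self) -> int:
        return self.maps.shape[0]


@dataclass
class SamplingMask:
    """Binary column-selection pattern encoding the acceleration factor."""

    columns: np.ndarray
    acceleration: int
    center_fraction: float
    kind: Literal["random", "equispaced"]

    def __post_init__(self):
        self.columns = np.asarray(self.columns).astype(np.uint8)
        if self.columns.ndim != 1:
            raise ValueError("mask must be a 1-D column selector")

    @property
    def n_ones(self) -> int:
        return int(self.columns.sum())


@dataclass
class MagnitudeImage:
    """Real non-negative spatial image (row, column), or a stack of slices."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise ValueError("magnitude image must be 2-D (or a 3-D slice stack)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("magnitude image contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("magnitude image must be non-negative")


@dataclass
class NoiseModel:
    """Complex Gaussian measurement noise: i.i.d. real/imag parts of sd ``sd``."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")


# ---------------------------------------------------------------------------
# Fourier pair
# ---------------------------------------------------------------------------

def _as_2d_complex(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D array, got ndim={arr.ndim}")
    return arr.astype(np.complex128, copy=False)


def fft2c(image) -> np.ndarray:
    """Centered, orthonormal 2-D DFT (image centre is the phase reference)."""
    x = _as_2d_complex(image)
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x), norm="ortho"))


def ifft2c(kspace) -> np.ndarray:
    """Exact inverse of :func:`fft2c`."""
    k = _as_2d_complex(kspace)
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k), norm="ortho"))


def _fft2c_stack(images: np.ndarray) -> np.ndarray:
    """fft2c over the trailing two axes of an arbitrary stack."""
    shifted = np.fft.ifftshift(images, axes=(-2, -1))
    return np.fft.fftshift(np.fft.fft2(shifted, norm="ortho"), axes=(-2, -1))


def _ifft2c_stack(kspaces: np.ndarray) -> np.ndarray:
    shifted = np.fft.ifftshift(kspaces, axes=(-2, -1))
    return np.fft.fftshift(np.fft.ifft2(shifted, norm="ortho"), axes=(-2, -1))


# ---------------------------------------------------------------------------
# coil model
# ---------------------------------------------------------------------------

def apply_sensitivities(image, sens: CoilSensitivitySet,
                        noise: NoiseModel | None = None) -> KSpaceVolume:
    """Simulate a single-slice multi-coil acquisition k_i = F(S_i x) + alpha_i.

    ``alpha_i`` has independent zero-mean Gaussian real and imaginary parts of
    standard deviation ``noise.sd``, drawn reproducibly from ``noise.seed``.
    """
    x = np.asarray(image.data if isinstance(image, MagnitudeImage) else image)
    if x.ndim != 2:
        raise ValueError("apply_sensitivities expects a single 2-D slice")
    if x.shape != sens.maps.shape[1:]:
        raise ValueError(
            f"image shape {x.shape} does not match sensitivity maps {sens.maps.shape[1:]}"
        )
    coil_images = sens.maps * x[None, :, :]
    kspace = _fft2c_stack(coil_images)
    if noise is not None and noise.sd > 0:
        rng = np.random.default_rng(noise.seed)
        alpha = noise.sd * (
            rng.standard_normal(kspace.shape) + 1j * rng.standard_normal(kspace.shape)
        )
        kspace = kspace + alpha
    return KSpaceVolume(kspace[None])


def rss_combine(coil_images) -> MagnitudeImage:
    """Root-sum-of-squares combination: per-pixel sqrt(sum_i |x_i|^2)."""
    arr = np.asarray(
        coil_images.data if isinstance(coil_images, CoilImageSet) else coil_images
    )
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("rss_combine needs a non-empty (coil, row, column) stack")
    combined = np.sqrt(np.sum(np.abs(arr) ** 2, axis=0))
    return MagnitudeImage(combined)


# ---------------------------------------------------------------------------
# under-sampling
# ---------------------------------------------------------------------------

def default_center_fraction(acceleration: int) -> float:
    """Fully-sampled centre fraction paired with an acceleration factor."""
    return 0.04 if acceleration >= 8 else 0.08


def make_mask(columns: int, acceleration: int, center_fraction: float,
              kind: Literal["random", "equispaced"] = "random",
              seed: int = 0) -> SamplingMask:
    """Build a Cartesian column-sampling mask.

    The central ``round(center_fraction * columns)`` consecutive columns are
    always kept.  ``random`` masks keep exactly ``round(columns/acceleration)``
    columns in total, the non-central ones drawn uniformly without
    replacement; ``equispaced`` masks keep every ``acceleration``-th column
    starting from a seeded offset, plus the centre block.
    """
    if acceleration < 1:
        raise ValueError("acceleration must be >= 1")
    if not 0.0 <= center_fraction <= 1.0:
        raise ValueError("center_fraction must be in [0, 1]")
    if kind not in ("random", "equispaced"):
        raise ValueError(f"unknown mask kind {kind!r}")
    n_center = int(round(center_fraction * columns))
    budget = int(round(columns / acceleration))
    if n_center > budget:
        raise ValueError(
            f"centre block ({n_center} columns) exceeds sampling budget "
            f"({budget} of {columns} at {acceleration}-fold)"
        )
    mask = np.zeros(columns, dtype=np.uint8)
    c_start = (columns - n_center) // 2
    mask[c_start:c_start + n_center] = 1
    rng = np.random.default_rng(seed)
    if acceleration == 1:
        mask[:] = 1
    elif kind == "random":
        remaining = budget - n_center
        candidates = np.flatnonzero(mask == 0)
        chosen = rng.choice(candidates, size=remaining, replace=False)
        mask[chosen] = 1
    else:  # equispaced
        offset = int(rng.integers(acceleration))
        mask[offset::acceleration] = 1
    return SamplingMask(mask, acceleration, center_fraction, kind)


def apply_mask(kspace: KSpaceVolume, mask: SamplingMask) -> KSpaceVolume:
    """Zero the unsampled columns of every slice and coil."""
    if kspace.shape[1] != mask.columns.shape[0]:
        raise ValueError(
            f"mask length {mask.columns.shape[0]} does not match "
            f"{kspace.shape[1]} k-space columns"
        )
    return KSpaceVolume(kspace.data * mask.columns[None, None, None, :])


# ---------------------------------------------------------------------------
# cropping & zero-filled reconstruction
# ---------------------------------------------------------------------------

def center_crop(image, target: tuple[int, int]) -> np.ndarray:
    """Centrally aligned crop; odd margins drop the extra row/column from the
    trailing side (leading margin = floor((in - out) / 2))."""
    arr = np.asarray(image.data if isinstance(image, MagnitudeImage) else image)
    th, tw = target
    h, w = arr.shape[-2], arr.shape[-1]
    if th > h or tw > w:
        raise ValueError(f"crop target {target} larger than input {(h, w)}")
    r0 = (h - th) // 2
    c0 = (w - tw) // 2
    return arr[..., r0:r0 + th, c0:c0 + tw]


def zero_filled_recon(kspace: KSpaceVolume, mask: SamplingMask,
                      target: tuple[int, int]) -> MagnitudeImage:
    """Aliased baseline: apply_mask -> per-coil ifft2c -> RSS -> centre crop.

    This is the single-channel network input.  Single-slice volumes yield a
    2-D image; multi-slice volumes a (slice, row, column) stack.
    """
    masked = apply_mask(kspace, mask)
    coil_images = _ifft2c_stack(masked.data)
    combined = np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=1))
    cropped = center_crop(combined, target)
    if cropped.shape[0] == 1:
        cropped = cropped[0]
    return MagnitudeImage(cropped)
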