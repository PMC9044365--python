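"""Synthetic multi-coil acquisition generator.

Produces phantom slices with the statistical structure the reconstruction
pipeline cares about — a compact bright object on a dark background, 15
receive coils with smooth spatially varying complex sensitivities (so the
per-coil images have inhomogeneous brightness), optional multiplicative
speckle emulating a fat-suppressed contrast, complex Gaussian measurement
noise, and Cartesian column under-sampling — without any external dataset.

Two contrast styles are provided: ``pd_like`` (clean ellipse-sum phantoms)
and ``pdfs_like`` (the same phantoms under seeded multiplicative log-normal
speckle).  Ellipse-sum phantoms are used instead of anatomical templates
because they are closed-form, seedable and dependency-free; their sharp
boundaries still produce the high-frequency content that makes column
under-sampling alias visibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .transforms import (
    CoilSensitivitySet,
    KSpaceVolume,
    MagnitudeImage,
    NoiseModel,
    SamplingMask,
    apply_mask,
    apply_sensitivities,
    default_center_fraction,
    make_mask,
)

__all__ = [
    "PhantomSpec",
    "SyntheticSample",
    "make_phantom",
    "make_coil_sensitivities",
    "simulate_dataset",
]


@dataclass
class PhantomSpec:
    """Geometry and contrast of a synthetic slice."""

    size: tuple[int, int] = (64, 64)
    n_ellipses: int = 6
    contrast: Literal["pd_like", "pdfs_like"] = "pd_like"
    speckle_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.size[0] < 32 or self.size[1] < 32:
            raise ValueError("phantom size must be at least 32x32")
        if self.n_ellipses < 1:
            raise ValueError("need at least one ellipse")
        if self.speckle_sd < 0:
            raise ValueError("speckle_sd must be non-negative")
        if self.contrast not in ("pd_like", "pdfs_like"):
            raise ValueError(f"unknown contrast {self.contrast!r}")


@dataclass
class SyntheticSample:
    """One simulated slice: ground truth plus its (masked) acquisition."""

    ground_truth: MagnitudeImage
    kspace: KSpaceVolume
    sensitivities: CoilSensitivitySet
    mask: SamplingMask
    acceleration: int
    volume_id: int = 0

    def __post_init__(self):
        if self.kspace.coil_count != self.sensitivities.coil_count:
            raise ValueError("k-space and sensitivity coil counts disagree")


def make_phantom(spec: PhantomSpec) -> MagnitudeImage:
    """Sum of randomly placed rotated ellipses, clipped to [0, 1].

    Ellipse centres stay within 10% of the image centre and semi-axes span
    16–32% of the image size, so every ellipse covers the centre pixel and no
    ellipse reaches the corners.  ``pdfs_like`` multiplies by seeded
    log-normal speckle before the final clip.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.size
    yy, xx = np.mgrid[0:rows, 0:cols]
    cy0, cx0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    scale = min(rows, cols)
    img = np.zeros((rows, cols), dtype=np.float64)
    for _ in range(spec.n_ellipses):
        cy = cy0 + rng.uniform(-0.1, 0.1) * scale
        cx = cx0 + rng.uniform(-0.1, 0.1) * scale
        a = rng.uniform(0.16, 0.32) * scale
        b = rng.uniform(0.16, 0.32) * scale
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(0.4, 1.0)
        ct, st = np.cos(theta), np.sin(theta)
        xr = (xx - cx) * ct + (yy - cy) * st
        yr = -(xx - cx) * st + (yy - cy) * ct
        img += amp * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    if spec.contrast == "pdfs_like" and spec.speckle_sd > 0:
        speckle = rng.lognormal(mean=0.0, sigma=spec.speckle_sd, size=img.shape)
        img = img * speckle
    return MagnitudeImage(np.clip(img, 0.0, 1.0))


def make_coil_sensitivities(n_coils: int, size: tuple[int, int],
                            seed: int = 0) -> CoilSensitivitySet:
    """Smooth complex coil maps peaked on a ring around the image.

    Each coil sits at a distinct angle on a ring of radius 0.42 * min(size)
    around the image centre; its magnitude is a broad Gaussian of the distance
    to the coil (brightness falls with distance from the coil, as for a
    physical receive element) and its phase a gentle random linear ramp.  The
    set is jointly normalised so sum_i |S_i|^2 = 1 at every pixel, and each
    coil's normalised magnitude peaks at a distinct pixel near its position.
    """
    if n_coils < 1:
        raise ValueError("need at least one coil")
    rng = np.random.default_rng(seed)
    rows, cols = size
    yy, xx = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    radius = 0.42 * min(rows, cols)
    sigma = 0.4 * max(rows, cols)
    start = rng.uniform(0, 2 * np.pi)
    maps = np.empty((n_coils, rows, cols), dtype=np.complex128)
    for i in range(n_coils):
        angle = start + 2 * np.pi * i / n_coils
        py = cy + radius * np.sin(angle)
        px = cx + radius * np.cos(angle)
        dist2 = (yy - py) ** 2 + (xx - px) ** 2
        mag = np.exp(-dist2 / (2 * sigma ** 2))
        gy, gx = rng.uniform(-2.0, 2.0, size=2)
        phase = 2 * np.pi * (gy * (yy - cy) / rows + gx * (xx - cx) / cols) / 8.0
        phase += rng.uniform(0, 2 * np.pi)
        maps[i] = mag * np.exp(1j * phase)
    power = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= power[None]
    return CoilSensitivitySet(maps, normalized=True)


def simulate_dataset(n_samples: int, spec: PhantomSpec, n_coils: int = 15,
                     acceleration: int = 4, noise_sd: float = 0.0,
                     seed: int = 0,
                     center_fraction: float | None = None,
                     mask_kind: Literal["random", "equispaced"] = "random",
                     ) -> list[SyntheticSample]:
    """Simulate ``n_samples`` independent single-slice acquisitions.

    Each sample runs phantom -> coil modulation (+ complex Gaussian noise of
    sd ``noise_sd``) -> column mask at ``acceleration``; the stored k-space is
    already masked.  Per-sample seeds derive deterministically from the master
    ``seed``, so the whole collection is bit-reproducible.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if center_fraction is None:
        center_fraction = default_center_fraction(acceleration)
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=(n_samples, 4))
    samples: list[SyntheticSample] = []
    for idx in range(n_samples):
        s_ph, s_sens, s_noise, s_mask = (int(s) for s in sub_seeds[idx])
        ph_spec = PhantomSpec(
            size=spec.size, n_ellipses=spec.n_ellipses, contrast=spec.contrast,
            speckle_sd=spec.speckle_sd, seed=s_ph,
        )
        gt = make_phantom(ph_spec)
        sens = make_coil_sensitivities(n_coils, spec.size, seed=s_sens)
        kspace = apply_sensitivities(gt, sens, NoiseModel(sd=noise_sd, seed=s_noise))
        mask = make_mask(spec.size[1], acceleration, center_fraction,
                         kind=mask_kind, seed=s_mask)
        masked = apply_mask(kspace, mask)
        samples.append(SyntheticSample(
            ground_truth=gt, kspace=masked, sensitivities=sens,
            mask=mask, acceleration=acceleration, volume_id=idx,
        ))
    return samples
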