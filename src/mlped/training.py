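"""Training loop and image-quality evaluation.

The network is trained end-to-end to minimise the L1 distance between its
reconstruction and the fully sampled ground truth, using RMSProp.  The L1
objective is reduced by the mean (not the sum) so the learning rate
transfers across image sizes.  Evaluation follows the accelerated-MRI
convention: NMSE, PSNR and SSIM per slice, averaged within a volume and then
across volumes, with the data range taken as the maximum of the ground-truth
volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import uniform_filter

from . import autodiff as ad
from .autodiff import Tensor
from .network import MLPED, Module
from .phantom import SyntheticSample
from .transforms import MagnitudeImage, zero_filled_recon

__all__ = [
    "TrainConfig",
    "MetricReport",
    "RMSProp",
    "l1_loss",
    "nmse",
    "psnr",
    "ssim",
    "network_input",
    "reconstruct_slice",
    "train",
    "evaluate",
]


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 0.001
    optimizer: Literal["rmsprop"] = "rmsprop"
    batch_size: int = 1
    seed: int = 0
    device: Literal["cpu", "gpu"] = "cpu"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.optimizer != "rmsprop":
            raise ValueError("only the rmsprop optimizer is supported")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def to_dict(self) -> dict:
        return {
            "epochs": self.epochs, "learning_rate": self.learning_rate,
            "optimizer": self.optimizer, "batch_size": self.batch_size,
            "seed": self.seed, "device": self.device,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class MetricReport:
    nmse: float
    psnr: float
    ssim: float
    grouping: Literal["per_slice", "per_volume"] = "per_volume"
    volume_id: int = 0


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _as_array(img) -> np.ndarray:
    return np.asarray(img.data if isinstance(img, MagnitudeImage) else img,
                      dtype=np.float64)


def l1_loss(recon, gt):
    """Mean absolute per-pixel difference.

    Accepts autodiff tensors (returning a differentiable scalar node) or
    plain arrays / magnitude images (returning a float).
    """
    if isinstance(recon, Tensor) or isinstance(gt, Tensor):
        recon_t = recon if isinstance(recon, Tensor) else Tensor(_as_array(recon))
        gt_t = gt if isinstance(gt, Tensor) else Tensor(_as_array(gt))
        return ad.mean_abs_error(recon_t, gt_t)
    a, b = _as_array(recon), _as_array(gt)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean())


def nmse(gt, pred) -> float:
    """Normalised mean squared error: ||gt - pred||^2 / ||gt||^2."""
    g, p = _as_array(gt), _as_array(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {p.shape}")
    denom = float(np.sum(g ** 2))
    if denom == 0.0:
        raise ValueError("nmse undefined for an all-zero ground truth")
    return float(np.sum((g - p) ** 2) / denom)


def psnr(gt, pred, data_range: float) -> float:
    """Peak signal-to-noise ratio 10*log10(data_range^2 / MSE), in dB.

    Returns +inf when the images are identical.
    """
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    g, p = _as_array(gt), _as_array(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {p.shape}")
    mse = float(np.mean((g - p) ** 2))
    if mse == 0.0:
        return math.inf
    return float(10.0 * np.log10(data_range ** 2 / mse))


def ssim(gt, pred, data_range: float, win_size: int = 7,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean local structural similarity with a uniform window.

    Local means, variances and covariance are estimated with a ``win_size``
    uniform filter using the sample-covariance normalisation N/(N-1); the
    mean is taken over the interior region where the window fits entirely
    (the accelerated-MRI evaluation convention).
    """
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    g, p = _as_array(gt), _as_array(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {p.shape}")
    if min(g.shape) < win_size:
        raise ValueError(f"images smaller than the {win_size}x{win_size} window")
    npix = win_size ** 2
    cov_norm = npix / (npix - 1)
    ux = uniform_filter(g, size=win_size)
    uy = uniform_filter(p, size=win_size)
    uxx = uniform_filter(g * g, size=win_size)
    uyy = uniform_filter(p * p, size=win_size)
    uxy = uniform_filter(g * p, size=win_size)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    score = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)
    )
    pad = (win_size - 1) // 2
    return float(score[pad:-pad, pad:-pad].mean())


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class RMSProp:
    """RMSProp with the usual defaults (decay 0.99, eps 1e-8, no momentum)."""

    def __init__(self, params: Sequence, lr: float = 0.001,
                 alpha: float = 0.99, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.square_avg = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.square_avg):
            if p.grad is None:
                continue
            g = p.grad
            v *= self.alpha
            v += (1.0 - self.alpha) * g * g
            p.data = p.data - self.lr * g / (np.sqrt(v) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


# ---------------------------------------------------------------------------
# reconstruction helpers
# ---------------------------------------------------------------------------

def network_input(sample: SyntheticSample) -> np.ndarray:
    """Zero-filled (aliased) magnitude image for one sample."""
    target = sample.ground_truth.data.shape
    zf = zero_filled_recon(sample.kspace, sample.mask, target)
    return zf.data


def reconstruct_slice(model: MLPED, aliased: np.ndarray) -> np.ndarray:
    """Standardise, run the network, undo the affine, clip to non-negative.

    Each input slice is standardised to zero mean / unit variance; the
    inverse affine is applied to the network output so reconstructions live
    in the original intensity units.
    """
    mu = float(aliased.mean())
    sd = float(aliased.std()) + 1e-8
    x = Tensor(((aliased - mu) / sd).astype(np.float32)[None, None])
    out = model(x)
    recon = out.data[0, 0].astype(np.float64) * sd + mu
    return np.clip(recon, 0.0, None)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(model: MLPED, data: Sequence[SyntheticSample],
          config: TrainConfig) -> tuple[MLPED, list[float]]:
    """Train in place; returns the model and per-epoch mean L1 losses.

    Per epoch the sample order is reshuffled from ``config.seed``; each step
    standardises the zero-filled input, runs the forward pass, de-standardises
    the output and takes an RMSProp step on the mean-L1 loss against the
    ground truth.  Fully reproducible for a fixed seed.
    """
    if len(data) == 0:
        raise ValueError("cannot train on an empty dataset")
    rng = np.random.default_rng(config.seed)
    model.train()
    optimizer = RMSProp(model.parameters(), lr=config.learning_rate)
    inputs = [network_input(s) for s in data]
    targets = [s.ground_truth.data for s in data]
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(data))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, stats = [], []
            for i in idx:
                mu = float(inputs[i].mean())
                sd = float(inputs[i].std()) + 1e-8
                xb.append(((inputs[i] - mu) / sd).astype(np.float32))
                stats.append((mu, sd))
            x = Tensor(np.stack(xb)[:, None])
            out = model(x)
            # undo the per-slice standardisation before the loss
            mus = np.array([m for m, _ in stats], dtype=np.float32)
            sds = np.array([s for _, s in stats], dtype=np.float32)
            if len(idx) == 1:
                recon = ad.scalar_affine(out, float(sds[0]), float(mus[0]))
            else:
                scale = Tensor(sds.reshape(-1, 1, 1, 1))
                shift = Tensor(mus.reshape(-1, 1, 1, 1))
                recon = ad.add(ad.mul(out, scale), shift)
            gt = Tensor(np.stack([targets[i] for i in idx])[:, None]
                        .astype(np.float32))
            loss = ad.mean_abs_error(recon, gt)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return model, history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(model: MLPED | None, data: Sequence[SyntheticSample],
             grouping: Literal["per_slice", "per_volume"] = "per_volume",
             ) -> list[MetricReport]:
    """NMSE/PSNR/SSIM of reconstructions against ground truth.

    With ``model=None`` the zero-filled input itself is scored (the aliased
    baseline).  Slices sharing a ``volume_id`` form a volume; the data range
    is the ground-truth maximum over the volume.  ``per_volume`` averages the
    per-slice metrics within each volume and returns one report per volume.
    """
    if len(data) == 0:
        raise ValueError("cannot evaluate an empty dataset")
    if model is not None:
        model.eval()
    volumes: dict[int, list[SyntheticSample]] = {}
    for s in data:
        volumes.setdefault(s.volume_id, []).append(s)
    reports: list[MetricReport] = []
    for vid in sorted(volumes):
        slices = volumes[vid]
        data_range = max(float(s.ground_truth.data.max()) for s in slices)
        if data_range <= 0:
            raise ValueError(f"volume {vid} has an empty ground truth")
        per_slice = []
        for s in slices:
            aliased = network_input(s)
            recon = (reconstruct_slice(model, aliased)
                     if model is not None else aliased)
            gt = s.ground_truth.data
            per_slice.append(MetricReport(
                nmse=nmse(gt, recon),
                psnr=psnr(gt, recon, data_range),
                ssim=ssim(gt, recon, data_range),
                grouping="per_slice", volume_id=vid,
            ))
        if grouping == "per_slice":
            reports.extend(per_slice)
        else:
            reports.append(MetricReport(
                nmse=float(np.mean([r.nmse for r in per_slice])),
                psnr=float(np.mean([r.psnr for r in per_slice])),
                ssim=float(np.mean([r.ssim for r in per_slice])),
                grouping="per_volume", volume_id=vid,
            ))
    return reports
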