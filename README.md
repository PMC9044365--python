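# mlped

Accelerated multi-coil MRI reconstruction with a **multi-level pooling
encoder–decoder network (MLPED)**, plus a self-contained parallel-imaging
simulator so the whole pipeline runs without any external dataset.

## The problem

MRI acquisition is slow because k-space (the spatial-frequency domain) is
sampled line by line.  Parallel imaging accelerates this by recording with
*N* receive coils at once and skipping phase-encoding columns; each coil *i*
sees the object *x* through its smooth complex sensitivity map *Sᵢ*:

```
kᵢ = F(Sᵢ x) + αᵢ ,   i = 1 … N
```

where *F* is the 2-D Fourier transform and *αᵢ* complex Gaussian measurement
noise.  Dropping columns (4- or 8-fold) violates the Nyquist criterion, so
the naive "zero-filled" reconstruction — inverse FFT of each coil, combined
by root sum of squares,

```
x_combine = ( Σᵢ |xᵢ|² )^{1/2} ,
```

— is contaminated by aliasing ghosts.  The network learns to remove them:

```
x_recon = D(M(E(x_combine,undersampled)))
```

with a five-level convolutional encoder *E* (channel widths 32, 64, 128,
256, 384, joined by 2×2 average pooling), four **multi-level pooling
modules** *M* on the skip paths (residual multi-kernel max pooling at
windows 2/3/5/6 with 1×1 reductions, followed by a three-convolution
Zoom-In/Zoom-Out stage with zoom factor 2, plus a residual connection), and
a decoder *D* that upsamples with pixel shuffle (sub-pixel convolution).
The default model has **7,886,593 trainable parameters (≈ 8 M)**.  Training
minimises the mean L1 error against the fully sampled reference with
RMSProp (lr 0.001); evaluation reports NMSE, PSNR and SSIM.

The network runs on a compact numpy reverse-mode autodiff engine included
in the package (`mlped.autodiff`) — no deep-learning framework required.

## Worked example

Train a reduced model (8 first-level channels) on simulated 64×64 15-coil
acquisitions at 4-fold acceleration — about a minute on one CPU core:

```python
import numpy as np
from mlped import (NetworkConfig, PhantomSpec, TrainConfig, build_mlped,
                   count_trainable_parameters, evaluate, simulate_dataset, train)

cfg = NetworkConfig(first_channels=8)          # reduced desk-scale model
model = build_mlped(cfg, seed=0)
print(f"trainable parameters: {count_trainable_parameters(model):,}")

spec = PhantomSpec(size=(64, 64), seed=0)
train_set = simulate_dataset(20, spec, n_coils=15, acceleration=4, seed=0)
heldout   = simulate_dataset(4,  spec, n_coils=15, acceleration=4, seed=1000)

model, history = train(model, train_set,
                       TrainConfig(epochs=10, learning_rate=1e-3, seed=0))
print(f"epoch-mean L1 loss: {history[0]:.4f} -> {history[-1]:.4f}")

baseline = evaluate(None, heldout)    # zero-filled (aliased) input
recon    = evaluate(model, heldout)   # network reconstruction
print(f"zero-filled  PSNR {np.mean([r.psnr for r in baseline]):.2f} dB, "
      f"SSIM {np.mean([r.ssim for r in baseline]):.3f}")
print(f"reconstructed PSNR {np.mean([r.psnr for r in recon]):.2f} dB, "
      f"SSIM {np.mean([r.ssim for r in recon]):.3f}")
```

Output:

```
trainable parameters: 507,313
epoch-mean L1 loss: 0.1131 -> 0.0420
zero-filled  PSNR 18.18 dB, SSIM 0.543
reconstructed PSNR 22.62 dB, SSIM 0.855
```

After 200 optimiser steps the network already recovers ~4.4 dB over its
aliased input on held-out phantoms: the de-aliasing behaviour the
architecture is designed for, at desk scale.

## Command line

```sh
mlped simulate --n 4 --coils 15 --accel 4 --seed 7 --out data/
mlped train --config run.yaml --out runs/
mlped evaluate --config run.yaml --checkpoint runs/model.npz --out metrics.tsv
mlped reconstruct data/volume_000.h5 --accel 4 --out recon.h5
```

Volumes use the public accelerated-MRI HDF5 dialect (datasets `kspace`,
shaped slices × coils × rows × columns, and `reconstruction_rss`), so real
multi-coil scanner exports drop in unchanged.

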