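# rcstpat — sparse-view photoacoustic image restoration

Photoacoustic tomography (PAT) reconstructs optical absorption from
laser-induced ultrasound recorded on a ring of detectors. Using only a
subset of the ring (sparse view: 32 or 64 of 256 elements) cuts acquisition
time and hardware cost, but delay-and-sum reconstructions from sparse data
are corrupted by radial streak artifacts. `rcstpat` removes those artifacts
with a **residual-conditioned sparse transformer (RCST)**: a U-shaped
transformer restoration network that runs in two phases, using the transport
residual of its own first pass as an explicit encoding of the degradation to
condition the second pass.

The package is self-contained for experimentation: it ships a seeded phantom
generator (vessel trees and disks), an analytic circular-Radon forward model
of a 256-element / 270° / 45.5 mm ring scanner, and delay-and-sum
back-projection — so paired (sparse-view, dense-view) training data is
manufactured on the fly, no downloads.

## Method

The restoration map `T` is trained as an optimal-transport problem between
the degraded domain and the clean domain. Writing r̂ = y − T(y) for the
transport residual, the objective is

    max_ω min_θ  E_x[φ_ω(x)] + E_y[ c(T_θ(y), y) + λ_g‖F(y − T_θ(y))‖₁ − φ_ω(T_θ(y)) ]
                 + (γ/|M|) Σ_(y,x) ‖T_θ(y) − x‖²

with `c` a mean-absolute transport cost, an ℓ1 penalty on the 2-D Fourier
transform of the residual (streaks are sparse, structured spectra), a
convolutional critic φ as the dual potential, and paired ℓ2 supervision.

The network itself (see `docs/methods.md` for the full account):

- **Two-phase residual conditioning** — x̂₁ = G(y); r̂₀ = y − x̂₁; output
  = G(y | E(r̂₀)), with a strided-conv pyramid E injecting the encoded
  residual at the bottleneck and each decoder level through learnable gates.
- **Top-k sparse channel attention (TKSA)** — per head, the Ĉ×Ĉ transposed
  attention matrix keeps only the k = ⌈ratio·Ĉ⌉ largest scores per row
  before a masked softmax; ratio 1 recovers dense attention exactly.
- **Mixed-scale feed-forward network (MSFN)** — parallel 3×3 and 5×5
  depth-wise branches with a cross-fed second stage.

Training and the network run on a small NumPy reverse-mode autodiff core
bundled with the package (float64, single-threaded, bit-reproducible on
CPU under a fixed seed).

## Worked example

```python
import numpy as np
from rcstpat import (PhantomSpec, SensorGeometry, make_paired_dataset,
                     ModelConfig, TrainConfig, fit, psnr, ssim)

# 20 seeded vessel phantoms on a 64x64 grid, reconstructed from 32 of 256
# detectors (degraded) and all 256 (target)
geom = SensorGeometry.for_grid(64, n_time=512)
specs = [PhantomSpec(seed=s) for s in range(20)]
pairs = make_paired_dataset(specs, rates=[32], geom=geom, size=64)

print("degraded SSIM: %.3f" % np.mean(
    [ssim(p.degraded.values, p.target) for p in pairs]))

# desk-scale training: 16 pairs, 8-channel model, 300 alternating steps
state = fit(pairs[:16], pairs[16:],
            ModelConfig.toy(seed=0),
            TrainConfig(seed=0, epochs=100, patch=64, max_steps=300))

gain = np.mean([psnr(state.model.restore(p.degraded.values), p.target)
                - psnr(p.degraded.values, p.target) for p in pairs[16:]])
print("held-out PSNR gain: %+.2f dB" % gain)
```

Typical output (a few minutes on one CPU):

```
degraded SSIM: 0.643
held-out PSNR gain: +1.06 dB
```

The first number says sparse-view reconstructions at 32 projections are
heavily streaked (SSIM ≈ 0.64 against the dense-view target); the second
says 300 training steps of the toy model already recover about 1 dB on
phantoms never seen in training (the exact gain varies with the phantom
seed; +1 to +3 dB is typical).

The same pipeline is scriptable from the shell:

```bash
rcst-pat phantoms --kind vessel --n 16 --size 256 --seed 0 --out phantoms/
rcst-pat simulate --n-phantoms 64 --rates 32,64,128 --size 64 --n-time 512 --seed 0 --out data/
rcst-pat train --data data/ --out runs/
rcst-pat eval --ckpt runs/epoch_0010.npz --data data/ --out report/
rcst-pat profile --image phantoms/phantom_0000.tiff --y0 32 --x0 0 --y1 32 --x1 63
```

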