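# Methods

This note documents the models, numerical choices and limitations of
`rcstpat`: a sparse-view photoacoustic tomography (PAT) restoration package
built around a residual-conditioned sparse transformer and a self-contained
analytic acoustic simulator.

## The restoration problem

Ring-array PAT scanners record laser-induced ultrasound on a circular
detector arc; reconstructing from a subset of the detectors (sparse view:
32 or 64 of 256 elements) cuts acquisition cost but leaves radial streak
artifacts in delay-and-sum reconstructions. The package treats artifact
removal as learned image restoration: a network T maps a degraded
sparse-view reconstruction y to an estimate of the dense-view image x.

## Degradation simulator

### Geometry

Defaults emulate a 256-element ring scanner: detectors on a 270° arc of
radius 45.5 mm, sound speed 1530 m/s, 2030 time samples, a 256 × 256
imaging grid with 0.1 mm pixels. Angles are measured from the +x axis,
counter-clockwise, with the arc gap centred on +x; detectors are evenly
spaced with half-open spacing (arc/n), so stride subsampling of the ring
(256 → 128/64/32) again yields an evenly spaced ring. The time step is
derived from the grid: c·dt·n_time = 1.15 × the maximum detector–pixel
distance, and geometries that cannot cover the grid fail fast.

### Forward model

In 2-D, an ideal point detector's trace is governed by the circular means
of the initial pressure over circles centred on the detector (the circular
Radon transform). `forward_project` evaluates entry (i, t) as the line
integral of the pressure map over the circle of radius c·t·dt centred on
detector i, by bilinear sampling along the arc segment that can intersect
the imaging square (arc step = half a pixel). This is exactly linear in
the source, rotationally covariant, and reproduces the feature that
matters for this package — streaks that intensify as projections drop —
at a tiny fraction of the cost of a pseudospectral wave solver. A full
wave solver would additionally model the absorbing boundary and finite
transducer bandwidth (the hardware's 40 MHz centre frequency); neither is
modelled — detectors are ideal broadband points, because bandwidth
filtering is orthogonal to the angular-subsampling artifact being studied.

A note on symmetry tolerances: a centred rotationally symmetric source
should give identical traces on all detectors. With bilinear sampling of a
*rasterized* source this holds only up to the spatial interpolation error,
O(h²·f'') ≈ 1e-3 relative for a smooth blob on a 64-grid, because the
270°/256 detector set is not a symmetry of the pixel raster. The tests
therefore assert machine-level symmetry (< 1e-6) on a 4-detector/360°
geometry whose 90° spacing *is* a raster symmetry, and 1e-3 on the
standard ring — the a-priori interpolation bound, not a fitted number.

### Reconstruction

`backproject` is delay-and-sum: each pixel sums, over detectors, the trace
value linearly interpolated at the time of flight for the pixel–detector
distance, normalized by detector count. Traces are pre-filtered along
time; the default is a ramp (|ω|) filter. Rationale: the detector ring
(45.5 mm) is far from the small imaging area (≤ 12.8 mm), so the circular
Radon transform is locally a linear Radon transform, for which the ramp is
the classical FBP kernel. It sharpens edges, keeps a peaked source's
maximum at the source (a pure first-difference filter turns blobs into
edge maps and migrates the maximum under the limited view), and produces
pronounced streaks under subsampling — SSIM against the dense target falls
from ≈ 0.99 at 128 projections to ≈ 0.65 at 32 on vessel phantoms.
First-difference ("diff") and unfiltered ("none") variants remain
available.

### Paired data

`make_paired_dataset` forward-projects each phantom once, reconstructs the
dense 256-projection image as the target (min–max normalized to [0, 1]; the
raw pressure map is available via a switch, matching the convention that
experimental ground truth is itself a dense-view reconstruction), and
reconstructs each requested sparse rate as the degraded input. Everything
is a deterministic function of the phantom specs; the simulator itself is
noise-free.

### Phantoms

Two seeded generators stand in for experimental imagery. Vessel trees:
biased random walks that branch with probability 0.08 per step and taper
multiplicatively, rasterized as tubes (1–6 px wide) with a smooth
quadratic rim and exactly-zero background; total drawn length targets a
seeded 5–16 % foreground fraction (the contract tested is 2–25 % over 100
seeds). Disks: anti-aliased disks with non-colliding centres and radii
3–12 % of the grid. Both are bit-deterministic in (spec, seed). What they
do **not** emulate: optical fluence heterogeneity, acoustic noise, tissue
texture; a network trained on them demonstrates that the pipeline learns,
not that it transfers to animal data.

## Restoration network

The restoration map runs a U-shaped encoder–decoder of Sparse Transformer
Blocks twice. Phase one produces a preliminary restoration x̂₁ = G(y); the
transport residual r̂₀ = y − x̂₁ (held exactly, bitwise, by construction)
carries the degradation fingerprint. Phase two re-runs the *same*
generator on y with a strided-conv pyramid encoding of r̂₀ injected at the
bottleneck and every decoder level through gated fusion
(feat + g ⊙ proj(embed), per-channel gate, init 0.1): zeroing every gate
makes phase two coincide exactly with phase one, which is the ablation
equality the tests assert.

Inside each block, channel attention with top-k sparsity (TKSA): 1×1 then
3×3 depth-wise convolutions form Q, K, V; each channel's spatial profile
in Q and K is L2-normalized (cosine-similarity attention), so per head the
Ĉ×Ĉ transposed attention matrix M = QKᵀ/λ is scale- and image-size-free —
without this normalization the Gram scores grow with H·W, the softmax
saturates into a brittle argmax, and desk-scale training stalls. M is
masked to its k = ⌈ratio·Ĉ⌉ largest entries per row (stable tie-break by
lowest index) before a masked softmax that renormalizes over exactly the
retained entries. λ is a learnable per-head scalar initialized at 1 — a
learnable scalar subsumes the usual √d convention. Per-head ratios cycle
through {1/2, 2/3, 3/4, 4/5}; ratio 1 reduces the block to dense
transposed attention to machine precision. The feed-forward half (MSFN)
expands channels 2× with a 1×1 convolution, runs parallel 3×3 and 5×5
depth-wise branches, cross-feeds them in a second stage, and fuses with a
1×1 convolution plus residual. Normalization is bias-free LayerNorm over
channels at each spatial site. Downsampling is pixel-unshuffle followed by
1×1 reduction (C → 2C, H/2); upsampling is the mirror image; skip
connections concatenate encoder features into the decoder with a 1×1
merge.

Defaults: 4 levels, (2, 3, 3, 4) blocks, 48 base channels, (1, 2, 4, 8)
heads — standard restoration-transformer scaling, fully overridable. The
`toy()` preset (8 channels, 3 levels, 1 block/level, ≈ 13 k parameters) is
what every desk-scale experiment uses.

Initialization is residual-friendly throughout: the output head (3×3
conv to 1 channel, added to y as a global residual), every attention
output projection, and every MSFN fusion convolution start at **zero**, so
each residual branch is inert and the untrained network is exactly the
identity map. Training grows the branches from the degraded baseline
instead of fighting a random-amplitude output — at desk scale this is the
difference between a restoration gain and divergence within the step
budget. All other convolutions use seeded He-normal initialization.

All tensors are (C, H, W) float64 without a batch axis (the protocol uses
batch size 1); the network and its training loop run on a small
reverse-mode autodiff core written on NumPy (`rcstpat.autodiff`), with
hand-written forward/backward kernels for grouped convolution, masked
softmax and the Fourier penalty, each validated against finite
differences.

## Training objective and protocol

The generator and a five-layer strided-conv critic φ (scalar mean output,
no sigmoid) play the minimax game

    max_ω min_θ E[φ_ω(x)] + E[ c(T_θ(y), y) + λ_g·g(y − T_θ(y)) − φ_ω(T_θ(y)) ]
                + (γ/|M|) Σ ‖T_θ(y) − x‖²

Choices the formulation leaves open, and how they are fixed here:

- transport cost c = mean absolute difference (the standard restoration
  transport cost; keeps the terms on comparable scales);
- residual penalty g = ℓ1 norm of the unnormalized 2-D DFT of the
  residual, mean-normalized inside the loss (λ_g = 0.01); the identities
  g(0) = 0, g(2r) = 2g(r), g(δ) = H·W hold exactly and the training loop
  calls the same public function;
- paired weight γ = 100 with |M| = batch size, so paired supervision
  dominates (RMSprop's per-parameter normalization makes the loss *scale*
  nearly irrelevant — what γ sets is the gradient *direction*);
- critic Lipschitz control by weight clipping at 0.01 (gradient penalty
  available), one critic step per generator step, expectations estimated
  by the single-sample minibatch.

Two further supervision choices: the phase-1 preliminary restoration
x̂₁ receives its own paired ℓ2 term at weight 0.5·γ (`stage1_weight`) —
both phases share weights, and supervising the first pass directly shapes
the residual that conditions the second; and each training crop is
augmented by a seeded rotation (k·90°) and horizontal flip, which at
16-image scale is what closes the train/held-out generalization gap.

Protocol: RMSprop (α = 0.99, ε = 1e-8, heavy-ball momentum 0.9), default
learning rate 1e-4 with the generator at half that, critic rate halved
every 20 epochs, batch 1, random seeded patch crops (128 × 128 at full
scale; clamped to the image and to pyramid divisibility at toy scale),
checkpoints every 10 epochs, per-epoch validation PSNR/SSIM. The momentum
term is what makes a 300-step desk-scale budget sufficient for a
measurable restoration gain; without it held-out PSNR barely moves. Each
iteration runs the generator once: the critic updates on the detached
output, then the generator update backpropagates through the freshly
updated critic. Training is bit-reproducible on CPU under a fixed seed,
and a saved `TrainState` resumes the exact trajectory.

## Metrics

PSNR uses data range 1.0 on normalized images; identical images are
reported as a 999 dB sentinel to keep CSVs numeric. SSIM uses the uniform
7 × 7 window with C1 = (0.01·range)², C2 = (0.03·range)² (Gaussian window
behind a flag); both delegate to scikit-image. Intensity profiles are
bilinear samples at equally spaced points on a user-chosen segment.
Because the SSIM window/constants and PSNR range are conventions, absolute
metric values are comparable only within runs of this package.

## Problem sizes for desk-scale experiments

All bundled experiments run on a 64 × 64 grid with 512 time samples, 20
vessel phantoms, and the toy network: the degradation-monotonicity
experiment averages SSIM over 20 phantoms at 32/64/128 projections; the
learning-signal experiment trains on 16 rate-32 pairs for 300 alternating
steps (≈ 2–3 minutes on one CPU) and evaluates on 4 held-out phantoms,
where it typically recovers +1 to +3 dB over the degraded input.
These sizes are the package's own test-scale choices; the architecture and
protocol scale to the full 256 × 256 / 2030-sample configuration
unchanged.

## Known limitations

- The forward model omits transducer bandwidth, directivity, acoustic
  attenuation and heterogeneous sound speed; it is a degradation
  generator, not a calibrated scanner model.
- Desk-scale training (13 k parameters, 300 steps) demonstrates a
  learning signal, not publication-scale restoration quality; the
  adversarial term is essentially inert at this scale and the paired term
  does the work.
- The float64 NumPy backend is single-threaded and CPU-bound; full-scale
  (256 × 256, 48-channel, 150-epoch) training is out of reach without a
  GPU framework, and the package makes no attempt at it.
- Per-image min–max normalization means absolute intensities are not
  preserved across images; metrics are computed in normalized units.
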