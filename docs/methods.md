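# Methods

## Model

`diffbts` performs three-target brain-lesion segmentation (Whole Tumor,
Tumor Core, Enhancing Tumor, nested ET ⊆ TC ⊆ WT) by denoising diffusion
over the label volume. Binary labels are mapped to the `{-1, +1}` latent
scale; the forward process `x_t = √ᾱ_t x_0 + √(1−ᾱ_t) z` with
`ᾱ_t = ∏_{i≤t}(1−β_i)` destroys them into Gaussian noise over `T` steps,
and a conditional denoiser learns the reverse map. Sampling is the
deterministic non-Markovian rule
`x_{t−1} = √ᾱ_{t−1} x̂_0 + √(1−ᾱ_{t−1}) ε`, with `ᾱ_0 := 1` so the final
step emits the clean prediction exactly; subsampled step lists make the
rule jump `t → t'` for any `t' < t`. Predictions are binarized at latent
0 (probability 0.5).

**Noise schedule.** Linear `β` from 1e-4 to 2e-2 over `T = 1000` steps
(a squared-cosine signal schedule is available). The guidance algorithm
is schedule-agnostic; these are the standard diffusion defaults. Reverse
sampling uses 10 uniformly spaced steps by default (5 in the scaled-down
study) — segmentation latents are strongly determined by the MRI
conditioning, so few deterministic steps suffice.

**Denoiser.** A UNet-style encoder–decoder over the 7-channel input
(3 noisy label channels + 4 modality channels). Per level: two 3×3×3
convolutions with group normalization and SiLU; 2× max-pooling between
levels; kernel-2 stride-2 transposed convolutions for upsampling; channel
concatenation with the skip path; zero-initialized 1×1×1 output head.
The sinusoidal step encoding passes through two linear maps with a SiLU
between them, and each block injects it after its first convolution via a
further linear map and SiLU. Inputs must be divisible by `2^(depth−1)`;
the sliding-window tiler handles larger or odd volumes.

*Parameterization.* The network predicts the clean latent `x̂_0`; the
noise estimate used by the sampler is derived by inverting the forward
process, `ε = (x_t − √ᾱ_t x̂_0)/√(1−ᾱ_t)`. The training loss is defined
on `x̂_0`, and predicting `ε` instead would amplify network error in the
loss by `1/√ᾱ_t` — about 150× at `t = T` under the default schedule —
which in practice makes the loss explode at high noise levels. Both
quantities are returned by `denoise()`, matching the sampler's
`x̂_0, ε_t ← Model(x_t)` interface.

*Width schedule.* Channel widths start at `base_width` (default 32) and
double per level, capped at 4× the base (multipliers 1, 2, 4, 4, …), the
convention of standard diffusion UNets, which keeps the deepest level
from dominating the budget. At depth 3 this is pure doubling
(32/64/128); depth 4 costs ≈ 2.7× the parameters of depth 3, consistent
with the lightweight-depth design point the architecture targets.

*Attention.* Each pre-pool feature map passes through 3D multi-head
efficient self-attention before feeding its skip connection:
`E(Q,K,V) = [C^(−1/4) softmax_ch(Q)] [(C^(−1/4) softmax_pos(K))ᵀ V]`
per head, heads split along channels and re-concatenated, followed by an
output projection and a residual connection. The softmax axes (channels
for Q, positions for K) are the only choice that makes the factorization
a normalized attention; the `C^(−1/4)` factor on each softmax output
(net `C^(−1/2)`, with `C` the full channel count) compensates the longer
flattened sequences of 3D volumes. The value aggregate
`(softmax_pos K)ᵀV` is a `d×d` context matrix independent of the number
of positions, so cost is linear in `n = D·H·W` and no `n×n` matrix is
ever materialized. The output projection is zero-initialized so each
block starts as the identity. The bottleneck level carries no attention
(its features do not feed a skip path); `heads` defaults to 4, reduced
to the channel count when narrower.

## Edge-blurring guided sampling

Deterministic sampling trades the diversity of the generative model for
reproducibility, but boundary voxels remain the least certain part of a
segmentation. EBG pushes each reverse step away from a version of its own
prediction whose boundaries have been degraded:

1. `ε_t, x̂_0 ← Model(x_t)`;
2. binarize `x̂_0` at latent 0 and mark every voxel with at least one
   differing neighbor (6-connectivity by default, 26 optional; volume
   borders replicate-padded so border-touching regions produce no
   spurious edges) — per-target masks `M_wt, M_tc, M_et`, concatenated
   into `M_t`;
3. Gaussian-blur `x̂_0` (separable kernel 3, σ = 1 voxel — the mildest
   perturbation that changes boundary voxels; blurring precedes any
   binarization so the graded prediction is what gets degraded);
4. re-noise the blur to the current step with the *same* noise `ε_t`
   (keeping the whole procedure deterministic given `x_T`);
5. swap the re-noised blur into the latent on boundary voxels only:
   `x̂_t = (1−M_t)⊙x_t + M_t⊙x̃_t`;
6. `ε̂ ← Model(x̂_t)`; extrapolate `ε̃ = ε̂ + (1+s)(ε_t − ε̂)` and take the
   deterministic step with `ε̃`.

At `s = 0` the extrapolation collapses to `ε_t` exactly; when every mask
is empty, `x̂_t = x_t` implies `ε̂ = ε_t` and guidance is inert for any
`s`. Both degeneracies are exercised as tests. The default `s = 0.05` is
the operating point for segmentation; the admissible range is `s > −1`.

**Uncertainty fusion.** Every reverse step contributes its `x̂_0`
(as probability `p = (x̂_0+1)/2`, clipped to [0, 1]). Per voxel and
channel, step `i` (sampling order, so later steps have larger `i`) gets
weight `w_i = exp(sigmoid((i+1)/10)·(1 − u(p_i)))` with entropy
uncertainty `u(p) = −p ln p` (natural log; `0·ln 0 := 0`; maximum `1/e`
at `p = 1/e`). Weights are normalized to sum to one per voxel — the
weighted sum is otherwise scale-ambiguous — and the fused probability is
binarized at 0.5. Uncertainty is computed per channel, matching the
three-channel prediction. Later-step weights strictly dominate at equal
uncertainty, encoding that reverse-process predictions sharpen as `t`
decreases.

## Training and inference

Training draws `t ~ U[1, T]` per sample, noises the label latent via the
forward process, and minimizes `L = L_Dice + L_BCE + L_MSE` (unweighted
sum; each term averaged over channels and voxels) between `x̂_0` and the
reference latent. For the Dice and BCE terms the prediction maps to a
clipped probability `p = clip((x̂_0+1)/2, 1e−7, 1−1e−7)`; the MSE term
compares latents directly. Optimization is AdamW (decoupled weight
decay 1e-3) with cosine-annealed learning rate from 1e-4 (full-scale
default) and batch size 2; runs are deterministic given the seed.
Divergence (non-finite loss) aborts with the epoch/batch/step indices.

Inference tiles volumes larger than the window with overlap 0.5 (window
origins at multiples of `window·(1−overlap)` plus a final flush-aligned
window), samples each window independently from its own seeded normal
latent, averages probabilities uniformly over overlaps, and thresholds at
0.5. A window exceeding the volume falls back to a single whole-volume
pass with a logged warning.

## Metrics

Dice `2|A∩B|/(|A|+|B|)` (1 when both masks are empty), Recall `|A∩B|/|B|`
(1 when the reference is empty — there are no positives to find), and
HD95: the maximum of the two directed 95th-percentile surface distances,
mirroring the max-of-directed structure of the Hausdorff distance,
computed between 6-connectivity boundary voxels (the same boundary
definition as the edge masks) via exact Euclidean distance transforms
with physical voxel spacing (BraTS volumes are 1 mm isotropic; the
phantoms carry explicit spacing). Empty masks yield an explicit NaN
sentinel; summary means skip undefined values and report how many were
skipped, rather than silently distorting averages.

## Synthetic phantoms

The generator emulates the *structure* of BraTS cases at desk scale: each
case places 1–2 ellipsoidal lesions with three concentric regions (semi-
axes drawn per axis from disjoint WT > TC > ET ranges, so nesting holds
by construction) on a homogeneous unit-intensity background. Each
modality surrogate renders the regions with its own contrast offsets —
the enhancing core brightest in the T1ce surrogate, the edema rim
brightest in the FLAIR surrogate, T2 bright over the whole lesion, T1
hypointense core — plus i.i.d. Gaussian noise (σ = 0.1 against region
contrasts of 0.2–1.0), then is z-score normalized. Labels derive exactly
from the generating geometry.

What the phantoms do **not** emulate: anatomical background texture,
bias fields, partial-volume effects, irregular lesion shapes, inter-site
intensity variation, or class imbalance at real-volume scale. Passing
the end-to-end checks therefore demonstrates that the pipeline —
conditioning, training, guided sampling, fusion, evaluation — is
internally correct and learnable, not that the model reaches clinical
BraTS accuracy; the published benchmark numbers require the real
datasets and GPU-scale training and are out of scope here.

## The scaled-down study

`diffbts.experiments.run_toy_study` fixes one desk-scale protocol, used
by both the test suite and `scripts/acceptance.py`: forty 24³ phantoms
(WT semi-axes 4.5–7 voxels so lesions occupy a realistic fraction of the
field of view), split 30 train / 10 held-out; a depth-2, base-width-8
denoiser (≈ 23k parameters); `T = 1000`, 20 epochs, batch 2, learning
rate 1e-3 (the 1e-4 full-scale default pairs with 300-epoch schedules
and is too conservative for 20 epochs on a model this small); 5-step
sampling. Guidance scales are compared on the same trained weights and
the same per-case initial noise, so differences isolate the guidance
term. The run takes a few minutes on one CPU and reaches mean held-out
WT Dice ≈ 0.9.

## Numerical and engineering choices

- Gradients come from HIPS `autograd` over a small set of fused
  primitives: convolution as one im2col gather plus one BLAS GEMM with
  hand-written VJPs (the input gradient is itself a flipped-kernel
  correlation, so the backward pass is also gather+GEMM, no scatter);
  fused sigmoid/SiLU/softmax/group-norm VJPs. Parameters and training
  tensors are float32; schedule tables are float64.
- Group count for normalization is reduced to the largest divisor of the
  channel count; `ᾱ` consistency is validated at construction to 1e-12;
  `softmax` uses max-shift; BCE probabilities are clipped at 1e-7.
- Determinism: phantom generation, batching, time-step draws, initial
  latents and window seeds all derive from explicit seeds;
  the sampler itself is noise-free by construction.
- Degenerate inputs: empty edge masks are valid (guidance inert); empty
  masks in metrics yield sentinels; `subsample_steps(T, 1)` yields `[T]`
  and the single step emits `x̂_0` directly.

## Known limitations

- CPU-scale only: the full BraTS protocol (155×240×240, depth 3, width
  32, 300 epochs) is supported by the code but not by desk hardware.
- The phantom realism gap above; no augmentation pipeline.
- `autograd` supports first-order gradients only (sufficient here).
- Sliding-window fusion averages probabilities uniformly; a
  Gaussian-weighted option would reduce seam artifacts on real-scale
  volumes.
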