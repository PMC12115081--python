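# diffbts

A lightweight 3D denoising-diffusion model for multimodal brain-tumor
segmentation, with **edge-blurring guided (EBG) sampling** and
entropy-weighted fusion of the per-step predictions.

Brain-tumor segmentation on BraTS-style data is a three-target task: from
four co-registered MRI sequences (T1, T1ce, T2, FLAIR) the model predicts
the nested binary masks Whole Tumor ⊇ Tumor Core ⊇ Enhancing Tumor.
`diffbts` treats the 3-channel label volume as the object of a diffusion
process: labels mapped to `{-1, +1}` are progressively noised by

```
x_t = sqrt(ᾱ_t) x_0 + sqrt(1 − ᾱ_t) z,   ᾱ_t = ∏_{i≤t} (1 − β_i)
```

and a UNet-style denoiser, conditioned on the MRI channels and the step
index, learns to recover `x_0`. Segmentation is deterministic reverse
(DDIM-style) sampling from pure noise:

```
x_{t−1} = sqrt(ᾱ_{t−1}) x̂_0 + sqrt(1 − ᾱ_{t−1}) ε_θ(x_t, t)
```

The package implements the three ingredients that distinguish the method:

- **3D multi-head efficient self-attention** on every skip connection:
  `E(Q,K,V) = [C^(−1/4) softmax_ch(Q)] [(C^(−1/4) softmax_pos(K))ᵀ V]`,
  which aggregates values into a `d×d` context matrix and is linear in the
  number of voxel positions `n = D·H·W` (no `n×n` similarity matrix).
- **EBG sampling**: at every reverse step the predicted label's boundary
  voxels are extracted per target (`M_wt, M_tc, M_et`), the prediction is
  Gaussian-blurred, re-noised, swapped into the latent on boundary voxels
  only, and the denoiser is re-run; the final noise estimate is
  extrapolated away from the boundary-degraded prediction,
  `ε̃ = ε̂ + (1 + s)(ε − ε̂)` with guidance scale `s` (default 0.05).
- **Uncertainty fusion**: the per-step clean predictions are averaged with
  weights `w_i = exp(sigmoid((i+1)/10)(1 − u))`, `u(p) = −p ln p`, so
  later, more confident steps dominate.

Training minimizes `L = L_Dice + L_BCE + L_MSE` between the predicted and
reference label latents (AdamW, cosine-annealed learning rate); inference
tiles large volumes with a sliding window at overlap 0.5. Evaluation
reports Dice, 95th-percentile Hausdorff distance (mm), and Recall per
target.

Everything runs on plain NumPy; gradients come from a small set of fused
[autograd](https://github.com/HIPS/autograd) primitives (im2col+GEMM
convolutions with hand-written VJPs), so no GPU framework is required.
Synthetic BraTS-like phantoms — co-registered multi-modality volumes with
nested ellipsoidal lesions — make every stage testable with no download.

## Worked example

```python
import numpy as np
from diffbts import (BackboneConfig, GuidanceConfig, InferConfig, TrainConfig,
                     PhantomSpec, build_backbone, generate_phantom,
                     make_schedule, sliding_window_predict, train)
from diffbts.metrics import report_from_masks

spec = PhantomSpec(shape=(24, 24, 24), n_cases=12, radius_wt=(4.5, 7.0),
                   radius_tc=(2.5, 4.0), radius_et=(1.2, 2.2), seed=1)
cases = generate_phantom(spec)

cfg = BackboneConfig(depth=2, base_width=8)
schedule = make_schedule(T=1000)
params = build_backbone(cfg, seed=1)
params, curve = train(params, cfg, schedule, cases[:10],
                      TrainConfig(lr=1e-3, epochs=10, batch_size=2, seed=1))
print(f"loss {curve[0]:.2f} -> {curve[-1]:.2f}")

labels, prob = sliding_window_predict(params, cfg, schedule,
                                      cases[10].modalities,
                                      InferConfig(n_steps=5),
                                      GuidanceConfig(s=0.05), seed=7)
rep = report_from_masks(labels, cases[10].labels)
print(f"WT Dice {rep.dice_wt:.3f}")
```

prints (10 quick epochs on 10 tiny phantoms):

```
loss 2.63 -> 2.44
WT Dice 0.719
```

The loss falls from its untrained value (≈ ln 2 + 1 + Dice term) as the
denoiser learns the lesion geometry, and a ten-epoch model already
recovers most of the whole-tumor mask of a held-out phantom; the 20-epoch
protocol below reaches WT Dice ≈ 0.9.

The same pipeline is available from the shell:

```sh
diffbts phantom --out data --n-cases 12 --size 24 --seed 1
diffbts train --data data --out model --epochs 20 --seed 1
diffbts sample --checkpoint model --data data --out preds -s 0.05 --steps 5
diffbts evaluate --pred preds --ref data --out report
```

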