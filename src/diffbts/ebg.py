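"""Edge-Blurring Guided (EBG) sampling and entropy-weighted fusion.

EBG adapts self-attention guidance to segmentation: instead of attention
maps, the guidance signal is the set of predicted segmentation boundaries.
At every reverse step the sampler

1. predicts the clean label latent ``xhat_0`` and noise ``eps_t``,
2. extracts per-target boundary masks from ``xhat_0`` (WT, TC, ET),
3. Gaussian-blurs ``xhat_0`` and re-noises the blur to the current step
   with the *same* noise ``eps_t`` (keeping the procedure deterministic),
4. swaps the re-noised blur into the latent on boundary voxels only,
5. re-runs the denoiser on the perturbed latent to get ``eps_hat``, and
6. extrapolates ``eps_tilde = eps_hat + (1 + s) (eps_t - eps_hat)``
   before taking the deterministic reverse step.

With guidance scale ``s = 0``, or whenever every boundary mask is empty,
the guided noise collapses to ``eps_t`` and the trajectory is exactly the
unguided deterministic sampler.

The per-step clean-latent predictions are additionally fused across steps
with entropy-based uncertainty weights ``w_i = exp(sigmoid((i+1)/10)
(1 - u))``, where ``u(p) = -p ln p`` and ``i`` counts sampling iterations,
so later (more accurate) steps receive higher weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .schedule import NoiseSchedule, ddim_step, latent_to_prob, q_sample

__all__ = [
    "GuidanceConfig",
    "EdgeMaskSet",
    "EBGStepTrace",
    "FusionState",
    "edges_mask",
    "gaussian_blur",
    "perturb_latent",
    "guided_eps",
    "entropy_uncertainty",
    "uncertainty_fusion",
    "ebg_sample",
]

_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_OFFSETS_26 = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


@dataclass(frozen=True)
class GuidanceConfig:
    """EBG hyperparameters.

    ``s`` is the guidance scale (0 disables guidance; 0.05 is the default
    operating point).  ``binarize_threshold`` is on the [-1, 1] latent
    scale, so 0.0 corresponds to probability 0.5.
    """

    s: float = 0.05
    blur_sigma: float = 1.0
    blur_kernel: int = 3
    connectivity: int = 6
    binarize_threshold: float = 0.0

    def __post_init__(self):
        if self.s <= -1.0:
            raise ValueError("guidance scale must satisfy s > -1")
        if self.blur_kernel % 2 == 0 or self.blur_kernel < 1:
            raise ValueError(f"blur_kernel must be a positive odd integer, got {self.blur_kernel}")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


@dataclass
class EdgeMaskSet:
    """Binary boundary masks per target and their channel concatenation."""

    m_wt: np.ndarray
    m_tc: np.ndarray
    m_et: np.ndarray
    m_t: np.ndarray = field(init=False)

    def __post_init__(self):
        self.m_t = np.stack([self.m_wt, self.m_tc, self.m_et], axis=0)


@dataclass
class EBGStepTrace:
    """All intermediates of one guided sampling iteration (3, D, H, W each)."""

    t: int
    xt: np.ndarray
    x0_hat: np.ndarray
    eps_t: np.ndarray
    m_t: np.ndarray
    x0_blur: np.ndarray
    xt_blur: np.ndarray
    xt_perturbed: np.ndarray
    eps_hat: np.ndarray
    eps_tilde: np.ndarray

    @property
    def h_t(self):
        """Generalized guidance condition ``M_t * x_t - M_t * xhat_t``."""
        return self.m_t * self.xt - self.m_t * self.xt_perturbed


@dataclass
class FusionState:
    """Per-step clean-latent predictions collected during sampling."""

    x0_latents: list = field(default_factory=list)
    step_indices: list = field(default_factory=list)

    def record(self, i: int, x0_latent: np.ndarray):
        self.step_indices.append(int(i))
        self.x0_latents.append(np.asarray(x0_latent))


def _edge_channel(binary: np.ndarray, connectivity: int) -> np.ndarray:
    """Voxels with at least one differing neighbor, replicate-padded."""
    offsets = _OFFSETS_6 if connectivity == 6 else _OFFSETS_26
    padded = np.pad(binary, 1, mode="edge")
    edge = np.zeros_like(binary, dtype=bool)
    d, h, w = binary.shape
    for oi, oj, ok in offsets:
        nb = padded[1 + oi : 1 + oi + d, 1 + oj : 1 + oj + h, 1 + ok : 1 + ok + w]
        edge |= nb != binary
    return edge.astype(np.uint8)


def edges_mask(x0_hat: np.ndarray, cfg: GuidanceConfig) -> EdgeMaskSet:
    """Boundary masks of the three predicted targets.

    Each channel of ``x0_hat`` is binarized at ``cfg.binarize_threshold``;
    a voxel is a boundary voxel iff at least one neighbor (6- or
    26-connectivity) has a different binary value.  Volume borders are
    replicate-padded, so a region touching the border produces no spurious
    border edge.
    """
    x0_hat = np.asarray(x0_hat)
    if x0_hat.ndim != 4 or x0_hat.shape[0] != 3:
        raise ValueError(f"expected a (3, D, H, W) volume, got {x0_hat.shape}")
    if not np.all(np.isfinite(x0_hat)):
        raise FloatingPointError("non-finite values in predicted latent")
    binary = x0_hat > cfg.binarize_threshold
    ms = [_edge_channel(binary[c], cfg.connectivity) for c in range(3)]
    return EdgeMaskSet(m_wt=ms[0], m_tc=ms[1], m_et=ms[2])


def _gauss_kernel1d(sigma: float, size: int) -> np.ndarray:
    r = size // 2
    if sigma <= 0 or size == 1:
        return np.array([1.0])
    x = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur(x: np.ndarray, cfg: GuidanceConfig) -> np.ndarray:
    """Separable truncated 3D Gaussian blur with replicate padding.

    Operates on the spatial axes of a (..., D, H, W) array; exactly
    mass-preserving on constant volumes, identity for kernel size 1.
    """
    k = _gauss_kernel1d(cfg.blur_sigma, cfg.blur_kernel)
    if k.size == 1:
        return np.array(x, dtype=float, copy=True)
    y = np.asarray(x, dtype=float)
    for ax in (-3, -2, -1):
        y = ndimage.correlate1d(y, k, axis=ax, mode="nearest")
    return y


def perturb_latent(xt: np.ndarray, xt_blur: np.ndarray, m_t: np.ndarray) -> np.ndarray:
    """Swap re-noised blurred content into the latent on boundary voxels.

    ``xhat_t = (1 - M_t) * x_t + M_t * xt_blur``; outside the edge masks
    the latent is returned bit-exactly.
    """
    xt, xt_blur, m_t = np.asarray(xt), np.asarray(xt_blur), np.asarray(m_t)
    if not (xt.shape == xt_blur.shape == m_t.shape):
        raise ValueError(f"shape mismatch: {xt.shape}, {xt_blur.shape}, {m_t.shape}")
    if not np.isin(m_t, (0, 1)).all():
        raise ValueError("edge mask must be binary")
    return np.where(m_t.astype(bool), xt_blur, xt)


def guided_eps(eps: np.ndarray, eps_hat: np.ndarray, s: float) -> np.ndarray:
    """Guidance extrapolation ``eps_hat + (1 + s) (eps - eps_hat)``."""
    if np.shape(eps) != np.shape(eps_hat):
        raise ValueError("eps and eps_hat must share a shape")
    return eps_hat + (1.0 + s) * (eps - eps_hat)


def entropy_uncertainty(p: np.ndarray) -> np.ndarray:
    """Element-wise entropy term ``u = -p ln p`` with ``0 ln 0 := 0``.

    Maximal at ``p = 1/e`` (value 1/e); zero at both p = 0 and p = 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return np.where(p > 0, -p * np.log(np.where(p > 0, p, 1.0)), 0.0)


def uncertainty_fusion(state: FusionState, threshold: float = 0.5):
    """Entropy-weighted fusion of the per-step clean-latent predictions.

    Per voxel and channel, prediction ``i`` (sampling order, later steps
    have larger ``i``) receives weight ``w_i = exp(sigmoid((i+1)/10)
    (1 - u(p_i)))``; the weights are normalized to sum to one and the
    weighted mean probability is binarized at ``threshold``.

    Returns ``(pred, prob)``: the fused binary labels and the fused
    probability map.
    """
    if not state.x0_latents:
        raise ValueError("cannot fuse an empty FusionState")
    probs = np.stack([latent_to_prob(x) for x in state.x0_latents])  # (k, 3, D, H, W)
    idx = np.asarray(state.step_indices, dtype=float)
    sig = 1.0 / (1.0 + np.exp(-(idx + 1.0) / 10.0))
    u = entropy_uncertainty(probs)
    w = np.exp(sig[:, None, None, None, None] * (1.0 - u))
    w = w / w.sum(axis=0, keepdims=True)
    prob = (w * probs).sum(axis=0)
    return (prob >= threshold).astype(np.uint8), prob


def ebg_sample(
    model,
    x_T: np.ndarray,
    steps: list[int],
    noise_schedule: NoiseSchedule,
    cfg: GuidanceConfig | None = None,
    record_traces: bool = False,
):
    """Run Algorithm-1 guided deterministic sampling from pure noise.

    Parameters
    ----------
    model : callable ``(x_t, t) -> (eps, xhat_0)``
        The trained denoiser (or an oracle fixture) closed over the MRI
        conditioning volumes.
    x_T : (3, D, H, W) array, the initial standard-normal latent.
    steps : strictly decreasing step indices (see ``subsample_steps``).
    cfg : guidance configuration; defaults to ``GuidanceConfig()``.
    record_traces : keep every :class:`EBGStepTrace` (memory-heavy).

    Returns
    -------
    (x0, fusion_state) or (x0, fusion_state, traces).
    """
    cfg = cfg or GuidanceConfig()
    xt = np.asarray(x_T, dtype=float)
    fusion = FusionState()
    traces: list[EBGStepTrace] = []
    for i, t in enumerate(steps):
        t_prev = steps[i + 1] if i + 1 < len(steps) else 0
        eps_t, x0_hat = model(xt, t)
        if not np.all(np.isfinite(x0_hat)):
            raise FloatingPointError(f"non-finite latent at sampling step t={t} (iteration {i})")
        masks = edges_mask(x0_hat, cfg)
        x0_blur = gaussian_blur(x0_hat, cfg)
        xt_blur = q_sample(x0_blur, t, eps_t, noise_schedule)  # re-noise with eps_t
        xt_pert = perturb_latent(xt, xt_blur, masks.m_t)
        eps_hat, _ = model(xt_pert, t)
        eps_tilde = guided_eps(eps_t, eps_hat, cfg.s)
        if record_traces:
            traces.append(
                EBGStepTrace(
                    t=t,
                    xt=xt.copy(),
                    m_t=masks.m_t,
                    x0_hat=x0_hat,
                    eps_t=eps_t,
                    x0_blur=x0_blur,
                    xt_blur=xt_blur,
                    xt_perturbed=xt_pert,
                    eps_hat=eps_hat,
                    eps_tilde=eps_tilde,
                )
            )
        fusion.record(i, x0_hat)
        xt = ddim_step(xt, t, eps_tilde, noise_schedule, t_prev=t_prev)
    if record_traces:
        return xt, fusion, traces
    return xt, fusion
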