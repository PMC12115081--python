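"""UNet-style 3D denoiser with time conditioning and attended skip paths.

The network maps a 7-channel volume — the 3 noisy label channels (WT, TC,
ET) concatenated with the 4 MRI modality channels — plus a diffusion step
index to a 3-channel estimate of the clean label latent ``xhat_0``.  The
noise estimate ``eps_theta(x_t, t)`` that the deterministic sampler
consumes is derived by inverting the forward process,
``eps = (x_t - sqrt(abar_t) xhat_0) / sqrt(1 - abar_t)``; :func:`denoise`
returns both.  Predicting ``xhat_0`` rather than ``eps`` keeps the
clean-latent training loss well-conditioned at high noise levels, where
the inversion in the other direction amplifies network error by
``1/sqrt(abar_t)`` (a factor of ~150 at the default schedule's final
step).

Encoder: per level, two 3x3x3 convolutions (group norm + SiLU), with the
time embedding injected after the first convolution through a linear map
and nonlinearity; a 2x max-pool between levels.  Each pre-pool feature map
passes through the 3D multi-head efficient self-attention block before it
feeds the skip connection.  Decoder: kernel-2 stride-2 transposed
convolutions, channel concatenation with the attended skip, and another
two-convolution block.  The final 1x1x1 head is zero-initialized so the
untrained network predicts the zero latent (probability 1/2 everywhere).

Channel widths double per level starting from ``base_width`` and are capped
at four times the base, following common diffusion-UNet width schedules
(multipliers 1, 2, 4, 4, ...); at the default depth 3 this is pure
doubling (32, 64, 128).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd.misc import flatten

from . import schedule as sched
from .attention3d import AttentionConfig, init_mhea_params, mhea3d
from .nn.functional import (
    conv3d,
    conv_transpose3d_2x,
    group_norm,
    linear,
    max_pool3d_2x,
    silu,
    time_embedding,
)

__all__ = ["BackboneConfig", "build_backbone", "forward", "denoise", "param_count"]

IN_CHANNELS = 7  # 3 noisy label channels + 4 MRI modalities
OUT_CHANNELS = 3  # WT, TC, ET clean-latent estimate
MULT_CAP = 4


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture hyperparameters of the denoiser."""

    depth: int = 3
    base_width: int = 32
    heads: int = 4
    gn_groups: int = 8
    time_dim: int = field(default=0)

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.time_dim == 0:
            object.__setattr__(self, "time_dim", 4 * self.base_width)
        if self.time_dim % 2:
            raise ValueError("time_dim must be even")

    @property
    def widths(self) -> list[int]:
        return [self.base_width * min(2**i, MULT_CAP) for i in range(self.depth)]


def _conv_init(rng, cout, cin, k):
    fan_in = cin * k**3
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k, k))
    return {"w": w, "b": np.zeros(cout)}


def _block_init(rng, cfg, cin, cout):
    return {
        "conv1": _conv_init(rng, cout, cin, 3),
        "tproj": {"w": rng.normal(0.0, cfg.time_dim**-0.5, (cfg.time_dim, cout)),
                  "b": np.zeros(cout)},
        "gn1": {"g": np.ones(cout), "b": np.zeros(cout)},
        "conv2": _conv_init(rng, cout, cout, 3),
        "gn2": {"g": np.ones(cout), "b": np.zeros(cout)},
    }


def _cast_tree(tree, dtype):
    if isinstance(tree, dict):
        return {k: _cast_tree(v, dtype) for k, v in tree.items()}
    if isinstance(tree, list):
        return [_cast_tree(v, dtype) for v in tree]
    return np.asarray(tree, dtype=dtype)


def build_backbone(cfg: BackboneConfig, seed: int = 0, dtype=np.float32) -> dict:
    """Initialize the parameter pytree of the denoiser (float32 by default)."""
    rng = np.random.default_rng(seed)
    tw = cfg.time_dim
    widths = cfg.widths
    params = {
        "time_mlp": {
            "w1": rng.normal(0.0, tw**-0.5, (tw, tw)),
            "b1": np.zeros(tw),
            "w2": rng.normal(0.0, tw**-0.5, (tw, tw)),
            "b2": np.zeros(tw),
        },
        "enc": [],
        "attn": [],
        "dec": [],
        "head": {"w": np.zeros((OUT_CHANNELS, widths[0], 1, 1, 1)),
                 "b": np.zeros(OUT_CHANNELS)},
    }
    cin = IN_CHANNELS
    for i, w in enumerate(widths):
        params["enc"].append(_block_init(rng, cfg, cin, w))
        cin = w
    for w in widths[:-1]:  # attention on the skip path of every pooled level
        acfg = AttentionConfig(channels=w, heads=min(cfg.heads, w))
        params["attn"].append(init_mhea_params(acfg, rng))
    for i in range(cfg.depth - 2, -1, -1):
        w_deep, w = widths[i + 1], widths[i]
        up = {"w": rng.normal(0.0, np.sqrt(2.0 / (w_deep * 8)), (w_deep, w, 2, 2, 2)),
              "b": np.zeros(w)}
        params["dec"].append({"up": up, "block": _block_init(rng, cfg, 2 * w, w)})
    return _cast_tree(params, dtype)


def _block(h, blk, emb, cfg):
    h = conv3d(h, blk["conv1"]["w"], blk["conv1"]["b"])
    tb = silu(linear(emb, blk["tproj"]["w"], blk["tproj"]["b"]))
    h = h + anp.reshape(tb, (tb.shape[0], tb.shape[-1], 1, 1, 1))
    h = silu(group_norm(h, blk["gn1"]["g"], blk["gn1"]["b"], cfg.gn_groups))
    h = conv3d(h, blk["conv2"]["w"], blk["conv2"]["b"])
    return silu(group_norm(h, blk["gn2"]["g"], blk["gn2"]["b"], cfg.gn_groups))


def forward(params: dict, cfg: BackboneConfig, x, t):
    """Clean-latent estimate for a 7-channel input volume at step(s) ``t``.

    x : (B, 7, D, H, W) with D, H, W divisible by ``2**(depth-1)``;
    t : scalar or (B,) step indices.  Returns (B, 3, D, H, W).
    """
    bsz, c, d, h, w = x.shape
    if c != IN_CHANNELS:
        raise ValueError(f"expected {IN_CHANNELS} input channels, got {c}")
    div = 2 ** (cfg.depth - 1)
    if d % div or h % div or w % div:
        raise ValueError(
            f"spatial size {(d, h, w)} not divisible by 2**(depth-1)={div}; pad the input"
        )
    t = np.broadcast_to(np.asarray(t), (bsz,))
    emb = time_embedding(t, cfg.time_dim).astype(params["time_mlp"]["w1"].dtype)
    emb = linear(silu(linear(emb, params["time_mlp"]["w1"], params["time_mlp"]["b1"])),
                 params["time_mlp"]["w2"], params["time_mlp"]["b2"])

    skips = []
    widths = cfg.widths
    for i in range(cfg.depth):
        x = _block(x, params["enc"][i], emb, cfg)
        if i < cfg.depth - 1:
            acfg = AttentionConfig(channels=widths[i], heads=min(cfg.heads, widths[i]))
            skips.append(mhea3d(x, acfg, params["attn"][i]))
            x = max_pool3d_2x(x)
    for j, i in enumerate(range(cfg.depth - 2, -1, -1)):
        dec = params["dec"][j]
        x = conv_transpose3d_2x(x, dec["up"]["w"], dec["up"]["b"])
        x = anp.concatenate([x, skips[i]], axis=1)
        x = _block(x, dec["block"], emb, cfg)
    return conv3d(x, params["head"]["w"], params["head"]["b"])


def denoise(params: dict, cfg: BackboneConfig, mri, xt, t, noise_schedule):
    """Run the denoiser on (MRI, noisy latent) and return (eps, xhat_0).

    Concatenates the 3 noisy label channels with the 4 modality channels to
    the 7-channel network input; the network predicts the clean latent and
    the noise estimate is derived from it by inverting the forward process.
    """
    mri = np.asarray(mri)
    squeeze = xt.ndim == 4
    if squeeze:
        xt, mri = xt[None], mri[None]
    if mri.shape[1] != 4 or xt.shape[1] != 3:
        raise ValueError(f"expected 4 MRI and 3 label channels, got {mri.shape[1]}, {xt.shape[1]}")
    if mri.shape[2:] != xt.shape[2:]:
        raise ValueError("MRI and latent volumes are not spatially aligned")
    x0_hat = forward(params, cfg, anp.concatenate([xt, mri], axis=1), t)
    eps = sched.predict_eps(xt, t, x0_hat, noise_schedule)
    if squeeze:
        return eps[0], x0_hat[0]
    return eps, x0_hat


def param_count(params: dict) -> int:
    """Total number of scalar parameters in a pytree."""
    flat, _ = flatten(params)
    return int(flat.size)
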