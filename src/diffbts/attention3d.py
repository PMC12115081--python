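"""3D multi-head efficient self-attention.

Dot-product attention compares every pair of the ``n = D*H*W`` voxel
positions and therefore costs O(n^2) — prohibitive for volumetric MRI.
The efficient factorization

    ``E(Q, K, V) = softmax_ch(Q) (softmax_pos(K)^T V)``

first aggregates the values into a (d x d) global context matrix using a
position-softmax over K, then redistributes it with a channel-softmax over
Q, so the cost is linear in n.  For 3D feature maps the flattened sequence
is much longer than in 2D, so each softmax output is additionally scaled by
``C^(-1/4)`` (net factor ``C^(-1/2)``, with C the full channel count) to
keep the magnitudes comparable across resolutions.

``dot_product_attention`` is the quadratic reference used as a test oracle;
``mhea3d`` is the multi-head volumetric block used inside the denoiser.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .nn.functional import softmax

__all__ = [
    "AttentionConfig",
    "dot_product_attention",
    "efficient_attention_head",
    "context_matrix",
    "mhea3d",
    "init_mhea_params",
]


@dataclass(frozen=True)
class AttentionConfig:
    """Channel count and head count; per-head width is ``channels // heads``."""

    channels: int
    heads: int = 1

    def __post_init__(self):
        if self.heads < 1:
            raise ValueError("heads must be >= 1")
        if self.channels % self.heads:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by heads ({self.heads})"
            )

    @property
    def head_width(self) -> int:
        return self.channels // self.heads


def dot_product_attention(Q, K, V):
    """Quadratic reference attention ``softmax(Q K^T / sqrt(d_k)) V``.

    Q, K: (..., n, d_k); V: (..., n, d_v).  Softmax is row-wise over the
    n key positions.  Materializes the (n, n) similarity matrix; intended
    as an oracle on tiny inputs, not for production use.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1] or K.shape[-2] != V.shape[-2]:
        raise ValueError(f"incompatible shapes {Q.shape}, {K.shape}, {V.shape}")
    sim = np.matmul(Q, np.swapaxes(K, -2, -1)) / np.sqrt(Q.shape[-1])
    return np.matmul(softmax(sim, axis=-1), V)


def context_matrix(Kh, Vh, C: int):
    """Global context ``(C^(-1/4) softmax_pos(K))^T V`` of shape (d, d).

    The shape depends only on the per-head width, never on the number of
    positions — this is what makes the attention linear in n.
    """
    k = softmax(Kh, axis=-2) * float(C) ** -0.25
    return anp.matmul(anp.swapaxes(k, -2, -1), Vh)


def efficient_attention_head(Qh, Kh, Vh, C: int):
    """Linear-complexity attention for one head.

    Qh, Kh, Vh: (..., n, d) with softmax over the channel axis for Q and
    over the position axis for K; both softmax outputs are scaled by
    ``C^(-1/4)`` where ``C`` is the full (all-heads) channel count.
    """
    for name, a in (("Q", Qh), ("K", Kh), ("V", Vh)):
        if isinstance(a, np.ndarray) and not np.all(np.isfinite(a)):
            raise FloatingPointError(f"non-finite values in {name}")
    q = softmax(Qh, axis=-1) * float(C) ** -0.25
    return anp.matmul(q, context_matrix(Kh, Vh, C))


def init_mhea_params(cfg: AttentionConfig, rng: np.random.Generator) -> dict:
    """Q/K/V projections ~ N(0, 1/C); output projection zero.

    Zero-initializing the output projection makes the residual block an
    identity map at initialization.
    """
    c = cfg.channels
    std = c**-0.5
    return {
        "wq": rng.normal(0.0, std, (c, c)),
        "bq": np.zeros(c),
        "wk": rng.normal(0.0, std, (c, c)),
        "bk": np.zeros(c),
        "wv": rng.normal(0.0, std, (c, c)),
        "bv": np.zeros(c),
        "wo": np.zeros((c, c)),
        "bo": np.zeros(c),
    }


def mhea3d(x, cfg: AttentionConfig, params: dict):
    """Multi-head efficient self-attention over a feature volume.

    Accepts ``(C, D, H, W)`` or batched ``(B, C, D, H, W)`` input; flattens
    space to ``n = D*H*W`` positions, projects to Q/K/V, splits ``heads``
    along channels, applies the efficient head attention in parallel,
    concatenates heads, projects, and adds a residual connection.  Output
    shape equals input shape.
    """
    squeeze = x.ndim == 4
    if squeeze:
        x = x[None]
    bsz, c, d, h, w = x.shape
    if c != cfg.channels:
        raise ValueError(f"feature volume has {c} channels, config expects {cfg.channels}")
    nh, hw = cfg.heads, cfg.head_width
    n = d * h * w
    xf = anp.swapaxes(anp.reshape(x, (bsz, c, n)), 1, 2)  # (B, n, C)
    q = anp.matmul(xf, params["wq"]) + params["bq"]
    k = anp.matmul(xf, params["wk"]) + params["bk"]
    v = anp.matmul(xf, params["wv"]) + params["bv"]

    def split(a):  # (B, n, C) -> (B, heads, n, head_width)
        return anp.transpose(anp.reshape(a, (bsz, n, nh, hw)), (0, 2, 1, 3))

    att = efficient_attention_head(split(q), split(k), split(v), c)
    att = anp.reshape(anp.transpose(att, (0, 2, 1, 3)), (bsz, n, c))
    out = anp.matmul(att, params["wo"]) + params["bo"]
    y = x + anp.reshape(anp.swapaxes(out, 1, 2), (bsz, c, d, h, w))
    return y[0] if squeeze else y
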