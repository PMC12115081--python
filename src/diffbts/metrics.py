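"""Segmentation metrics (Dice, HD95, Recall) and the training loss.

HD95 is the 95th percentile of the directed surface distances,
symmetrized as the maximum of the two directions, in physical units given
the voxel spacing.  Surfaces use the same 6-connectivity, replicate-padded
boundary definition as the edge-mask extraction, so a region that touches
the volume border contributes no border surface.

The training loss is the unweighted sum of Dice, binary cross-entropy and
mean-squared-error terms between the predicted clean latent and the
reference label latent; it is written with :mod:`autograd.numpy` and is
differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import autograd.numpy as anp
import numpy as np
from scipy import ndimage

from .ebg import _edge_channel

__all__ = [
    "dice",
    "hd95",
    "recall",
    "combined_loss",
    "MetricsReport",
    "report_from_masks",
    "TARGETS",
]

TARGETS = ("wt", "tc", "et")


def _as_binary(a, name):
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be a binary mask")
    return a.astype(bool)


def dice(a, b) -> float:
    """Dice similarity coefficient ``2|A n B| / (|A| + |B|)``; 1 if both empty."""
    a, b = _as_binary(a, "A"), _as_binary(b, "B")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def recall(a, b) -> float:
    """Sensitivity ``|A n B| / |B|``; 1 when the reference B is empty."""
    a, b = _as_binary(a, "A"), _as_binary(b, "B")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    nb = b.sum()
    if nb == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / nb)


def _surface(mask: np.ndarray) -> np.ndarray:
    """6-connectivity boundary voxels of a binary mask (replicate padding)."""
    return _edge_channel(mask.astype(np.uint8), 6).astype(bool) & mask


def hd95(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th-percentile symmetric surface distance in physical units.

    Returns ``nan`` (an explicit undefined sentinel, not an exception)
    when either mask is empty or has no surface voxels.
    """
    a, b = _as_binary(a, "A"), _as_binary(b, "B")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa, sb = _surface(a), _surface(b)
    if not sa.any() or not sb.any():
        return float("nan")
    dt_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    d_ab = np.percentile(dt_b[sa], 95)
    d_ba = np.percentile(dt_a[sb], 95)
    return float(max(d_ab, d_ba))


def combined_loss(x0_hat, x0, smooth: float = 1e-5):
    """Dice + BCE + MSE loss between predicted and reference label latents.

    Both arguments live on the [-1, 1] latent scale; for the Dice and BCE
    terms the prediction is mapped to a clipped probability
    ``p = clip((x + 1) / 2, eps, 1 - eps)`` and the reference to exact
    {0, 1} targets.  The MSE term is taken directly between the latents.
    Each term is averaged over channels and voxels; the total is their
    unweighted sum.  Differentiable in ``x0_hat``.
    """
    y = (np.asarray(x0) + 1.0) / 2.0
    p = anp.clip((x0_hat + 1.0) / 2.0, 1e-7, 1.0 - 1e-7)
    bce = anp.mean(-(y * anp.log(p) + (1.0 - y) * anp.log(1.0 - p)))
    # soft Dice per channel over the spatial axes, averaged
    spatial = tuple(range(x0_hat.ndim))[-3:]
    inter = anp.sum(p * y, axis=spatial)
    sums = anp.sum(p, axis=spatial) + anp.sum(y, axis=spatial)
    dice_term = 1.0 - anp.mean((2.0 * inter + smooth) / (sums + smooth))
    mse = anp.mean((x0_hat - np.asarray(x0)) ** 2)
    total = dice_term + bce + mse
    if isinstance(total, (float, np.floating)) and not np.isfinite(total):
        raise FloatingPointError("non-finite loss")
    return total


@dataclass
class MetricsReport:
    """Per-target Dice/HD95/Recall and their means for one or more cases.

    Undefined HD95 values (empty masks) are excluded from means;
    ``n_undefined_hd95`` counts the exclusions.
    """

    dice_wt: float
    dice_tc: float
    dice_et: float
    hd95_wt: float
    hd95_tc: float
    hd95_et: float
    recall_wt: float
    recall_tc: float
    recall_et: float
    n_undefined_hd95: int = 0

    @property
    def dice_mean(self) -> float:
        return float(np.mean([self.dice_wt, self.dice_tc, self.dice_et]))

    @property
    def hd95_mean(self) -> float:
        vals = [self.hd95_wt, self.hd95_tc, self.hd95_et]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def recall_mean(self) -> float:
        return float(np.mean([self.recall_wt, self.recall_tc, self.recall_et]))

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(dice_mean=self.dice_mean, hd95_mean=self.hd95_mean,
                 recall_mean=self.recall_mean)
        return d


def report_from_masks(pred, ref, spacing=(1.0, 1.0, 1.0)) -> MetricsReport:
    """Evaluate 3-channel (WT, TC, ET) predicted vs reference label masks."""
    pred, ref = np.asarray(pred), np.asarray(ref)
    if pred.shape != ref.shape or pred.shape[0] != 3:
        raise ValueError(f"expected matching (3, D, H, W) masks, got {pred.shape}, {ref.shape}")
    vals = {}
    n_undef = 0
    for c, name in enumerate(TARGETS):
        vals[f"dice_{name}"] = dice(pred[c], ref[c])
        h = hd95(pred[c], ref[c], spacing)
        if not np.isfinite(h):
            n_undef += 1
        vals[f"hd95_{name}"] = h
        vals[f"recall_{name}"] = recall(pred[c], ref[c])
    return MetricsReport(n_undefined_hd95=n_undef, **vals)
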