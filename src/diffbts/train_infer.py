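"""Training loop, sliding-window inference, and case evaluation.

Training follows the standard denoising-diffusion recipe: per step a batch
of cases is drawn, a step index ``t`` is sampled uniformly in ``[1, T]``
per sample, the label latent is noised through the forward process, the
network predicts the noise, and the Dice + BCE + MSE loss is applied to
the implied clean-latent prediction.  Optimization uses AdamW
(decoupled weight decay) with cosine-annealed learning rate.

Inference tiles large volumes with a sliding window (default overlap 0.5),
runs guided sampling per window, and averages the fused probabilities over
overlapping voxels before thresholding.
"""

from __future__ import annotations

import csv
import glob
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
from autograd import value_and_grad

from . import schedule as sched
from .backbone import BackboneConfig, denoise, forward
from .ebg import GuidanceConfig, ebg_sample, uncertainty_fusion
from .metrics import MetricsReport, combined_loss, report_from_masks
from .nn.optim import AdamW, cosine_annealing
from .phantom_io import VolumeSample, brats_label_encode

logger = logging.getLogger("diffbts")

__all__ = [
    "TrainConfig",
    "InferConfig",
    "train",
    "sliding_window_predict",
    "evaluate",
    "evaluate_pairs",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings: AdamW, cosine annealing."""

    lr: float = 1e-4
    lr_min: float = 0.0
    weight_decay: float = 1e-3
    epochs: int = 300
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 and self.lr != 0.0:
            raise ValueError("learning rate must be non-negative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass(frozen=True)
class InferConfig:
    """Sliding-window sampling settings."""

    window: tuple | None = None  # None: whole volume
    overlap: float = 0.5
    n_steps: int = 10
    fusion: bool = True
    threshold: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must lie in [0, 1)")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def _stack_cases(cases: list[VolumeSample]):
    mri = np.stack([c.modalities for c in cases]).astype(np.float32)
    x0 = np.stack([sched.labels_to_latent(c.labels) for c in cases]).astype(np.float32)
    return mri, x0


def train(
    params: dict,
    cfg: BackboneConfig,
    noise_schedule: sched.NoiseSchedule,
    cases: list[VolumeSample],
    tcfg: TrainConfig = TrainConfig(),
):
    """Train the denoiser on a list of cases; returns (params, loss_curve).

    ``loss_curve`` holds the mean loss of each epoch.  Fully deterministic
    given ``tcfg.seed`` and the initial parameters.
    """
    if not cases:
        raise ValueError("need at least one training case")
    mri_all, x0_all = _stack_cases(cases)
    n = len(cases)
    rng = np.random.default_rng(tcfg.seed)
    opt = AdamW(lr=tcfg.lr, weight_decay=tcfg.weight_decay)
    T = noise_schedule.T

    def loss_fn(p, mri_b, x0_b, t_b, z_b):
        xt = sched.q_sample(x0_b, t_b, z_b, noise_schedule)
        x0_hat = forward(p, cfg, np.concatenate([xt, mri_b], axis=1), t_b)
        return combined_loss(x0_hat, x0_b)

    vg = value_and_grad(loss_fn)
    curve = []
    for epoch in range(tcfg.epochs):
        lr = cosine_annealing(tcfg.lr, tcfg.lr_min, epoch, tcfg.epochs)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            t_b = rng.integers(1, T + 1, size=idx.size)
            z_b = rng.standard_normal(x0_all[idx].shape, dtype=np.float32)
            loss, grads = vg(params, mri_all[idx], x0_all[idx], t_b, z_b)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch starting {start} (t={t_b.tolist()})"
                )
            params = opt.step(params, grads, lr=lr)
            losses.append(float(loss))
        curve.append(float(np.mean(losses)))
        logger.info("epoch %d/%d lr=%.2e loss=%.4f", epoch + 1, tcfg.epochs, lr, curve[-1])
    return params, curve


def _axis_origins(size: int, win: int, overlap: float) -> list[int]:
    if win >= size:
        return [0]
    stride = max(1, int(round(win * (1.0 - overlap))))
    origins = list(range(0, size - win + 1, stride))
    if origins[-1] != size - win:
        origins.append(size - win)
    return origins


def sliding_window_predict(
    params: dict,
    cfg: BackboneConfig,
    noise_schedule: sched.NoiseSchedule,
    mri: np.ndarray,
    icfg: InferConfig = InferConfig(),
    gcfg: GuidanceConfig = GuidanceConfig(),
    seed: int = 0,
):
    """Guided sampling over a tiled volume; returns (labels, probability).

    Each window is sampled with :func:`diffbts.ebg.ebg_sample` from its own
    seeded standard-normal latent; overlapping probabilities are averaged
    uniformly and thresholded per channel.
    """
    mri = np.asarray(mri, dtype=np.float32)
    if mri.ndim != 4 or mri.shape[0] != 4:
        raise ValueError(f"expected a (4, D, H, W) MRI volume, got {mri.shape}")
    shape = mri.shape[1:]
    win = tuple(icfg.window) if icfg.window else shape
    if any(w > s for w, s in zip(win, shape)):
        logger.warning("window %s exceeds volume %s; using a single whole-volume window",
                       win, shape)
        win = shape
    steps = sched.subsample_steps(noise_schedule.T, icfg.n_steps)
    rng = np.random.default_rng(seed)
    prob_sum = np.zeros((3,) + shape)
    counts = np.zeros(shape)
    origins = [
        (i, j, k)
        for i in _axis_origins(shape[0], win[0], icfg.overlap)
        for j in _axis_origins(shape[1], win[1], icfg.overlap)
        for k in _axis_origins(shape[2], win[2], icfg.overlap)
    ]
    for oi, oj, ok in origins:
        sl = (slice(oi, oi + win[0]), slice(oj, oj + win[1]), slice(ok, ok + win[2]))
        mri_w = mri[(slice(None),) + sl]

        def model(xt, t, _mri=mri_w):
            return denoise(params, cfg, _mri, xt, t, noise_schedule)

        x_T = rng.standard_normal((3,) + win, dtype=np.float32)
        x0, fusion = ebg_sample(model, x_T, steps, noise_schedule, gcfg)
        if icfg.fusion:
            _, prob = uncertainty_fusion(fusion, threshold=icfg.threshold)
        else:
            prob = sched.latent_to_prob(x0)
        prob_sum[(slice(None),) + sl] += prob
        counts[sl] += 1.0
    prob = prob_sum / counts
    labels = (prob >= icfg.threshold).astype(np.uint8)
    return labels, prob


def _find_segs(directory: str) -> dict[str, str]:
    """Map case id -> segmentation path for flat or per-case-dir layouts."""
    paths = glob.glob(os.path.join(directory, "*_seg.nii.gz"))
    paths += glob.glob(os.path.join(directory, "*", "*_seg.nii.gz"))
    return {os.path.basename(p)[: -len("_seg.nii.gz")]: p for p in sorted(paths)}


def evaluate_pairs(
    preds: dict[str, np.ndarray],
    refs: dict[str, np.ndarray],
    spacing=(1.0, 1.0, 1.0),
) -> tuple[dict[str, MetricsReport], MetricsReport]:
    """Per-case metric reports plus the across-case mean report.

    Mean HD95 skips undefined (empty-mask) entries; the summary report
    counts how many were skipped.
    """
    common = sorted(set(preds) & set(refs))
    if not common:
        raise ValueError("no matching case ids between predictions and references")
    missing = sorted(set(preds) ^ set(refs))
    if missing:
        logger.warning("excluding %d unmatched case(s): %s", len(missing), missing)
    reports = {cid: report_from_masks(preds[cid], refs[cid], spacing) for cid in common}
    fields = [f"{m}_{t}" for m in ("dice", "hd95", "recall") for t in ("wt", "tc", "et")]
    means, n_undef = {}, 0
    for f in fields:
        vals = np.array([getattr(r, f) for r in reports.values()])
        if f.startswith("hd95"):
            n_undef += int(np.sum(~np.isfinite(vals)))
            vals = vals[np.isfinite(vals)]
        means[f] = float(np.mean(vals)) if vals.size else float("nan")
    summary = MetricsReport(n_undefined_hd95=n_undef, **means)
    return reports, summary


def evaluate(pred_dir: str, ref_dir: str, out_prefix: str | None = None):
    """Evaluate predicted vs reference segmentations stored as NIfTI.

    Both directories are scanned for ``*_seg.nii.gz`` (flat or per-case
    subdirectories); raw {0, 1, 2, 4} encodings are expanded to the three
    nested targets.  Optionally writes ``<out_prefix>.csv`` (one row per
    case plus a summary row) and ``<out_prefix>.json``.
    """
    import nibabel as nib

    def load(paths):
        return {
            cid: brats_label_encode(np.asarray(nib.load(p).dataobj).astype(np.int16))
            for cid, p in paths.items()
        }

    preds, refs = load(_find_segs(pred_dir)), load(_find_segs(ref_dir))
    reports, summary = evaluate_pairs(preds, refs)
    if out_prefix:
        rows = [{"case_id": cid, **r.as_dict()} for cid, r in reports.items()]
        rows.append({"case_id": "mean", **summary.as_dict()})
        with open(out_prefix + ".csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
        with open(out_prefix + ".json", "w") as fh:
            json.dump({"cases": {cid: r.as_dict() for cid, r in reports.items()},
                       "summary": summary.as_dict()}, fh, indent=2)
    return reports, summary
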