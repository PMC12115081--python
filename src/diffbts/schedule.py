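"""Variance schedule, forward diffusion, and deterministic reverse sampling.

The diffusion operates on 3-channel label latents (WT, TC, ET) with binary
labels mapped to ``{-1, +1}``.  Steps are indexed ``t = 1..T``; ``t = 0``
denotes the clean latent and the cumulative signal level is defined as
``alpha_bar(0) = 1`` so the final reverse step emits the predicted clean
latent exactly.

Forward process:  ``x_t = sqrt(abar_t) x_0 + sqrt(1 - abar_t) z``.

Deterministic (non-Markovian) reverse step:

    ``x_{t-1} = sqrt(abar_{t-1}) xhat_0 + sqrt(1 - abar_{t-1}) eps``

with ``xhat_0 = (x_t - sqrt(1 - abar_t) eps) / sqrt(abar_t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

__all__ = [
    "NoiseSchedule",
    "LatentState",
    "make_schedule",
    "q_sample",
    "predict_x0",
    "predict_eps",
    "ddim_step",
    "subsample_steps",
    "labels_to_latent",
    "latent_to_labels",
    "latent_to_prob",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step noise tables beta_t, alpha_t = 1 - beta_t, abar_t = prod alpha_i.

    ``betas[i]`` corresponds to step ``t = i + 1``.
    """

    betas: np.ndarray
    alphas: np.ndarray = field(init=False)
    alpha_bars: np.ndarray = field(init=False)

    def __post_init__(self):
        betas = np.asarray(self.betas, dtype=float)
        if betas.ndim != 1 or betas.size < 1:
            raise ValueError("betas must be a non-empty 1D sequence")
        if np.any(betas <= 0.0) or np.any(betas >= 1.0):
            raise ValueError("all beta_t must lie strictly in (0, 1)")
        alphas = 1.0 - betas
        alpha_bars = np.cumprod(alphas)
        if np.any(np.diff(alpha_bars) >= 0):
            raise ValueError("alpha_bar must be strictly decreasing")
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "alphas", alphas)
        object.__setattr__(self, "alpha_bars", alpha_bars)

    @property
    def T(self) -> int:
        return int(self.betas.size)

    def alpha_bar(self, t):
        """abar_t for integer step(s) t in [0, T]; abar_0 = 1 by definition."""
        t = np.asarray(t)
        if np.any(t < 0) or np.any(t > self.T):
            raise ValueError(f"step index out of range [0, {self.T}]: {t}")
        abars = np.concatenate([[1.0], self.alpha_bars])
        out = abars[t]
        return float(out) if out.ndim == 0 else out


@dataclass
class LatentState:
    """A noisy 3-channel label latent at diffusion step ``t``."""

    x: np.ndarray
    t: int

    def __post_init__(self):
        ch_axis = 0 if self.x.ndim == 4 else 1
        if self.x.ndim not in (4, 5) or self.x.shape[ch_axis] != 3:
            raise ValueError(
                "latent must be (3, D, H, W) or (B, 3, D, H, W); "
                f"got shape {self.x.shape}"
            )


def make_schedule(
    T: int,
    beta_start: float = 1e-4,
    beta_end: float = 2e-2,
    kind: str = "linear",
) -> NoiseSchedule:
    """Build a variance schedule.

    ``linear`` interpolates beta evenly from ``beta_start`` to ``beta_end``;
    ``cosine`` uses the squared-cosine signal schedule (beta endpoints are
    ignored apart from validation).
    """
    if not isinstance(T, (int, np.integer)) or T < 1:
        raise ValueError(f"T must be a positive integer, got {T!r}")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError(f"need 0 < beta_start <= beta_end < 1, got {beta_start}, {beta_end}")
    if kind == "linear":
        betas = np.linspace(beta_start, beta_end, T)
    elif kind == "cosine":
        s = 0.008
        ts = np.arange(T + 1) / T
        abar = np.cos((ts + s) / (1 + s) * np.pi / 2) ** 2
        betas = np.clip(1.0 - abar[1:] / abar[:-1], 1e-8, 0.999)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    return NoiseSchedule(betas=betas)


def _coeffs(schedule: NoiseSchedule, t, x):
    """sqrt(abar_t) and sqrt(1-abar_t), broadcastable against ``x``.

    Scalar steps yield python floats (weak promotion keeps float32 volumes
    in float32); per-sample step vectors yield arrays cast to ``x``'s dtype.
    """
    t_arr = np.asarray(t)
    if np.any(t_arr < 1) or np.any(t_arr > schedule.T):
        raise ValueError(f"step index must lie in [1, {schedule.T}], got {t}")
    abar = schedule.alpha_bar(t_arr)
    if not t_arr.ndim:
        return float(np.sqrt(abar)), float(np.sqrt(1.0 - abar))
    # per-sample steps for a batched (B, C, D, H, W) volume
    shape = (t_arr.size,) + (1,) * (np.ndim(x) - 1)
    a = np.sqrt(abar).reshape(shape)
    b = np.sqrt(1.0 - abar).reshape(shape)
    if isinstance(x, np.ndarray):
        a, b = a.astype(x.dtype), b.astype(x.dtype)
    return a, b


def q_sample(x0, t, z, schedule: NoiseSchedule):
    """Forward diffusion: noise a clean latent to step ``t``.

    ``t`` may be a scalar or a per-sample vector for batched input.
    """
    if np.shape(z) != np.shape(x0):
        raise ValueError("noise z must have the same shape as x0")
    a, b = _coeffs(schedule, t, x0)
    return a * x0 + b * z


def predict_x0(xt, t, eps, schedule: NoiseSchedule):
    """Invert the forward process given a noise estimate.

    ``xhat_0 = (x_t - sqrt(1 - abar_t) eps) / sqrt(abar_t)``.  Differentiable
    in ``xt`` and ``eps``.
    """
    a, b = _coeffs(schedule, t, xt)
    if np.any(np.asarray(a) == 0.0):
        raise ZeroDivisionError("degenerate schedule: alpha_bar_t == 0")
    return (xt - b * eps) / a


def predict_eps(xt, t, x0, schedule: NoiseSchedule):
    """Noise implied by a clean-latent prediction.

    Inverts the forward process the other way round:
    ``eps = (x_t - sqrt(abar_t) x0) / sqrt(1 - abar_t)``.  Differentiable
    in ``xt`` and ``x0``.
    """
    a, b = _coeffs(schedule, t, xt)
    if np.any(np.asarray(b) == 0.0):
        raise ZeroDivisionError("degenerate schedule: alpha_bar_t == 1")
    return (xt - a * x0) / b


def ddim_step(xt, t, eps, schedule: NoiseSchedule, t_prev=None):
    """One deterministic reverse step from ``t`` to ``t_prev`` (default t-1).

    At ``t_prev = 0`` (abar = 1) the output is exactly the predicted clean
    latent.  ``t_prev`` may be any step below ``t``, enabling subsampled
    sampling trajectories.
    """
    if np.shape(eps) != np.shape(xt):
        raise ValueError("eps must have the same shape as x_t")
    if t_prev is None:
        t_prev = t - 1
    if not (0 <= t_prev < t):
        raise ValueError(f"need 0 <= t_prev < t, got t_prev={t_prev}, t={t}")
    x0_hat = predict_x0(xt, t, eps, schedule)
    abar_prev = schedule.alpha_bar(t_prev)
    return np.sqrt(abar_prev) * x0_hat + np.sqrt(1.0 - abar_prev) * eps


def subsample_steps(T_train: int, n_steps: int) -> list[int]:
    """Evenly spaced, strictly decreasing step indices for fast sampling.

    ``n_steps = T_train`` yields every step ``[T, ..., 1]``; ``n_steps = 1``
    yields ``[T]``.
    """
    if not (1 <= n_steps <= T_train):
        raise ValueError(f"need 1 <= n_steps <= T_train, got {n_steps} > {T_train}")
    if n_steps == 1:
        return [int(T_train)]
    steps = np.unique(np.round(np.linspace(T_train, 1, n_steps)).astype(int))[::-1]
    return [int(s) for s in steps]


def labels_to_latent(labels):
    """Map binary {0,1} label channels to the {-1,+1} latent scale."""
    return np.asarray(labels, dtype=float) * 2.0 - 1.0


def latent_to_labels(x, threshold: float = 0.0):
    """Threshold a latent back to binary labels (default midpoint 0)."""
    return (np.asarray(x) > threshold).astype(np.uint8)


def latent_to_prob(x):
    """Affine map of a [-1, 1] latent to a clipped [0, 1] probability map."""
    return anp.clip((x + 1.0) / 2.0, 0.0, 1.0)
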