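"""AdamW with cosine-annealed learning rate for parameter pytrees."""

from __future__ import annotations

import math

import numpy as np
from autograd.misc import flatten


def cosine_annealing(lr_max: float, lr_min: float, epoch: int, epochs: int) -> float:
    """Cosine-annealed learning rate at the start of ``epoch`` (0-based)."""
    if epochs <= 1:
        return lr_max
    frac = min(max(epoch, 0), epochs - 1) / (epochs - 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * frac))


class AdamW:
    """Adaptive-moment optimizer with decoupled weight decay.

    Operates on arbitrary parameter pytrees by flattening them to a single
    vector; the tree structure of the gradients must match the parameters.
    """

    def __init__(self, lr=1e-4, weight_decay=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self._m = None
        self._v = None
        self._t = 0

    def step(self, params, grads, lr=None):
        """Return updated params; ``lr`` overrides the stored rate (scheduling)."""
        lr = self.lr if lr is None else lr
        flat_p, unflatten = flatten(params)
        flat_g, _ = flatten(grads)
        if self._m is None:
            self._m = np.zeros_like(flat_p)
            self._v = np.zeros_like(flat_p)
        b1, b2 = self.betas
        self._t += 1
        self._m = b1 * self._m + (1 - b1) * flat_g
        self._v = b2 * self._v + (1 - b2) * flat_g**2
        mhat = self._m / (1 - b1**self._t)
        vhat = self._v / (1 - b2**self._t)
        flat_p = flat_p - lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * flat_p)
        return unflatten(flat_p)
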