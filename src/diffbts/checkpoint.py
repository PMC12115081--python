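"""Checkpoint save/load: parameter pytrees in .npz plus a JSON sidecar."""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import numpy as np

from .backbone import BackboneConfig

__all__ = ["save_checkpoint", "load_checkpoint"]


def _flatten_tree(tree, prefix=""):
    if isinstance(tree, dict):
        for k, v in tree.items():
            yield from _flatten_tree(v, f"{prefix}{k}.")
    elif isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            yield from _flatten_tree(v, f"{prefix}{i}.")
    else:
        yield prefix[:-1], np.asarray(tree)


def _set_path(tree, path, value):
    keys = path.split(".")
    node = tree
    for k, nxt in zip(keys[:-1], keys[1:]):
        k = int(k) if k.isdigit() else k
        default = [] if nxt.isdigit() else {}
        if isinstance(node, list):
            while len(node) <= k:
                node.append(None)
            if node[k] is None:
                node[k] = default
            node = node[k]
        else:
            node = node.setdefault(k, default)
    k = keys[-1]
    if isinstance(node, list):
        k = int(k)
        while len(node) <= k:
            node.append(None)
        node[k] = value
    else:
        node[k] = value


def save_checkpoint(path: str, params: dict, cfg: BackboneConfig, extra: dict | None = None):
    """Write ``<path>.npz`` (weights) and ``<path>.json`` (config/metadata)."""
    arrays = dict(_flatten_tree(params))
    np.savez(path + ".npz", **arrays)
    meta = {"backbone": asdict(cfg)}
    if extra:
        meta.update(extra)
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_checkpoint(path: str):
    """Load a checkpoint written by :func:`save_checkpoint`.

    Returns ``(params, cfg, meta)``.
    """
    npz_path = path + ".npz" if not path.endswith(".npz") else path
    base = npz_path[: -len(".npz")]
    if not os.path.exists(npz_path):
        raise FileNotFoundError(f"missing checkpoint weights: {npz_path}")
    params: dict = {}
    with np.load(npz_path) as data:
        for key in data.files:
            _set_path(params, key, data[key])
    with open(base + ".json") as fh:
        meta = json.load(fh)
    cfg = BackboneConfig(**meta.pop("backbone"))
    return params, cfg, meta
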