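"""Shared helpers: seeding, input coercion, positive-definite repairs."""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd


def child_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from a master seed.

    Stages are named, so adding a stage never shifts the seeds of the
    existing ones.
    """
    h = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def rng_for(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, stage))


def as_data_matrix(data) -> tuple[np.ndarray, list[str]]:
    """Coerce item-response input to (n x p float array, item labels).

    Accepts an ItemResponseMatrix, a DataFrame, or a plain array.
    """
    if hasattr(data, "values_array") and hasattr(data, "item_ids"):
        return data.values_array(), list(data.item_ids)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(c) for c in data.columns]
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D participants x items array")
    return arr, [f"V{i + 1}" for i in range(arr.shape[1])]


def as_weight_matrix(net) -> np.ndarray:
    """Coerce a network-like object to its symmetric weight matrix."""
    w = net.weights if hasattr(net, "weights") else net
    if hasattr(w, "to_numpy"):
        w = w.to_numpy()
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    return w


def net_labels(net, p: int) -> list[str]:
    labels = getattr(net, "labels", None)
    if labels is None:
        return [f"V{i + 1}" for i in range(p)]
    return list(labels)


def nearest_pd_correlation(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, eps, None)
    repaired = (vecs * vals) @ vecs.T
    d = 1.0 / np.sqrt(np.diag(repaired))
    repaired = repaired * np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return 0.5 * (repaired + repaired.T)


def is_positive_definite(mat: np.ndarray, tol: float = 0.0) -> bool:
    return bool(np.linalg.eigvalsh(mat).min() > tol)
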