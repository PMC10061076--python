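"""Cosine-similarity evaluation metric for 3D direction decoding."""

from __future__ import annotations

import warnings

import numpy as np


def cosine_similarity(pred, target) -> float:
    """Cosine of the angle between two vectors.

    1 for perfect prediction, 0 for orthogonal vectors, -1 for opposite
    direction.  A zero-norm input is defined to score 0 (with a warning) so
    the metric stays training-safe.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    np_, nt = np.linalg.norm(pred), np.linalg.norm(target)
    if np_ == 0.0 or nt == 0.0:
        warnings.warn("zero-norm vector in cosine similarity; returning 0", stacklevel=2)
        return 0.0
    return float(np.clip(np.dot(pred, target) / (np_ * nt), -1.0, 1.0))


def cosine_similarity_rows(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Row-wise cosine similarity for (n, 3) arrays; zero-norm rows score 0."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    pn = np.linalg.norm(pred, axis=-1)
    tn = np.linalg.norm(target, axis=-1)
    denom = pn * tn
    out = np.zeros(denom.shape)
    ok = denom > 0
    out[ok] = np.sum(pred * target, axis=-1)[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0)


def mean_cosine_similarity(pred: np.ndarray, target: np.ndarray) -> float:
    """Unweighted mean of per-sample cosine similarities."""
    if len(pred) == 0:
        raise ValueError("empty prediction set")
    return float(np.mean(cosine_similarity_rows(pred, target)))
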