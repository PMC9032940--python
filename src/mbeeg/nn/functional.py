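"""Stateless numerical primitives used by the layers and the loss."""

from __future__ import annotations

import numpy as np

__all__ = [
    "softmax_probabilities",
    "elu",
    "elu_grad",
    "sigmoid",
    "cross_entropy",
]


def softmax_probabilities(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax ``p_i = exp(v_i) / sum_j exp(v_j)``.

    Computed with max-subtraction, which leaves the result mathematically
    unchanged (the softmax is shift-invariant) but avoids overflow.

    Parameters
    ----------
    logits : ndarray, shape (batch, n_classes)

    Returns
    -------
    ndarray of the same shape; each row is non-negative and sums to 1.
    """
    logits = np.asarray(logits, dtype=np.float64)
    if logits.ndim != 2:
        raise ValueError(f"logits must be 2-D (batch, classes), got {logits.shape}")
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits contain non-finite values")
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def elu(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Exponential linear unit: x for x>0, alpha*(exp(x)-1) otherwise."""
    return np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0)))


def elu_grad(x: np.ndarray, y: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Derivative of ELU given input x and output y (= elu(x))."""
    return np.where(x > 0, 1.0, y + alpha)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def cross_entropy(probs: np.ndarray, labels01: np.ndarray) -> float:
    """Mean categorical cross-entropy of softmax outputs.

    ``labels01`` are 0-based integer class indices.
    """
    n = probs.shape[0]
    p = np.clip(probs[np.arange(n), labels01], 1e-12, None)
    return float(-np.mean(np.log(p)))
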