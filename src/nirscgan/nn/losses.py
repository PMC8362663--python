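"""Numerically stable losses with analytic gradients."""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "softmax_cross_entropy", "bce_with_logits"]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of (N, K) logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy of integer ``labels`` under ``logits``.

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the mean
    loss with respect to the logits.
    """
    n = logits.shape[0]
    p = softmax(logits)
    idx = (np.arange(n), np.asarray(labels, dtype=int))
    loss = float(-np.log(np.maximum(p[idx], 1e-300)).mean())
    grad = p.copy()
    grad[idx] -= 1.0
    return loss, grad / n


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits (sigmoid folded in).

    Uses the log-sum-exp form ``max(z,0) − z·t + log(1+exp(−|z|))`` so no
    overflow occurs for large |z|.  Returns ``(loss, dlogits)``.
    """
    z = np.asarray(logits).ravel()
    t = np.asarray(targets, dtype=z.dtype).ravel()
    loss = float((np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))).mean())
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    grad = (p - t) / z.size
    return loss, grad.reshape(np.shape(logits))
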