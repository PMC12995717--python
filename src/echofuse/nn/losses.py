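"""Loss functions returning (loss, gradient-with-respect-to-logits)."""

from __future__ import annotations

import numpy as np


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross entropy on raw logits (numerically stable)."""
    logits = np.asarray(logits, dtype=np.float64).ravel()
    targets = np.asarray(targets, dtype=np.float64).ravel()
    if logits.shape != targets.shape:
        raise ValueError(f"shape mismatch {logits.shape} vs {targets.shape}")
    # softplus(l) - y*l, with softplus computed stably
    loss = np.mean(np.logaddexp(0.0, logits) - targets * logits)
    probs = 1.0 / (1.0 + np.exp(-logits))
    grad = (probs - targets) / logits.size
    return float(loss), grad.astype(np.float32)


def cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean softmax cross entropy; ``targets`` are integer class ids."""
    logits = np.asarray(logits, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.int64).ravel()
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = logits.shape[0]
    loss = -float(logp[np.arange(n), targets].mean())
    grad = np.exp(logp)
    grad[np.arange(n), targets] -= 1.0
    return loss, (grad / n).astype(np.float32)
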