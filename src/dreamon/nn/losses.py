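"""Loss functions returning ``(loss, dlogits)`` pairs.

Cross-entropy accepts soft targets (any point on the probability simplex),
which is what interpolated class-weight labels require; for one-hot
targets it reduces to ordinary cross-entropy.
"""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean soft-target cross-entropy ``-sum_c t_c log p_c`` and its logit gradient."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-(targets * np.log(p + 1e-12)).sum() / n)
    dlogits = (p - targets) / n
    return loss, dlogits


def bce_with_logits(logits: np.ndarray, target: float):
    """Mean binary cross-entropy on raw logits against a constant target (0 or 1)."""
    x = logits.reshape(-1)
    n = x.size
    loss = float(np.mean(np.maximum(x, 0) - x * target + np.log1p(np.exp(-np.abs(x)))))
    sig = 1.0 / (1.0 + np.exp(-x))
    dlogits = ((sig - target) / n).reshape(logits.shape)
    return loss, dlogits
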