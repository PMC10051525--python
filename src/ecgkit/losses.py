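"""Training objectives.

Three losses cover the three tasks: categorical cross-entropy for the
five-class beat task, binary focal loss ``FL = -alpha_t * (1-p_t)^gamma *
log(p_t)`` for the imbalanced binary diagnostic task, and plain binary
cross-entropy for atrial-fibrillation segment classification. Scalar closed
forms are exposed for testing; the ``*_from_logits`` variants build the
differentiable batch losses used by the training loop (reduction: mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "FocalParams",
    "categorical_cross_entropy",
    "binary_focal_loss",
    "binary_cross_entropy",
    "softmax_ce_from_logits",
    "focal_from_logits",
    "bce_from_logits",
]

_P_CLAMP = 1e-7


@dataclass
class FocalParams:
    """Focal-loss hyperparameters: weighting factor and focusing exponent."""

    alpha_t: float = 0.25
    gamma: float = 2.0

    def __post_init__(self):
        if not 0.0 < self.alpha_t <= 1.0:
            raise ValueError("alpha_t must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def categorical_cross_entropy(scores, p_index: int) -> float:
    """CE = -log(softmax(scores)[p_index]), via the log-sum-exp stable form."""
    s = np.asarray(scores, dtype=np.float64)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("scores must be a vector of at least 2 class scores")
    if not 0 <= p_index < s.size:
        raise ValueError(f"p_index {p_index} out of range for {s.size} classes")
    m = s.max()
    lse = m + np.log(np.exp(s - m).sum())
    return float(lse - s[p_index])


def _clamp(p: float) -> float:
    return float(np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP))


def binary_focal_loss(p: float, y: int, params: FocalParams = FocalParams()) -> float:
    """FL(p_t) = -alpha_t * (1 - p_t)^gamma * log(p_t), p_t = p if y else 1-p."""
    if y not in (0, 1):
        raise ValueError("y must be 0 or 1")
    p = _clamp(p)
    p_t = p if y == 1 else 1.0 - p
    return float(-params.alpha_t * (1.0 - p_t) ** params.gamma * np.log(p_t))


def binary_cross_entropy(p: float, y: int) -> float:
    """BCE = -[y log p + (1-y) log(1-p)] with probability clamping."""
    if y not in (0, 1):
        raise ValueError("y must be 0 or 1")
    p = _clamp(p)
    return float(-(y * np.log(p) + (1 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# differentiable batch losses (mean reduction)
# ---------------------------------------------------------------------------

def softmax_ce_from_logits(logits: Tensor, labels) -> Tensor:
    """Mean categorical cross-entropy over a (batch, C) logit tensor."""
    labels = np.asarray(labels, dtype=int)
    B, C = logits.shape
    onehot = np.zeros((B, C))
    onehot[np.arange(B), labels] = 1.0
    m = Tensor(logits.data.max(axis=1, keepdims=True))  # detached shift
    lse = ((logits - m).exp().sum(axis=1, keepdims=True)).log() + m
    return (lse.reshape(B) - (logits * Tensor(onehot)).sum(axis=1)).mean()


def _pt(logits: Tensor, labels) -> tuple[Tensor, np.ndarray]:
    y = np.asarray(labels, dtype=np.float64).reshape(-1)
    p = logits.reshape(logits.data.size).sigmoid().clip(_P_CLAMP, 1.0 - _P_CLAMP)
    p_t = p * Tensor(y) + (1.0 - p) * Tensor(1.0 - y)
    return p_t, y

def focal_from_logits(logits: Tensor, labels,
                      params: FocalParams = FocalParams()) -> Tensor:
    """Mean binary focal loss; class weight alpha_t on positives,
    (1 - alpha_t) on negatives (the canonical alpha-balanced form)."""
    p_t, y = _pt(logits, labels)
    alpha = params.alpha_t * y + (1.0 - params.alpha_t) * (1.0 - y)
    fl = Tensor(-alpha) * ((1.0 - p_t) ** params.gamma) * p_t.log()
    return fl.mean()


def bce_from_logits(logits: Tensor, labels) -> Tensor:
    """Mean binary cross-entropy over a (batch,) or (batch, 1) logit tensor."""
    p_t, _ = _pt(logits, labels)
    return (-(p_t.log())).mean()
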