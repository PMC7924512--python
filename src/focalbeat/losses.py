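"""Classification losses: cross-entropy, focal, and α-balanced focal.

All losses operate on one-hot targets ``t`` and softmax probabilities ``p``
over the four beat classes and reduce by the arithmetic mean over the batch.
With ``p_t`` the probability assigned to the true class:

* cross-entropy:      ``CE = -log(p_t)``
* focal:              ``FL = -(1 - p_t)^γ log(p_t)``
* α-balanced focal:   ``FL' = -α_t (1 - p_t)^γ log(p_t)``

The ``(1 - p_t)^γ`` modulating factor shrinks the contribution of already
well-classified examples, so abundant easy beats (class N) stop drowning out
the rare classes; larger γ shrinks them harder, and γ = 0 recovers plain
cross-entropy.  Probabilities are clipped to ``[1e-7, 1]`` before the log.

``softmax_loss_gradient`` supplies the exact gradient with respect to the
pre-softmax logits for all three variants; training consumes that, and a
test verifies it against numerical differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "cross_entropy",
    "focal_loss",
    "alpha_focal_loss",
    "compute_loss",
    "softmax_loss_gradient",
    "EPS",
]

EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Loss selection; defaults replicate the reference configuration
    (plain, non-α-balanced focal loss with γ = 2)."""

    kind: str = "focal"  # cross_entropy | focal | alpha_focal
    gamma: float = 2.0
    alpha: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cross_entropy", "focal", "alpha_focal"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.kind == "alpha_focal":
            if self.alpha is None or len(self.alpha) != 4:
                raise ValueError("alpha_focal requires exactly 4 alpha weights")
            if any(a <= 0 for a in self.alpha):
                raise ValueError("alpha weights must be > 0")


def _p_true(targets: np.ndarray, probs: np.ndarray) -> np.ndarray:
    targets = np.asarray(targets, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if targets.shape != probs.shape or targets.ndim != 2:
        raise ValueError(
            f"targets and probs must share shape (batch, n_classes); "
            f"got {targets.shape} vs {probs.shape}"
        )
    return np.clip((targets * probs).sum(axis=1), EPS, 1.0)


def cross_entropy(targets: np.ndarray, probs: np.ndarray) -> float:
    """Mean batch cross-entropy, natural log."""
    return float(np.mean(-np.log(_p_true(targets, probs))))


def focal_loss(targets: np.ndarray, probs: np.ndarray, gamma: float = 2.0) -> float:
    """Mean batch focal loss with modulating exponent ``gamma``."""
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    pt = _p_true(targets, probs)
    return float(np.mean(-((1.0 - pt) ** gamma) * np.log(pt)))


def alpha_focal_loss(
    targets: np.ndarray,
    probs: np.ndarray,
    gamma: float = 2.0,
    alpha: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> float:
    """Mean batch α-balanced focal loss (per-class weight on the true class)."""
    alpha_arr = np.asarray(alpha, dtype=float)
    if alpha_arr.shape != (np.asarray(targets).shape[1],):
        raise ValueError(
            f"alpha must have one weight per class, got shape {alpha_arr.shape}"
        )
    pt = _p_true(targets, probs)
    a_t = np.asarray(targets, dtype=float) @ alpha_arr
    return float(np.mean(-a_t * (1.0 - pt) ** gamma * np.log(pt)))


def compute_loss(targets: np.ndarray, probs: np.ndarray, config: LossConfig) -> float:
    if config.kind == "cross_entropy":
        return cross_entropy(targets, probs)
    if config.kind == "focal":
        return focal_loss(targets, probs, config.gamma)
    return alpha_focal_loss(targets, probs, config.gamma, config.alpha)


def softmax_loss_gradient(
    targets: np.ndarray, probs: np.ndarray, config: LossConfig
) -> np.ndarray:
    """Gradient of the mean batch loss w.r.t. the pre-softmax logits.

    For ``L = -α_t (1-p_t)^γ log(p_t)`` with ``p = softmax(z)``:

        dL/dp_t = α_t [ γ (1-p_t)^(γ-1) log(p_t) - (1-p_t)^γ / p_t ]
        dp_t/dz_j = p_t (1[j = t] - p_j)

    γ = 0 collapses to the familiar ``(p - t) / batch``.
    """
    targets = np.asarray(targets, dtype=float)
    probs = np.asarray(probs, dtype=float)
    batch = targets.shape[0]
    pt = _p_true(targets, probs)[:, None]  # (B, 1)
    gamma = 0.0 if config.kind == "cross_entropy" else config.gamma
    if config.kind == "alpha_focal":
        a_t = (targets @ np.asarray(config.alpha, dtype=float))[:, None]
    else:
        a_t = 1.0
    one_m = np.clip(1.0 - pt, EPS, 1.0)
    if gamma == 0.0:
        dl_dpt = -a_t / pt
    else:
        dl_dpt = a_t * (gamma * one_m ** (gamma - 1.0) * np.log(pt) - one_m**gamma / pt)
    dpt_dz = pt * (targets - probs)  # (B, C): p_t * (1[j=t] - p_j)
    return dl_dpt * dpt_dz / batch
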