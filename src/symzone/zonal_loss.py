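"""Zonal loss: hierarchical cross-entropy with inter-class probability
constraints, and its focal variant.

The model predicts a two-channel probability map ``p = [p0, p1]`` per voxel
against hierarchical labels ``m = [m0, m1]`` (see :mod:`symzone.labels`).
Because the label pattern [0, 1] is undefined, any prediction with
``p1 > p0`` is inconsistent and is penalized by substituting constrained
probabilities before the cross-entropy::

    p0' = p0              if m0 = 1        p1' = min(p0, p1)  if m1 = 1
        = max(p0, p1)     if m0 = 0            = p1           if m1 = 0

The modified cross-entropy is then

    L(P, M) = sum_v  -m · log p'  - (1 - m) · log(1 - p')

and the focal form down-weights easy voxels with the usual modulating
factor (gamma = 0 recovers the plain modified cross-entropy)::

    L_ZL(P, M) = sum_v  -m (1-p')^γ log p'  -  (1-m) p'^γ log(1-p')

Two parallel implementations are provided: vectorized NumPy functions (the
public evaluation API) and autodiff-graph versions (suffixed ``_t``) used
in training.  The test suite checks both against an independent per-voxel
scalar oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "LossConfig",
    "constrain_probs",
    "modified_ce",
    "zonal_loss",
    "focal_loss_binary",
    "zonal_loss_t",
    "focal_loss_binary_t",
]


@dataclass(frozen=True)
class LossConfig:
    """gamma: focal exponent (>= 0); eps: log-clamp; reduction: 'sum' | 'mean'."""

    gamma: float = 2.0
    eps: float = 1e-7
    reduction: str = "sum"

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0 < self.eps <= 1e-3:
            raise ValueError("eps must be in (0, 1e-3]")
        if self.reduction not in ("sum", "mean"):
            raise ValueError("reduction must be 'sum' or 'mean'")


def _validate_pair(p: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    m = np.asarray(m)
    if p.shape != m.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs labels {m.shape}")
    if p.shape[0] != 2:
        raise ValueError("expected 2-channel maps with channel axis first")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if np.any((m[1] == 1) & (m[0] == 0)):
        raise ValueError("undefined label pattern [0, 1] encountered")
    return p, m


def constrain_probs(p: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Apply the inter-class constraints elementwise over a (2, ...) pair."""
    p, m = _validate_pair(p, m)
    p0, p1 = p[0], p[1]
    m0, m1 = m[0], m[1]
    q0 = np.where(m0 == 1, p0, np.maximum(p0, p1))
    q1 = np.where(m1 == 1, np.minimum(p0, p1), p1)
    return np.stack([q0, q1])


def _ce_terms(q: np.ndarray, m: np.ndarray, gamma: float, eps: float) -> np.ndarray:
    q = np.clip(q, eps, 1.0 - eps)
    m = m.astype(np.float64)
    pos = -np.log(q)
    neg = -np.log(1.0 - q)
    if gamma > 0:
        pos = (1.0 - q) ** gamma * pos
        neg = q ** gamma * neg
    return m * pos + (1.0 - m) * neg


def _reduce(terms: np.ndarray, reduction: str) -> float:
    # "mean" averages over voxels (the channel pair still sums), so the two
    # reductions differ only by the voxel count.
    if reduction == "sum":
        return float(terms.sum())
    return float(terms.sum(axis=0).mean())


def zonal_loss(p: np.ndarray, m: np.ndarray, cfg: LossConfig = LossConfig()) -> float:
    """Focal hierarchical loss on a (2, D, H, W) probability/label pair."""
    q = constrain_probs(p, m)
    return _reduce(_ce_terms(q, np.asarray(m), cfg.gamma, cfg.eps), cfg.reduction)


def modified_ce(p: np.ndarray, m: np.ndarray, cfg: LossConfig = LossConfig(gamma=0.0)) -> float:
    """Constrained cross-entropy: the gamma = 0 zonal loss."""
    cfg = LossConfig(gamma=0.0, eps=cfg.eps, reduction=cfg.reduction)
    return zonal_loss(p, m, cfg)


def focal_loss_binary(p: np.ndarray, m: np.ndarray, cfg: LossConfig = LossConfig()) -> float:
    """Plain focal loss on a single-channel probability map (baseline)."""
    p = np.asarray(p, dtype=np.float64)
    m = np.asarray(m)
    if p.shape != m.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs labels {m.shape}")
    return _reduce(_ce_terms(p, m, cfg.gamma, cfg.eps), cfg.reduction)


# -- autodiff-graph variants (used by the training loop) ----------------------


def _ce_terms_t(q: "nn.Tensor", m: np.ndarray, gamma: float, eps: float) -> "nn.Tensor":
    q = q.clamp(eps, 1.0 - eps)
    m = m.astype(np.float32)
    pos = -q.log()
    neg = -(1.0 - q).log()
    if gamma > 0:
        pos = (1.0 - q).pow(gamma) * pos
        neg = q.pow(gamma) * neg
    return nn.Tensor(m) * pos + nn.Tensor(1.0 - m) * neg


def _reduce_t(terms: "nn.Tensor", reduction: str, channel_axis: int) -> "nn.Tensor":
    if reduction == "sum":
        return terms.sum()
    n_vox = terms.data.size / terms.shape[channel_axis]
    return terms.sum() * (1.0 / float(n_vox))


def zonal_loss_t(p: "nn.Tensor", m: np.ndarray, cfg: LossConfig = LossConfig()) -> "nn.Tensor":
    """Differentiable zonal loss; p has shape (N, 2, D, H, W), m matches.

    Ties p0 == p1 in the max/min route their gradient to channel 0.
    """
    m = np.asarray(m)
    if p.shape != m.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs labels {m.shape}")
    if np.any((m[:, 1] == 1) & (m[:, 0] == 0)):
        raise ValueError("undefined label pattern [0, 1] encountered")
    p0 = _slice_channel(p, 0)
    p1 = _slice_channel(p, 1)
    m0 = m[:, 0:1].astype(np.float32)
    m1 = m[:, 1:2].astype(np.float32)
    q0 = nn.Tensor(m0) * p0 + nn.Tensor(1.0 - m0) * nn.maximum(p0, p1)
    q1 = nn.Tensor(m1) * nn.minimum(p0, p1) + nn.Tensor(1.0 - m1) * p1
    terms = _ce_terms_t(q0, m[:, 0:1], cfg.gamma, cfg.eps) + _ce_terms_t(
        q1, m[:, 1:2], cfg.gamma, cfg.eps
    )
    if cfg.reduction == "sum":
        return terms.sum()
    return terms.sum() * (1.0 / float(m[:, 0].size))


def focal_loss_binary_t(p: "nn.Tensor", m: np.ndarray, cfg: LossConfig = LossConfig()) -> "nn.Tensor":
    """Differentiable plain focal loss; p has shape (N, 1, D, H, W)."""
    m = np.asarray(m)
    if p.shape != m.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs labels {m.shape}")
    terms = _ce_terms_t(p, m, cfg.gamma, cfg.eps)
    if cfg.reduction == "sum":
        return terms.sum()
    return terms.sum() * (1.0 / float(m.size))


def _slice_channel(p: "nn.Tensor", c: int) -> "nn.Tensor":
    """Channel slice (N, 1, D, H, W) of a 5-D tensor, with gradient."""
    data = p.data[:, c : c + 1]

    def backward(g, p=p, c=c):
        if p.requires_grad:
            full = np.zeros_like(p.data)
            full[:, c : c + 1] = g
            p._accum(full)

    return nn.Tensor._from_op(data, (p,), backward)
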