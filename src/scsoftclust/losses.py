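"""Training objectives: reconstruction, structure-guided contrastive, soft KL.

The total objective is  L = L_r + alpha * L_c + beta * L_s  where

* L_r sums squared reconstruction errors over cells for both modalities;
* L_c is a contrastive alignment between the consensus H_hat and each
  modality head H^m, in which the structural matrix S down-weights
  structurally close cells among the negatives:

      L_c = -(1/2n) sum_i sum_m log( e^{D(H_hat_i, H_i^m)/T}
            / ( sum_j e^{(1 - S_ij) D(H_hat_i, H_j^m)/T} - e^{1/T} ) )

  The subtracted e^{1/T} can drive the denominator non-positive (already for
  n = 1 with perfectly aligned heads), so the denominator is clamped below at
  1e-8 and clamp events are counted.  The alternative reading — subtracting
  the i = j self term instead — is available via
  ``denominator="drop_self"``;
* L_s = sum_i KL(gamma_i || q_i) pulls the Student-t assignments q toward the
  fuzzy c-means memberships gamma, which are treated as a constant target (no
  gradient flows through gamma).  The classical target-distribution KL
  (p derived from q) is kept as `dec_target_kl` for the soft-clustering
  ablation.

Natural logarithms throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, maximum

logger = logging.getLogger(__name__)

__all__ = [
    "LossWeights",
    "reconstruction_loss",
    "cosine_similarity",
    "contrastive_loss",
    "soft_clustering_loss",
    "dec_target_kl",
    "student_t_q",
    "total_loss",
]

_NORM_FLOOR = 1e-12
_DENOM_FLOOR = 1e-8
_warned_zero_norm = False


@dataclass(frozen=True)
class LossWeights:
    """Trade-off weights: alpha on the contrastive term, beta on the soft term."""

    alpha: float = 1.0
    beta: float = 1.0
    temperature: float = 0.5

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")


def _check_same_shape(a, b, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what}: shapes {a.shape} vs {b.shape} differ")


def reconstruction_loss(x1, x2, x1_hat: Tensor, x2_hat: Tensor) -> Tensor:
    """Sum over cells of squared Euclidean reconstruction error, both modalities."""
    x1, x2 = Tensor._lift(x1), Tensor._lift(x2)
    x1_hat, x2_hat = Tensor._lift(x1_hat), Tensor._lift(x2_hat)
    _check_same_shape(x1, x1_hat, "RNA reconstruction")
    _check_same_shape(x2, x2_hat, "ATAC reconstruction")
    return ((x1 - x1_hat) ** 2).sum() + ((x2 - x2_hat) ** 2).sum()


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1].

    Zero-norm vectors have their norm floored at 1e-12 (warned once per run).
    """
    global _warned_zero_norm
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if (nu < _NORM_FLOOR or nv < _NORM_FLOOR) and not _warned_zero_norm:
        logger.warning("zero-norm vector in cosine similarity; norm floored at 1e-12")
        _warned_zero_norm = True
    return float(u @ v / (max(nu, _NORM_FLOOR) * max(nv, _NORM_FLOOR)))


def _row_normalize(t: Tensor) -> Tensor:
    norms = maximum((t * t).sum(axis=1, keepdims=True).sqrt(), _NORM_FLOOR)
    return t / norms


def _validate_row_stochastic(m: np.ndarray, name: str) -> None:
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError(f"{name} must be row-stochastic (rows summing to 1)")


def contrastive_loss(
    h_hat: Tensor,
    h1: Tensor,
    h2: Tensor,
    s: Tensor,
    temperature: float,
    denominator: str = "as_printed",
) -> tuple[Tensor, int]:
    """Structure-guided contrastive loss; returns (loss, clamp count).

    The clamp count is the number of (cell, modality) denominators that hit
    the 1e-8 floor, a diagnostic for how often the subtracted e^{1/T} term
    dominates.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if denominator not in ("as_printed", "drop_self"):
        raise ValueError("denominator must be 'as_printed' or 'drop_self'")
    h_hat, h1, h2, s = map(Tensor._lift, (h_hat, h1, h2, s))
    n = h_hat.shape[0]
    for m, name in ((h1, "h1"), (h2, "h2")):
        if m.shape != h_hat.shape:
            raise ValueError(f"{name} shape {m.shape} != h_hat shape {h_hat.shape}")
    if s.shape != (n, n):
        raise ValueError(f"S must be {n}x{n}, got {s.shape}")
    _validate_row_stochastic(s.data, "S")

    inv_t = 1.0 / temperature
    hn = _row_normalize(h_hat)
    clamped = 0
    per_modality = []
    eye = np.eye(n)
    for hm in (h1, h2):
        hmn = _row_normalize(hm)
        sim = hn @ hmn.T                       # n x n cosine similarities
        pos = (hn * hmn).sum(axis=1)           # diagonal D(H_hat_i, H_i^m)
        expo = ((1.0 - s) * sim * inv_t).exp()
        row_total = expo.sum(axis=1)
        if denominator == "as_printed":
            den = row_total - float(np.exp(inv_t))
        else:
            den = row_total - (expo * eye).sum(axis=1)
        clamped += int((den.data < _DENOM_FLOOR).sum())
        den = maximum(den, _DENOM_FLOOR)
        per_modality.append((pos * inv_t - den.log()).sum())
    loss = -(per_modality[0] + per_modality[1]) * (1.0 / (2.0 * n))
    return loss, clamped


def student_t_q(h: Tensor, centers: Tensor) -> Tensor:
    """Differentiable Student-t (nu=1) assignments of embeddings to centers."""
    h, centers = Tensor._lift(h), Tensor._lift(centers)
    h_sq = (h * h).sum(axis=1, keepdims=True)          # n x 1
    c_sq = (centers * centers).sum(axis=1, keepdims=True).T  # 1 x k
    d2 = maximum(h_sq + c_sq - 2.0 * (h @ centers.T), 0.0)
    w = 1.0 / (1.0 + d2)
    return w / w.sum(axis=1, keepdims=True)


def soft_clustering_loss(gamma: np.ndarray, q: Tensor) -> Tensor:
    """Sum over cells of KL(gamma_i || q_i), gamma a constant target.

    Non-negative, zero iff gamma equals q row-wise; q entries are floored at
    1e-12 before the log.
    """
    gamma = np.asarray(gamma, dtype=np.float64)
    q = Tensor._lift(q)
    _check_same_shape(Tensor(gamma), q, "soft clustering loss")
    _validate_row_stochastic(gamma, "gamma")
    _validate_row_stochastic(q.data, "q")
    g_log_g = float(np.where(gamma > 0, gamma * np.log(np.maximum(gamma, 1e-300)), 0.0).sum())
    cross = (Tensor(gamma) * maximum(q, 1e-12).log()).sum()
    return g_log_g - cross


def dec_target_kl(q: Tensor) -> Tensor:
    """Classical self-training KL with target p_ij = (q_ij^2 / f_j) normalized.

    f_j are the soft cluster frequencies; p is derived from the current q and
    detached.  This is the baseline objective the soft-clustering ablation
    falls back to.
    """
    q = Tensor._lift(q)
    qd = q.data
    f = qd.sum(axis=0, keepdims=True)
    p = qd**2 / f
    p = p / p.sum(axis=1, keepdims=True)
    p_log_p = float(np.where(p > 0, p * np.log(np.maximum(p, 1e-300)), 0.0).sum())
    cross = (Tensor(p) * maximum(q, 1e-12).log()).sum()
    return p_log_p - cross


def total_loss(lr, lc, ls, weights: LossWeights):
    """L = L_r + alpha * L_c + beta * L_s (exactly L_r when alpha = beta = 0)."""
    out = lr
    if weights.alpha != 0.0:
        out = out + weights.alpha * lc
    if weights.beta != 0.0:
        out = out + weights.beta * ls
    return out
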