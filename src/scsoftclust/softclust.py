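"""Soft cluster assignments: Student-t responsibilities and fuzzy c-means.

Two membership notions coexist during training.  ``q`` is the Student-t
(one degree of freedom) soft assignment of each embedded cell to each cluster
center, the differentiable quantity the clustering loss pushes on.  ``gamma``
is the fuzzy c-means membership: the closed-form minimizer of

    min_gamma  sum_j gamma_ij^m ||z_i - mu_j||^2   s.t.  sum_j gamma_ij = 1,

with fuzzifier m > 1.  gamma serves as the (constant) target distribution.
All functions here are plain numpy; the differentiable Student-t used inside
the training loss lives in `losses`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "SoftClusterState",
    "student_t_assignment",
    "fuzzy_memberships",
    "update_centers",
    "initialize_centers",
    "fcm_objective",
]

_COINCIDE_TOL = 1e-12


@dataclass
class SoftClusterState:
    """Cluster centers plus both membership matrices for one set of embeddings."""

    centers: np.ndarray  # k x d_f
    gamma: np.ndarray    # n x k, rows sum to 1
    q: np.ndarray        # n x k, rows sum to 1
    fuzzifier: float
    n_clusters: int

    def __post_init__(self) -> None:
        if self.fuzzifier <= 1.0:
            raise ValueError("fuzzifier m must be strictly greater than 1")
        for name in ("gamma", "q"):
            m = getattr(self, name)
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"{name} rows must sum to 1")


def student_t_assignment(h: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Student-t (nu=1) soft assignment of each row of ``h`` to each center.

    q_ij = (1 + ||h_i - mu_j||^2)^-1, normalized over j.
    """
    h = np.atleast_2d(np.asarray(h, dtype=np.float64))
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    d2 = cdist(h, centers, metric="sqeuclidean")
    w = 1.0 / (1.0 + d2)
    return w / w.sum(axis=1, keepdims=True)


def fuzzy_memberships(
    z: np.ndarray, centers: np.ndarray, fuzzifier: float
) -> np.ndarray:
    """Closed-form fuzzy c-means memberships of ``z`` rows w.r.t. ``centers``.

    gamma_ij is proportional to ||z_i - mu_j||^(-2/(m-1)).  A point that
    coincides with one or more centers gets its unit mass split uniformly
    over the coinciding centers (the degenerate-limit convention).
    """
    if fuzzifier <= 1.0:
        raise ValueError("fuzzifier m must be strictly greater than 1")
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    dist = cdist(z, centers)
    gamma = np.zeros_like(dist)
    at_center = dist < _COINCIDE_TOL
    coincides = at_center.any(axis=1)
    if coincides.any():
        rows = at_center[coincides]
        gamma[coincides] = rows / rows.sum(axis=1, keepdims=True)
    free = ~coincides
    if free.any():
        # log-space for stability: the exponent -2/(m-1) blows up as m -> 1
        logit = (-2.0 / (fuzzifier - 1.0)) * np.log(dist[free])
        logit -= logit.max(axis=1, keepdims=True)
        inv = np.exp(logit)
        gamma[free] = inv / inv.sum(axis=1, keepdims=True)
    return gamma


def fcm_objective(
    z: np.ndarray, centers: np.ndarray, gamma: np.ndarray, fuzzifier: float
) -> float:
    """The weighted-distance objective that `fuzzy_memberships` minimizes."""
    d2 = cdist(np.atleast_2d(z), np.atleast_2d(centers), metric="sqeuclidean")
    return float((gamma**fuzzifier * d2).sum())


def update_centers(
    z: np.ndarray, gamma: np.ndarray, fuzzifier: float
) -> np.ndarray:
    """Stationarity update mu_j = sum_i gamma_ij^m z_i / sum_i gamma_ij^m.

    Used for initialization-time fuzzy c-means iterations; during joint
    training the centers are free parameters by default.  A cluster whose
    total fuzzy weight underflows is re-seeded to the least-committed point.
    """
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    w = np.asarray(gamma, dtype=np.float64) ** fuzzifier
    totals = w.sum(axis=0)
    centers = np.empty((gamma.shape[1], z.shape[1]))
    for j, total in enumerate(totals):
        if total < 1e-12:
            fallback = int(np.argmin(gamma.max(axis=1)))
            logger.warning("cluster %d empty; re-seeding to point %d", j, fallback)
            centers[j] = z[fallback]
        else:
            centers[j] = w[:, j] @ z / total
    return centers


def initialize_centers(h: np.ndarray, k: int, seed: int) -> np.ndarray:
    """k-means centroids (10 restarts, seeded) of the embedding ``h``."""
    h = np.atleast_2d(np.asarray(h, dtype=np.float64))
    if h.shape[0] < k:
        raise ValueError(f"cannot place {k} centers with only {h.shape[0]} points")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(h)
    return km.cluster_centers_.astype(np.float64)
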