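"""External clustering indices: best-match accuracy, NMI, ARI.

All three are computed from the contingency table between the true and
predicted partitions.  Accuracy maximizes the matched fraction over
one-to-one relabelings of the predictions (linear assignment on the padded
square table); NMI normalizes mutual information by the arithmetic mean of
the two label entropies (natural log; the ratio is base-invariant); ARI is
the pair-counting Rand index adjusted for chance via its hypergeometric
expectation.  Each is invariant to renaming clusters in either argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import comb

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "contingency_table",
    "clustering_accuracy",
    "nmi",
    "ari",
    "evaluate",
]


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray  # k_true x k_pred
    row_sums: np.ndarray
    col_sums: np.ndarray
    n: int


def _as_labels(x, name: str) -> np.ndarray:
    arr = np.asarray(x).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    return arr


def contingency_table(true_labels, pred_labels) -> ContingencyTable:
    t = _as_labels(true_labels, "true_labels")
    p = _as_labels(pred_labels, "pred_labels")
    if t.shape[0] != p.shape[0]:
        raise ValueError(f"label lengths differ: {t.shape[0]} vs {p.shape[0]}")
    _, ti = np.unique(t, return_inverse=True)
    _, pi = np.unique(p, return_inverse=True)
    counts = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(counts, (ti, pi), 1)
    return ContingencyTable(
        counts=counts,
        row_sums=counts.sum(axis=1),
        col_sums=counts.sum(axis=0),
        n=t.shape[0],
    )


def clustering_accuracy(true_labels, pred_labels) -> float:
    """Fraction of cells correct under the best one-to-one cluster matching.

    The contingency table is zero-padded to square when the two partitions
    have different numbers of clusters, so unmatched clusters contribute 0.
    """
    ct = contingency_table(true_labels, pred_labels)
    k = max(ct.counts.shape)
    padded = np.zeros((k, k), dtype=np.int64)
    padded[: ct.counts.shape[0], : ct.counts.shape[1]] = ct.counts
    rows, cols = linear_sum_assignment(padded, maximize=True)
    return float(padded[rows, cols].sum()) / ct.n


def _entropy(freqs: np.ndarray, n: int) -> float:
    p = freqs[freqs > 0] / n
    return float(-(p * np.log(p)).sum())


def nmi(true_labels, pred_labels) -> float:
    """Normalized mutual information, 2*MI / (H(U) + H(V)).

    When both partitions are trivial (each a single cluster) both entropies
    vanish; the partitions are then identical and the score is 1 by
    convention.  A single trivial partition against a non-trivial one scores 0.
    """
    ct = contingency_table(true_labels, pred_labels)
    h_u = _entropy(ct.row_sums, ct.n)
    h_v = _entropy(ct.col_sums, ct.n)
    if h_u == 0.0 and h_v == 0.0:
        logger.info("both labelings constant; NMI defined as 1.0")
        return 1.0
    if h_u == 0.0 or h_v == 0.0:
        return 0.0
    nz = ct.counts > 0
    nij = ct.counts[nz].astype(np.float64)
    outer = np.outer(ct.row_sums, ct.col_sums)[nz].astype(np.float64)
    mi = float((nij / ct.n * np.log(nij * ct.n / outer)).sum())
    return 2.0 * mi / (h_u + h_v)


def ari(true_labels, pred_labels) -> float:
    """Adjusted Rand index from binomial coefficients of the contingency table."""
    ct = contingency_table(true_labels, pred_labels)
    if ct.n < 2:
        raise ValueError("ARI requires at least 2 samples")
    sum_ij = comb(ct.counts, 2).sum()
    sum_a = comb(ct.row_sums, 2).sum()
    sum_b = comb(ct.col_sums, 2).sum()
    expected = sum_a * sum_b / comb(ct.n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # only possible when both partitions are the same trivial partition
        # (both one cluster, or both all singletons)
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def evaluate(true_labels, pred_labels) -> dict[str, float]:
    """All three indices as a plain dict (the shape the CLI serializes)."""
    return {
        "acc": clustering_accuracy(true_labels, pred_labels),
        "nmi": nmi(true_labels, pred_labels),
        "ari": ari(true_labels, pred_labels),
    }
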