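"""Paired bimodal count simulator with known (soft) cluster structure.

Cells live in a shared latent space containing k cluster archetypes placed at
a controlled pairwise distance (``separation``).  A pure cell is its
archetype plus isotropic Gaussian noise; a transitional cell is a convex
mixture of two archetypes with mixture weight drawn from Uniform(0.3, 0.7),
recorded as its true soft membership.  Each modality observes the latent
coordinates through an independent fixed random linear map followed by
softplus (to obtain non-negative rates) and Poisson sampling, so both count
matrices share the latent cluster geometry but nothing else — mimicking
paired scRNA/scATAC profiles of the same cells.

Everything is drawn from a single seeded generator, so outputs are
bit-identical for a fixed spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import MultimodalDataset, save_dataset

__all__ = ["SyntheticSpec", "generate", "generate_with_latent", "write_dataset"]

# mean count level of the Poisson rates; chosen to give sparse but informative
# counts comparable to shallow droplet sequencing after log1p
_COUNT_SCALE = 5.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated paired dataset.

    Defaults emulate a small multi-ome benchmark: ~1.7k cells, 5 clusters,
    1000 RNA features against a much narrower ATAC summary (25 features).
    ``separation`` is the Euclidean distance between any two cluster
    archetypes in latent units; ``noise_sd`` the within-cluster latent spread.
    """

    n_cells: int = 1728
    n_clusters: int = 5
    d_rna: int = 1000
    d_atac: int = 25
    separation: float = 8.0
    noise_sd: float = 0.5
    frac_transitional: float = 0.0
    seed: int = 0
    latent_dim: int = 10

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_clusters", "d_rna", "d_atac", "latent_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.separation <= 0 or self.noise_sd <= 0:
            raise ValueError("separation and noise_sd must be positive")
        if not 0.0 <= self.frac_transitional < 1.0:
            raise ValueError("frac_transitional must lie in [0, 1)")
        if self.n_cells < self.n_clusters:
            raise ValueError("need at least one cell per cluster")


def _archetypes(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """k archetype rows with pairwise distance exactly `separation`."""
    p = max(spec.latent_dim, spec.n_clusters)
    basis, _ = np.linalg.qr(rng.normal(size=(p, spec.n_clusters)))
    # orthonormal columns -> pairwise distance sqrt(2); rescale to separation
    return basis.T * (spec.separation / np.sqrt(2.0))


def generate_with_latent(
    spec: SyntheticSpec,
) -> tuple[MultimodalDataset, np.ndarray, np.ndarray]:
    """As :func:`generate`, additionally returning the latent coordinates."""
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_cells, spec.n_clusters
    arch = _archetypes(spec, rng)
    p = arch.shape[1]

    base = np.arange(n) % k
    rng.shuffle(base)
    memberships = np.zeros((n, k))
    memberships[np.arange(n), base] = 1.0

    n_trans = int(round(spec.frac_transitional * n))
    trans_idx = rng.choice(n, size=n_trans, replace=False)
    if n_trans:
        partner = (base[trans_idx] + rng.integers(1, k, size=n_trans)) % k
        w = rng.uniform(0.3, 0.7, size=n_trans)
        memberships[trans_idx] = 0.0
        memberships[trans_idx, base[trans_idx]] = w
        memberships[trans_idx, partner] = 1.0 - w

    latent = memberships @ arch + rng.normal(scale=spec.noise_sd, size=(n, p))

    def modality(d: int) -> np.ndarray:
        proj = rng.normal(size=(p, d)) / np.sqrt(p)
        rate = _COUNT_SCALE * np.logaddexp(0.0, latent @ proj)  # softplus
        return rng.poisson(rate).astype(np.float64)

    x_rna = modality(spec.d_rna)
    x_atac = modality(spec.d_atac)
    labels = memberships.argmax(axis=1).astype(np.int64)

    ds = MultimodalDataset(
        x_rna=x_rna, x_atac=x_atac, labels=labels, n_clusters=k,
    )
    return ds, memberships, latent


def generate(spec: SyntheticSpec) -> tuple[MultimodalDataset, np.ndarray]:
    """Simulate one paired dataset.

    Returns the dataset (raw counts plus hard labels = membership argmax) and
    the n x k matrix of true soft memberships; every membership row sums to 1,
    and transitional rows have exactly two nonzero entries.
    """
    ds, memberships, _ = generate_with_latent(spec)
    return ds, memberships


def write_dataset(
    ds: MultimodalDataset,
    memberships: np.ndarray,
    outdir,
    format: str = "csv",
) -> None:
    """Persist a simulated dataset in the layouts `data_io` reads.

    Adds ``memberships.csv`` (cells x clusters) next to the matrices and the
    labels file.
    """
    import pandas as pd

    save_dataset(ds, outdir, format=format)
    pd.DataFrame(
        memberships,
        index=ds.cell_ids,
        columns=[f"cluster_{j}" for j in range(memberships.shape[1])],
    ).to_csv(f"{outdir}/memberships.csv")
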