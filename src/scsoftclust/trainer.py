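"""End-to-end optimization: pretraining, joint training, ablations, sweeps.

The schedule is: (1) pretrain the two autoencoders on reconstruction alone;
(2) initialize cluster centers by k-means on the fused consensus embedding;
(3) jointly optimize  L = L_r + alpha L_c + beta L_s  full-batch with Adam,
recomputing the fuzzy target memberships gamma (detached) at the start of
every epoch, with early stopping on the total loss; (4) produce final labels
by k-means on the consensus embedding H_hat — the primary hard assignment —
alongside the fuzzy memberships gamma and their argmax.

Training is full batch: the structural matrix is n x n, so the practical
ceiling is n of a few thousand cells on one CPU.  Everything is seeded; two
runs with the same config are bit-identical.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .autodiff import Tensor
from .data_io import MultimodalDataset
from .losses import (
    LossWeights,
    contrastive_loss,
    dec_target_kl,
    reconstruction_loss,
    soft_clustering_loss,
    student_t_q,
    total_loss,
)
from .metrics import evaluate
from .model import FusionNetwork, NetworkShapes
from .softclust import fuzzy_memberships, initialize_centers, update_centers

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "ClusteringResult",
    "Adam",
    "build_network",
    "pretrain",
    "fit",
    "run_ablation",
    "run_sweep",
]

_MIN_IMPROVEMENT = 1e-6


@dataclass(frozen=True)
class TrainingConfig:
    """Every knob of a training run.

    Defaults: loss weights alpha = beta = 1 with temperature 0.5, fuzzifier
    1.5, bottleneck 64, fused width 128, 200 pretraining epochs, 50 joint
    epochs with patience 20, learning rate 5e-4.
    """

    n_clusters: int
    alpha: float = 1.0
    beta: float = 1.0
    temperature: float = 0.5
    fuzzifier: float = 1.5
    bottleneck: int = 64
    fused_dim: int = 128
    hidden: tuple[int, ...] = (256,)
    attention_dim: int | None = None
    attention_scale: str = "sqrt_d"
    contrastive_denominator: str = "as_printed"
    soft_space: str = "fused"
    center_update: str = "gradient"
    pretrain_epochs: int = 200
    train_epochs: int = 50
    patience: int = 20
    learning_rate: float = 5e-4
    seed: int = 0
    use_contrastive: bool = True
    use_soft: bool = True
    use_attention: bool = True

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be positive")
        if self.pretrain_epochs < 0 or self.train_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must be > 1")
        if self.soft_space not in ("fused", "concat"):
            raise ValueError("soft_space must be 'fused' or 'concat'")
        if self.center_update not in ("gradient", "fcm"):
            raise ValueError("center_update must be 'gradient' or 'fcm'")
        object.__setattr__(self, "hidden", tuple(self.hidden))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden"] = list(self.hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def weights(self) -> LossWeights:
        return LossWeights(
            alpha=self.alpha if self.use_contrastive else 0.0,
            beta=self.beta,
            temperature=self.temperature,
        )


@dataclass
class ClusteringResult:
    """Output of one fit: soft memberships, both hard labelings, diagnostics."""

    soft_memberships: np.ndarray          # final gamma, n x k
    hard_labels: np.ndarray               # k-means on H_hat (primary)
    gamma_labels: np.ndarray              # argmax of gamma
    h_hat_final: np.ndarray
    history: dict[str, list[dict]] = field(default_factory=dict)
    metrics: dict[str, float] | None = None
    config: TrainingConfig | None = None


class Adam:
    """Adaptive-moment gradient descent over a fixed list of parameters."""

    def __init__(self, params: list[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def build_network(ds: MultimodalDataset, config: TrainingConfig) -> FusionNetwork:
    shapes = NetworkShapes(
        d1=ds.x_rna.shape[1],
        d2=ds.x_atac.shape[1],
        hidden=config.hidden,
        bottleneck=config.bottleneck,
        fused_dim=config.fused_dim,
        attention_dim=config.attention_dim,
        attention_scale=config.attention_scale,
    )
    return FusionNetwork(shapes, seed=config.seed)


def _abort_on_nan(loss_value: float, epoch: int, phase: str, params: list[Tensor]) -> None:
    if np.isfinite(loss_value):
        return
    max_grad = max(
        (float(np.abs(p.grad).max()) for p in params if p.grad is not None),
        default=float("nan"),
    )
    raise RuntimeError(
        f"non-finite loss at {phase} epoch {epoch} "
        f"(loss={loss_value}, max|grad|={max_grad})"
    )


def pretrain(
    ds: MultimodalDataset,
    config: TrainingConfig,
    network: FusionNetwork | None = None,
) -> tuple[FusionNetwork, list[dict]]:
    """Optimize the autoencoders on reconstruction loss alone.

    With ``pretrain_epochs = 0`` the returned network is exactly the seeded
    initialization.
    """
    network = network or build_network(ds, config)
    params = network.autoencoder_parameters()
    opt = Adam(params, config.learning_rate)
    history: list[dict] = []
    for epoch in range(1, config.pretrain_epochs + 1):
        z1, z2 = network.encode(ds.x_rna, ds.x_atac)
        x1_hat, x2_hat = network.decode(z1, z2)
        loss = reconstruction_loss(ds.x_rna, ds.x_atac, x1_hat, x2_hat)
        opt.zero_grad()
        loss.backward()
        _abort_on_nan(float(loss.data), epoch, "pretrain", params)
        opt.step()
        history.append({"epoch": epoch, "lr": float(loss.data)})
    return network, history


def fit(ds: MultimodalDataset, config: TrainingConfig) -> ClusteringResult:
    """Run the full pipeline on a preprocessed dataset.

    Early stopping halts the joint phase once the total loss has not improved
    by at least 1e-6 for ``patience`` consecutive epochs.  The primary hard
    labeling is k-means on the final consensus embedding; the fuzzy
    memberships gamma and their argmax are always reported alongside.
    """
    n, k = ds.n_cells, config.n_clusters
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} cells")
    if not ds.preprocessed:
        logger.info("fitting on a dataset not marked preprocessed")

    network, pre_history = pretrain(ds, config)

    def soft_coords(state):
        return state.h_hat if config.soft_space == "fused" else state.z_cat

    state = network.forward(ds.x_rna, ds.x_atac, use_attention=config.use_attention)
    centers = Tensor(
        initialize_centers(soft_coords(state).data, k, config.seed),
        requires_grad=config.center_update == "gradient",
    )

    params = network.parameters()
    if config.center_update == "gradient":
        params = params + [centers]
    opt = Adam(params, config.learning_rate)
    weights = config.weights()

    history: list[dict] = []
    best = np.inf
    stale = 0
    for epoch in range(1, config.train_epochs + 1):
        state = network.forward(ds.x_rna, ds.x_atac, use_attention=config.use_attention)
        z_soft = soft_coords(state)
        gamma = fuzzy_memberships(z_soft.data, centers.data, config.fuzzifier)
        q = student_t_q(z_soft, centers)

        l_r = reconstruction_loss(ds.x_rna, ds.x_atac, state.x1_hat, state.x2_hat)
        clamp_count = 0
        if config.use_contrastive:
            l_c, clamp_count = contrastive_loss(
                state.h_hat, state.h1, state.h2, state.s,
                config.temperature, config.contrastive_denominator,
            )
        else:
            l_c = Tensor(0.0)
        l_s = soft_clustering_loss(gamma, q) if config.use_soft else dec_target_kl(q)
        loss = total_loss(l_r, l_c, l_s, weights)

        opt.zero_grad()
        loss.backward()
        _abort_on_nan(float(loss.data), epoch, "train", params)
        opt.step()
        if config.center_update == "fcm":
            centers.data = update_centers(z_soft.data, gamma, config.fuzzifier)

        record = {
            "epoch": epoch,
            "lr": float(l_r.data),
            "lc": float(l_c.data),
            "ls": float(l_s.data),
            "total": float(loss.data),
            "clamp_count": clamp_count,
        }
        history.append(record)

        if best - record["total"] >= _MIN_IMPROVEMENT:
            best = record["total"]
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                logger.info("early stop at epoch %d (no improvement for %d)", epoch, stale)
                break

    state = network.forward(ds.x_rna, ds.x_atac, use_attention=config.use_attention)
    z_soft = soft_coords(state)
    gamma = fuzzy_memberships(z_soft.data, centers.data, config.fuzzifier)
    h_hat = state.h_hat.data
    hard = KMeans(n_clusters=k, n_init=10, random_state=config.seed).fit_predict(h_hat)
    result = ClusteringResult(
        soft_memberships=gamma,
        hard_labels=hard.astype(np.int64),
        gamma_labels=gamma.argmax(axis=1).astype(np.int64),
        h_hat_final=h_hat,
        history={"pretrain": pre_history, "train": history},
        metrics=evaluate(ds.labels, hard) if ds.labels is not None else None,
        config=config,
    )
    return result


_ABLATION_VARIANTS = {
    "full": {},
    "no_contrastive": {"use_contrastive": False},
    "no_soft": {"use_soft": False},
    "no_attention": {"use_attention": False},
}


def run_ablation(
    ds: MultimodalDataset, config: TrainingConfig
) -> tuple[dict[str, ClusteringResult], pd.DataFrame]:
    """Fit the full model and its three single-module ablations, shared seed.

    The no-soft variant swaps the fuzzy-target KL for the classical
    self-training target; no-contrastive drops L_c; no-attention forces
    uniform attention.  Requires ground-truth labels for the metric table.
    """
    if ds.labels is None:
        raise ValueError("ablation scoring requires ground-truth labels")
    results: dict[str, ClusteringResult] = {}
    rows = []
    for name, overrides in _ABLATION_VARIANTS.items():
        res = fit(ds, replace(config, **overrides))
        results[name] = res
        rows.append({"variant": name, **res.metrics})
    return results, pd.DataFrame(rows)


def run_sweep(
    ds: MultimodalDataset,
    config: TrainingConfig,
    alphas: list[float],
    betas: list[float],
    temperatures: list[float],
) -> pd.DataFrame:
    """Grid sweep over (alpha, beta, T) with a shared seed.

    The Cartesian product is deduplicated, so the row count equals the number
    of distinct parameter triples; each row carries ACC/NMI/ARI.
    """
    if not (alphas and betas and temperatures):
        raise ValueError("all three grids must be non-empty")
    if ds.labels is None:
        raise ValueError("sweep scoring requires ground-truth labels")
    triples = sorted(set(itertools.product(alphas, betas, temperatures)))
    rows = []
    for a, b, t in triples:
        res = fit(ds, replace(config, alpha=a, beta=b, temperature=t))
        rows.append({"alpha": a, "beta": b, "temperature": t, **res.metrics})
    return pd.DataFrame(rows)
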