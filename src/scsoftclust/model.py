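"""The fusion network: per-modality autoencoders plus structure-guided fusion.

Each modality is compressed by its own encoder to a bottleneck latent
(Z1 for RNA, Z2 for ATAC).  The concatenated latent Z = [Z1 Z2] drives a
global attention step: a row-stochastic n x n structural matrix

    S = softmax( (Z W1)(Z W2)^T / scale )

captures pairwise cell-cell relationships over the whole batch, and the fused
consensus representation is the residual form

    H_hat = (Z + S R) W3 + b3,      R = Z W_R,

so that when S is uninformative the consensus degrades gracefully to a linear
map of Z.  Two affine heads project the modality latents into the consensus
width so cosine similarities between H_hat and H1/H2 are well defined, and
mirror-image decoders reconstruct each input from its latent.

Everything is built on the in-package autodiff engine; a forward pass returns
a :class:`FusionState` holding every intermediate as a graph node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["NetworkShapes", "FusionState", "Linear", "FusionNetwork"]


@dataclass(frozen=True)
class NetworkShapes:
    """Widths of every stage of the network.

    ``attention_dim`` is the width of the W1/W2 projections whose scaled dot
    product forms the structural matrix; ``attention_scale`` selects whether
    the logits are divided by sqrt(attention_dim) (standard scaled attention,
    the default) or by attention_dim itself.
    """

    d1: int
    d2: int
    hidden: tuple[int, ...] = (256,)
    bottleneck: int = 64
    fused_dim: int = 128
    attention_dim: int | None = None
    attention_scale: str = "sqrt_d"

    def __post_init__(self) -> None:
        if self.bottleneck < 1 or self.fused_dim < 1:
            raise ValueError("bottleneck and fused_dim must be >= 1")
        if not self.hidden:
            raise ValueError("hidden must list at least one width")
        if self.attention_scale not in ("sqrt_d", "d"):
            raise ValueError("attention_scale must be 'sqrt_d' or 'd'")

    @property
    def attn_dim(self) -> int:
        return self.attention_dim or 2 * self.bottleneck


@dataclass
class FusionState:
    """All per-batch intermediates of one forward pass (graph nodes)."""

    z1: Tensor
    z2: Tensor
    z_cat: Tensor
    s: Tensor
    r: Tensor
    h_hat: Tensor
    h1: Tensor
    h2: Tensor
    x1_hat: Tensor
    x2_hat: Tensor


class Linear:
    """Affine layer with Glorot-uniform weights, seeded at construction."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int, bias: bool = True):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.w = Tensor(rng.uniform(-limit, limit, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.w
        return out + self.b if self.b is not None else out

    @property
    def params(self) -> list[Tensor]:
        return [self.w] if self.b is None else [self.w, self.b]


class _MLP:
    """Stack of affine layers with elu between them (linear final layer)."""

    def __init__(self, rng: np.random.Generator, widths: list[int]):
        self.layers = [Linear(rng, a, b) for a, b in zip(widths[:-1], widths[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.elu()
        return x

    @property
    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params]


class FusionNetwork:
    """Encoders, decoders, attention fusion, and modality heads.

    All parameters are initialized from a single seeded generator so two
    networks built with the same shapes and seed are bit-identical.
    """

    def __init__(self, shapes: NetworkShapes, seed: int = 0):
        self.shapes = shapes
        rng = np.random.default_rng(seed)
        h = list(shapes.hidden)
        self.encoder1 = _MLP(rng, [shapes.d1, *h, shapes.bottleneck])
        self.encoder2 = _MLP(rng, [shapes.d2, *h, shapes.bottleneck])
        self.decoder1 = _MLP(rng, [shapes.bottleneck, *reversed(h), shapes.d1])
        self.decoder2 = _MLP(rng, [shapes.bottleneck, *reversed(h), shapes.d2])
        zc = 2 * shapes.bottleneck
        self.w_r = Linear(rng, zc, zc, bias=False)
        self.w1 = Linear(rng, zc, shapes.attn_dim, bias=False)
        self.w2 = Linear(rng, zc, shapes.attn_dim, bias=False)
        self.w3 = Linear(rng, zc, shapes.fused_dim)
        self.head1 = Linear(rng, shapes.bottleneck, shapes.fused_dim)
        self.head2 = Linear(rng, shapes.bottleneck, shapes.fused_dim)

    # -- pieces ---------------------------------------------------------------
    def encode(self, x1: Tensor | np.ndarray, x2: Tensor | np.ndarray) -> tuple[Tensor, Tensor]:
        x1, x2 = Tensor._lift(x1), Tensor._lift(x2)
        if x1.shape[1] != self.shapes.d1 or x2.shape[1] != self.shapes.d2:
            raise ValueError(
                f"input widths {(x1.shape[1], x2.shape[1])} do not match "
                f"network dims {(self.shapes.d1, self.shapes.d2)}"
            )
        return self.encoder1(x1), self.encoder2(x2)

    def decode(self, z1: Tensor, z2: Tensor) -> tuple[Tensor, Tensor]:
        return self.decoder1(z1), self.decoder2(z2)

    def structural_matrix(self, z_cat: Tensor) -> Tensor:
        """Row-stochastic global attention over cells (scaled dot product)."""
        a = z_cat @ self.w1.w
        b = z_cat @ self.w2.w
        d_bar = float(self.shapes.attn_dim)
        scale = np.sqrt(d_bar) if self.shapes.attention_scale == "sqrt_d" else d_bar
        return ((a @ b.T) * (1.0 / scale)).row_softmax()

    def uniform_structural_matrix(self, n: int) -> Tensor:
        """The attention-ablated S: every cell attends uniformly to all cells."""
        return Tensor(np.full((n, n), 1.0 / n))

    def fuse(self, z_cat: Tensor, s: Tensor) -> tuple[Tensor, Tensor]:
        """Residual attention fusion; returns (h_hat, r)."""
        if s.shape[0] != z_cat.shape[0]:
            raise ValueError(
                f"S has {s.shape[0]} rows for {z_cat.shape[0]} cells"
            )
        r = self.w_r(z_cat)
        h_hat = self.w3(z_cat + s @ r)
        return h_hat, r

    def modality_heads(self, z1: Tensor, z2: Tensor) -> tuple[Tensor, Tensor]:
        return self.head1(z1), self.head2(z2)

    # -- full pass ------------------------------------------------------------
    def forward(
        self,
        x1: Tensor | np.ndarray,
        x2: Tensor | np.ndarray,
        use_attention: bool = True,
    ) -> FusionState:
        z1, z2 = self.encode(x1, x2)
        z_cat = concat([z1, z2], axis=1)
        s = (
            self.structural_matrix(z_cat)
            if use_attention
            else self.uniform_structural_matrix(z_cat.shape[0])
        )
        h_hat, r = self.fuse(z_cat, s)
        h1, h2 = self.modality_heads(z1, z2)
        x1_hat, x2_hat = self.decode(z1, z2)
        return FusionState(
            z1=z1, z2=z2, z_cat=z_cat, s=s, r=r,
            h_hat=h_hat, h1=h1, h2=h2, x1_hat=x1_hat, x2_hat=x2_hat,
        )

    def parameters(self) -> list[Tensor]:
        groups = [
            self.encoder1, self.encoder2, self.decoder1, self.decoder2,
            self.w_r, self.w1, self.w2, self.w3, self.head1, self.head2,
        ]
        return [p for g in groups for p in g.params]

    def autoencoder_parameters(self) -> list[Tensor]:
        """Parameters touched by reconstruction alone (the pretraining set)."""
        groups = [self.encoder1, self.encoder2, self.decoder1, self.decoder2]
        return [p for g in groups for p in g.params]
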