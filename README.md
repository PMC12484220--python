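# scsoftclust

Structure-guided **soft** deep clustering of paired scRNA-seq + scATAC-seq
profiles.

Single-cell clustering methods almost universally make hard assignments: each
cell gets exactly one cluster label. But cells in developing or perturbed
tissue pass through transitional states, and a cell halfway between two
identities is poorly described by either label alone. When two modalities are
measured in the same cells (transcript counts and chromatin accessibility),
naive fusion of the two compressed representations adds a second problem:
redundant and conflicting information between modalities degrades the joint
embedding.

`scsoftclust` addresses both. It learns, per cell, a consensus embedding fused
across modalities under a global attention mechanism, and it assigns every
cell a *probability vector over clusters* (a fuzzy membership) alongside the
conventional hard label.

## Model

Given paired matrices X¹ ∈ ℝ^(n×d₁) (RNA) and X² ∈ ℝ^(n×d₂) (ATAC) over the
same n cells:

1. **Encoding.** Modality-specific encoders give latents Z¹ = F¹(X¹),
   Z² = F²(X²) (bottleneck 64 each); mirror decoders reconstruct X̂¹, X̂².
2. **Structure-guided fusion.** With Z = [Z¹ Z²], a row-stochastic structural
   matrix S = softmax((ZW₁)(ZW₂)ᵀ / √d̄) captures global cell–cell
   relationships, and the consensus embedding is the residual form
   Ĥ = (Z + S·R)W₃ + b₃ with R = ZW_R (fused width 128).
3. **Contrastive alignment.** Affine heads H¹, H² project each latent into
   the consensus width. A contrastive loss pulls D(Ĥᵢ, Hᵢᵐ) (cosine) up while
   the structural matrix down-weights structurally close cells among the
   negatives:

   L_c = −(1/2n) Σᵢ Σₘ log [ e^{D(Ĥᵢ,Hᵢᵐ)/T} / ( Σⱼ e^{(1−Sᵢⱼ)D(Ĥᵢ,Hⱼᵐ)/T} − e^{1/T} ) ]

4. **Soft clustering.** Fuzzy c-means memberships
   γᵢⱼ ∝ ‖Ĥᵢ − μⱼ‖^(−2/(m−1)) (fuzzifier m = 1.5) act as the target for the
   Student-t soft assignments qᵢⱼ through L_s = Σᵢ KL(γᵢ ‖ qᵢ).
5. **Total objective.** L = L_r + αL_c + βL_s, optimized full-batch with Adam
   after reconstruction-only pretraining; final hard labels come from k-means
   on Ĥ, with γ and its argmax always reported alongside.

Evaluation uses best-match accuracy (optimal assignment on the contingency
table), NMI (arithmetic-mean normalization) and ARI.

The whole network and all three losses run on a small reverse-mode autodiff
engine over numpy (`scsoftclust.autodiff`) — float64 throughout, fully
deterministic for a fixed seed, no GPU or deep-learning framework required.
Training is full-batch (S is n×n), so the practical ceiling is a few thousand
cells on one CPU.

## Worked example

Simulate paired counts with 4 clusters in which 20 % of cells are
*transitional* (convex mixtures of two cluster archetypes), then fit:

```python
import numpy as np
import scsoftclust as sc

spec = sc.SyntheticSpec(n_cells=600, n_clusters=4, d_rna=1000, d_atac=25,
                        separation=8.0, noise_sd=0.5, frac_transitional=0.2, seed=0)
ds, true_memberships = sc.generate(spec)
ds = sc.preprocess(ds, n_top_features=2000)

config = sc.TrainingConfig(n_clusters=4, pretrain_epochs=50, train_epochs=20, seed=0)
result = sc.fit(ds, config)

print(result.metrics)
```

This prints

```
{'acc': 0.975, 'nmi': 0.9053, 'ari': 0.9342}
```

i.e. the hard labeling recovers the simulated clusters almost perfectly even
though a fifth of the cells genuinely sit between two clusters. The soft
memberships are where those cells show up: the mean membership entropy of
transitional cells is 0.689 versus 0.054 for pure cells, and individual rows
of `result.soft_memberships` recover the simulated mixtures (cluster indices
are arbitrary up to permutation):

```
transitional cell:  predicted [0.029 0.431 0.499 0.042]   true mixture [0.   0.44 0.56 0.  ]
pure cell:          predicted [0.004 0.003 0.988 0.004]   true mixture [0.   1.   0.   0.  ]
```

The same pipeline is available from the shell:

```bash
scsoftclust simulate --n 600 --k 4 --seed 0 --out sim/
scsoftclust fit --rna sim/rna.csv --atac sim/atac.csv --labels sim/labels.txt --out runs/
scsoftclust evaluate --true sim/labels.txt --pred runs/<run>/labels.txt
```

plus `ablate` (full model vs each single-module ablation) and `sweep`
(α × β × T grids).

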