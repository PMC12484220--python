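# Methods

## Data model and preprocessing

The input is a pair of non-negative matrices over the same n cells: RNA
counts X¹ (n × d₁) and ATAC accessibility X² (n × d₂), with rows aligned.
Preprocessing treats the two modalities symmetrically: each is library-size
normalized per cell to the median depth, log1p-transformed, and reduced to
its `n_top_features` (default 2000) highest-dispersion features. Dispersion
is the per-column variance of the normalized log1p matrix, computed on the
*full* matrix before selection, so every retained column is exactly a column
of the normalized input; ties break toward the lower column index, making
selection deterministic. Cells with zero total counts have their library
size floored at 1 (with a warning) rather than being dropped — QC filtering
is out of scope. ATAC-specific transforms (TF-IDF, binarization) are not
applied by default; a `binarize_atac` flag exists for peak matrices where
presence/absence is the meaningful signal. Preprocessing is idempotent: a
dataset carries a `preprocessed` flag and a second application is a no-op
(re-normalizing log-space values would otherwise corrupt them). Datasets that
arrive already processed can skip the step entirely.

## Network

Each modality has its own encoder (widths input → 256 → 64, elu on the
hidden layer, linear bottleneck) and a mirror-image decoder. The bottleneck
of 64 per modality and fused width of 128 are the defaults; all widths are
configurable. The concatenated latent Z (width 128) drives the fusion:

* R = Z·W_R keeps R at the width of Z, so the residual sum Z + S·R is
  well-typed; W₃ then projects to the fused width. This is the minimal
  reading of the fusion equation that type-checks end to end.
* The structural matrix S = softmax((ZW₁)(ZW₂)ᵀ / √d̄) uses projections
  W₁, W₂ of width d̄ = 2·bottleneck by default. Scaling by √d̄ follows the
  standard scaled-dot-product convention; a config switch
  (`attention_scale: d`) divides by d̄ instead for users who want the
  plain-d variant. S is computed over the full batch — training is
  full-batch by design (the attention and contrastive terms are O(n²)), with
  a practical ceiling around 10⁴ cells on one CPU.
* The modality heads H¹, H² are separate affine maps from each bottleneck
  latent into the fused width. They are heads rather than the raw latents
  because the contrastive similarity D(Ĥᵢ, Hᵢᵐ) needs equal widths; the
  alternative (reusing Z¹/Z² directly) would force bottleneck = fused width.

Parameters are Glorot-uniform initialized from a single seeded generator;
two networks built with the same shapes and seed are bit-identical.

## Losses

**Reconstruction** L_r is the plain sum over cells of squared Euclidean
error for both modalities.

**Structure-guided contrastive** L_c uses cosine similarity between the
consensus row Ĥᵢ and each modality head row. The denominator sums
e^{(1−Sᵢⱼ)·D/T} over all j — structurally close cells (large Sᵢⱼ) are
down-weighted as negatives — and subtracts e^{1/T}. That subtraction can make
the denominator non-positive: already at n = 1 with perfectly aligned heads
it equals 1 − e^{1/T} < 0. The implementation clamps the denominator below
at 1e-8 and counts clamp events per epoch (`clamp_count` in the history). An
alternative reading — subtracting the i = j self-term instead, which keeps
the denominator positive whenever n > 1 — ships behind
`contrastive_denominator: drop_self`; the default is the formula as written,
with the clamp as the documented numerical guard. Temperature T defaults to
0.5.

**Soft clustering** L_s = Σᵢ KL(γᵢ ‖ qᵢ). qᵢⱼ is the Student-t kernel with
one degree of freedom (the convention of the deep-embedded-clustering
family) over distances from Ĥᵢ to the centers μⱼ. γ is the closed-form
fuzzy-c-means minimizer of Σⱼ γᵢⱼᵐ‖Ĥᵢ − μⱼ‖² on the simplex:
γᵢⱼ ∝ ‖Ĥᵢ − μⱼ‖^(−2/(m−1)), computed in log space for stability as m → 1,
with unit mass split uniformly over coinciding centers in the degenerate
case. γ is recomputed at the start of every epoch and *detached*: gradients
flow only through q (i.e. through Ĥ and μ), mirroring the target-distribution
convention of self-training clustering objectives. The fuzzifier default is
m = 1.5. The soft-clustering space is Ĥ by default (`soft_space: concat`
switches to Z).

For the soft-clustering ablation the classical self-training KL with target
pᵢⱼ = (qᵢⱼ²/fⱼ)/Σ(q²/f) replaces L_s, so "without soft clustering" still has
a clustering objective, just the hard-leaning conventional one.

**Total** L = L_r + α·L_c + β·L_s with α = β = 1 by default; α = β = 0
reduces exactly to the autoencoder.

All losses use natural logarithms. Gradients come from the package's
reverse-mode autodiff engine over float64 numpy arrays; finite-difference
checks in the test suite hold to relative error well below 1e-3.

## Optimization schedule

1. **Pretrain** the autoencoders on L_r alone (default 200 epochs; only
   encoder/decoder parameters step).
2. **Initialize centers** by k-means (10 restarts, seeded) on the pretrained Ĥ.
3. **Joint phase** (default 50 epochs): per epoch recompute γ, evaluate
   L_r + αL_c + βL_s, backpropagate, and take one full-batch Adam step
   (lr 5e-4). Centers are free parameters updated by gradient by default;
   `center_update: fcm` replaces this with the weighted-mean stationarity
   update μⱼ = Σγᵢⱼᵐzᵢ / Σγᵢⱼᵐ after each step. Early stopping halts the
   joint phase once the total loss has failed to improve by ≥ 1e-6 for
   `patience` (default 20) consecutive epochs; the joint epochs are counted
   inside the early-stopping window.
4. **Labels.** The primary hard labeling is k-means on the final Ĥ; the
   fuzzy memberships γ and their argmax are always emitted alongside. The
   two labelings usually agree on pure cells and differ exactly where
   softness matters; both are reported rather than adjudicated.

Non-finite losses abort with the epoch and max-gradient magnitude.
Everything — parameter init, k-means, the simulator — is seeded, so a run is
bit-reproducible from its config.

## Synthetic data

The simulator places k archetypes at exact pairwise distance `separation` in
a latent space (orthonormal directions scaled by separation/√2). A pure cell
is its archetype plus N(0, noise_sd²) noise; a transitional cell is
w·archetype_a + (1−w)·archetype_b + noise with w ~ Uniform(0.3, 0.7), and its
true membership row records (w, 1−w). Each modality observes the latents
through an independent fixed Gaussian linear map, softplus (scaled ×5 to
give realistic shallow-sequencing count levels), and Poisson sampling. The
defaults (1728 cells, 5 clusters, dims 1000/25, separation 8, noise 0.5)
emulate a small multi-ome benchmark in which the ATAC side is a narrow
low-dimensional summary.

What the simulator does *not* emulate: peak-level zero inflation and the
extreme sparsity of real scATAC, batch effects, doublets, or
trajectory-shaped (rather than pairwise-mixture) transitions. Tests passing
on these data therefore demonstrate that the machinery recovers planted
cluster and mixture structure under Poisson noise — not performance on real
tissue.

## Verification problem sizes

The end-to-end checks run at simulation scale chosen for a single CPU:
cluster recovery uses n = 600, k = 4, separation 8, seeds {0,1,2}, with a
reduced schedule (50 pretrain / 20 joint epochs); ablation comparisons use 5
seeds at 30/15 epochs; transitional-entropy checks use frac_transitional =
0.3 at 30/15; sweep plumbing runs at n = 120 with 2-epoch fits. At
separation 8 the planted structure is unambiguous, so recovery ARI is
expected near 1 and the interesting assertions are the *relative* ones
(ablations, entropy contrast) and the oracle equivalences.

## Known limitations

* Full-batch O(n²) attention bounds n; no mini-batching or sparse attention.
* Exactly two modalities.
* Squared-error reconstruction on log-normalized values — no count
  likelihood (ZINB/NB) heads.
* The printed contrastive denominator needs the clamp guard described above;
  with temperatures well below 1 the e^{1/T} term can dominate small
  batches, which is visible in `clamp_count`.
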