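# Methods

## Model overview

The clustering model couples three components over a cell–cell graph
G = (X, A) built from the preprocessed expression matrix X ∈ R^(N×M):

- an **autoencoder** (AE) with encoder widths M → 256 → 64 → 16 capturing
  per-cell feature structure (hidden layers ReLU, latent and output layers
  linear, MSE reconstruction of X);
- a **graph-attention autoencoder** (GATE) of equal depth, whose layer l
  computes single-head attention over each cell's graph neighbourhood
  (self-loop included) from the layer input U(l−1):
  att_ij = softmax_{j∈N_i} LeakyReLU(aᵀ[W h_i ‖ W h_j]) with slope 0.2,
  pre-activation S(l) = att · (U(l−1) W(l)ᵀ), H(l) = ReLU(S(l)); the
  decoder reconstructs the adjacency as Â = sigmoid(H(L) H(L)ᵀ) under MSE
  over all N² entries;
- **layer-wise fusion** U(r) = Z(r) + H(r) for r = 1 … L−1 feeding the next
  GATE layer.  The input layer is not fused (U(0) = X, not 2X), and the
  final embeddings Z(L), H(L) stay channel-specific; this avoids an
  arbitrary doubling of the input scale while still re-anchoring every
  intermediate structural layer to the feature channel.

Structural grouping enters through the spectral relaxation of the K-way
normalized cut.  Each layer's S is read as a relaxed partition matrix and
penalised with

L_SG(l) = ‖(1/N) SᵀS − I_d‖_F² − (1/NK) tr(Sᵀ D^{-1/2} A D^{-1/2} S),

summed over layers.  The identity is d×d at the layer's native width
(layers are not projected to K columns — the only reading that is
well-typed for every layer); the 1/(NK) normalisation always uses the
target cluster count.  On the manifold (1/N)SᵀS = I the loss is bounded
below by minus the mean of the K largest eigenvalues of
D^{-1/2} A D^{-1/2} (Ky Fan), with equality at the scaled top-K
eigenvectors.  Off the manifold the soft penalty trades off against the
linear trace reward, so the *unconstrained* global minimum sits lower, at
−(1/K) Σ_{k≤K} (λ_k + λ_k²/4K); the package exposes this closed form
(`spectral.unconstrained_optimum`) as the optimisation oracle used in
tests.  The minimiser's column space is still the top-K eigenspace, which
is the property the training loss exploits.

Self-supervision is **decoupled**: Student-t soft assignments
q_ij ∝ (1 + ‖z_i − c_j‖²)^{-1} and sharpened targets
p_ij ∝ q_ij²/f_j (f_j the soft cluster frequency) are computed separately
per channel, each with its own centre set initialised by K-means on that
channel's pretrained embedding and updated by gradient.  Targets are
recomputed every `update_interval` epochs and held fixed (stop-gradient)
in between.  The joint objective is

L = L_res + KL(P_z‖Q_z) + α L_SG + β KL(P_h‖Q_h),  α = 3e-5, β = 10.

Final labels are the row argmax of Q_h (the structural channel fuses both
information sources); the feature channel Q_z is available via
`label_channel="z"`.

## Graph construction

Pearson correlation between cells, negatives clipped to zero, is denoised
by network-enhancement diffusion: zero the diagonal, keep each row's k_ne
largest affinities (default min(20, ⌈N/10⌉)), symmetrise, row-normalise
into a transition matrix P, smooth W ← P W Pᵀ for two steps, symmetrise.
Diffusion cannot create mass across zero-transition blocks, so
block-structured similarity stays block-structured while sparse noise
edges are damped relative to within-community affinity.  The enhanced
similarity is sparsified to a binary KNN adjacency (default k = 15) with
union symmetrisation (an edge exists if either endpoint selects the
other), ties at the k-th position all admitted, and self-loops added —
binary because the cut objective counts links, union because it keeps the
graph connected-ish, self-loops because attention needs every
neighbourhood non-empty.

## Preprocessing

Standard single-cell QC via scanpy: genes expressed in fewer than
`min_cells` = 3 cells and cells expressing fewer than `min_genes` = 200
genes are dropped; counts are scaled per cell to the median library size
and log1p-transformed; the `n_hvg` = 2000 genes with the highest variance
of log-normalised expression are retained (ties broken by gene order, so
the selection is deterministic and idempotent).  All thresholds are
configurable; transformed (non-count) input skips normalisation with a
warning.

## Training schedule and numerical choices

Everything is full-batch Adam on float64 (the data are desk-scale), on a
small reverse-mode autodiff engine written for this package; gradients of
every loss term are validated against central finite differences in the
test suite.

- AE pretraining: 100 epochs at lr 1e-3 on L_AE.
- GATE pretraining: 100 epochs at lr 1e-3 on L_GATE + 1e-2·L_SG with the
  AE frozen.  The structural-grouping warm-up weight (1e-2, much larger
  than the joint-phase α) and a damped initialisation of the attention
  weight matrices (Glorot × 0.1) are both needed to keep the structural
  channel alive: with H = ReLU(S) ≥ 0 the sigmoid-gram decoder satisfies
  Â ≥ 0.5 everywhere, and its MSE has a degenerate stationary point at
  H = 0 (all ReLUs dead).  The orthonormality penalty in L_SG holds S near
  scale √N and prevents the collapse; its true optimum under the
  non-negativity of H is an embedding with disjoint cluster support,
  which is exactly the structure we want the channel to learn.
- Joint phase: up to 200 epochs at lr 3e-5 over all parameters including
  both centre sets, targets refreshed every epoch.  The joint rate is
  deliberately below the pretraining rate: larger steps let the decoder's
  degenerate pull shrink H faster than the KL terms can sharpen it,
  merging clusters; at 3e-5 the overall loss decreases smoothly.
- Stopping: training stops when fewer than `stop_tol` = 0.1% of labels
  change between consecutive target refreshes, but only after a burn-in
  of `min_joint_epochs` = 100 epochs — on well-separated data the label
  assignment is stable from the first epoch while the objective is still
  descending, and stopping inside that transient would return an
  under-trained model.
- A non-finite value in any loss term aborts with the term name and epoch.
- Determinism: one `numpy` generator seeded from `random_state` drives
  parameter initialisation and derives the K-means seed; identical
  configuration and seed reproduce labels bit-for-bit.

Label extraction breaks argmax ties toward the lowest cluster index, so a
fully uniform row maps to cluster 0 (degenerate but deterministic).

Ablation flags (`use_res`, `use_ae`, `use_gate`, `use_sg`, `use_kl`)
remove single components: disabling a channel removes its reconstruction,
KL term and (for GATE) the grouping loss; disabling self-supervision
replaces the joint phase's KL terms with a terminal K-means on the learned
embedding.

## The synthetic-data generator

`simulate` follows the standard Splatter-style recipe: per-gene base means
Gamma(2, rate 0.5); per-group log-normal differential-expression factors
(log-mean 1.0, log-sd 0.4, half inverted) applied to a `de_prob` = 0.3
fraction of genes; group expression profiles normalised to fractions;
per-cell library sizes LogNormal(log 20000, 0.25); negative-binomial
counts with dispersion 0.2 (variance μ + 0.2μ²); then mean-dependent
logistic dropout P(zero) = σ(shape·(midpoint − log μ)) with shape 1.  The
default midpoint 0.85 realises ≈ 20% zero entries at the default size
(1000 cells × 1000 genes, four equal groups); `calibrate_dropout` bisects
the midpoint against the realized zero fraction, which is monotone in it,
and `subsample_depth` thins counts binomially for sequencing-depth
experiments.

The DE strength defaults produce clearly separated groups — the regime in
which recovery can meaningfully be asserted.  The generator emulates
library-size variation, over-dispersion and sparsity, but *not* batch
effects, trajectories/continuous states, cell-size covariates or
ambient RNA; passing the recovery tests therefore demonstrates correct
mechanics and robustness to sparsity, not performance on the full
messiness of real tissues.

## Evaluation

ARI and NMI come from scikit-learn (NMI with the arithmetic-mean
normaliser by default; min/geometric/max available).  Marker genes are
ranked per predicted cluster by a one-vs-rest two-sided Wilcoxon rank-sum
test (tie-corrected normal approximation) on log-normalised expression,
ordered by ascending p-value with |log-fold-change| and gene id as
tie-breaks and truncated to `n_top`; no multiple-testing correction is
applied to the ranking.

## Problem sizes

The bundled benchmarks run at 1000 cells × 1000 genes (the simulator
default) for the recovery and dropout-robustness checks, and at 120–300
cells for unit-level checks; graphs for brute-force partition enumeration
have ≤ 8 nodes.  Dense N×N attention is used throughout — at desk scale
this is faster and simpler than sparse kernels.

## Known limitations

- The adjacency decoder cannot represent edge probabilities below 0.5
  (H ≥ 0), so L_GATE saturates at 0.25·(zero fraction of A); it acts as a
  regulariser rather than a calibrated generative term.
- Single attention head; no inductive inference on unseen cells; K must
  be supplied.
- The spectrally relaxed loss is optimised through network
  parameterisation, so nothing enforces that per-layer S matrices stay
  near the constraint manifold during joint training; the α weight keeps
  the term advisory.
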