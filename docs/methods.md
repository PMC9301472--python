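# Methods

## Problem and model

`connpool` predicts a continuous symptom-severity score (e.g. an ADOS
calibrated severity score) from a subject's functional brain network. The
input to the model is a single n × n connectivity matrix **g**; the output
is one real number. The pipeline has four stages.

### 1. Connectivity construction

Given a timepoints × n ROI time-series matrix, edges are estimated either
as Pearson correlations of the demeaned series,

    c_ij = t̃_iᵀ t̃_j / √((t̃_iᵀ t̃_i)(t̃_jᵀ t̃_j)),

or as the Tikhonov-regularized precision matrix

    P = (C + ρI)⁻¹,   C = (1/T) X̃ᵀX̃,   ρ = 0.1 by default,

which damps indirect connections. The empirical covariance uses the 1/T
normalization. The precision matrix is used directly as connectivity; a
`partial_correlation` flag rescales it to −P_ij/√(P_ii P_jj) for users who
prefer that sign convention.

The matrix is then **proportionally thresholded**: the diagonal is zeroed
and exactly ⌊s·n(n−1)/2⌋ upper-triangle entries of largest absolute value
survive, with their signed weights (s = 5% by default). Ranking by
magnitude but keeping signs preserves anticorrelation information. Ties at
the cutoff are broken by (i, j) lexicographic order so results are
platform-independent. Retained edges are z-scored per subject (population
sd, ddof = 0, over retained entries only; zeros stay exactly zero).

Inter-site and covariate (age, sex) effects are removed per retained-edge
position by OLS on intercept + one-hot site indicators (first level
dropped) + age + a 0/1 sex indicator. By default coefficients are fitted
on the whole sample and residuals replace values for all rows; fitting on
training folds only (`fit_rows`) is available as the leakage-safe
alternative. This linear residualization is the in-scope stand-in for full
empirical-Bayes multi-site harmonization, which is deliberately out of
scope here.

### 2. Feature extractor (E2E/E2N)

Instead of hand-chosen node features, edge features are learned on the
line graph of g. Each edge-to-edge (E2E) layer applies a cross-shaped
kernel:

    f^{l+1,b}_{ij} = lReLU( Σ_a Σ_k r^{l,a,b}_k f^{l,a}_{ik} + c^{l,a,b}_k f^{l,a}_{kj} ),

with leaky slope 1/3, two E2E layers, and a constant number d of feature
maps per layer (d₁ = 1, the input map is g itself). The edge-to-node (E2N)
layer aggregates each node's incident edge features:

    e^b_i = lReLU( Σ_a Σ_k w^{a,b}_k f^{L,a}_{ik} ),

yielding the n × d node-feature matrix X.

### 3. Adjacency embedding and self-attention pooling

The pooling stage needs a binary graph A. Three embeddings are supported:
`identity` (R = g), `e2e` (one extra learned E2E kernel on the last hidden
edge features), and `averaging` (mean over the last layer's d maps). In
every case A_ij = 1 iff sigmoid(R_ij) ≥ 0.5, i.e. R_ij ≥ 0, symmetrized by
logical OR. The hard threshold is not differentiable; during training a
straight-through estimator substitutes the (symmetrized) sigmoid in the
backward pass so the e2e-embedding kernel receives gradient
(`adjacency_grad="detach"` gives the stop-gradient alternative; for the
identity and averaging modes the choice only affects the input gradient,
not any parameter gradient in identity mode).

Each of the L = 2 attention-pooling layers scores nodes with a fixed
2-GCN stack,

    S = sigmoid(GCN(lReLU(GCN(X, A; W⁰)), A; W¹)),
    GCN(X, A; W) = D̃^{-1/2} Ã D̃^{-1/2} X W,  Ã = A + I,

with hidden width p = 1, keeps the ⌈k·n_l⌉ top-scoring nodes (k = 1/2;
ties go to the lowest original index), and updates features residually,
X' = X̂ ⊙ Ŝ + X̂. The readout z = Σ_l [mean_i x_i^l ‖ max_i x_i^l] ∈ ℝ^{2d}
sums the per-layer mean‖max summaries; a 128 → 64 → 1 fully connected head
(leaky-ReLU hidden activations, biases everywhere, no dropout) produces
the prediction. The symbol L is conventionally overloaded in this architecture family
(last E2E layer index, attention-layer count, readout bound); this
implementation reads it as: 2 E2E layers, 2
attention-pooling layers, and a fixed 2-GCN score stack; the readout sums
(not concatenates) across pooling layers; the E2N output feeds the
attention network with no extra nonlinearity.

### 4. Training and evaluation

SGD with momentum 0.9, weight decay 1e-4 (implemented as grad + λθ, i.e.
the gradient of L + (λ/2)‖θ‖²), mini-batches of 8, MSE loss, He
initialization (N(0, 2/fan_in); the fan-in of a cross filter is 2n·d_in,
of an E2N filter n·d_in), and a cosine schedule
α_t = ½(1 + cos(tπ/T))·α₀ annealed to zero. Evaluation uses nested
cross-validation: 5 seeded outer folds (uniform shuffle, not stratified);
within each outer training set a seeded 90/10 split provides inner
validation, and the parameters from the epoch with the best inner
validation MAE are kept (best-validation is the conservative choice of
selection rule).
Out-of-fold predictions are pooled across folds and summarized as MAE,
Pearson r, and the two-sided p-value from the t-transform of r with N − 2
degrees of freedom. Targets are used on their natural scale.

The reference operating point for ABIDE-scale cohorts is α₀ = 1e-5,
T = 1000 epochs, d = 32. Because no autodiff framework is a dependency of
this package, the network and its gradients run on a small reverse-mode
engine over numpy arrays (`connpool.autodiff`); every backward rule is
verified against central finite differences in the test suite, and
training is done in float64.

## Interpretation

**Three-level CCA.** Per subject, the E2N node embeddings X_nf (n × d,
domain 1) are related to eight binary-graph nodal measures X_gm (n × 8,
domain 2): degree, clustering, local efficiency, betweenness, eigenvector,
subgraph centrality, flow coefficient, k-core number. Level 1 is the
maximum pairwise Pearson correlation per measure; level 2 the multiple
correlation (√R² of regressing the measure on the embeddings); level 3 the
first canonical correlation, computed by SVD of the whitened
cross-covariance Σ₁₁^{-1/2} Σ₁₂ Σ₂₂^{-1/2} with a ridge of 1e-8 added to
the within-set covariances (n can be close to d for small atlases). By
construction level 1 ≤ level 2 ≤ level 3 up to arithmetic error. The
analysis is run per subject and summarized as mean ± sd across subjects;
pooling nodes across subjects is a conceivable alternative reading, but
per-subject distributions match the way the analysis is usually displayed.

**Graph measures.** The measures are computed on the binarized thresholded
graph (edge = any retained weight; negative weights count by magnitude)
because k-core, flow and subgraph centrality are only standard for binary
graphs; a `weighted` flag swaps in weighted degree/clustering/efficiency.
Betweenness is unnormalized raw geodesic counts (each unordered pair once,
fractional credit for ties). The flow coefficient of node i is the
fraction of neighbour pairs of i not directly connected (the open,
i.e. geodesic, 2-paths through i), which equals 1 − clustering on simple
graphs; no formula is given in the source literature for these two names,
so the standard brain-connectivity-toolbox conventions are used and
documented. Eigenvector centrality is the nonnegative unit-norm principal
eigenvector of the largest component (zeros elsewhere); betweenness and
local efficiency are per-component on disconnected graphs.

**Saliency.** The attribution of edge (i, j) is ∂ŷ/∂g_ij, computed by
backpropagation with the binarized pooling adjacency held constant, then
symmetrized as (PD + PDᵀ)/2. Holding A fixed is not merely a convenience:
the threshold makes the full model piecewise constant in A, so the
gradient on the differentiable branch is the only well-defined local
sensitivity. Note the model is generically *non-differentiable* exactly at
edges between two isolated nodes of the sparse input (their E2E
pre-activations sit exactly on the leaky-ReLU kink); gradient-vs-finite-
difference checks therefore use inputs with no isolated nodes. Saliency is
computed at the model's actual input scale (post-thresholding,
post-standardization). Per-subject maps are averaged into a group map and
the top 10% of edges by |mean PD| are reported as an edge table
(region1, region2, PD value); an alternative "≥ fraction of max" rule is
available.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes
without any real imaging data: per subject a symmetric matrix with
3-block community structure; fixed per-(edge, site) offsets emulating
acquisition bias (sd 0.2); ages uniform on [7, 30] and sex Bernoulli(1/2)
echoing typical developmental-cohort ranges; and a sparse support of s
planted edges whose values drive the score. Planted edges get a large
mean magnitude (|raw| ≈ 2.0 vs background sd 0.4) so they survive 5%
proportional thresholding with high probability, and they co-vary through
a shared per-subject severity factor (loading 0.5, edge-specific noise
sd 0.2) — a coherent network alteration, the regime connectome-wide
association studies assume. This coherence matters quantitatively: were
the planted edges independent, each would carry marginal correlation
√(0.64/15) ≈ 0.21 with the score, and at N = 300 no estimator — the
cross-validated ridge reference included — can recover pooled r ≥ 0.5
from 435 candidate edges; with the shared factor the ridge reference
reaches r ≈ 0.7, so the stated ceiling is actually approachable at this
sample size. The score is

    y_i = Σ_{(u,v)∈S} W*_uv g_i[u,v] − offset + δ·site + β_age(age−āge) + β_sex·sex + ε,

computed from the *processed* matrices (the model's actual input) and
centered; the noise sd is calibrated from the realized sd of the planted
component so the signal contributes exactly `signal_fraction` of the score
variance — the attainable prediction ceiling is its square root. A
`timeseries` mode draws block-covariance multivariate-normal series and
pushes them through the full Pearson/Tikhonov pipeline instead; it is
slower and the planted coupling is less sharply controlled, so the
benchmark uses the direct mode. What passing tests on these cohorts does
*not* show: robustness to hemodynamics, motion artifacts, non-Gaussian
noise, or real inter-site heterogeneity.

## The recovery benchmark

`connpool.experiments.run_recovery_experiment` is the package's
integration experiment: N = 300 subjects, n = 30 ROIs, s = 15 planted
edges, signal fraction 0.64 (ceiling r = 0.8), 3 sites. Model: identity
adjacency embedding, d = 8 feature maps; training: 200 epochs, α₀ = 1e-3,
3 restarts per fold, otherwise the standard recipe. d and α₀ were chosen
by inner validation on one fold (d ∈ {4, 8, 16}, α₀ ∈ {3e-4 … 1e-2};
large rates diverge at this target scale, d = 8 with α₀ = 1e-3 maximized
validation performance); the ABIDE-scale defaults (d = 32, α₀ = 1e-5,
T = 1000) are tuned to a cohort and epoch budget this scaled-down problem
does not have. Restarts exist because, at 240 training subjects, some
seeded initializations memorize the training set instead of generalizing;
the restart with the lowest inner-validation MAE is kept, and a restart
whose loss diverges is discarded as long as another completes. Success
criteria: pooled held-out r ≥ 0.5, MAE below the predict-the-mean
baseline, and precision@s of the group saliency map at least 3× the
chance rate s/(n(n−1)/2). Out-of-fold saliency is used: each subject is
attributed with the fold model that never saw it.

## Numerical choices and limitations

- float64 throughout; oracle tolerances 1e-5 (layers), 1e-8/1e-10 (linear
  algebra identities).
- Deterministic tie-breaks everywhere (threshold cutoff: lexicographic;
  top-k pooling: lowest original index; readout max: first argmax).
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; the full pipeline is bitwise reproducible.
- Degenerate inputs raise informative errors: zero-variance ROI series,
  singular (C + ρI), all-equal retained edges, rank-deficient
  residualization designs, constant vectors in correlation.
- Gradient clipping is off by default (`clip_norm` enables it); the
  divergence guard raises with the epoch at which loss became non-finite.
- The model is not permutation-invariant (kernels are node-indexed); it is
  equivariant under simultaneous permutation of nodes and kernel entries,
  which the tests exercise.
- All stages are batched across the mini-batch, including pooling (graphs
  coarsen differently per subject, but the survivor count is identical, so
  per-sample top-k indices feed one batched gather); the per-sample code
  path is kept for introspection and is bit-identical. On one CPU the full
  recovery benchmark runs in about six minutes.
- The CCA drops constant measure columns per subject (a measure can be
  degenerate on a given sparse graph) and uses a covariance-scaled ridge,
  since flow and clustering are exactly collinear on min-degree-2 graphs.
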