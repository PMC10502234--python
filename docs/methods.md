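# Methods

## The model

t-SNE embeds samples x_1..x_n ∈ R^d as y_1..y_n ∈ R^d′ (d′ = 2 or 3) by
minimizing KL(P‖Q), where P holds symmetrized Gaussian input-space
affinities with per-sample bandwidths calibrated to a target perplexity,
and Q is the Student-t kernel q_ij = u_ij/Z, u_ij = (1+‖y_i−y_j‖²)^−1,
Z = Σ_{k≠l} u_kl.  The optimizer is momentum gradient descent on

    ∂KL/∂y_i = 4 Σ_{j≠i} (p_ij − q_ij) φ_ij,   φ_ij = (y_i − y_j) u_ij,

with early exaggeration (P multiplied by a factor for the first iterations)
and optional sign-based gain adaptation.

`tsnegrad` differentiates this whole pipeline.  Writing G_i^t = ∂y_i^t/∂x_i
(a d′ × d block per sample) and assuming the cross-sample blocks
∂y_i/∂x_j (i ≠ j) vanish, each iteration updates G through exactly the
arithmetic the optimizer applies to y:

    ∂(grad_i)/∂x_i = 4 Σ_{j≠i} [ (∂p_ij/∂x_i − ∂q_ij/∂x_i) ⊗ φ_ij
                                 + (p_ij − q_ij) ∂φ_ij/∂x_i ],

with ∂q_ij/∂x_i = (∂q_ij/∂y_i) G_i and ∂φ_ij/∂x_i = (∂φ_ij/∂y_i) G_i.
A velocity-derivative tensor runs alongside the optimizer's velocity so
momentum (and, when enabled, gains treated as per-iteration constants) is
mirrored exactly.  G^0 = 0 because the initialization is an isotropic
Gaussian independent of the data.  The closed forms used:

    ∂p_{j|i}/∂x_i = −2β_i p_{j|i} [ (x_i−x_j) − Σ_k p_{k|i}(x_i−x_k) ]
    ∂p_{i|j}/∂x_i = −2β_j p_{i|j} (1 − p_{i|j}) (x_i−x_j)
    ∂q_ij/∂y_i    = [ −2u_ij²(y_i−y_j) + 4 q_ij Σ_k u_ik²(y_i−y_k) ] / Z
    ∂φ_ij/∂y_i    = u_ij I − 2u_ij² (y_i−y_j)(y_i−y_j)ᵀ

Bandwidths β_i are held constant during differentiation: the perplexity
calibration is a root-find, so its output is treated as data, and every
finite-difference oracle freezes β identically.  Early exaggeration scales
P and ∂P/∂x by the same factor, which keeps tracking exact.

The per-sample attribution is the gradient of the sample's squared distance
from the embedding centroid, A_i = 2 ŷ_iᵀ G_i with ŷ = y − mean(y): a single
d-vector per sample saying which input features pushed the sample to where
it sits.  ‖y‖² is origin-dependent, and the optimizer itself never
re-centers (a translation does not change KL); centering once at the end
makes the score translation-consistent and is recorded in output metadata.
Variants: `positive_only` zeroes negative entries; `grad_times_input` is
|A ∘ x|.  Downstream rankings use |A| unless `positive_only` is requested.
Group-level scores are |mean over member rows| — the absolute value of the
mean, so features pushing members in opposite directions cancel.

## What the tracked gradient is — and is not

Under the cross-block assumption the recursion computes the *exact*
derivative of a well-defined map: re-integrate sample i's embedding through
the full optimizer arithmetic while every other sample replays its
reference trajectory.  The test suite verifies this to ~1e−7 relative
against whole-trajectory central finite differences of that map.

It is *not* the derivative of the fully coupled pipeline.  Perturbing x_i
also moves every other sample (p_ji and the conditional normalizers depend
on x_i), and those displacements feed back into y_i.  On small instances
this feedback is comparable to — and can dominate — the diagonal term.
The assumption is what makes the computation tractable (a dense n × n × d′ × d
tensor would be needed otherwise), and the corruption experiments are the
empirical evidence that the diagonal part carries usable signal; users
should read attributions as local sensitivity scores of the per-sample
placement map, not as full counterfactual derivatives.

A second caveat: the linearized per-sample dynamics can be unstable even
when the embedding itself converges.  With aggressive learning rates and a
large exaggeration factor, ‖G‖ grows exponentially during the exaggeration
phase and the attribution degenerates into amplified noise (finite but
astronomically scaled G is the diagnostic; `fit_attributions` warns when it
sees this).  The experiments in this package (examples, acceptance runs) therefore use
the gentler classic schedule — exaggeration factor 4 and a learning rate of
order n/15 (20 for n = 300) — under which G stays O(1) while clusters still
resolve fully; `OptimizerConfig` keeps the conventional untracked defaults.

## Attribution visibility and perplexity

A feature can receive attribution only through ∂p_ij/∂x_i, i.e. only if it
modulates an affinity that carries weight.  When clusters are separated by
many noise standard deviations and the perplexity is below the cluster
size, cross-cluster affinities underflow (measured ~1e−15 at shift 6,
noise 1, perplexity 30) and the features *defining* the separation become
invisible: per-sample gradients contain only within-cluster noise and
class-averaged attributions are uninformative.  For between-cluster
questions the affinity graph must bridge clusters; the recovery experiment
uses perplexity ≈ 2 × cluster size (170 for four clusters of 75).  The same
reasoning applies to real data: choose the perplexity at the scale of the
structure to be explained.  (Conversely, at perplexities this large the
×12 exaggeration schedule over-compresses and the embedding can collapse;
exaggeration 4 avoids this.)

## Optimizer conventions

Defaults follow reference implementations: 1000 iterations, momentum
0.5 → 0.8 at iteration 250, exaggeration ×12 for 250 iterations, learning
rate "auto" = max(n/(4·exaggeration), 50), Gaussian init with σ = 1e−4
(data-independent, as gradient tracking requires), no early stopping (a
fixed iteration budget; the per-checkpoint KL log is the convergence
monitor).  Gains are off by default in tracked runs because gain adaptation
is sign-based and non-differentiable; when enabled they are treated as
per-iteration constants in the tracking.  Tracked analyses override
exaggeration and learning rate as described above.  Divergence (any
|y| > 1e8) raises with the iteration index.

Numerical choices: conditional affinities floored at 1e−12 before
symmetrization; bisection on the row perplexity to |2^H − perplexity| <
1e−5 with at most 200 iterations, failing loudly with the offending row
(coincident points can make a target unreachable); selection ties broken
by ascending feature index; k-NN distance ties broken by sample index.

## Barnes–Hut mode

A quadtree (2-D only) groups distant points; a cell of width w at distance
r is treated as one mass at its center of mass when w/r < theta.  theta = 0
reproduces exact sums to machine precision.  One traversal per iteration
supplies all the kernel moments the tracker needs — Σu, Σu², Σu²Δ, Σu³ΔΔᵀ —
so tracked Barnes–Hut runs reuse the force tree; the P-weighted sums stay
exact and dense (sparse approximate affinities are out of scope).  Accuracy
is reported as the largest force/gradient error divided by the largest
force/gradient magnitude — per-point ratios are meaningless where opposing
contributions cancel and the true force is ~0.  At theta = 0.5 on clustered
n = 200 embeddings this normalized error is ~2% for forces and <10% for
tracked gradients.

## Corruption-based validation

For each t-SNE seed: fit a reference (tracked) embedding, rank features by
a selector, corrupt the top round(fraction·d) features, refit on the
corrupted data with a fresh perplexity calibration but the same
embedding-init seed (isolating the corruption effect from init noise), and
compare embeddings with three metrics — Spearman correlation of all
pairwise distances, ARI between seeded 10-restart K-means clusterings
(K = number of known classes, else 10), and mean 10-NN retention.
Selection levels: per sample (local), per class, or one set for the whole
dataset (class/global sets keep the features most often in member samples'
top-fraction sets; membership is ≥ the (100−k)th percentile).  Corruption
methods: mean (each selected cell replaced by the mean of the selected
cells of that feature within the corruption scope — the selecting samples
locally/globally, the class members at class level), within-feature seeded
permutation, and column removal (global only).  Baselines: 10 seeded random
subsets per configuration, |feature| enrichment, Laplacian score on P or on
the embedding kernel Q (ascending = important; recomputed per class for the
class level), Fisher score (supervised control), and a PCA-variance control
(Σ over top PCs covering 90% of variance of λ_c·loading²).  Cell results
aggregate over seeds (and subsets) with percentile bootstrap 95% CIs (1000
resamples).  Pairwise-distance Spearman uses all pairs up to n = 3000 and a
seeded 10⁶-pair subsample beyond.

## Synthetic generator

Base samples are i.i.d. N(0, noise_sd²) in R^d; cluster c ≠ 0 translates
its disjoint truth-feature subset by +shift; cluster 0 is the null cluster
with no translated features.  Defaults: 4 clusters × 75 samples, d = 30, 5
truth features per cluster, shift 6, noise 1 — isotropic noise plus
translation is the simplest construction realizing translation-defined
clusters, and every parameter is exposed.  `hierarchy=True` makes paired
signal clusters share one truth feature, inducing super-clusters (off by
default so truth subsets stay disjoint).  Recovery scoring: per cluster,
AUROC of the class-averaged |attribution| as a classifier of truth
membership, a one-sided rank-sum p-value, and the truth fraction in the top
decile; the null cluster is scored against the union of all truth features
(its placement is driven by the features defining its neighbors).  What
passing shows: the tracked gradient recovers *translation-defined* cluster
structure; it says nothing about correlated features, nonlinear manifolds,
count noise, or batch structure, none of which the generator emulates.

## Mutation encoding

Aligned sequences are encoded against a reference (1-based coordinates
after dropping reference-gap columns): one binary feature per observed
alternate state (substitution base or deletion) per position.  Filters
follow viral consensus-genome practice: N and other non-ACGT codes are
missing; deletion runs > 12 nt are recoded as missing over their span
(alignment/assembly artifacts); singleton features are dropped; the first
and last 100 reference positions are dropped (poorly covered ends).
Multi-allelic sites yield one feature per alternate state.  Missing calls
can be imputed as reference (0), retaining pre-imputation missingness
frequencies — the QC procedure correlates cluster-averaged attributions
with per-cluster missingness (one-sided permutation p-values, exact for
≤ 6 features) to detect clusters driven by shared missing-data patterns.
Marker identification thresholds group-averaged attribution and feature
frequency at a per-group percentile (default 90th) and reports the four
quadrants.

## Problem sizes and test design

Experiments in the test-suite and acceptance script run at desk scale:
n = 300, d = 30 for recovery and corruption (300–750 iterations), n ≤ 25
for arithmetic-equivalence checks, n = 200 for Barnes–Hut accuracy, and
n ≤ 12 for whole-trajectory finite differences, with seeds fixed or derived
from a single CLI seed.  The literal per-pair tracker in
`tsnegrad.reference` exists purely as an independent arithmetic path for
equivalence testing.  Tracked fits cost O(n²·d′·d) per iteration — about a
d/2-fold overhead over a plain dense fit — and memory O(n·d′·d + n²).

## Known limitations

- Cross-sample attribution (∂y_i/∂x_j) is out of scope by construction.
- Dense P everywhere: n beyond ~5000 becomes slow and memory-heavy.
- Barnes–Hut is 2-D only (quadtree; no octree or FFT interpolation).
- Attribution quality depends on embedding quality and on the stability of
  the linearized dynamics; inspect the KL log and the G-magnitude warning.
- The percentile convention for "top k%" membership (≥ the (100−k)th
  percentile, index-ascending tie-break) is one of several defensible
  choices and is documented rather than configurable.
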