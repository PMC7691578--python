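# Methods

## Model and procedure

`evosel` selects a compact feature panel from a features × samples
expression matrix with class labels, then evaluates the panel with
survival and differential-expression statistics. The selection procedure
is a stochastic wrapper: candidate subsets are scored by the
cross-validated accuracy of an actual classifier rather than by a filter
statistic, so feature interactions influence the search.

### Preprocessing

Raw counts are normalized per sample to reads per million and transformed
as log2(RPM + 1); the pseudo-count of 1 keeps zero counts at exactly zero
after the transform. Features with a zero fraction strictly above 60% in
*any* class group are removed (evaluated on the count/RPM scale, where
zeros are meaningful), and when several cohorts are combined only features
present in all of them are kept, in the order of the first cohort.
Incomplete clinical rows (missing vital status or follow-up days) are
excluded, never imputed; the exclusion count is logged.

### SNE feature reordering

The original asymmetric SNE is used, not the t-distributed variant: both
the input affinities P and the embedding affinities Q are row-conditional
Gaussian distributions, which makes the objective Σᵢ KL(Pᵢ‖Qᵢ)
well-defined row by row. Per-point variances are calibrated by bisection
(≤ 64 steps) so that every row's perplexity, 2^entropy, matches the target
within 10⁻³. Features are standardized across samples before embedding,
so Euclidean distance between feature vectors is monotone in
1 − Pearson correlation and "neighboring features" means "correlated
features".

The embedding dimension is 1 because the only consumer of the embedding
is an ordering: features are sorted by their embedded coordinate (ties
broken by original index, constant features placed last with a warning).
Gradient descent uses the asymmetric-SNE gradient
2 Σⱼ (pᵢⱼ − qᵢⱼ + pⱼᵢ − qⱼᵢ)(yᵢ − yⱼ) with momentum 0.5 for the first
250 iterations and 0.8 thereafter, from a small random initialization
(SD 10⁻⁴).

Numerical choice: with unit-variance Gaussian Q the gradient magnitude
grows linearly in the coordinate scale, so a large fixed learning rate
diverges multiplicatively. The default learning rate is 1.0 and the
optimizer backtracks — on a KL increase beyond 5% of the best value it
returns to the best-so-far coordinates, zeroes the velocity, and halves
the step (growing it again by 5% per accepted step, capped at the
configured rate). Best-so-far coordinates are returned, making the
recorded KL history nonincreasing by construction.

### CMA-ES

A self-contained (μ/μ_w, λ) CMA-ES. Defaults for the full-scale profile:
λ = 200, μ = 100, σ₀ = 0.3, C₀ = I, 200 generations. Recombination weights
follow the log-rank scheme wᵢ ∝ ln(μ + ½) − ln i; the learning rates c₁,
c_μ, c_c, c_σ and damping d_σ use the standard dimension-dependent tutorial
formulas. The covariance update is the plain rank-one + rank-μ
recombination

C⁺ = (1 − c₁ − c_μ) C + c₁ p_c p_cᵀ + c_μ Σᵢ wᵢ yᵢ yᵢᵀ,  yᵢ = (xᵢ − m)/σ,

with the evolution path p_c smoothed using the normalizer
√(c_c(2 − c_c)μ_eff) that makes the path stationary under neutral
selection; the stall-gating heuristic (h_σ) is deliberately omitted so the
update is exactly the stated recombination. The step size adapts by
cumulative step-size adaptation on the conjugate path p_σ. Eigen
decompositions are cached and refreshed every ⌈1/(10·H·(c₁+c_μ))⌉
generations; eigenvalues are clamped at 10⁻¹⁴ to keep C positive definite
under finite precision. Reported best-ever values are elitist, so the
per-generation history is nondecreasing. Non-finite objective values rank
the offending solution worst rather than aborting the run.

The optimizer's initial mean is the decode threshold t (0.5 per
coordinate), so the initial selection probability per feature is ½ and
the size penalty immediately shapes the search.

### Decoding and the objective

An individual is a weight vector over positions of the reordered feature
sequence; position k selects its feature when w_k ≥ t (inclusive
comparison, t = 0.5 held fixed — the threshold is a constant of the
procedure, not an evolved gene, though `DecoderConfig` accepts an
`anchors` mode in which H < D anchor weights are shared by nearest
position). Subsets are scored by stratified 5-fold cross-validation:
overall (micro) accuracy across pooled held-out folds, with a fixed fold
seed per run so scores are comparable across individuals, memoized by
subset. Scores are penalized as accuracy − α·max(0, |S| − Υ)/D (α = 0.5).
An empty decode scores −1, strictly below any attainable value, so the
search is repelled from degenerate individuals.

Classifiers are consumed through scikit-learn behind a small spec
(random forest with 50 trees; RBF-SVM with γ = 0.05, C = 1.0; Gaussian
naive Bayes; K-NN with K = 5 and brute-force neighbor search, which avoids
per-fold tree builds at the small sample sizes this objective sees;
decision tree). Their internals are out of scope.

### Multi-run stabilization

One run's best subset is the elitist best over all generations; ties on
objective value go to the smaller subset, then lexicographic order. R runs
execute with distinct seeds derived from a master seed via a seed
sequence, recorded in the run manifest for exact replay. Features are then
ranked by frequency of appearance across run-best subsets (ties: mean
best objective of contributing runs, then original index), and forward
selection evaluates every cumulative prefix of the ranked list, returning
the prefix with maximal CV accuracy (ties: shortest prefix). The
cumulative-prefix scan is used rather than classical add-if-improved
forward selection; both finalizations are reasonable, and the prefix scan
is the one that operates directly on the frequency ranking.

The coverage expectation E[distinct] = D − D(1 − S/D)ᴿ (from per-feature
Bernoulli indicators and linearity of expectation) quantifies the value of
additional runs; its discrete increment at R further runs estimates how
many never-seen features one more run would surface.

### Cox survival evaluation

Each selected feature is evaluated by a univariate Cox
proportional-hazards fit: Newton–Raphson on the Breslow-tie log partial
likelihood (Breslow tie handling matches the Breslow baseline estimator
used downstream; Efron is not offered), convergence at |Δβ| < 10⁻⁸ or 50
iterations, Newton steps clipped at ±5 to survive near-monotone
likelihoods, standard error from the observed information, two-sided
normal Wald p. Perfect separation (monotone likelihood) surfaces as a
non-converged flag rather than a spurious estimate. The cumulative
baseline hazard is Breslow's estimator; the survival function
S(τ) = exp(−H₀(τ)e^{xβ}) = S₀(τ)^{e^{xβ}} is exposed on the results
object. Up/down-regulation calls use a two-group one-way ANOVA
(tumor vs pooled normals) at p < 0.05 with the sign of the tumor−normal
mean difference; FDR control across features is Benjamini–Hochberg.

### Association ranking

Feature–target pairs are correlated (Pearson) within each cancer-type
group. The cumulative negative-correlation score sums the *negative*
per-group correlations only (positive correlations neither help nor hurt),
and the association count is the number of groups with r < 0. Ranking is
by count (descending), then score (ascending, more negative first), then
IDs. An optional significance gate (correlation-test p below a cutoff)
can restrict counted groups; it is off by default.

## Synthetic data generator

The expression generator emulates the shape of log2-scale multi-class
miRNA-seq data: a features × samples Gaussian matrix around a baseline of
5.0 (log2 RPM scale) with noise SD 1.0, 11 classes × 30 samples and
D = 60 by default. Each class owns a block of informative features that
shift by `effect_delta` noise SDs in that class only and share a latent
factor, x = √ρ·f + √(1−ρ)·ε, giving exact pairwise correlation ρ = 0.6
inside the block — the correlated-neighbor structure the SNE reordering
exploits. Optional zero inflation zeroes entries to mimic dropout.

What the generator does *not* emulate: negative-binomial count dispersion,
batch effects, class imbalance, or realistic library-size variation.
Passing tests therefore demonstrate the machinery's correctness and its
recovery behavior under a clean planted-signal model, not performance on
real TCGA-scale data.

The survival generator draws a standard-normal covariate and event times
from the proportional-hazards model with exponential baseline,
T ~ Exp(rate = r₀·e^{xβ}), with independent exponential censoring, so at
β = 0 the censored fraction is c/(c + r₀) in closed form (the calibration
tests use r₀ = 1/500 and c = 1/2000 per day, ≈ 20% censoring).

## Study sizes used by the test suite and acceptance script

Chosen as desk-scale versions of the procedure that keep every stage
exercised: Cox calibration uses 200 replicates at n = 500 (β = 0.7) and
500 null replicates at n = 300; the end-to-end recovery study uses
5 classes × 30 samples, D = 50 with one planted feature per class
(effect 2 SD), R = 10 runs of 30 generations with population 20, K-NN
scoring, and target panel size Υ = 5, repeated 10 times. The K-NN scorer
is used there because its cost per evaluation is smallest among the five
classifiers at these sample sizes.

## Known limitations

- The SNE embedding is optimized by first-order descent with restarts and
  can settle in local optima; different seeds give different (valid)
  feature orders. Only the ordering, not the geometry, is consumed.
- CMA-ES on the effectively binary decode landscape plateaus once most
  weights are far from the threshold; the multi-run frequency ranking, not
  single-run convergence, provides the stability.
- The Cox implementation is univariate by design (one coefficient per
  feature per cohort); multivariable fits, stratification, time-varying
  effects, Kaplan–Meier curves and log-rank tests are out of scope.
- ANOVA regulation calls compare tumor samples against pooled normals;
  matched-normal designs are not distinguished.
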