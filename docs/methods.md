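# Methods

## The progression model

`ppsi` models P features of an observation-by-feature matrix X (N×P) as
polynomial functions of a latent pseudotime axis t ∈ [0, 1], discretized
into K+1 evenly spaced stages t_k = k/K. Stage 0 is the normative
anchor: every trajectory has a fixed zero intercept, so a z-score of 0 —
the value a confounder-matched control would show — maps to the start of
the progression. Each of S subtypes owns an independent coefficient
matrix Θ_s ∈ R^{D×P}; evaluating M_s = T·Θ_s at all stages produces the
multidimensional stage-cluster centroids.

The likelihood treats every (subtype, stage) cell as an isotropic
Gaussian with fixed standard deviation σ around its centroid. Fixing σ
lets the log-density reduce to `ln α − (x − μ)²/β` with α = 1/(σ√2π),
β = 2σ² precomputed once; the sum over features is computed in the log
domain so underflow cannot occur. Each observation is hard-assigned to
its maximum-likelihood cell and the dataset log-likelihood is the sum of
those maxima; the loss adds λ·Σ|θ|. One loss evaluation is O(S·K·P·N)
and the implementation is fully vectorized over records.

**Assumptions.** Features are normative z-scores (the `DataMatrix`
carries a provenance flag; fitting without it warns rather than errors,
since z-scoring is an assumption, not an enforceable property). Noise is
Gaussian with a common scale across features and stages. Observations
are independent; pseudotime is a severity ordering, not calendar time,
and is identified only up to orientation and monotone reparameterization
of sampling density.

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) on minibatches sampled without
replacement from a seeded generator, with the likelihood term rescaled
by N/|batch| so λ keeps the same meaning at any batch size. Assignments
are held fixed within an iteration and gradients flow only through each
record's argmax cell — the hard-assignment subgradient familiar from
k-means/hard EM. The learning rate warms up linearly over the first 10%
of iterations to `max_lr`, then anneals along a cosine to 1% of
`max_lr`. Argmax ties break toward the lowest stage, then the lowest
subtype index: deterministic, and biased toward "less progressed" under
genuine ambiguity.

**Initialization.** Coefficients start at N(0, 0.1) noise with the
per-feature data mean added to the degree-1 term. The data anchor
matters: with a pure near-zero start the model can assign every record
to stage 0 in the first iteration, and because the stage-0 basis row is
identically zero the likelihood gradient then vanishes everywhere,
freezing training permanently. Anchoring the t = 1 end of each initial
trajectory near the data mean keeps all stages competitive from the
first iteration; the residual noise breaks subtype symmetry.

**Defaults and units.** K = 15 non-zero stages (a typical middle value;
staging resolution trades against per-stage sample size); σ = 1.0 in
z-score units (one control-residual standard deviation); λ = 0.05;
`max_lr` = 0.1; 2000 iterations; minibatch fraction 0.2. The iteration
count, schedule shape and Adam constants are library choices — the
method itself only requires "gradient descent with an annealing
schedule" — and are exposed in `FitConfig`. Fits are deterministic given
`seed`. A non-finite loss raises an error naming the iteration.

## Normative z-scoring

Per feature, ordinary least squares of the control sample on confounders
plus intercept (numpy `lstsq` on a shared design matrix); z = (y − ŷ)/s_ε
with s_ε the residual standard deviation using the unbiased denominator
C − Q − 1 (the choice of denominator is a convention; at typical control
sample sizes the difference is negligible). Degenerate (zero-residual)
features and rank-deficient confounder designs are rejected with the
offending columns named; control rows with missing values are dropped
with a logged count. Categorical confounders must be numerically encoded
by the caller.

## The simulator

The generator draws ground-truth trajectories and samples observations
from them, emulating the statistical structure of cross-sectional
disease-progression panels:

1. Features are grouped into `n_clusters` coefficient clusters; cluster
   sizes target a configurable Atkinson inequality index (aversion
   parameter 1, i.e. 1 − geometric/arithmetic mean) through a geometric
   proportion family inverted by bisection, then largest-remainder
   apportionment.
2. Per subtype, cluster coefficient means are drawn with magnitude
   uniform in `means_range` and random sign (independently per subtype
   unless `shared_clusters`); per-feature coefficients are normal around
   the cluster mean with a per-cluster spread in [`stdev_min`,
   `stdev_max`].
3. Per-feature noise coefficients are uniform in [`noise_min`,
   `noise_max`]; records get a subtype (proportions targeting the
   class-imbalance Atkinson index), a continuous stage from the
   subtype's Beta(a, b) sampling distribution (shapes uniform in
   `sampling_bias_minmax`, shared across subtypes when
   `shared_sampling_bias`), and observed values = polynomial at the
   stage + noise · N(0, 1).

Default ranges: means 1–4, cluster spread 0.2–0.5, noise 0.2–1.5 (in
z-score units), Beta shapes 1–4, imbalance indices 0.1. The exact
procedure behind the published generator is not public; this
reconstruction follows its published parameter table and is documented
as such.

**What passing tests on simulated data do and do not show.** The
generator produces exactly the model family the fitter assumes
(polynomial trajectories, Gaussian noise, independent records), so
recovery results certify the estimator, not the model's adequacy for
real data: real panels have non-Gaussian noise, missing values,
longitudinal correlation, and trajectories that are not polynomials.
Because both subtypes' curves pass through the origin and are drawn
independently, subtype separability varies strongly between draws —
some generated datasets are intrinsically ambiguous (even assignment
under the true coefficients recovers subtypes poorly), which dominates
the spread of benchmark ARI values across seeds.

## Model selection

`run_sweep` fits every (order, subtype count) combination across
shuffled K-fold splits (sklearn `KFold`, seeded) and computes six
metrics *on the held-out fold* — training-split metrics would reward
overfitting. The metrics: stage-distribution (population SD of
per-stage counts; lower = more even staging), evaluation distance (mean
pairwise distance between subtype curves; 0 by convention for S = 1),
silhouette against other subtypes' stage-centroids (NaN for S = 1),
correlation comparison (Pearson between the data-estimated and
curve-implied feature covariance triangles, unbiased covariances,
subtypes with < 3 records or zero variance skipped), AIC
(2·D·P·S − 2·log-likelihood), and Euclidean R² (1 − residual/total sum
of squares around assigned centroids). Degenerate cases return explicit
NaN flags, never silent zeros. No automatic choice is made: the sweep
emits the table (and optional boxplots) and the analyst selects.

## Feature dropout

`dropout_report` re-runs inference with one feature at a time withheld
by omitting its terms from the log-likelihood sum — not by zero-imputing,
which would inject the normative mean as fake evidence. No refitting
occurs, so the report is O(P) likelihood evaluations and runs in seconds
at P = 50, N = 500. Importance is the fraction of records whose
(subtype, stage) assignment changes (the union event, so it is ≥ each of
the subtype-only and stage-only fractions). `select_features` applies a
strict importance cutoff, preserving feature order.

## Validation statistics

Subtyping recovery uses the adjusted Rand index (delegated to
scikit-learn; NaN when either labeling has a single class, where the
chance-corrected index is undefined). Staging recovery reports the
Pearson correlation together with |r| and an inversion flag, since the
loss does not identify the axis orientation. Longitudinal metrics
(subtype consistency, stage monotony ≥, stage progression >) take
aligned baseline/follow-up assignments; chance baselines permute the
baseline↔follow-up pairing, which preserves both marginal distributions
— the minimal-assumption null. p-values are one-sided (fraction of
permuted values ≥ observed), CIs are 2.5/97.5 permutation percentiles.

## Numerical choices and edge cases

- Bisection for Atkinson targeting runs on the geometric family
  p_i ∝ r^i; targets at or beyond the family's achievable maximum raise
  an error reporting the range. Index tolerance 1e-6.
- Model JSON serialization uses Python's shortest-repr floats, so Θ
  round-trips bit-exactly; the format is versioned and unknown versions
  are rejected.
- `DataMatrix` rejects missing/non-finite values at construction;
  imputation is upstream of this package by design.
- Stage indices are 0-based (stage 0 = control anchor); subtype labels
  are 1-based.

## Problem sizes used in the test suite

The shipped tests exercise desk-scale versions of the published
experiments: the head-to-head benchmark at its original size (500
records, 6 features, 20 fits), recovery and sweep properties at 60–500
records with 4–20 features, and the under/over-estimation comparison
over 20 generated datasets at 300 records each — sizes chosen so the
full suite completes in a few minutes while keeping each effect
detectable.

## Known limitations

- Hard assignment makes the loss piecewise-smooth; fits are local optima
  and seed-dependent (the benchmark averages over 20 seeds for this
  reason).
- Fixed isotropic σ mis-weights features whose true noise differs;
  assignments are invariant to σ, but training dynamics and the λ
  balance are not.
- Pseudotime orientation is unidentified; downstream comparisons should
  use |r| or fix orientation externally.
- A single polynomial per feature cannot express piecewise or saturating
  trajectories; spline bases are out of scope.
- The sweep's correlation-comparison metric discriminates subtype count
  only weakly when subtypes are poorly separated.
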