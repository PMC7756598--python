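# Methods

## Model and hypotheses

A study measures m ≥ 2 endpoints; the researcher states an a priori
direction for each.  The tested parameter φ is the researcher's *predictive
ability*: the probability that a given endpoint's observed direction matches
the prediction.  The hypotheses are H₀: φ ≤ φ₀ against H₁: φ > φ₀, with
φ₀ ∈ (0, 1) chosen before analysis (default 0.5 — "better than chance";
values ≥ 0.5 are recommended, and higher φ₀ costs power).

Prediction outcomes pᵢ ∈ {0, 1} are scored against the observed sample
effects: the mean of within-subject differences (paired design) or the
difference of group means, second group level minus first (two-group
design).  An exactly-zero observed effect scores the prediction as
*incorrect* — the conservative resolution of a case the test definition
leaves open; it occurs with probability zero for continuous data.

The statistic T_m = Σ pᵢwᵢ weights each correct prediction by
wᵢ = (Σⱼ r²ᵢⱼ)⁻¹.  The row sum of squared correlations includes the
diagonal term r²ᵢᵢ = 1; this is what pins the limiting values wᵢ = 1
(independence) and wᵢ = 1/m (perfect association), hence W ∈ [1, m] as an
effective endpoint count.

Under H₀ the pᵢ are modelled as iid Bernoulli(φ₀), with the weights treated
as fixed.  Treating sample-derived weights as fixed is an approximation
whose practical effect is quantified by the sensitivity study below.

## Exact null distribution and p-value

All 2ᵐ prediction vectors are enumerated (subset sums built by doubling);
vector p contributes probability φ₀^Σp(1−φ₀)^(m−Σp) at value pᵀw.  Values
within an absolute tie tolerance of 1e−9 are merged (probability-weighted
representative), and the p-value is the inclusive upper tail
P(T ≥ t_obs − 1e−9) — "as or more extreme", robust to floating-point sums
of weights arriving in different orders.  Enumeration is capped at m = 25
(2²⁵ ≈ 3.4e7 vectors); beyond the cap the caller is directed to the normal
approximation or Monte-Carlo.  `exact_tail_probability` computes a single
tail without sorting the full support, which is what the simulation loops
use.

Special cases, used as test oracles: C = I gives T ~ Binomial(m, φ₀);
C = J gives T = X/m with X ~ Binomial(m, φ₀).

## Normal approximation

T_m ≈ Normal(μ = φ₀W, σ = √(φ₀(1−φ₀)Σw²ᵢ)).  No continuity correction is
applied: the support of T_m is an irregular set of subset sums, so no
well-defined half-step exists.  `method="auto"` uses the exact distribution
for m ≤ 20 and the normal approximation above (the threshold is exposed as
`exact_limit`).

Accuracy is quantified by the GMAE protocol: per random correlation matrix,
draw 1000 Bernoulli(φ₀) prediction vectors, evaluate |F_exact − F_normal|
at their statistic values, average, then average over matrices.  For
m ≤ `exact_limit` F_exact is the enumerated CDF; above it, the empirical
CDF of the sampled statistics.  Note the ECDF reference has a Monte-Carlo
noise floor of roughly 0.4/√1000 ≈ 0.012, so measured GMAE plateaus near
0.01 at φ₀ = 0.5 once the true approximation error falls below the floor;
comparisons across m therefore use a consistent reference (the monotone
decrease in GMAE is cleanest at φ₀ near the boundary, e.g. 0.9, where the
true error dominates the floor).

## Decision rule

Reject iff p ≤ α **and** T_m ≥ 1 (gate on by default, switchable).  The
gate requires at least one *effective* endpoint to be predicted correctly:
under perfect dependence (W = 1) every endpoint must be right, so correctly
predicting monotone copies of one endpoint cannot produce a rejection.
Feasibility: rejection at level α is possible at all only when φ₀^m ≤ α
(only the all-correct record can be the most extreme); `minimum_required_m`
implements exactly this rule, giving m = 5, 6, 9, 14, 29 for
φ₀ = 0.5, 0.6, 0.7, 0.8, 0.9 at α = 0.05.

## O'Brien OLS comparator

T_OLS = Σ t_k / √(1ᵀR̂1), with pooled-variance two-sample t statistics (or
one-sample t on paired differences), R̂ the same correlation matrix used for
the weights (pooled within-group, each group de-meaned), and a one-sided
upper-tail p-value from t(df), df = N − 2 (two-group) or n − 1 (paired).
The df choice is configurable because the small-sample reference for this
statistic is known to be approximate; pooled-variance t matches the
equal-variance multivariate-normal simulation design.  The statistic is
invariant to per-endpoint location/scale changes and is powerful only for
equidirectional effects: under balanced ±δ effects Σt_k is mean-zero, so
its rejection rate stays near α.

## Random correlation matrices

`random_correlation` implements the C-vine construction: partial
correlations on tree level k drawn as 2·Beta(b_k, b_k) − 1 with
b_k = α_d + (m − 1 − k)/2, composed recursively into full correlations.
α_d = 1 (LKJ η = 1) makes the draw uniform over the space of
positive-definite correlation matrices — the reference ensemble for every
simulation study.  Correlation matrices are generated directly (no
covariance intermediate: under this ensemble the distribution on
correlations is the stated uniform one).  In dimension 2 the off-diagonal
is Uniform(−1, 1), checked by a KS test; positive definiteness is
guaranteed by construction.

## Synthetic data generator

`make_dataset` draws multivariate normal data with unit variances, so the
per-endpoint mean shifts δ are standardized effect sizes: group 1 ~
MVN(0, C) and group 2 ~ MVN(δ, C) with n per group, or n paired difference
vectors ~ MVN(δ, C).  Effect patterns: `const` (δ on all endpoints),
`bidirectional-const` (first ⌊m/2⌋ negated), `stagger` (δ·k/m for endpoint
k = 1..m), `bidirectional-stagger` (stagger with the smallest half
negated), `spike` (1.0 SD on endpoint 1, 0.1 SD elsewhere), `null`.
Defaults follow the simulation designs the test was characterised under:
δ base 0.5 SD, n ∈ {3, 10, 20, 50} per group, m ∈ {6, 16, 26, 50}.

What the generator does *not* emulate: non-normal marginals, unequal group
variances, missing data, or structured (block/AR) correlation families.
Passing simulation tests therefore demonstrate the operating
characteristics under the idealised multivariate-normal, equal-variance
conditions, not robustness to their violation.

## Simulated predictions

The per-endpoint prediction equals the true sign of δ_k with probability
φ (independently per endpoint; a +1 reference is used where δ_k = 0), and
is scored as correct only when the observed sample effect also falls on the
true side of zero.  A wrong-direction prediction never receives credit,
even if sampling error happens to push the observed effect to its side.
This conjunction is what ties the *realised* per-endpoint success rate to
both φ and the traditional effect size: with small δ and small n the
observed sign confirms the truth with probability only slightly above 1/2,
so the realised success rate φ·P(sign confirmed) drops below φ — which is
why the test runs conservative (type-I error well below α) for small
effects and approaches the nominal level only as δ√n grows, and why the
type-I error decreases with m.  A symmetric scoring rule (credit whenever
prediction matches the observed sign, however both got there) would instead
pin the success rate at exactly 0.5 whenever φ = 0.5, making the type-I
error flat in (δ, n, m) — inconsistent with the operating characteristics
the test is documented to have.

Weights in every simulated test come from the *sample* correlation matrix
of the simulated data (pooled within-group), as they would in practice.

## Monte-Carlo design, seeds and scales

One master seed spawns an independent child stream per (matrix, replicate)
via `numpy.random.SeedSequence`, so any cell is reproducible in isolation.
`SimResult.mc_se` is the binomial standard error √(r(1−r)/N) over all
replicates; `cluster_se` (between-matrix) is also provided since replicates
share matrices.

Default scales are chosen so each study cell runs in seconds on one CPU:
20 correlation matrices × 100 replicates for power/type-I cells (N = 2000),
25 × 20 for sensitivity cells (N = 500), and 10–20 matrices × 1000
prediction sets for GMAE.  Full-scale runs (50 × 100 per cell, 100 × 1000
for GMAE) are a config change away; stochastic checks compare within three
combined Monte-Carlo standard errors, treating published table entries as
Monte-Carlo estimates at 50 × 100 themselves.

## Sensitivity of conclusions to sample weights

Per replicate: draw a true matrix from the uniform ensemble, estimate a
sample correlation matrix from n = 20 MVN observations, draw Bernoulli(φ)
outcomes, and run the test with both weight sets (exact for m ≤ 20, normal
above); record whether the reject/fail decisions agree.  Agreement is
averaged uniformly over the (m, φ) grid.  Cells where φ₀ renders rejection
infeasible (e.g. m = 5 at φ₀ = 0.7) agree trivially and are excluded from
grids meant to measure disagreement.

## Known limitations

- Weights from small-sample correlations are noisy; the sensitivity study
  bounds the practical impact (~98% decision agreement at n = 20) but a
  pre-specified or historical correlation matrix is the safer choice when
  available.
- Constant φ across endpoints is assumed; endpoint-specific predictive
  ability (a weighted Poisson-binomial null) is out of scope.
- Predictions are strictly one-sided; "change / no-change" predictions are
  out of scope.
- The exact method is limited to m ≤ 25 by enumeration; above that only
  the normal approximation is provided.
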