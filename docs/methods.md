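# Methods

`vapegeo` implements a small-area estimation and spatial-correlation
workflow for nicotine-use prevalence across Canadian-style census
divisions, together with a synthetic study generator that stands in for
the restricted survey microdata such analyses normally require.  This
note records the statistical model, the generator's design, the
numerical choices, and the limits of what the test suite can show.

## The estimation model

For respondent *i* in division *j*, the binary past-month outcome
(ENDS/vaping use, or smoking) follows a random-intercepts multilevel
logistic model

    logit P(y_ij = 1) = β₀ + x_ij'β₁ + u_0j,      u_0j ~ N(0, σ²_u0)

with fixed effects for age band (three ordinal levels), sex/gender
(binary) and data source (survey product × year), and a division-level
Gaussian random intercept capturing between-community heterogeneity on
the log-odds scale.  The intercept β₀ is the log-odds at the joint
reference cell: youngest age band, female, alphabetically first source.

**Survey weights.**  Pooled surveys carry incompatible weights, so the
package rescales them per division before fitting.  Method "A"
(cluster-size scaling) makes weights sum to the division's respondent
count n_j; method "B" rescales to the effective sample size
(Σw)²/Σw².  Scaled weights enter the fit as frequency-style weights in
a pseudo-likelihood.  Method A is the default and is idempotent.  Note
that unequal weights add design-effect variance between divisions
beyond binomial noise; with the default log-normal weights
(sd(log w) = 0.5) this inflates σ̂²_u0 by roughly the design effect
divided by the per-division information.  The weighted fit remains the
default because the descriptive target is the weighted population
rate; the unweighted fit is available via `use_weights=False`.

**Numerical integration.**  The marginal likelihood integrates u_0j out
per division.  The default is a Laplace approximation (posterior mode
by per-division Newton iterations, vectorized across divisions, with a
step clip at ±10 and convergence at 1e-10 on the step); adaptive
Gauss–Hermite quadrature centred on the mode is available
(`method="agq"`, `n_quad` nodes) and is used internally with 40 nodes
for posterior means and variances.  Optimization is L-BFGS-B over
(β, σ_u) with σ_u bounded in [0, 5], start values from an ordinary
weighted logistic GLM and σ_u = 0.3, tolerance 1e-9 on the relative
objective change, at most 200 iterations.  Non-convergence is flagged
on the results object and warned about.  A variance estimate at the
zero boundary (σ̂_u < 1e-4) is reported as exactly 0 with a boundary
flag, never negative.  The fixed-effect covariance is a numeric
observed-information matrix (central differences of the approximate
log-likelihood), computed lazily because it is only needed for
intervals.

## Precision-weighted shrinkage

The raw division residual r_j on the logit scale is attenuated by the
precision weight

    û_0j = r_j · σ²_u0 / (σ²_u0 + σ²_e0 / n_j)

so sparsely sampled divisions are pulled hardest toward the grand
mean.  Two conventions needed fixing because the source method names
only "a community-specific residual":

- r_j is **defined** as the empirical-Bayes posterior mean of u_0j
  divided by its own shrinkage factor.  Both r_j and the posterior mode
  are exposed on the results object.  This makes the shrinkage identity
  exact: applying the factor to r_j reproduces the posterior mean, and
  tests assert agreement with direct numerical integration to 1e-8.
- σ²_e0 defaults to π²/3 ≈ 3.29, the level-1 variance of the latent
  logistic scale, since a logistic model has no free residual variance.
  It is configurable.

n_j is the respondent count (under method-A scaling this equals the
within-division weight sum).  The factor is 0 when n_j = 0 or
σ²_u0 = 0, tends to 1 as n_j → ∞, and is monotone in both n_j and
σ²_u0.

**Standardized prevalence.**  Division prevalence is the
profile-averaged inverse logit,
prevalence_j = Σ_cells π(cell) · expit(x_cell'β̂ + û_0j).  The default
reference profile is the pooled weighted empirical joint distribution
of age × sex with the source fixed at the reference survey-year — the
target population the paper-style "age/sex-adjusted, source-adjusted"
rate refers to is not stated anywhere, so the pooled mix is the
package's choice.  Intervals come from 1000 parametric draws: β from
its estimated multivariate normal sampling distribution and u_0j from
its empirical-Bayes posterior normal, percentile 2.5/97.5.  The draws
condition on σ̂²_u0 (no variance-component uncertainty), a deliberate
simplification.

## Spatial statistics

Spatial weights are row-standardized k-nearest-neighbour matrices on
planar centroid coordinates (w_ii = 0, weight 1/k per neighbour,
asymmetry allowed; distance ties broken lexicographically by division
id for reproducibility).  Geographic inputs must be projected to planar
coordinates before use.

Global Moran's i uses the standard cross-product form; significance is
by Monte Carlo permutation with the pseudo-p rule
p = (1 + #{permuted ≥ observed}) / (n_sims + 1), upper tail by default
(positive clustering), with lower and two-sided tails available.  The
neighbourhood scale is selected by trials: Moran's i of the estimated
vaping surface is evaluated for candidate k ∈ {1,…,8} (a user-supplied
adjacency replaces the trials) and the argmax specification is kept,
with the full trial table exported.  Tie goes to the earlier candidate.

Lee's L couples Pearson correlation with the spatial autocorrelation of
both variables:

    L_XY = Σ_i [(Σ_j w_ij (x_j − x̄)) · (Σ_j w_ij (y_j − ȳ))]
           / (√Σ_i (x_i − x̄)² · √Σ_i (y_i − ȳ)²).

Under identity weights it is exactly Pearson's r.  Inference permutes
the (x_i, y_i) **pairs** jointly over locations, preserving the
aspatial x–y correlation and testing only the spatial component; the
two-sided pseudo p applies the (1+count)/(n_perm+1) rule to
|L − mean(L_perm)|.  An analytic null was deliberately not used: the
permutation approach matches the Monte Carlo treatment of Moran's i and
makes no distributional assumption.  The covariate sweep reports raw
permutation p as primary with Benjamini–Hochberg-adjusted values
alongside; covariates are z-scored before the statistic (cosmetic — L
is scale-invariant).  Divisions that are suppressed or missing a
covariate are excluded listwise per pair, and the weights matrix is
subset and re-row-standardized to the divisions actually used.

## The synthetic world

The generator emulates the statistical structure of a pooled
multi-survey small-area study with known ground truth.  Defaults encode
the reference design:

| parameter | default | meaning |
|---|---|---|
| n_divisions / n_provinces | 293 / 10 | divisions nested in contiguous province strips on the unit square |
| median_respondents | 304 | median division sample size |
| size_dispersion | 0.7 | sd of log division sizes (log-normal around the median; IQR ≈ 190–490) |
| beta0_ends / beta0_smoke | logit(0.04) / logit(0.12) | baseline log-odds at the reference cell |
| beta_age | (0, −0.6, −1.4) | vaping concentrated in the youngest band |
| beta_sex | 0.35 | male vs female |
| sources | 12 survey×year labels | offsets rise over the study window, expressed relative to the reference source |
| sigma_u_true | 0.3 | sd of the division random effect (logit scale) |
| spatial_range | 0.15 | exponential correlation length of the u surface |
| covariate_effects | {ice: 0.1} | planted association, covariate units per logit |
| weight_dispersion | 0.5 | sd of log survey weights, mean 1, outcome-independent |

The latent surface u is a zero-mean Gaussian field over centroids with
exponential kernel exp(−d/range) — the simplest field with a single
range parameter; range 0 gives i.i.d. effects.  Division sizes are
log-normal because only the median of the real design is public; the
dispersion 0.7 is a one-time realism choice (heavy right tail, a few
metropolitan-size divisions), not a fitted value.  Respondent
covariates are drawn independently of division (three age bands, binary
sex, sources at shares proportional to the real survey sizes), weights
are log-normal with mean 1 independent of the outcome (no weight model
is published), and both outcomes are Bernoulli draws from the linear
predictor sharing one latent field with outcome-specific intercepts.
Area covariates are a_c + b_c·u_j + noise, clipped to natural ranges
(percentages to [0,100], ICE to [−1,1], incomes positive).

What the generator does **not** emulate: postal-code geocoding error,
non-response and frame exclusions, multi-stage sampling designs,
distinct latent surfaces for smoking vs vaping (they share one field,
so their synthetic spatial correlation is high by construction), or
realistic polygon geometries.  Passing recovery tests therefore shows
the estimator chain is correct under its own assumptions, not that the
real surveys satisfy them.

## Privacy suppression

Divisions with n_j below a configurable threshold (default 10; the
obligation is named in the source setting but the threshold is not) are
either flagged and withheld, or merged into their nearest neighbour by
centroid distance — smallest division first, ties by id, iterating
until all remaining divisions meet the threshold.  A merged estimate is
the count-weighted mean of the pooled members, recorded under the
absorbing division, and every step is logged to the run manifest.
Suppression never alters surviving divisions' estimates.

## Determinism and problem sizes

Every random draw descends from one master seed through named
`SeedSequence` streams (generation, interval draws, weight trials,
correlation sweep), so two runs of the pipeline with the same
configuration produce byte-identical outputs; spatial weights
serialize float values as hex for bit-exact round-trips.  The test
suite verifies parameter recovery and shrinkage dominance on 50
independent replicates of the full reference design (293 × ~304), null
calibration of both permutation tests on 500 replicates of 60 divisions
at 199 permutations, and brute-force agreement of the spatial
statistics on thousands of small random instances.  The
boundary-recovery check (σ_u = 0) uses 165 divisions × ~304 respondents
(n ≈ 50,000) with equal weights and a moderate-prevalence outcome so
the Monte Carlo noise floor of σ̂²_u0 sits well below the 0.01
acceptance line; the weight-scale selection check uses engineered
dipole-block geometries (blocks of four = two anticorrelated pairs
around a shared block value) for which k = 3 is the strict argmax of
expected Moran's i — a plain constant-value block of four makes
k ∈ {1,2,3} exact ties, so no scale could be "favoured".

## Known limitations

- The Laplace approximation biases variance components slightly for
  rare outcomes with small divisions; adaptive quadrature is available
  but slower, and posterior summaries always use 40-node quadrature.
- Weighted fits inherit the pseudo-likelihood's design-effect
  inflation of σ̂²_u0 described above.
- Interval coverage is approximate: draws condition on σ̂²_u0 and treat
  the empirical-Bayes posterior of u_0j as exact.
- Lee's L as defined (no finite-sample spatial normalization) can in
  principle exceed |1| for adversarial weight matrices with very
  unbalanced column sums; for k-NN weights this does not occur in
  practice and is property-tested on random instances.
- The merge strategy recomputes merged estimates as count-weighted
  means rather than refitting the multilevel model on pooled records.
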