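# Methods

`countysvi` implements a county-level suicide analysis pipeline: trend
statistics on a county-year panel, a gradient-boosted prediction model
of county suicide counts, Shapley-value feature attribution, and a
composite Suicide Vulnerability Index (SVI) built from directional
percentile ranks of the most important features. Real county mortality
data cannot be redistributed, so the package ships a documented
synthetic-panel generator whose planted structure lets every stage be
tested end to end.

## The county panel

The unit of analysis is the US county (5-digit FIPS code), observed
yearly over 2010–2019. Each record carries population, the annual
suicide count, and 17 county characteristics in three groups —
Demographics (total population in thousands, %Female, %White,
%AfricanAmerican, %OtherRaces, median age), Socio-economic (median
income in thousand $, %Poverty, %Unemployed, %SomeCollege, social
association rate per 10k, %SingleParentHouseholds, violent crime rate
per 100k) and Health (opioid dispensing rate per 100 persons,
%Uninsured, mentally unhealthy days per month, %ExcessiveDrinking).
Validation enforces the obvious physical constraints (percentages in
[0, 100], race shares summing to ≤ 100.5 to absorb published rounding,
positive population, non-negative integer counts) and reports *every*
violation, not just the first. Missing values are rejected, never
imputed. FIPS codes are kept as zero-padded strings throughout because
several states have leading zeros and integer keys silently corrupt
GeoJSON joins.

A note on cause-of-death coding: suicide counts in US mortality data
are conventionally identified by ICD-10 intentional self-harm codes.
Sources differ on whether the range is X60–X64 or the full X60–X84
block; the panel schema is agnostic (it stores counts, not causes), but
users assembling real panels should be aware the narrower range
undercounts.

## Synthetic panel generator

The generator (`countysvi.simulate`) draws, per county:

- population ~ LogNormal(μ=10.3, σ=1.3), clipped to [100, 10⁷] —
  median ≈ 30k persons with a heavy right tail, matching the order of
  magnitude and skew of real county populations;
- %Female ~ Normal(50.4, 2.2) truncated to [20, 60]; median age ~
  Normal(41, 5.4) truncated to [20, 65];
- race shares = 100 × Dirichlet(8, 1.5, 0.5), so shares always sum to
  100 exactly;
- the 11 socio-economic/health features from a single latent
  "deprivation" factor d ~ N(0,1): each feature is
  mean + scale·(±ρ·d + √(1−ρ²)·noise) clipped to a plausible range,
  with loading ρ = 0.6 by default (`latent_strength`). This induces
  the realistic collinearity of poverty, unemployment, crime, opioid
  dispensing, uninsurance etc. without modelling them separately.

Features are constant across years within a county (county
characteristics drift slowly relative to a decade of mortality counts).
The log suicide rate of county c in year t is

    log r_ct = log(base_rate) + Σ_f β_f z_cf + (t−t₀)·log(1+trend) + ε_c

with z_cf the within-panel z-score of feature f, ε_c ~ N(0, σ_eps) and
counts S_ct ~ Poisson(r_ct · P_c / 10⁵). Defaults: base_rate = 15 per
100k (the approximate national suicide rate), σ_eps = 0.05, trend = 0.
Planted effects: β = +0.20 for %White, +0.15 for MedianAge, −0.15 for
%Female, −0.20 for %AfricanAmerican; the 12 remaining non-population
features receive nuisance effects drawn once per seed from
U(−0.05, 0.05). Population carries no β: it acts only through the
Poisson exposure, which is precisely what makes total population the
dominant explanatory feature for raw counts without planting the effect
twice.

What the generator does **not** emulate: spatial autocorrelation,
year-to-year feature drift, count suppression in small counties,
reporting artefacts, and any real-data marginal beyond order of
magnitude. Passing recovery tests therefore show that the pipeline
recovers planted structure of realistic shape and strength — not that
it would recover the true effect structure of real mortality data.

## Trend statistics

Percent change per county is 100·(last − first)/first over the panel's
first and last year; counties with a zero first-year count have no
defined change and are excluded *and reported* (real mortality
registries suppress small counts, so the denominator is ambiguous
there). The threshold fractions `frac_ge[t]` count counties whose
change **strictly exceeds** t%; a county sitting exactly at the
threshold does not count. Average county rate is the mean over years of
the annual rate per 100,000 (mean of yearly rates, not a pooled ratio).
Rate maps use half-open shade bins [0,10), then width-5 steps, with an
open top bin ≥35 — only the two extreme anchors are conventional, the
interior widths are a configurable choice.

## Prediction stage

The design matrix has one row per county: features averaged over the
panel years, target = mean annual suicide count (a mean annual rate per
100k target is available as a config option). Evaluation protocol:

- 80:20 train/test split assigned by ranking a keyed blake2 hash of
  each FIPS code — deterministic, exact to one row, and invariant to
  row order;
- grid search over tree depth {2, 3, 5} × learning rate
  {0.05, 0.1, 0.3} × number of trees {200, 500, 1000}, scored by mean
  10-fold cross-validated R² on the training split only, ties broken
  toward fewer, then shallower, trees;
- final refit on the full training split; R² reported on train, CV and
  the held-out 20%.

The boosting objective is Poisson deviance (`count:poisson`), i.e. the
trees model the *log* of the expected count. This is the canonical loss
for count data with exposure, and it matters here: county counts span
four orders of magnitude, and with plain squared error the fit is
dominated by a handful of large counties — across the whole squared-
error grid the held-out R² plateaus near 0.94 on default panels, well
below the ~0.996 ceiling set by the irreducible rate noise, whereas the
log-link model reaches ≈ 0.986. On the log scale the planted signal is
exactly additive, which is also why shallow (depth-2) trees win the
grid. Squared error remains available via `ModelSpec.objective`.

Held-out R² on the raw count scale is a fragile statistic on
heavy-tailed targets: it is largely determined by how well the few
largest test counties happen to be bracketed by training counties, so
it fluctuates by a few points across seeds even with zero rate noise.
The reported train/CV/test triple makes this visible.

## Shapley attribution

Attribution uses the interventional (marginal) value function
v(S) = E_b[f(x_S, b_{∖S})] with the expectation over an explicit,
seeded background sample of design rows (100 by default). Two
independent implementations exist:

- `exact_shapley`: the classical formula by full subset enumeration
  (refuses > 20 features) — the validation oracle;
- the fast path: an exact per-tree traversal. For one (foreground,
  background) pair and one tree, a leaf is reached by coalition S iff
  every split on its path is satisfied by x (feature ∈ S) or by b
  (feature ∉ S); collecting the k distinct path features that must come
  from x and the m that must come from b, the leaf's Shapley
  contribution to each such feature has a closed form obtained by
  summing the coalition weights over the unconstrained features. The
  traversal prunes subtrees inconsistent with both rows, and the whole
  kernel is numba-compiled.

Both paths use the same value function, so they agree to numerical
precision (asserted at 10⁻⁶, observed ~10⁻¹⁴), and per-row efficiency
(base value + Σφ = prediction) holds by construction. With the Poisson
objective, attributions are on the model's margin (log-count) scale;
directions and rankings are unaffected by the monotone link.

Feature importance is the mean |φ| per feature; the effect direction is
the sign of the Pearson correlation between a feature's values and its
φ column — the one-number version of reading a SHAP beeswarm plot — and
is omitted when either side has zero variance. Dependence-plot data
(feature value, φ, colour feature) are exported unaggregated.

## The vulnerability index

For the top p = 5 features by mean |φ|, each county receives a
directional percentile score: values are oriented so that larger means
more vulnerable (reversed for negative-direction features), then ranked
with X = (rank − 1)/(N − 1), ties at their mean rank. This convention
makes a unique maximum score exactly 1.00 and a unique minimum exactly
0.00, consistent with how the published reference table prints
extremes; the exact tie rule in the original analysis is unknown, so it
is isolated behind one function. Percentiles are computed on the same
per-county decade-averaged features used for the design matrix.

Weights are the selected features' mean |φ| normalised to sum to one —
with X_i ∈ [0, 1] and convex weights, SVI = Σ W_i X_i is guaranteed to
land on the stated 0–1 scale, which is the reason for the sum-to-one
normalisation (the original weights were never published). Counties are
binned into five vulnerability classes [0,0.2) … [0.8,1], top bin
closed.

A ten-row reference table of published percentile scores and index
values ships with the package. Because the original W_i are unprinted,
`estimate_weights` recovers them by constrained least squares (W ≥ 0,
Σ W = 1, SLSQP from a uniform start); on the reference rows the fit
reproduces every printed index to two decimals with max residual
≈ 0.003, which supports the sum-to-one reading. The recovered weights
put ≈ 0.86 on total population.

## Reproducibility

Every stochastic step (panel generation, nuisance-effect draws, split
hashing, CV folds, background sampling) takes an explicit seed; the
pipeline writes a manifest of SHA-256 hashes over all artifacts, and
identical config + seed gives identical hashes. Problem sizes used by
the test suite: the headline fit runs at the full 3,140-county default;
sign/rank-recovery runs five replicates at 1,000 counties with the
grid point the full-scale search selects (depth 2, rate 0.3, 500
trees); oracle-equivalence runs on a depth-2, 3-feature model with 20
query rows and a 50-row background.

## Known limitations

- The generator's rate model is a log-linear stand-in; the original
  analysis has no generative model, so absolute magnitudes of
  importance scores are not comparable to real-data results.
- Held-out R² on counts depends on split luck in the population tail
  (see above); compare seeds before reading much into a single value.
- Attribution assumes feature independence in the background
  (interventional convention); correlated features (the deprivation
  block) share credit accordingly.
- Percentile scores are panel-relative: adding or removing counties
  changes every score.
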