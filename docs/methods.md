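# Methods

## Model and estimation

The response (sqrt-transformed light-saturated photosynthesis, or
log-transformed water-use efficiency) is modeled as a Gaussian linear mixed
model

    y = Xβ + Z_farm u_f + Z_plot u_p + Z_subplot u_s + ε,

with independent random intercepts at each nesting level and i.i.d.
residuals. The fixed part is the quadratic trait–environment–variety
surface described in the README: linear and quadratic terms for every
standardized trait and soil variable, all trait × soil products, a
treatment-coded variety factor interacting with every linear term and with
each trait × soil product, plus linear farm-level climate covariates.
Quadratic terms do not interact with variety and trait quadratics do not
interact with soils: that is the reading of the model family under which
the full design for 4 traits, 2 soils, 5 varieties and 2 covariates has
exactly 83 columns, and the term count formula
1 + (g−1) + 2p + 2q + c + pq + (p+q+pq)(g−1) is verified against
brute-force enumeration in the tests. Covariates enter linearly with no
interactions for the same reason.

Variance components are estimated by REML on the profiled criterion over
variance *ratios* γ_j = σ²_j/σ²_ε: β and σ²_ε have closed-form profiles, so
the optimizer works in 3 dimensions regardless of model size. Every
criterion evaluation uses the Woodbury identity on the stacked group
indicators, costing O(m³) in the number of group levels (189 here) rather
than O(n³). The optimizer is L-BFGS-B with the analytic envelope-theorem
gradient, bounds γ ∈ [0, 10⁶] and a deterministic start list
{0.1, 1.0, (1, ½, ¼)}; near-zero ratios are snapped to exactly zero when
that does not worsen the criterion by more than 1e-8. Bounded optimization
on the ratio scale (rather than a log parameterization) was chosen so that
boundary estimates γ = 0 are reachable exactly. The REML log-likelihood
follows the lme4 convention (no |X'X| term), making log-likelihoods and
AIC values directly comparable with that ecosystem; the test suite checks
agreement with lme4 to ~1e-4 on a nested fixture. AIC uses
k = k_fixed + k_random + 1 and, by default, the REML likelihood — matching
the convention of the tooling this pipeline mirrors — with the caveat that
comparing REML-AIC across different fixed-effect sets is heterodox; ML AIC
is available via `aic_likelihood: ml` (the ML profile is re-optimized, not
evaluated at the REML ratios).

## Small-sample inference

Kenward–Roger is implemented in its linear-covariance form: with
V = Σ θ_j Z_j Z_jᵀ + σ²_ε I all second derivatives of V vanish, so the
adjusted coefficient covariance is Φ_A = Φ + 2Φ[ΣΣ W_ij(Q_ij − P_iΦP_j)]Φ
with W the inverse expected REML information (½ tr(P G_i P G_j)), and the
F-test uses the scaled-F calibration of the original method. All trace
terms are reduced to group-level blocks — no n × n matrix is formed — which
is what makes the 5000-replicate calibration experiment feasible. The
implementation reproduces pbkrtest's adjusted covariance and F/ddf/p to
three significant digits on the test fixture, gives ddf = n − k exactly for
fixed-effects-only models, and the classical between-cluster df (7 for a
farm-level coefficient among 9 farms) on balanced split-plot designs.
Satterthwaite df (per-contrast, eigendecomposition for multi-df tests) are
available as a cheaper fallback and agree with Kenward–Roger to < 0.1 on
balanced designs. Degenerate fits with residual variance ~0 skip the
adjustment (there is no sampling variability to adjust for).

## Type-II tests and backward elimination

Type-II hypothesis matrices follow the classical (SAS-style) construction:
for term t, columns are ordered [terms not containing t | t | terms
containing t] and the rows of the unit-diagonal forward elimination
(Doolittle) of X'X belonging to t form L. In the OLS case this reproduces
the model-comparison definition SS(t | all terms not containing t) exactly,
and on balanced orthogonal designs type-II equals sequential sums of
squares — both are tested. (The R ecosystem is not internally consistent
here: lmerTest and car build different type-II hypotheses for lower-order
terms with continuous predictors; cross-validation against R is therefore
pinned to the maximal term, where all constructions coincide, plus the OLS
model-comparison oracle.) The reported Sum Sq / Mean Sq columns are
reconstructed as mean_sq = F·σ̂²_ε for layout parity with mixed-model ANOVA
printouts; the tests are the F/ddf/p columns.

Backward elimination repeatedly tests the *removable* terms (those not
contained in any term still in the model; the intercept never) by type-II F
and drops the least significant one while its p-value exceeds α = 0.05,
refitting after each drop; the random part is never selected over. Ties
are broken toward the higher-order term, then lexicographically, making the
path deterministic. The final model re-asserts that every removable term
is significant, and replaying a selection trace reproduces the final fit
bit for bit. No multiple-testing correction is applied (raw p-values at
α = 0.05, following the reporting convention of this analysis family).
Elimination defaults to Satterthwaite tests for speed, with
Kenward–Roger for the reported final ANOVA tables.

When two environmental predictors are collinear (Pearson |r| strictly
above 0.6 on the transformed, standardized scale — soil N and C in
practice), the pipeline fits one full model per alternative and keeps the
backward-selected model with the smaller AIC.

## Preprocessing

Gas-exchange triplicates are averaged per plant (plants with fewer than
three readings are averaged with a warning; plants with none are flagged
and removed only by the explicit missing-physiology step). WUE = A_sat/TR.
LMA = leaf dry mass / leaf area. Taproot volume uses the printed
truncated-cone form V = ⅓π·RL·(RD² + r² + RD·r) with tip size r = 0.05 cm;
RD is recorded in mm and converted to cm first. The formula uses the
diameter where a cone formula would use radii — it is evaluated verbatim,
with a `use_radius` switch that halves RD and a `cylinder` alternative for
sensitivity runs; TTD = dry mass / volume either way, and TTD is only ever
used on the log scale after standardization, where a constant factor
shifts the mean and leaves slopes untouched. Default transforms: log for
TTD, LMA, soil N/C/P and WUE; square root for LA, PD and A_sat; climate
covariates identity. Predictors are z-standardized (population SD) after
transformation; responses are transformed but *not* standardized, so
slopes read as transformed-response units per predictor SD. Outliers are
removed by |z| > 4 on transformed LA — a configurable default standing in
for an unspecified "extremely high" rule — computed globally, after which
the data are not re-standardized.

## Synthetic trials

The generator emulates a 9-farm × 5-variety × 3-subplot × 3-plant organic
on-farm trial (405 plants). Soil N and C are log-normal with farm- and
subplot-level variation (SDs 0.15/0.15 on the log scale) and correlation
0.8 at both levels; soil P is independent log-normal; temperature and
precipitation are uniform over 16.6–20.5 °C and 97.2–237.9 mm at farm
level. Traits vary at farm (SD 0.4), subplot (0.2) and plant (1.0) level
with mild plant-level correlations (max 0.45, all below the 0.6 screen),
placed on realistic raw scales (LA ~100–260 cm², LMA ~0.004 g cm⁻²,
PD ~4–8 mm, TTD ~0.14 g cm⁻³). Responses are drawn from the full term
graph: the default A_sat effects are a −0.105 TTD × soil-P slope with
variety-dependent soil-P slopes; the default WUE effects put the
PD–soil-N slope at −0.144 for the reference variety and +0.211 for OP2,
plus smaller two- and three-way structure. Default variance components are
(0.30, 0.12, 0.06, 0.25) for sqrt A_sat and (0.18, 0.07, 0.035, 0.035) for
log WUE — farm > plot > subplot, residual chosen so the conditional R²
lands near what multi-farm trials report. Five missing-physiology plants
and two extreme-LA outliers are injected by default so the attrition path
(405 → 398) is exercised end to end.

Raw measurements are generated consistently (leaf dry mass = LMA·LA,
taproot dry mass = TTD·volume, triplicates with zero-sum deviations), so on
complete tables the preprocessing path recovers the generative analysis
scale *exactly* — the tests assert agreement to 1e-15. What the generator
does not emulate: real soil distributions beyond plausible ranges, climate
time series, spatial farm structure, non-Gaussian measurement error, or
missingness that is informative rather than random. Passing recovery and
calibration tests therefore demonstrates correctness of the estimator and
selection machinery under the assumed model, not robustness to field
pathologies.

## Experiments behind the headline numbers

* Type-I calibration: 5000 simulated null trials of the full nested design,
  subplot-level covariate, KR F at α = 0.05; observed rejection rate must
  lie in [0.04, 0.06].
* Parameter recovery: 500 replicate trials (no attrition), full 83-column
  fit; 95% Wald CIs on the adjusted covariance with Satterthwaite df;
  mean coverage must lie in [0.93, 0.97] and variance-component relative
  bias below 10%.
* Selection retention: 200 seeded replicates with one true trait × soil
  effect and one true trait × soil × variety effect, both 0.3 SD, on a
  two-trait/one-soil term graph at the full design size (the reduced graph
  keeps the experiment's runtime proportionate without changing the
  procedure or the effect size); both true terms must survive in ≥ 90% of
  runs and free null terms be retained at roughly the test level
  (band [0.01, 0.10] around α = 0.05).
* R² decomposition: generative σ²_fixed = 1, σ²_random = 2, σ²_ε = 1 at
  n = 2000 recovers marginal/conditional R² of 0.25/0.75.

## Degenerate inputs and numerical choices

Zero-variance predictors, non-positive values under log, duplicate nested
keys, soil values varying within a subplot, rank-deficient designs (aliased
columns are named via pivoted QR) and broken variety specifications all
raise typed errors. Variance ratios below 1e-8 are treated as boundary
zeros. A correlation exactly at the collinearity threshold is not flagged
(strict inequality). The optimizer tolerance (1e-11 relative on the
criterion) comfortably exceeds the 1e-6 accuracy the brute-force grid
oracle demands.

## Known limitations

Only one categorical factor (variety) and polynomial degree ≤ 2 are
supported — the model family of this analysis, not a general formula
language. Random effects are nested intercepts only (no crossed effects,
random slopes or heteroscedastic residuals). Exact replication of a
backward-selection *path* across implementations is not guaranteed (ties,
df conventions); final-model refits are the stable cross-implementation
quantity. AIC comparisons across fixed-effect sets under REML inherit the
caveat noted above.
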