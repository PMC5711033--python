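# Methods

## Generative model

All analyses presume the linear single-instrument system

    x = β_g·g + ε_g            g ~ Binomial(2, maf), maf defaults to 0.5
    y = β_x·x + ε_x            (causal model)
    x_o = α_mx + β_mx·x + ε_mx,  ε_mx ~ N(0, σ²_mx)
    y_o = α_my + β_my·y + ε_my,  ε_my ~ N(0, σ²_my)

with intercepts ignored and all residuals independent normal.  Measurement
error is non-differential and split into a scale component (α_m, β_m) and an
imprecision component (σ²_m); only imprecision attenuates correlations.  The
non-causal variant replaces the `x → y` edge with a second direct path
`g → y`, so the traits are correlated purely through the shared instrument
and the population cor(x, y | g) is zero.

The simulator parameterises effects as population variances explained:
traits have unit variance, `β_g = sqrt(var_gx / var(g))`,
`β_x = sqrt(var_xy)`, and residual variances are solved in closed form
(1 − var_gx, 1 − var_xy).  This makes population quantities exact functions
of the configuration — in particular

    ρ_t,to = β_m / sqrt(β_m² + σ²_m)   (per trait)
    d      = ρ_x,xo − ρ_xy·ρ_y,yo

so each grid cell carries an exact d stratum, rather than one estimated by
rescaling.  The non-causal model sizes its direct path so that the marginal
instrument–outcome association matches the causal model with the same
configuration (cor(g,y)² = var_gx·var_xy), keeping the two models
comparable from the instrument's point of view.  The default experiment
grid is cor(g,x)² = 0.1; cor(x,y)² ∈ {0.2, 0.4, 0.6, 0.8};
σ²_mx, σ²_my ∈ {0, 0.2, …, 1}; n ∈ {100, 1000, 10000} — 432 cells, 100
replicates each by default.  Per-cell seeds are derived from the master seed
by hashing the cell's parameters, so enlarging a grid never changes the
random stream of existing cells.

What the generator does *not* emulate: linkage disequilibrium and dosage
uncertainty in the instrument, horizontal pleiotropy, non-genetic
confounding of x and y, binary traits, winner's curse in the discovery of
instruments, and correlated measurement errors between the traits.  Passing
tests therefore demonstrate behaviour under clean single-instrument linear
additivity, not robustness to those failure modes.

## Direction inference

**Correlation recovery.**  With summary statistics the instrument–trait
correlation magnitude is recovered from the p-value and sample size by
inverting the two-sided slope t-test: t = t⁻¹(1 − p/2; n − 2),
|r| = t/√(t² + n − 2).  This uses exactly the fields the typical summary
table provides and needs no allele frequencies; a beta/SE-based path is
deliberately out of scope.  Effect-allele harmonisation flips the sign of
the outcome beta when alleles differ; since the Steiger comparison uses
absolute correlations, harmonisation affects only reported effect signs.

**Steiger tests.**  One-sample data use the correlated-correlations Z

    Z = (z_gx − z_gy)·sqrt((N − 3) / (2(1 − ρ_xy)·h)),
    r_m² = (ρ_gx² + ρ_gy²)/2,  f = (1 − ρ_xy)/(2(1 − r_m²)),
    h = (1 − f·r_m²)/(1 − r_m²)

(the classic `r.test` formulation); two-sample data use
Z = (z_gx − z_gy)/√(1/(N₁−3) + 1/(N₂−3)).  Conventions: the two
instrument–trait correlations enter as absolute values, ρ_xy keeps its sign
(raw signs are preserved in reporting); p is two-sided from the standard
normal; direction is the sign of Z with Z = 0 mapped to "undetermined" (no
tie-break); a correlation triple whose h term is non-positive (not positive
definite) raises a degenerate-input error.  Multiple independent
instruments combine as r = √(Σ rᵢ²), with an error if they would jointly
explain more than 100% of variance.  A directional call requires both
p_Steiger < α and p_MR < α; α defaults to 0.05 for convenience, with the
usual caveat that fixed thresholds are a compilation convention, not an
inference principle.

**MR estimation.**  The Wald ratio β_out/β_exp uses the first-order delta
SE (se_out/|β_exp|) and a normal reference, the standard summary-data
convention.  2SLS is just-identified here, so the point estimate is exactly
cov(g,y)/cov(g,x); its SE is the IV sandwich form with residuals taken
against the observed exposure and a t reference on n − 2 df.  p_MR is
essentially invariant to swapping exposure and outcome with a shared
instrument, so computing it in the Steiger-inferred orientation cannot flip
calls.  Multi-instrument effect meta-analysis (IVW, MR-Egger, weighted
median) is out of scope; only correlation aggregation supports multiple
SNPs.

## The CIT reimplementation

Conditions 1–3 are F-tests (1 df, so t-tests) of the focal covariate in the
stated linear regressions; conditioning means inclusion as a covariate.
Condition 4 — SNP independent of outcome given exposure — is an equivalence
test estimated by simulation.  With F_obs the statistic for g in
`y ~ x + g`, null outcomes are constructed as

    y* = b̂_x·x + m·b̂_marg·g + perm(residuals of y ~ x + g)

where b̂_marg is the marginal SNP–outcome slope (the association that would
survive adjustment if the exposure were no mediator at all) and m the
equivalence margin.  p4 = (1 + #{F_null ≤ F_obs})/(n_null + 1) is small
when the observed residual association is credibly below the margin.  The
margin defaults to m = 1/3: a residual instrument–outcome effect below one
third of its no-mediation magnitude counts as mediated.  The value was set
by comparing population noncentralities: it must sit above the sampling
noise of a fully mediated model at the study's sample sizes (else power
collapses) and below the residual effect that exposure imprecision of
σ²_mx ≈ 1 leaves behind (else the test cannot register measurement-error
violations at all).  Larger margins make the CIT more permissive, smaller
ones more conservative; m is exposed as a parameter.  n_null defaults to
500 and the seed is recorded in the result.

Consequence of the margin construction worth knowing: under pure genetic
confounding (g affecting both traits directly) the unmediated path exceeds
the margin in *both* orientations, so the bidirectional CIT returns
"no evidence" rather than the both-significant/confounding code; the
confounding code still arises when both omnibus p-values fall below α for
other reasons.  No numerical agreement with other CIT implementations is
claimed anywhere — the behavioural contract (null calibration, power under
full mediation, degradation and direction-flipping under exposure
measurement error) is what the tests pin down.

## Measurement-error sensitivity analysis

Attenuation multiplies a true instrument–trait correlation by ρ_t,to, so a
hypothesised error pair (ρ_x,xo, ρ_y,yo) implies corrected correlations
robs/ρ.  Admissible values are bounded below by the observed correlations
themselves (a corrected correlation cannot exceed 1): ρ_x,xo ∈ [ρ_g,xo, 1]
and likewise for y.  `predicted_surface` reports the corrected ρ_gy − ρ_gx
for a single user-supplied error pair (a revised inference for a scenario
the user believes in).

`reliability_R` integrates over the whole admissible rectangle, treating
every admissible error value as equally likely (a user-supplied weighting
hook exists but defaults to uniform).  The integrand is the difference in
corrected variance explained, z = (ρ_gy,o/ρ_y,yo)² − (ρ_gx,o/ρ_x,xo)², and
the two volumes are the sums of |z| over the grid cells where the sign
supports, respectively opposes, the empirically inferred direction.  R is
reported in the fixed x → y orientation (favouring volume over opposing
volume), so swapping the observed correlations yields the reciprocal ratio;
callers conventionally pass the inferred exposure as x, making
R = vol_support/vol_oppose.  Numerical conventions, chosen for determinism
and reproducibility of the published worked value: an endpoint-inclusive
uniform grid with 500 points per axis by default (the value drifts by a few
percent with resolution because the surface is steep along the lower edges;
the default is part of the method's definition), no seeds needed; exact
z = 0 cells contribute nothing to either volume; a zero opposing volume is
reported as R = +∞ with a flag rather than an error.  For the worked case
ρ_gx² = 0.01, ρ_xy² = 0.1 the default settings give R = 4.40.

The analytic bias operations are straightforward algebra on the model:
`attenuation_D` (D ∈ (0, 1], D = 1 iff no imprecision — scale changes alone
never bias), `residual_cov_bias` (= β_my·β_g·β_x·var(g)·(1 − D), the
quantity that violates the mediation condition), and `d_statistic` with the
interpretation that d > 0 marks the reliable region for the Steiger
comparison.  The analytic confounding-region surface is not implemented;
confounding sensitivity is addressed only through the non-causal simulation
model.

## Numerical and degenerate-input conventions

Zero-variance vectors, |r_xy| = 1, zero first-stage slopes, collinear CIT
covariates and identical exposure/outcome vectors raise typed errors rather
than propagating NaNs.  p-values are floored at the smallest positive
float to keep downstream log/max operations defined.  Tables are written
with 10 significant digits; round-tripping reproduces fields at that
precision.  Genotypes are additive 0/1/2 with no dosage support.

## Problem sizes in the test suite

The suite runs the simulations at reduced scale chosen to keep the full run
around a minute while leaving comfortable Monte-Carlo slack: calibration
checks use 400–500 replicates at n = 300–1000; power and monotonicity
checks use 15–50 replicates at n = 10⁴ with 150–200 permutation nulls; the
largest single draws (oracle checks of population formulas) use n = 10⁵–10⁶
once.  The acceptance script uses the full 500 replicates at n = 1000 with
the default 500 permutation nulls where those quantities are defined.
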