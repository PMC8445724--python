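# Methods

## Model and estimators

The model is the canonical-link Poisson GLM: independent counts
yᵢ ~ Poisson(μᵢ), μᵢ = exp(xᵢ′β), fitted by Fisher scoring / IRLS with
weights Ŵ = diag(μ̂) and working response ẑᵢ = log μ̂ᵢ + (yᵢ − μ̂ᵢ)/μ̂ᵢ.
IRLS starts at μ̂⁽⁰⁾ = y + 0.5 (guards log 0), iterates to a tolerance of
1e-8 on the maximum coefficient change with at most 50 iterations, and
reports non-convergence as a flag (`converged_ = False`) carrying the last
iterate rather than an exception. A singular X′ŴX on the first scoring
step raises a rank-deficiency error; a singularity that develops later
(one observation's weight overwhelming the cross-product) is reported as
divergence. The log-likelihood is monitored across iterations and a
warning is emitted if it decreases.

The Liu estimator is a one-shot shrinkage of the converged ML solution,

    β̂_d = (X′ŴX + I)⁻¹ (X′ŴX + d·I) β̂_ML,   d ∈ [0, 1],

with Ŵ frozen at the ML fit (no re-iteration). In the eigenbasis
X′ŴX = QΛQ′ each rotated coefficient αⱼ = (Q′β̂)ⱼ is multiplied by
(λⱼ + d)/(λⱼ + 1). The selection rules are

    d̂₁ = max(0, minⱼ (αⱼ² − 1)/(1/λⱼ + αⱼ²)),
    d̂₂ = max(0, minⱼ (αⱼ² − 1)/(1/λⱼ + α²_max)),

both additionally capped at 1 because the estimator is defined on [0, 1].
Shrinkage applies to the full coefficient vector including the intercept
(`shrink_intercept=False` restricts it to the slopes). By default the
shrinkage operates on the raw design scale; note that unlike ML, the Liu
estimator is *not* invariant to rescaling the columns of X, so the choice
of scale is part of the model specification.

## Influence diagnostics

Both estimators get the same four statistics, with p counting regressors
excluding the intercept and q = p + 1 fitted coefficients:

- Cook's distance, Cᵢ = χᵢ′² hᵢᵢ / (q (1 − hᵢᵢ)); the quadratic form
  Δβ′(X′ŴX)Δβ/q at the one-step Δβ is algebraically identical and is
  cross-checked at run time (on rows with h < 0.99; the identity is
  numerically meaningless at h ≈ 1). Cutoff 4/(n − 1).
- Change in Pearson χ²: Δχᵢ² = χᵢ²/(1 − hᵢᵢ). Cutoff 3.84 (the 5 %
  χ²₁ critical value).
- Change in deviance: Δdᵢ² = dᵢ² + χᵢ² hᵢᵢ/(1 − hᵢᵢ) (default), with the
  simplified variant dᵢ²/(1 − hᵢᵢ) behind `variant="simplified"`.
  Cutoff 3.84.
- DFFITS, default jackknife form tᵢ √(hᵢᵢ/(1 − hᵢᵢ)) with
  tᵢ = χᵢ′ √((n − q)/(n − q + 1 − χᵢ′²)); cutoff 2√(q/n) on |DFFITS|.
  A second form, `fitted_change`, evaluates the fitted-value-difference
  definition Ŵᵢᵢ xᵢ′Δβ̂(i)/√hᵢᵢ at the one-step displacement. The two
  differ by a factor ≈ √Ŵᵢᵢ and by the jackknife rescaling; the
  fitted-change form is the variant whose flag set matches the published
  football analysis, and both are exposed.

Pearson residuals use the √μ̂ denominator (the form whose squares sum to
the Pearson statistic); the raw ratio (y − μ̂)/μ̂ is available as a
separate accessor. Deviance residuals use the y log(y/μ̂) → 0 convention
at y = 0. An observation with leverage 1, or a jackknife radicand ≤ 0,
yields an infinite statistic (always flagged) rather than an exception.

Liu-side specifics: the Liu hat matrix is implemented in the symmetric
sandwich order H_d = Ŵ^{1/2}X (X′ŴX+I)⁻¹(X′ŴX+dI)(X′ŴX)⁻¹ X′Ŵ^{1/2},
which reduces to the ML hat matrix at d = 1 and satisfies
trace(H_d) = Σ(λⱼ+d)/(λⱼ+1) and h_dᵢᵢ ≤ hᵢᵢ for d ≤ 1. (The eigen form
shows h_d *increases* toward h as d → 1; only the bound h_d ≤ h is
asserted.) The deletion formula uses the distinct ridge-type leverage
m_di = kᵢ(K′K+I)⁻¹kᵢ′, K = Ŵ^{1/2}X, with 0 ≤ m_di < m_i = hᵢᵢ < 1; both
quantities are exposed. The one-step displacement is

    β̂_d − β̂_d(i) = (X′ŴX + I)⁻¹ xᵢ Ŵᵢᵢ^{1/2} χ_di / (1 − m_di),

with d held at its full-data value (re-selection after deletion is
available only in the exact-refit reporting mode). Because the
displacement keeps its (X′ŴX+I)⁻¹ prefactor and (1 − m_di) denominator,
the Liu Cook's distance at d = 1 tracks the ML Cook's distance closely
(within ~20 % on typical fits) but is not an exact identity; the
leverage-based statistics (Δχ², Δd², DFFITS) do reduce exactly at d = 1.
Liu Cook's distance defaults to the plain metric Δβ′(X′ŴX)Δβ/q; a
sandwich-metric form is exposed alongside.

## Condition index

`condition_index` computes √(λ_max/λ_min) of a cross-product matrix under
four conventions: `correlation` (regressor correlation matrix — the
textbook default), `raw` (X′X with intercept), `weighted` (X′ŴX with
intercept), and `correlation_full` (correlation matrix of the response
together with the regressors). On the football data these give 13.64,
2121.3, 2181.1 and 31.363 respectively; the published value for this
dataset (31.274) is matched, to 0.3 %, only by the full-table correlation
convention, which the acceptance checks therefore pin and which should be
read as "eigen-analysis of the whole data table" rather than of the
design alone.

## The football fixture

The bundled CSV reproduces the published 20 × 6 table verbatim. Its two
goal columns are goals conceded and goal difference (the latter is
negative for most clubs); the regression design analysed alongside the
table uses goals scored and goals conceded, recovered as
scored = conceded + difference. This derivation is pinned by the
post-deletion coefficient-change table, which the derived design
reproduces exactly (to the printed decimal) for all three deletion sets
under exact refits, while the verbatim columns do not. Percentage changes
are 100·|β̂_full − β̂_del|/|β̂_full|; a warning is raised when a full-data
coefficient is near zero, since the percentage is then dominated by the
denominator (the yellow-card coefficient, ≈ −6e-5, is why its deletion
impact is ≈ 3945 %).

On this fit both d-rules select d = 0: only one rotated coefficient
exceeds 1 in absolute value, so the minimum criterion is negative and the
floor at 0 binds. Because the raw-scale eigenvalues of X′ŴX are large
(≈ 0.9 to 3×10⁶), (X′ŴX+I)⁻¹(X′ŴX) ≈ I and the d = 0 Liu fit is nearly
identical to ML; the Liu flag sets published for this dataset (which
differ sharply from the ML ones) could not be reproduced under any
combination of d ∈ [0,1], residual/leverage/weight conventions, or
regressor standardisations that we explored, and the corresponding
checks are left failing rather than tuned.

## Simulation design

One cell of the detection study is parameterised by (n, p, ρ², d-rule)
with defaults n = 25, p = 2, ρ² = 0.75, 1000 replications. Regressors are
x_ij = √(1−ρ²) z_ij + ρ z_{i,p+1} with z i.i.d. standard normal, giving
pairwise population correlation ρ². Slopes default to βⱼ = 1/√p (the
simplest solution of Σβⱼ² = 1) with zero intercept; both are
overridable. Contamination adds (column mean + 6) to every entry of row
15 *before* the response is drawn, so the planted row is generative: its
count is consistent with its own outlying predictor. Detection means the
planted row exceeds the measure's cutoff; an infinite DFFITS (jackknife
radicand failure) counts as detection. Replications whose IRLS fit fails
are discarded and reported in `n_failed_fits` (they are rare — at most a
few per thousand in the extreme n = 200, ρ² = 0.99 cell). Each
replication runs on its own child RNG stream spawned from the master
seed, so results are exactly reproducible and cells are independent.

Under this design the planted row is a ~6-SD leverage point whose count
matches its own mean, so leverage-driven measures (Cook, DFFITS) detect
it nearly always (97–99.5 % across the cells we report) while
residual-driven measures (Δχ², Δd²) stay near the 5 % test size. The
reference study reports intermediate rates (e.g. Cook ≈ 79 % at n = 25
with Δχ² ≈ 47 %) that neither this generative scheme nor a
leverage-only variant (contaminating X after y is drawn) reproduces at
any shift magnitude we scanned; the spread between its leverage- and
residual-driven columns is not attainable from the stated design, and we
keep the stated design rather than tune it. What the simulation *does*
show robustly: the Liu diagnostics with d̂₁ detect the planted row
essentially as often as their ML counterparts, detection does not degrade
with collinearity up to ρ² = 0.99, and the per-cell equalities
(Δχ² ≈ Δd², Cook ≈ DFFITS within each estimator) mirror the reference
tables' internal structure.

What the generator does not emulate: real over-dispersion, zero
inflation, multiple simultaneous outliers, response-side contamination,
or masking/swamping effects between influential points — passing
detection rates here say nothing about those regimes.

## Numerical choices

- Linear predictors beyond ±500 are treated as divergence during IRLS
  (exp is meaningless there in double precision); the simulator
  additionally caps the *true* predictor at 30 when drawing counts, since
  Poisson draws beyond e³⁰ are not representable meaningfully.
- Leverages are clipped to [0, 1] against roundoff before use.
- Statistics at exactly zero residual are returned as exact zeros,
  short-circuiting 0·∞ artefacts at h = 1.
- Eigen-decompositions use symmetric solvers (`eigh`); the Liu transform
  is computed in the eigenbasis and verified against dense solves in the
  tests.
- All cutoffs live in one place (`default_cutoffs`) with p = number of
  regressors excluding intercept; the jackknife residual uses q = p + 1
  fitted coefficients in both numerator conventions, making the ML and
  Liu versions consistent.

## Problem sizes

The test suite runs the two reported simulation cells at the full 1000
replications (≈ 10 s together) and keeps every oracle comparison on
problems of n ≤ 60, so the whole suite completes in well under a minute;
the acceptance script repeats the two cells at 1000 replications.

## Known limitations

- One-step displacements are first-order: they are exact for the frozen
  weighted least-squares subproblem but only approximate the full refit;
  on benign data the per-coefficient correlation with exact refits
  exceeds 0.99 (tested), but for gross outliers the one-step
  understates the change.
- The Liu Cook's distance does not reduce exactly to the ML Cook's
  distance at d = 1 (see above); treat cross-estimator comparisons of
  Cook values as approximate.
- No offsets, exposures, over-dispersion models, non-canonical links,
  ridge/Lasso/two-parameter estimators, or formula interface.
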