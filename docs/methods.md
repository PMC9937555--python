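# Methods

## Model and hypotheses

All methods assume complete-case data on N subjects with d ≥ 2
approximately continuous items X₁,…,X_d and one discrete grouping
variable Z with levels 1..p (reference level 1).  The reflective factor
model for standardized items is

    Xᵢ = λᵢ η + εᵢ,   η ~ N(0,1),  E εᵢ = 0,  Var(Xᵢ) = 1,

with reliabilities λᵢ ∈ (0,1).  The *structural* null hypothesis under
test is that Z is independent of (X₁,…,X_d) given η.  Its observable
consequence is that the contrast vector Δ_z = (E(Xᵢ|Z=z) − E(Xᵢ|Z=1))ᵢ is
proportional to (λ₁,…,λ_d) for every z — equivalently, the (p−1)×d
contrast matrix has rank one.  Nothing causal needs to be assumed about
Z: the restriction must hold for treatments, outcomes, and even
confounded or causally unrelated variables, which is what makes the tests
widely applicable.

Both tests are distance-metric GMM statistics: with per-subject moment
vectors U_k(θ) of dimension m, mean Ū(θ), and Σ the empirical covariance
of U_k, the statistic is min_θ N·Ū(θ)ᵀΣ⁻¹Ū(θ), referred to χ² with
m − q degrees of freedom (q = number of identified nuisance parameters).
Σ is evaluated once, at initial consistent estimates, and held fixed
(one-step GMM); the asymptotics do not prescribe the finite-sample
weighting point, and the one-step choice keeps the minimization a
fixed-weight quadratic problem.

## Reliability estimation

Independent errors imply Cov(Xᵢ,Xⱼ) = λᵢλⱼ for i ≠ j.  The estimator
solves the d weighted estimating equations

    Σ_{j≠i} λⱼ (C_ij − λᵢλⱼ) = 0,    C_ij the divisor-N sample covariance,

by damped Newton iteration in log λ (positivity enforced by the
parameterization; max 200 iterations, residual tolerance 1e−10).  The
system has spurious roots far from the rank-1 cone, so the iteration is
initialized at the median of the Spearman-type closed forms
√(C_si C_sj / C_ij) over pairs (i,j) — exact at rank-1 input, robust
otherwise.  For d = 3 the closed form is itself the unique positive
solution.

An equivalent "quasi-poisson"-tagged solver fits the working model
log E(C_ij) = Λᵢ + Λⱼ to the d(d−1)-vector of covariances (both
orderings, no intercept) by log-link quasi-likelihood with
**homoscedastic** working variance, and exponentiates.  With constant
working variance the quasi-score for Λ_s is exactly the weighted
equation above, so the two solvers agree to solver precision on any
admissible covariance set (the suite checks 1e−6 over random instances).
A variance-proportional-to-mean working model would instead produce the
unweighted equations Σ_{j≠i}(C_ij − λᵢλⱼ) = 0, which coincide only at
exactly rank-1 C; this is why the homoscedastic variance is essential,
and why the dispersion parameter is irrelevant to the point estimates.
All pairwise covariances must be positive; `auto_reverse_code` greedily
flips item signs (flip the item whose mean covariance with the rest is
most negative, repeat) to achieve this, warning when positivity is
unattainable.

## T0: reliability-dependent test

Moments, for z = 1..p and i = 1..d (m = pd):

    U_k[(z,i)] = I(Z_k = z) · (X_ik − γᵢ − (λᵢ/λ_ref) β_z),   β₁ = 0,

with q = d + p − 1 parameters (γ, β), giving df = (d−1)(p−1).  The
reference indicator is the one with the largest |λ̂| (any nonzero-λ item
is valid; the largest is numerically safest for the ratio λᵢ/λ_ref).

Internally the model is parameterized as E(Xᵢ|Z=z) = γᵢ + λᵢ ν_z with
ν_z = β_z/λ_ref, the group contrast on the latent scale.  At fixed λ̂ the
two parameterizations span the same mean family, but the ν form makes the
fitted statistic — and the variance correction below — exactly invariant
to which indicator plays the reference role; β = λ̂_ref·ν is reported for
interpretability.  Initial values: γ from the level-1 means; ν from the
least-squares projection of the contrast matrix onto λ̂ (also
reference-invariant).

When λ is estimated rather than known, the weight matrix is the
empirical covariance of the adjusted rows

    Ũ_k = U_k − A B⁻¹ V_k,
    A = mean ∂U_k/∂λ,   B = mean ∂V_k/∂λ,
    V_ik = Σ_{j≠i} λⱼ[(X_ik−X̄ᵢ)(X_jk−X̄ⱼ) − λᵢλⱼ],

which is the influence-function expansion of √N·Ū(θ, λ̂) around the true
λ.  In the ν parameterization A has entries −w_z ν_z on the (z,i,i)
slots (w_z the level proportion); B has the analytic form
B[i,m] = C_im − 2λᵢλ_m (m≠i), B[i,i] = −Σ_{j≠i}λⱼ².  The per-subject
derivative in the paper-facing (γ, β) convention is also exposed
(`du_dlambda`); it differs from the ν-fixed derivative by a column lying
in the span of ∂U/∂θ, which does not affect the asymptotic distribution.
A simulation in the test suite verifies the corrected Σ against the
Monte-Carlo covariance of √N·Ū with plug-in λ̂, and that the correction
moves the null rejection rate toward the nominal level (without it the
test is markedly conservative, because plug-in λ̂ makes Ū under-dispersed
relative to the naive Σ).  When the user supplies λ as known, the
uncorrected Σ is used.

Because the test leans on the independent-errors covariance structure
through λ̂, correlated errors invalidate it: with exchangeable error
correlation 0.3 and Z still generated from η alone, T0 rejects
essentially always.  That scenario is exactly what motivates T1.

## T1: reliability-free test

Moments, for w = 1..p and i = 1..d (m = dp):

    U_k[(w,i)] = I(Z_k = w) · (X_ik − γᵢ − αᵢ β_w),   β₁ = 0.

Only the products αᵢβ_w are identified (αᵢ/τ, β_wτ give the same model),
so the raw 2d + (p−1) coordinates carry one redundancy: the identified
parameter count is 2d + p − 2 and df = dp − (2d+p−2) = (d−1)(p−2),
positive only for p ≥ 3.  During optimization the scale is fixed by
freezing one coordinate: by default the α coordinate of largest initial
magnitude, alternatively β₂ (`normalization="beta2"`); the statistic is
invariant to the convention (checked to 1e−5).  Initial values come from
the leading singular triplet of the contrast matrix; γ from the level-1
means.  With p = 2 the model is saturated and the test degenerates —
the implementation refuses and points to T0.  Composite groupings (e.g.
mortality × prior exercise giving p = 4) are built by
`build_composite_z`, which orders cells lexicographically with the first
factor varying fastest and drops empty cells with a warning.

T1 uses only the rank-1 restriction on group means — no distributional
assumptions from the factor model — so it stays calibrated under
correlated errors (asserted in the suite for exchangeable correlation
0.3) at the price of requiring p ≥ 3 and typically somewhat lower power
per contrast.

## Numerical choices

- Covariances and variances use divisor N throughout, matching the 1/N
  factor in the estimating equations; standardization (mean 0, variance
  1 by divisor N) is applied by default before testing and can be
  disabled (the rank-1 restriction of T1 is scale-equivariant, but the
  reliability model assumes unit variance).
- Weight-matrix inversion is by eigendecomposition with relative
  eigenvalue cutoff 1e−10; rank deficiency beyond what a moment system
  structurally implies triggers a small logged ridge
  (1e−8·trace(Σ)/m).
- The quadratic form is minimized by BFGS with analytic gradients
  (gradient tolerance 1e−8, max 500 iterations); moment means and
  Jacobians are computed from per-level sufficient statistics
  (level proportions and level means), so an optimizer step costs
  O(dp), independent of N.  If the first solve ends with gradient norm
  above 1e−6, up to five perturbed restarts (caller-seeded) are tried
  and the smallest value kept.  T0's moments are linear in (γ, ν), so
  its problem is exactly quadratic; T1's are bilinear in (α, β).
- p-values are upper-tail chi-square probabilities; a statistic of 0
  (exactly solvable moment conditions) gives p = 1.

## Synthetic data generator

`GeneratorConfig` defaults describe the simulation conditions used
throughout: d = 5 items with loadings (0.8, 0.7, 0.75, 0.65, 0.6) —
moderate, unequal, in the range typical of well-behaved multi-item
scales — N = 2,000 subjects, and Z generated by thresholding η at
standard-normal quantiles giving equal level probabilities (a
multinomial-logistic mechanism in η is available).  Errors are normal by
default, with options for scaled-t (5 df, unit variance) tails and
exchangeable cross-correlation; indicator variances are exactly 1 at the
population level, and finite-sample standardization is applied afterwards
like real data.  Alternatives add per-level mean shifts δ to chosen
items — the simplest mechanism that gives Z a direct dependence on items
beyond η.  A shift proportional to λ across items mimics a latent-mean
difference and is flagged as indistinguishable from the null.

What the generator does **not** emulate: Likert discretization (real
scale items take 5 or 7 ordered values; the tests treat them as
approximately continuous, as does the motivating application),
missing-data mechanisms, longitudinal structure, or multi-factor
latents.  Passing calibration here therefore shows correctness of the
statistics under the stated model, not robustness to coarse
discreteness or missingness.

## Monte-Carlo harness and problem sizes

Per-replicate seeds derive from (base seed, replicate index) through a
counter-based stream, so results are independent of execution order.
Failed fits are excluded from the rejection-rate denominator and
counted; more than 5% failures flags the estimate unreliable.  Rates
carry exact (Clopper–Pearson) binomial 95% intervals.  The test suite
runs null calibration at 2,000 replicates of N = 2,000 (rejection rates
asserted within [0.035, 0.065] at α = 0.05, Kolmogorov–Smirnov distance
to the reference chi-square below 0.05) and power ordering over direct
effects δ ∈ {0.1, 0.2, 0.4} at 400 paired replicates per point; the
acceptance script uses 1,000 calibration replicates.  These bounds are
engineering targets justified by the asymptotics, not externally
reported values.

## Known limitations

- Both tests are asymptotic; at small N (a few hundred) with many
  moment conditions (large d·p) the chi-square approximation degrades
  and group sizes must comfortably exceed d.
- T0's validity rests on the independent-errors covariance model used
  for λ̂; the plug-in correction fixes the sampling uncertainty of λ̂,
  not misspecification of that model.
- Rejection says only that a *univariate structural* latent cannot
  generate the data; it does not identify the true causal structure,
  and the tests offer no model selection among alternatives.
- Continuous Z, covariate-stratified testing, and multidimensional
  latents are out of scope.
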