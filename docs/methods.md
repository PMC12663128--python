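# Methods

This note records the models implemented in `normbench`, the numerical
choices behind them, and what the synthetic experiments do and do not show.

## Data model

All analyses consume long-format person-level records (age in decimal years,
raw score, optional group label). Ages are continuous; "year;month" style
ages should be converted as years + months/12 before import. Cohorts are
half-open one-year bins anchored at integer ages, `[k, k+1)`, matching how
age-in-years cohorts are usually formed. A missing group column is treated
as a single group `"all"` — the engine never requires sex or any other
stratifier, though reference construction is typically run per sex.

## Synthetic data generator

The generator draws from an exactly known age-varying Box–Cox law: smooth
polynomial trajectories L(t) (skewness), M(t) (median, > 0) and S(t)
(coefficient of variation, > 0), degree ≤ 3. For each one-year cohort it
draws ages uniformly within the cohort (not at midpoints — continuous ages
exercise interpolation) and z ~ N(0,1), then maps

    y = M(t) (1 + L(t) S(t) z)^(1/L(t)),   or   M(t) exp(S(t) z)  for L = 0,

recording the true percentile Φ(z) per record. The Box–Cox sample space is
truncated where 1 + L·S·z ≤ 0; such deviates are redrawn (cap 100 per
record), which amounts to sampling the truncated law. The L = 0 branch
switches at |L| < 1e-8 for numerical continuity of the two formulas.

Two presets provide study-shaped conditions: a positively skewed BMI-like
measure over ages 5–19 (negative L, rising median, mildly widening spread)
and a near-symmetric VO2max-like measure over ages 12–19 (L ≈ 0.8, slowly
drifting median, constant relative spread). The shapes are generic
stylizations of pediatric BMI and adolescent aerobic-capacity references;
they are deliberately *not* estimates of any real cohort's trajectories.
Optional floor/ceiling censoring emulates limited-range instruments and
breaks the parametric assumption; the default censored scenario clips the
VO2max-like sample at 30 and 62 ml/kg/min (≈ 3 % of records per side).

What the generator does not emulate: survey sampling design and weights,
measurement error distinct from trait dispersion, secular trends, and
between-group heterogeneity. Passing tests therefore demonstrate
correctness of the estimators under their generative assumptions (and under
controlled violation via censoring), not representativeness claims about
any real population.

## Parametric route (LMS)

The penalized log-likelihood is the Box–Cox kernel per record minus
curvature penalties `½ α ∫ (curve″)²` per curve. Implementation choices:

* **Positivity is structural.** M and S are parameterized on the log scale;
  L on the identity scale, clamped to [−5, 5]. Consequently the curvature
  penalty acts on the curve *as parameterized* (log M, log S, identity L).
  For flat curves both readings coincide (zero penalty), and the smoothing
  behaviour is qualitatively identical; this keeps positivity guaranteed
  rather than hoped for.
* **Exact penalty algebra.** Each curve is a natural cubic spline through
  its knot values g; `∫ s″² = gᵀKg` with the standard tridiagonal
  construction K = Q R⁻¹ Qᵀ. No quadrature is involved, and the identity is
  unit-tested against knot-aligned Simpson integration (exact for the
  piecewise-quadratic integrand).
* **Knots.** At every distinct age when there are ≤ 100 of them (with
  continuous ages this is rare), otherwise at 20 age quantiles. Fewer than
  4 distinct ages is a hard error.
* **Smoothing control.** α per curve, either given directly or derived from
  an equivalent-degrees-of-freedom target by bisection on
  tr[(BᵀB + αK)⁻¹BᵀB], which decreases monotonically from the basis rank to
  2 (the penalty's null space is the straight lines). Defaults edf_L = 2,
  edf_M = 4, edf_S = 3 — common practice for this model family, all
  config-exposed; they are not a reproduction claim about any particular
  software's defaults.
* **Optimization.** Joint quasi-Newton maximization over all spline
  coefficients with analytic gradients (finite-difference-checked in the
  tests), initialized from L ≡ 1, running per-cohort median and coefficient
  of variation. The penalty Hessian αK can exceed the likelihood curvature
  by ~10 orders of magnitude (α grows without bound as edf → 2), so the
  coefficients are whitened through the eigenbasis of K
  (g = U diag(1/√(1+αλ)) c) before L-BFGS-B, followed by a Newton-CG polish
  with finite-difference Hessian-vector products. Convergence is declared
  when the gradient norm with respect to the optimized coefficients falls
  below 1e-5; otherwise the model carries `converged=False` and a warning.
  If the whitened solution violates the L clamp, a bounded refinement in
  knot-value space is run from that solution. The objective trace is
  monotone non-decreasing across outer iterations (asserted in tests).
* **Evaluation outside the fitted age range** uses the natural spline's
  linear extension (its true boundary behaviour) and logs a warning once
  per model. Centile curves whose Box–Cox power argument is non-positive at
  some age are reported as NaN at those grid points — the centile lies
  beyond the transform's support — never clamped.

One printed form of the likelihood kernel circulating in the literature
contains a doubled "log log S" term; the correct Cole–Green kernel has a
single − log S (it is the Jacobian of the Box–Cox transform against the
normal kernel), and that is what is implemented.

## Distribution-free route (cNORM)

* **Location scale.** Θ is the within-cohort inverse normal-rank transform
  expressed as a T score. The rank estimator is rankit, (r − 0.5)/n, with
  midranks for ties; Blom, Tukey and van der Waerden variants are
  config-selectable (they differ by at most ~1/n). The same transform
  serves as the evaluation benchmark.
* **Standardization before powering.** Raw T scores to the 5th power and
  ages to the 3rd produce hopelessly ill-conditioned design matrices, so Θ
  and age are affinely standardized (fixed (50, 10) for Θ; training
  mean/SD for age) before the monomials are formed. An affine change of
  variables leaves the polynomial model class unchanged.
* **Exact best-subset search.** For each size s ≤ 8 the intercept plus the
  s-subset minimizing RSS is found by exhaustive enumeration over all
  candidate subsets, vectorized through Gram-matrix batched Cholesky
  solves (~10⁶ subset solves per fit in a few seconds). Rank-deficient
  subsets are skipped with a warning. The search is exact, and is tested
  against a naive per-subset least-squares oracle.
* **Selection rule.** Smallest size with in-sample R² ≥ 0.99 *and* a
  passing coherence check; if no size manages both, the best-R² coherent
  size; if nothing is coherent, the best-R² model flagged
  `coherence_passed=False`, which refuses inversion and table export. The
  coherence check evaluates the analytic ∂r/∂Θ on a grid over the observed
  age range × Θ ∈ [20, 80] (±3 SD) and requires it strictly positive —
  equivalently, extracted centiles cannot cross.
* **Inversion.** Norm scores solve r(Θ*, a) = y by Brent root-finding on
  [20, 80] to 1e-6 T-units. Scores outside the model's range at that age
  clamp to 20/80 with a flag; if bracketing fails, a 0.01-T-step grid
  search minimizing squared error is used and flagged. No closed-form
  quintic solution exists in general, and the bounded domain guarantees a
  bracket for coherent models. Norm scores beyond ±3 SD are not claimed by
  either route.

## Comparison protocol

`T_actual` is computed once from the *complete* dataset and looked up for
test records — the benchmark represents the manifest norms a conventional
per-cohort table would deliver, and region membership (T ≤ 30 / T ≥ 70,
boundaries inclusive) is decided by this benchmark, not by predictions.
Repetition r uses seed `base_seed + r`, recorded per run-row, so any single
run can be re-executed. Failed fits become NaN rows with the error message;
the sweep never aborts. R² is the squared Pearson correlation (the
alternative 1 − SSE/SST reading is not used); the decomposition
RMSE² = Bias² + Var(error) holds identically and is asserted in tests.
Summaries report mean ± SE per method × size × region; significance
modelling on top of the per-run table (e.g. mixed models) is left to the
user, who can load the exported CSV into any stats package.

## Problem sizes

The default experiment sizes are chosen to run on a desk machine: synthetic
samples of 300 per cohort (7 cohorts) for the comparison sweeps, 20
repetitions in the test suite, 10–20 in the analysis drivers, and 5 in the
acceptance script — against the full protocol's 1,000 repetitions. At these
sizes the mean RMSE estimates carry SEs of a few hundredths of a T-unit,
ample for the qualitative conclusions; per-run CSV export allows scaling
the repetition count arbitrarily.

## Known limitations

* Single explanatory variable (age); no weighting or post-stratification.
* The LMS route fits the Cole–Green model only — no heavier-tailed or
  kurtotic families.
* Smoothing parameters are fixed per fit (no automatic selection by
  information criteria or cross-validation).
* The rank-based benchmark is itself noisy in small cohorts; comparisons
  against it conflate model error with benchmark error, which is inherent
  to the protocol (both methods face the same benchmark).
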