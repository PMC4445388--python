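# Methods

## The question and the models

The analysis asks whether years of education are associated with later-life
cognitive performance through the general factor *g* or through specific
tests.  Twelve observed variables enter: an age-11 intelligence score
(Moray House Test), years of education, and ten age-70 cognitive tests
(six WAIS-III subtests, three WMS-III subtests, and a repeat of the MHT).
All models regress education on age-11 IQ and extract one *g* factor from
the ten subtests; they differ only in how education reaches the subtests
(via *g*, via direct paths, or both).  Age-11 IQ also predicts *g*, so every
education effect is an association with *change* relative to childhood
ability.

The measurement model is a single factor plus five residual covariances
between content-overlapping test pairs (two speeded coding tests, two verbal
memory tests, two visuospatial reasoning tests, two working memory tests,
and one unexpectedly negative pair involving the repeated MHT).  This choice
is supported in-package three ways: Horn's parallel analysis retains exactly
one factor; 2–4-factor oblimin EFAs produce only doublet-heavy factors; and
a sequential modification-index search starting from the bare one-factor
model frees exactly those five pairs.  Alternative measurement structures
(correlated 2/3/4-factor, hierarchical, bifactor) are available in the
catalogue for comparison.

## Estimation

Models are compiled to RAM matrices (A directed, S symmetric, F selection)
with implied covariance Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ.  The *g* (residual)
variance is fixed at 1 for identification; every other variance is free.

* **Summary ML** minimises F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p;
  χ² = (n−1)F_ML(θ̂).  Standard errors come from the inverse expected
  information, (n−1)/2 · tr(Σ⁻¹∂Σ_jΣ⁻¹∂Σ_k); the bivariate-regression case
  reproduces the closed-form OLS standard error to machine precision.
* **FIML** groups rows by missingness pattern and maximises the casewise
  normal log-likelihood over each row's observed subset of (μ(θ), Σ(θ)),
  with free intercepts per observed variable.  Its χ² is the likelihood
  ratio against the saturated model, whose MLE is obtained by EM on the
  pattern sufficient statistics; standard errors use the observed
  information (finite differences of the analytic gradient).  On complete
  data FIML coincides with summary ML on the divisor-n moments (verified to
  1e−6 in the tests).

Optimisation is Fisher scoring (Newton steps on the expected information
with backtracking line search and adaptive ridging), with an L-BFGS fallback
and up to five jittered restarts; convergence requires the gradient
inf-norm below 1e−10·(1+|f|).  Analytic gradients follow the RAM derivative
identity ∂Σ = B∂A·Σ_all + B∂S·Bᵀ + Σ_all·∂AᵀBᵀ with B = (I−A)⁻¹, checked
against central differences to 1e−6.  Start values: loadings
0.7·sd(indicator)/sd(factor guess), uniquenesses half the sample variance,
regressions and residual covariances 0, intercepts at the sample means;
latent scale guesses use a marker indicator when one is fixed.  Inadmissible
points (non-PD Σ) return a large objective value so the line search backs
off; negative variance estimates are flagged on the result, never clipped.

Fit indices follow the usual definitions — RMSEA = √(max(χ²−df,0)/(df(n−1))),
CFI and TLI against the independence model with free variances (and free
means under FIML).  With df = 0 RMSEA and TLI are reported as NaN.  AIC is
−2lnL + 2k for FIML; for summary fits only a relative AIC (χ² + 2k) is
meaningful, and every nested contrast satisfies ΔAIC = Δχ² − 2Δdf exactly,
so ΔAIC values are comparable across the two conventions even though
absolute AICs are not.  Modification indices are 1-df score statistics,
g'H⁻¹g/2 on the χ² scale, computed at the fitted solution with the
candidate appended at zero; drop tests refit with a parameter fixed at zero
and report the likelihood-ratio difference.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| n for summary fits | 1,091 (cohort total) | the published fit used all rows casewise; alternatives `min` (1,028) and `mean` (1,078) are selectable and shift χ² by <6% |
| parallel-analysis iterations / percentile | 1,000 / 95th | the published retention rule |
| oblimin γ | 0 (quartimin) | the standard "direct oblimin" default |
| elimination α | .05 | conventional; the procedure drops the single largest-p education path per refit |
| PD repair floor | 1e−8 eigenvalue clip | 2-decimal printed correlations can be numerically semi-definite; clipping preserves the printed values to ~3 decimals (the packaged matrix is PD, min eigenvalue 0.291, so the repair never triggers on the fixture) |
| convergence tol | 1e−10 relative gradient | Fisher scoring converges quadratically, so this costs little |

## The synthetic cohort

The generator emulates the study data as an n = 1,091 multivariate-normal
sample with the printed means/SDs/correlations and per-variable MCAR masks
hitting the printed observed counts exactly (1,028–1,091; education always
complete).  `exact_moments` mode recolors centred, whitened draws so the
sample mean and ddof-1 covariance equal the targets to machine precision —
complete-data fits to such a cohort reproduce summary-based fits identically.
What it does **not** emulate: bounded/discrete test scores (normality is
deliberate — it is the assumption under which the ML fit statistics are
derived; an optional rounding post-step exists but is off by default), any
MAR/MNAR mechanism, joint missingness patterns (only per-variable margins
are published), and age/sex structure.  A green test on synthetic data
therefore establishes correctness of the estimation machinery under the
model's own assumptions, not robustness to their violation.

## Design choices where the published description is open

* Parallel analysis uses principal-component eigenvalues of random normal
  data (the original formulation); operating on the correlation matrix plus
  (n, p) is distributionally equivalent to operating on raw uncorrelated
  scores.
* EFA extraction is maximum likelihood (principal-axis selectable); the
  extraction method is not stated in the published analysis.
* Backward elimination drops one path per step, the one with the largest
  likelihood-ratio p ≥ α, refitting after each drop; p-values for single
  paths use drop tests (not Wald ratios).
* Two-indicator group factors in the bifactor model get equated loadings as
  the minimal identifying constraint; first-order factors in the
  hierarchical model are scaled by a fixed unit marker loading.
* Residualization uses complete-pairs OLS of each subtest on age-11 IQ;
  rows missing either member keep a missing residual.
* Summary-fit χ² uses the (n−1) multiplier; FIML χ² is the likelihood ratio
  against the saturated model.  The conventions differ by O(1/n) and only
  differences are compared across models fitted the same way.

## Known limitations and discrepancies

* The published first eigenvalue of the ten-subtest battery (4.29) is not
  reproducible from the published correlation submatrix, which yields 4.531
  (SMC-reduced: 3.958).  The retention decision — one factor — is unaffected.
  The package reports the value the matrix implies.
* Standardized paths differ from the published raw-data FIML estimates by up
  to ~.03 (notably age-11 IQ → *g*: .669 vs .69 in Model A, .714 vs .74 in
  Model C), consistent with fitting to correlations printed at 2 decimals.
  All Δχ² values agree within ~13%, and every model-ranking conclusion
  (C < B < A by AIC, in the main analysis and all three robustness variants)
  reproduces exactly.
* The residualized robustness variant (subtests adjusted for age-11 IQ)
  reproduces Model C as best when run on a complete exact-moments cohort,
  where the residualized covariance is a deterministic function of the
  printed moments.  With the printed MCAR missingness imposed first, the
  C-vs-B contrast — marginal in the published analysis too — can flip at
  some generator seeds; the orderings in the other two robustness variants
  are seed-free and stable.
* Absolute degrees of freedom are not comparable to the published table
  (whose parameterisation is not fully recoverable); all df *differences*
  (2, 4, 6) are, and they anchor the comparisons.
* The backward elimination on the fixture drops only the Spatial Span path
  at α = .05 (p = .39; Digit Span Backwards starts at p = .053 but falls to
  .033 once Spatial Span is removed, and Letter-Number Sequencing to .015),
  so the dropped set is a strict subset of the published three.  Model C
  itself is defined by the published seven direct paths, not by the
  elimination outcome.
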