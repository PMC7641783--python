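# Methods

## The model

`pointscore` derives an integer point-based risk score from a cohort of
care episodes with a binary outcome (for example first-day ICU data and
inpatient mortality). The deployable object is a small table: each of a
few predictors is cut into ordered categories, each category carries a
nonnegative integer number of points, and an episode's risk class is the
sum of its points. The derivation pipeline is:

1. **Cleaning.** Values outside user-supplied physical plausibility
   ranges become missing. The cohort is randomly split into training
   (70%), validation (10%) and test (20%) partitions. Missing continuous
   values in every partition are imputed with the *training* median;
   missing categorical values become an explicit `Unknown` level
   (missingness in EHR data is often informative, and an indicator level
   lets the weighting stage estimate its effect rather than erase it).
2. **Ranking.** A random forest (100 trees, Gini splitting, `sqrt(p)`
   candidate variables per split, trees grown to maximum size without
   pruning, bootstrap per tree) ranks all candidate predictors by raw
   mean decrease in Gini impurity:
   `Imp(X) = (1/N_T) Σ_trees Σ_{τ splits on X} w(τ) ΔGini(τ)` with
   `w(τ) = N_τ/N`. Only the order is consumed downstream, so the
   importances are not normalized. Ties are broken by variable name so
   the ranking is deterministic.
3. **Transformation.** Each selected continuous variable is cut at its
   training percentiles `k1, k2, k3, k4` (defaults 5, 20, 80, 95 —
   symmetric 5%/15% tails around a 60% central band, a sensible default
   for near-normally distributed vitals and labs). Bins are left-closed:
   a value equal to a cutoff falls in the bin above it. Duplicate
   percentiles (heavily tied labs) collapse, shrinking the category
   count instead of failing. Categorical variables with more than `K`
   (default 5) levels have their rarest levels pooled into `Other`.
4. **Weighting.** A multivariable logistic regression on one-hot
   category indicators estimates a coefficient per non-reference
   category. The category with the lowest first-pass coefficient becomes
   each variable's reference and the model is refitted, which makes the
   remaining coefficients nonnegative up to sampling noise; rare
   residual negatives are clamped to zero (and logged — the raw values
   are preserved on the fit object). Every coefficient is divided by the
   smallest positive coefficient across all variables (`beta_lowest`)
   and rounded half away from zero, so the least influential category
   maps to one point. Rounding half away from zero (2.5 → 3) is the
   convention of clinical score tables; Python's builtin banker's
   rounding would be surprising here.
5. **Model size.** For each candidate number of variables `m` (top-`m`
   by ranking), the pipeline derives a score on the training partition
   and records the *integer* score's AUC on the validation partition —
   the deployed object is the integer score, so the curve evaluates
   exactly that. The user picks `m` from the plot, or the plateau rule
   picks the smallest `m` whose AUC gain to every larger evaluated `m`
   is below `delta` (default 0.005).
6. **Fine-tuning.** The serialized transform spec is the editable
   surface: a clinician replaces automatic cutoffs (say 47.83) with
   conventional round values (48), and the score is re-derived. The
   package validates monotonicity but deliberately does not auto-round —
   cutoff choice is a domain-knowledge act.
7. **Evaluation.** On the held-out test partition (touched only here):
   AUC by the Mann–Whitney rank statistic, percentile-bootstrap 95% CIs
   (default 1000 episode resamples; replicates missing a class are
   redrawn), operating points at the ROC upper-left-corner optimum and
   at the thresholds where sensitivity (resp. specificity) first reaches
   about 95%, and binned calibration (observed event rate per score
   interval). The classification rule is *positive iff score ≥
   threshold* throughout; on integer scores this convention is
   consequential, so it is printed in the report header.

## Numerical choices

- **Ridge stabilization.** The logistic fit always carries a small L2
  penalty (λ = 1e-4 on slopes, on the summed-loss scale; the intercept
  is unpenalized). Categories with zero events then get large-but-finite
  coefficients instead of diverging; the fit is flagged (`separation`)
  when any |β| > 10. Collapsing such categories into a neighbor is a
  config alternative left to the caller.
- **`beta_lowest` threshold.** Coefficients ≤ 1e-6 are excluded from the
  `beta_lowest` minimum to avoid dividing by a numerically-zero
  coefficient; if no coefficient exceeds the threshold the score would
  be all-zero and derivation fails loudly.
- **Percentiles** use linear interpolation between order statistics —
  continuous in the data and the numpy default.
- **Frequency/importance ties** break by name; distance ties in the
  optimal-threshold search break toward the lowest threshold.
- **Split sizes** round the train and validation fractions and give the
  remainder to test; an empty partition is an error, and an optional
  outcome-stratified mode (off by default) protects small cohorts.
- **Seeds.** One global seed fans out to the split, forest and bootstrap
  stages by fixed offsets, so a run is bit-reproducible and each stage
  is individually reproducible.

## The synthetic cohort generator

Real first-day EHR extracts are access-restricted, so the package ships
a generator whose default (`default_ehr_spec`) emulates an adult-ICU
first-day table: nine continuous signal variables (age, heart rate,
respiratory rate, systolic blood pressure, temperature, SpO2, platelet,
BUN, lactate) with plausible marginal shapes, ten pure-noise labs, and
two weakly structured categoricals (sex, admission type). Each signal
variable has *true* cutoffs at conventional clinical boundaries and
*true* integer points; the outcome is drawn from
`P(Y=1) = expit(intercept + slope·T + e)`, `e ~ N(0, noise_sd²)`, where
`T` is the row's true total. Truth is expressed in the same formalism
the pipeline estimates, which makes parameter recovery well-posed: the
fitted category coefficients converge to `slope ×` the true points (the
noise term attenuates all of them by a common factor, preserving order).

Design choices, made once:

- **Identifiability by construction.** Every true bin keeps at least
  ~1.5% marginal mass and distinct points within a variable differ by at
  least 3. Early drafts violated both (an SpO2 bin with ~0.02% mass made
  releveling latch onto a two-observation reference; 1-point gaps are
  statistically invisible at these sample sizes) and produced a test bed
  that failed for reasons unrelated to the code under test.
- **Signal strength.** `slope = 0.15` per point. Fully grown trees
  spread roughly half of the impurity budget uniformly across all
  variables (~0.0073 per variable at n_train = 14,000), and the weakest
  signal variable must clear that floor with margin for ranking recovery
  to be a property of the method rather than a coin flip; 0.15 yields a
  ≥1.10× importance ratio of worst-signal over best-noise in replicated
  runs.
- **Prevalence.** The intercept is calibrated by bisection (on one fixed
  internal simulation of 50,000 true totals, so it is deterministic) to
  an event prevalence of ~9%, typical of ICU inpatient-mortality
  cohorts. Default cohort size is 44,918 episodes; tests use 20,000 to
  keep runtimes reasonable.
- **`noise_sd = 0.5`** models mild unmeasured patient heterogeneity.
- **Missingness is MCAR** (default 2% per cell). Informative missingness
  is out of scope.

What passing tests on this generator do *not* show: robustness to
correlated predictors (labs and vitals co-vary in real patients; the
generator draws them independently), to informative missingness, to
longitudinal aggregation choices, or to outcome prevalences far from
9%. Bounded marginals are approximated by unbounded distributions (SpO2
can exceed 100%), which is harmless for the estimation machinery but
means the synthetic tables are not clinically literal.

## Known limitations

- Paper-table-style score derivation assumes additive category effects;
  interactions are not modeled (by design — additivity is what makes
  the table usable at the bedside).
- The plateau rule for `m` is one operationalization of "no longer
  improving"; it is deliberately simple and the manual mode is
  first-class because model-size choice is usually a human trade-off.
- Published-score convention promises every point "larger than one", but
  integer rounding can produce 1 and clamping can produce 0; this
  package guarantees nonnegative integers with a 0-point reference per
  variable, which is the defensible reading.
- Bootstrap CIs are percentile intervals; no analytic (DeLong) AUC
  variance is provided.
- PPV/NPV depend on prevalence; on case-control-sampled data they are
  not interpretable, and the package does not attempt to re-weight them.

## Problem sizes used in the shipped checks

Module tests run at n ≤ 10,000. The end-to-end recovery checks use
n = 20,000 with 20 generator replicates for the ranking property and a
500-replicate bootstrap in the acceptance script's pipeline run; the
full default cohort size (44,918) is exercised once for the prevalence
check. These sizes were chosen to make the stochastic assertions stable
at the stated thresholds.
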