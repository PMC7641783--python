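# pointscore

**Automatic derivation of interpretable, integer point-based clinical
risk scores from tabular cohort data.**

Clinical front-line tools like early-warning scores assign a few integer
points to categories of a handful of variables (age 48–78 years → 14
points, lactate ≥ 4 mmol/L → 21 points, …); the summed total stratifies
risk without a computer. Hand-crafting such scores is slow and ad hoc.
`pointscore` automates the derivation from a rectangular cohort table
(one row per episode, mixed continuous/categorical predictors, binary
outcome) while keeping every intermediate object editable by a
clinician.

The pipeline:

1. **Rank** candidate variables by random-forest mean decrease in Gini
   impurity (100 trees, √p variables per split);
2. **Transform** continuous variables into ≤ K ordered categories at the
   training percentiles k₁…k₄ (defaults 5, 20, 80, 95; bins are
   left-closed, so a value equal to a cutoff falls in the bin above);
3. **Weight** categories by multivariable logistic regression, relevel
   each variable at its lowest-risk category, divide all coefficients by
   the smallest positive one (β_lowest) and round half away from zero:
   `points = round(β / β_lowest)`;
4. **Select** the number of variables m from a validation-set parsimony
   curve (integer-score AUC versus m);
5. **Fine-tune** cutoffs by hand (47.83 → 48) and re-derive;
6. **Evaluate** on a held-out test set: rank-statistic AUC with
   percentile-bootstrap 95% CIs, operating points at the ROC
   upper-left-corner optimum and at ~95% sensitivity / specificity, and
   binned calibration.

A truth-known synthetic EHR-like cohort generator
(`pointscore.default_ehr_spec`) makes every stage testable without
access-restricted patient data: outcomes are drawn from a *known*
cutoffs-plus-integer-points score through a logistic link, so the
pipeline's estimates can be compared against ground truth.

## Worked example

```python
import pointscore as ps

spec = ps.default_ehr_spec(n=20_000, seed=7)   # synthetic ICU-like cohort
cohort, truth = ps.generate_cohort(spec)

model = ps.RiskScoreModel(cohort, seed=1)      # 70/10/20 split, 100 trees, K=5
results = model.fit()
print(results.summary())
```

This prints the derived score table and its held-out performance
(abridged):

```
Point-based risk score derivation results
=========================================================
episodes: 20000  (train 14000 / val 2000 / test 4000)
outcome: death  (test prevalence 8.6%)
variables: 9 of 21 candidates (selected on the validation parsimony curve)
total score range: 0 to 49
...
  age
    <35.75064127614758          0
    35.75064127614758-49.42767552063657    1
    49.42767552063657-77.12785427597602    3
    77.12785427597602-90.64468045774369    5
    >=90.64468045774369         6
...
Test-set performance (positive iff score >= threshold)
---------------------------------------------------------
  AUC 0.838 (95% CI 0.815-0.859)
  optimal          threshold 22: sens 74.0%  spec 78.6%  ppv 24.7%  npv 97.0%
  sensitivity~95%  threshold 17: sens 95.7%  spec 36.3%  ppv 12.5%  npv 98.9%
  specificity~95%  threshold 26: sens 37.9%  spec 95.8%  ppv 45.8%  npv 94.2%
```

Reading it: the pipeline picked m = 9 of the 21 candidates (in this
synthetic cohort, exactly the nine variables that truly carry signal),
each category's integer points grow with its fitted log-odds, and an
episode scoring ≥ 22 points would be flagged at ~74% sensitivity and
~79% specificity. The raw quantile cutoffs are deliberately unrounded —
the fine-tuning pass is where a human replaces 35.75… with 36:

```python
refined = results.refine({"age": [30, 48, 78, 85]})   # re-derives the score
print(refined.score_table.to_markdown())
```

Artifacts (`ranking.json`, `parsimony.csv/png`, `transform_spec.json`,
`score_table.json/md`, `eval_report.csv/md`, `calibration.csv`,
`run.json`) are persisted with `results.save_artifacts("outdir")`; the
score table JSON plus transform spec JSON are the complete deployable
object.

The same flow is available from the shell:

```bash
pointscore synth --n 20000 --seed 7 --out cohort.csv --truth truth.json
pointscore run --config run.yaml --seed 1
pointscore refine --config run.yaml --cutoffs overrides.yaml
```

## Scope

`pointscore` derives and evaluates scores; it does not extract cohorts
from EHR systems, model informative missingness, or fit comparator
models (full/stepwise/LASSO logistic regression, RF classifiers). See
`docs/methods.md` for the model, the numerical choices, the synthetic
generator's design and its limitations.
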