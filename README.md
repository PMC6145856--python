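# docprog

Multidomain prognostic modelling for chronic disorders of consciousness
(DOC): predicting the one-year Coma Recovery Scale–Revised (CRS-R) outcome
and classifying consciousness recovery at the single-subject level from
resting-state fMRI functional-network features combined with clinical
characteristics.

## Who this is for

Researchers building or auditing prognostic models for severely
brain-injured patients (vegetative state / unresponsive wakefulness
syndrome, minimally conscious state), and methodologists who want a tested,
reusable implementation of the full pipeline — preprocessing, feature
construction, two-stage feature selection, partial least squares
regression, and the internal/external validation machinery — exercisable
end-to-end on synthetic cohorts without any patient data.

## The model

For patient $i$, let $x_i \in \mathbb{R}^q$ collect the selected imaging
features plus four clinical covariates (age, DOC duration, and two etiology
dummies with trauma as reference). All predictors are z-scored with
training-set constants; the response $y_i$ is the CRS-R total score
(0–23) at follow-up, kept on its natural scale. A PLS1 regression with
three latent variables gives

$$\hat{y}_i = \beta_0 + \sum_j \beta_j \frac{x_{ij} - \mu_j}{\sigma_j},$$

and a subject is classified as *consciousness recovery* (GOS ≥ 3) when
$\hat{y}_i \ge c$, with the cutoff $c$ chosen on the training ROC curve
(Youden's criterion). The imaging features are

* **231 pairwise functional connectivities** — Fisher-z transformed Pearson
  correlations between all pairs of 22 ROI-averaged time series spanning
  six networks (default mode, executive control, salience, sensorimotor,
  auditory, visual);
* **22 template-resemblance features** — the spatial correlation between
  each ROI's whole-brain seed connectivity z-map and a healthy-control
  group template (one-sample t map) for that ROI's network.

Selection is a univariate correlation screen (two-sided p < 0.05 against
the follow-up CRS-R) followed by competitive adaptive reweighted sampling
with PLS (CARS-PLSR). Predictor importance uses sMC F-values; internal
validation uses the optimism-corrected bootstrap (selection re-run inside
every replicate) and out-of-bag majority voting; agreement uses
Bland–Altman; and clinical-only / imaging-only / combined models are
compared via bootstrap accuracy distributions, repeated-measures ANOVA and
the root-mean-square standardized effect Ψ.

## Worked example

```python
from docprog import CohortSpec, PrognosticPLSModel, gen_cohort

spec = CohortSpec(seed=2)                 # 63 patients, 30 controls, 22 ROIs
subjects, table, truth = gen_cohort(spec)
model = PrognosticPLSModel.from_dataframe(table)
res = model.fit(seed=0)
print(f"R2 {res.rsquared:.3f}  AUC {res.auc:.3f}  cutoff {res.cutoff:.2f}")
print(res.summary().splitlines()[3])
preds = res.predict(table[table.group == "patient"])
print(preds.head(3))
```

prints

```
R2 0.777  AUC 0.958  cutoff 11.08
features: 18 (14 imaging)
         predicted_score  imaging_subscore         label
id
sub-000         6.825217         -3.451656  non_recovery
sub-001         5.715902         -3.195753  non_recovery
sub-002         9.118151          0.097865  non_recovery
```

The apparent R² (0.78) is the in-sample fit of the PLS regression to the
follow-up CRS-R score; the AUC (0.96) summarizes how well the predicted
score separates recovered from non-recovered patients; the cutoff (11.08,
on the CRS-R scale) is the score at or above which a subject is labelled
`recovery`. `sub-000`'s predicted score of 6.8 falls below the cutoff, so
the model predicts non-recovery; the negative imaging subscore says the
imaging features alone pull the prediction down relative to the training
mean.

A shell pipeline over NIfTI volumes, motion TSVs and a clinical CSV is
available as `docprog simulate|preprocess|features|train|predict|validate
--config run.yaml` (see `docs/methods.md` for the configuration schema and
modelling details).

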