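# cogsurv

Personalized cognitive decline as a time-dependent predictor of tumor
progression in high-grade glioma.

## The problem

Patients with glioblastoma or anaplastic astrocytoma undergo neuropsychological
assessment (a 10-score battery) one day before surgery (month 0) and every
three months afterwards, alongside MRI follow-up, for up to 24 months.
Progression of the tumor may be reflected in cognition before — or by the time
— it is established radiologically.  Which cognitive functions are sensitive,
however, differs between patients: the functions most burdened by the tumor
(edema, mass effect) are hypothesized to recover most after resection and to
deteriorate first when disease recurs.

`cogsurv` implements that idea as a reusable, tested pipeline for
biostatisticians and neuropsychology researchers:

1. **Normative reliable change** (`cogsurv.normative`).  On healthy-control
   test–retest data, each test's retest score is regressed on its baseline
   score (OLS).  A patient's change is scored as a regression-based Reliable
   Change Index,

   RCI = (observed retest − predicted retest) / SEE,

   where SEE is the control regression's standard error of estimate on
   n − p − 2 degrees of freedom.  Practice effects and regression to the mean
   are absorbed by the control regression; positive RCI = improvement.
   Demographically corrected z-scores (impairment: Z ≤ −1.5) are also provided.
2. **Personalized selection and decline** (`cogsurv.personalization`).  For
   each patient, the three tests with the highest month 0 → 3 RCIs are
   selected (sign-blind, deterministic roster-order tie-break).  Follow-up
   RCIs are re-baselined at month 3 (T6−T3, T9−T3, …); cognitive decline (CD)
   at a visit is RCI ≤ −1.00 on at least two of the three selected tests.
3. **Discrete-time survival** (`cogsurv.survival`).  Decline timelines and
   progression/censoring records are expanded into 3-month counting-process
   intervals, and a discrete Cox proportional-hazards model with the
   time-dependent, absorbing covariate CD and age at surgery is fit by
   maximizing the *exact discrete-ties* (conditional-logistic) partial
   likelihood — the canonical choice when event times sit on a coarse grid.
   Efron and Breslow ties are available as labelled alternatives.  The fit
   reports hazard ratios with Wald CIs, a likelihood-ratio test, and a
   Harrell-type c-index generalized to time-dependent covariates.
4. **Synthetic cohorts** (`cogsurv.synthetic`).  A generator with known ground
   truth: hazard-driven cohorts (mode A) for estimator validation and
   tumor-driven cohorts (mode B) for end-to-end phenomenology.
5. **I/O and the study table** (`cogsurv.cohort_io`).  CSV schemas for scores
   and events, plus a packaged transcription of the published 25-patient
   per-patient table (diagnosis, location, selected tests, progression).

## Worked example

`examples/04_decline_predicts_progression.py` simulates a 120-patient
tumor-driven cohort and runs the full pipeline:

```
patients analyzed: 120, progression events: 51, with decline: 72
HR for progression given cognitive decline: 6.20 (95% CI 3.01-12.73)
HR per year of age: 0.991
LR chi2(2) = 30.0, p = 3.1e-07, c-index = 0.70
median time to progression: 12 months; median time to decline: 9 months
```

The hazard ratio says declining patients progress at about six times the
per-interval hazard of cognitively stable patients of the same age; the
c-index of 0.70 says the model's linear predictor correctly orders a random
comparable pair 70% of the time.  The other examples cover the packaged study
table (`01`), reliable-change scoring (`02`), selection sensitivity (`03`) and
estimator calibration against known truth (`05`).

The same pipeline is scriptable from the shell:

```sh
cogsurv simulate --seed 1 --out sim/
cogsurv run --config config.yaml --out results/
cogsurv summarize          # counts from the packaged study table
```

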