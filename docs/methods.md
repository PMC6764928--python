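# Methods

This note documents the statistical procedures `cogsurv` implements, the
assumptions behind its synthetic-data generator, and the numerical and design
choices made where the construction was genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Reliable change against retest norms

For each test, healthy-control test–retest pairs are fit by ordinary least
squares: `retest = a + b·baseline (+ demographic terms) + ε`.  A patient
contrast is scored as

    RCI = (observed retest − predicted retest) / SEE,

with SEE the standard error of estimate on `n − p − 2` residual degrees of
freedom (intercept + slope + `p` covariates), so the residual variance is
unbiased.  This is the McSweeny-style regression-based reliable-change
construction: the control regression absorbs mean practice effects and
regression to the mean, and for a stable subject drawn from the control
population the RCI is approximately standard normal (exactly, up to the
O(1/n_controls) estimation error of the norm — which is why the null-behavior
check fits the norm on 2,000 controls).

Choices:

- **One model per test, all intervals.**  The same norm scores every contrast
  (months 0→3 and the re-baselined 3→6, 3→9, … contrasts) regardless of
  interval length.  The retest interval may be added as a covariate but is off
  by default.  Consequence: later contrasts re-apply a practice correction
  estimated from a first retest; this mirrors standard practice and is a known
  approximation.
- **Missing data.**  A test absent at either end of a contrast yields an
  absent RCI, never an imputed one.
- **Degenerate inputs.**  Zero baseline variance raises a degenerate-design
  error; an exactly linear retest (SEE = 0, detected at machine precision
  relative to the response scale) raises a perfect-fit error because the RCI
  is undefined.
- **Orientation.**  Scores are stored higher-is-better; the roster can flag
  tests (e.g. completion times) to be sign-flipped at ingestion so "positive
  RCI = improvement" is unambiguous.

Impairment uses a separate single-occasion demographic norm (age, sex,
education): `Z = (score − predicted)/residual SD`, impaired iff `Z ≤ −1.5`,
boundary inclusive.

## Personalized selection and the decline criterion

The three tests with the highest month 0→3 RCIs form the patient's selection.
Selection is sign-blind (the least-negative tests are selected when fewer than
three improved).  Exact ties at the selection boundary break deterministically
in roster order; the battery order is fixed, so repeated runs agree.

Cognitive decline (CD) at a follow-up visit: at least two of the three
selected tests have RCI ≤ −1.00 (inclusive) in that visit's re-baselined
vector.  Each visit is judged on its own vector — the criterion is not
accumulated across visits — and a selected test missing at a visit counts as
not declined, so a visit observing fewer than two selected tests can never
trigger CD.  Both readings ("per-visit" vs. "cumulative across visits") are
defensible; the per-visit reading matches a visit-timeline presentation of
decline and is the one implemented.  For survival analysis CD is absorbing:
once a patient meets the criterion, their status stays "declined".

The threshold (−1.00), the selection size (3) and the count (2) are all
configurable (`AnalysisCriteria`); a stricter −1.645 cutoff used elsewhere in
the literature is available through configuration but is not the default.

## Discrete-time proportional hazards

Assessments and MRIs sit on a 3-month grid, so progression times are heavily
tied and a continuous-time likelihood is inappropriate.  Risk intervals are
`(3, 6], (6, 9], …`: risk time starts at the month-3 re-baselining visit
because decline is undefined before the first follow-up after it.  The CD
status applicable to an interval is the status at the interval's terminal
assessment, so decline observed at the same visit as progression counts as
exposed — assessments preceded disclosure of imaging results, so same-visit
decline is legitimately predictive rather than reactive.

The model is Cox's discrete logistic model: per-interval event odds
`h/(1−h) = (h0_t/(1−h0_t))·exp(xβ)`.  Its exact conditional likelihood at an
event time with risk set R and d tied failures F is

    ∏_{i∈F} w_i / e_d({w_j : j∈R}),   w_j = exp(x_j'β),

where `e_d` is the degree-d elementary symmetric polynomial, evaluated by the
truncated-product recurrence with max-weight factoring and tracked rescaling
(stable for risk sets of thousands).  Covariates are centered internally (the
likelihood is translation-invariant, verified in tests).  Optimization is BFGS
from zero with a tight gradient tolerance; standard errors come from the
inverse of a central-difference Hessian; Wald CIs use z at the requested
alpha; the LR statistic is twice the log-likelihood gain over the
no-covariate null with df = number of covariates.  With singleton event times
this likelihood coincides exactly with Breslow's and Efron's (a tested
identity); both are exposed as labelled `ties` alternatives for sensitivity.

Monotone likelihoods (perfect separation) are detected by probing: any
coefficient larger than 3 internal SDs is pushed 5 SDs further out, and if the
likelihood does not worsen the estimate is capped, flagged `converged=False`,
and a warning is issued — never silent output.

**Concordance.**  The printed c-index of a time-dependent-covariate model is
not uniquely defined; the package uses a generalized Harrell construction: at
each event time, the failing subject is compared against every risk-set
member not failing at that time, using linear predictors evaluated at the
covariate values current in that interval; c = (concordant + ½ ties) /
comparable.  This is one defensible choice and is documented as such.

**Medians.**  Median time-to-event over the patients experiencing the event;
with an even count the lower central order statistic is taken so the median
lands on an actual assessment month.

## Synthetic cohorts

The generator emulates the study design — 10 tests, visits at months 0–24 on
a 3-month grid, recovery concentrated on a tumor-burdened subset, decline
preceding progression, discrete per-interval hazards, dropout and
administrative censoring — without claiming to be the study's true
data-generating process.

**Scores** follow a trait + occasion model: per-test stable trait (reliability
r = 0.8, so the retest slope is 0.8 and SEE = SD·√(1−r²)), a general-ability
factor carrying half the trait variance (the positive manifold of cognitive
batteries), a one-time practice gain of 0.1 SD on the first retest, and
per-visit occasion noise of which half is a session-level factor shared across
the battery within a visit (fatigue, mood, medication that day).  Controls are
drawn from the matching bivariate law `retest = a + b·baseline + N(0, SEE)`,
so fitted norms are correctly specified for simulated patients.  Demographic
effects (age −0.15 points/year, small sex and education shifts) enter the
baseline so demographic norms are meaningful.

Effect sizes are specified on the RCI scale: `delta_pre` (default 1.5) is the
expected month 0→3 RCI on a burdened test (implemented as a raw-score
suppression of `delta_pre·SEE/slope` at month 0, fully recovered at month 3 by
default), and `delta_dec` (default 1.5) is minus the expected re-baselined RCI
on a declined test.

**Mode A (hazard-driven)** validates the estimator: decline status switches on
at a random interval (probability 0.15/interval), and the per-interval event
probability follows the discrete logistic link `h = expit(logit(h0) + β·cd)`
with `h0 = 0.05` and true `β = ln 5`.  The logistic link is used because the
exact discrete-ties likelihood estimates the odds parameter; generating with a
hazard-ratio link would make the target parameter differ from `β` by a
link-mismatch bias at usable baseline hazards.  At `β = 0` the two links
coincide, so null calibration is link-independent.  Scores are made consistent
with the truth by expressing decline on two of the three burdened tests from
onset onward.

**Mode B (tumor-driven)** exercises the causal narrative: events are drawn
from the baseline hazard alone, and burdened-test scores drop `delta_dec` from
one interval (`lead_intervals`) before the event.

Censoring: per-interval dropout (0.03), administrative study-end censoring for
a late-enrolled fraction (0.15, horizon uniform on months 6–21), and
completion at month 24.  Reproducibility: a single seed split into
per-subject `SeedSequence` streams, so enlarging a cohort never perturbs
earlier subjects' draws; identical parameters and seed give byte-identical
tables.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: item-level test content, floor/ceiling effects,
practice saturation over many repeats (later visits re-earn the first-retest
gain, slightly elevating long-run simulated scores), medication and mood
covariates, tumor-location structure in which tests are burdened, and any
dependence of dropout on cognition (censoring is non-informative by
construction).  The classifier also has an irreducible noise-driven
false-positive rate (roughly 5–10% per visit under the null for the default
criterion — a property of the RCI ≤ −1, two-of-three rule itself, visible in
any application of it), so simulated decline onsets are reproduced exactly
only up to occasional earlier noise flags; the consistency test conditions
accordingly.

## Problem sizes

The validation studies use cohorts chosen to make Monte-Carlo error small
relative to the acceptance bands: parameter recovery uses 100 replicates of
400 patients; null calibration 500 replicates of 100; RCI null behavior
10,000 scored pairs against a 2,000-control norm; selection sensitivity 200
patients; oracle agreement 20 random toy datasets of up to 6 subjects plus
one closed-form example.

## Known limitations

- The discrete fit's standard errors are asymptotic Wald; profile-likelihood
  intervals are not implemented.
- The c-index definition above is one of several in use for time-dependent
  covariates; values are not comparable across definitions.
- No competing risks, frailty, or performance-status covariates; patients are
  excluded (and reported) rather than partially used when the month 0 or 3
  assessment is missing.
- The packaged study table stores age bands and location labels as printed;
  no midpoint imputation or relabelling is performed, and two published
  footnote letters collide (the impairment-column superscript reuses the
  end-reason letter); the fixture follows the per-row letters.
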