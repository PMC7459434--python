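# Methods

## The prediction problem

The package treats retrospective recurrence surveillance as person-month
classification. For each patient, months inside the valid claims window are
labelled 0 before the second breast cancer event (SBCE) and 1 from the event
month onward; a gradient-boosted ensemble maps month-level features to the
probability of being post-event, and person-level presence/timing calls are
derived by thresholding the probability series. The method deliberately uses
the *entire* claims record — including months after the candidate event — so
it is a retrospective auditing tool, not a prospective predictor: the
`until_g` (months to next occurrence) features look forward by design.

Assumptions: claims histories are reasonably complete over follow-up; the
event leaves a footprint in coded utilisation (work-up shortly before the
recorded event month, treatment afterwards); one patient's months are
exchangeable with another's given the features (no within-patient
correlation is modelled beyond the engineered history features).

## Windows, filters, and aggregation

- **Valid window** — starts with the first full calendar month beginning at
  least 6 months after diagnosis; ends at follow-up end, truncated 3 months
  before a non-breast second primary and 1 month before a second breast
  event after the first. The censoring offsets (−3, −1) are applied in
  month-index arithmetic because the panel's resolution is monthly.
- **Calendar placement** — the deidentified data model stores only days
  since diagnosis; a synthetic jitter (uniform day-of-year within the
  diagnosis year) places each patient on a calendar grid for month binning.
  Month frequencies are therefore proportional to month lengths. The
  fractional part of age at diagnosis is redrawn uniformly, since the true
  birthday offset is not recoverable; recomputed ages may differ from the
  source by under a year. A jitter-free `relative` bin mode (30.4375-day
  months since diagnosis) is available for data without calendar placement.
- **Eligibility** — patients need at least one in-window claim, and event
  patients at least one in-window claim on or after the event day; every
  exclusion is logged with a reason, never silent.
- **Deduplication and rare codes** — any code counts at most once per
  patient-day. A diagnosis code is kept only if at least one patient has it
  on two separate days; the rule reads literally on diagnosis codes and so
  does not touch procedure codes (a switch extends it). It is evaluated on
  deduplicated claims *before* window truncation; evaluating it after
  truncation would drop slightly more codes for heavily censored cohorts.

## Features

Per code group: the monthly count; months since the last strictly-prior
in-window occurrence and until the next strictly-later one, with −1 when no
such occurrence exists (the current month never feeds since/until — its
information is already in the count); and the fraction of strictly-prior
in-window months containing the group, defined as 0 in the window's first
month (−1 is reserved for since/until). The prior-month denominator counts
all in-window months before the current one, including zero-claim months;
months outside the window never count. Registry covariates are one-hot
encoded with stored category order (the encoding is a package choice);
months since diagnosis and age-in-month (age at diagnosis + month/12) are
numeric. Diagnosis calendar year is available as an optional feature,
default off.

## Model and tuning

XGBoost binary classification (`tree_method="hist"`, single thread,
logloss), wrapped in a scikit-learn estimator. The 80:20 split and the
5 cross-validation folds are assigned at the *patient* level, stratified by
event status, so no patient's months straddle a fold — month-level rows from
one patient are strongly dependent and would otherwise leak. The default
grid searches tree depth {3, 6} × learning rate {0.1, 0.3}, with the number
of boosting rounds picked by early stopping on held-out-fold AUC (cap 400,
patience 25); the default fixed setting (depth 3, rate 0.1, 300 rounds) is
used when no grid is requested. Class-imbalance reweighting
(`scale_pos_weight`) is available but off by default. Feature importance is
split frequency across trees, descending, ties broken by feature name. All
randomness funnels through one master seed with per-stage derived
substreams, recorded in the run report.

## Person-level inference

A patient is positive at threshold PT if any monthly probability *strictly*
exceeds PT — strict, because tree ensembles can emit probabilities exactly
equal to a grid value. The default timing rule is first exceedance; the
alternative rule (month of maximum increase between adjacent probabilities,
earliest maximiser on ties, shift-invariant by construction) is implemented
and labelled in the output, since both conventions are in circulation for
this method and they can disagree. A single-month series has no adjacent
pair; the max-increase rule then returns that month. The default grid is
0.10–0.75 in steps of 0.05.

## Evaluation

Month-level ROC/AUC via the trapezoid rule (equal to Mann–Whitney
concordance with ties at one half; the test suite cross-checks this against
an O(n²) pairwise oracle). Person-level sensitivity, specificity, PPV and
NPV per threshold, with zero-denominator ratios reported as absent rather
than zero. Timing differences are predicted − observed month over correctly
detected event patients (negative = early prediction). Kaplan–Meier curves
(via lifelines, cross-checked against hand-computed product-limit values)
compare observed event times among event patients with predicted times,
censoring non-predicted patients at last follow-up; ties process events
before censorings, the standard product-limit convention. Emitted tables are
rounded to 3 decimals; internal values are unrounded.

## The simulator

`SimConfig` defaults encode the study conditions the pipeline is meant to
face: cumulative event probability 0.25 by month 168, realised through a
discrete monthly hazard with geometric decay 0.94 (events front-loaded, as
with clinical recurrence) multiplied by 2.0 for stage II and 1.6/1.3 for
ER/PR-negative status, the baseline root-found so the covariate-mixture
incidence hits the target exactly; gamma follow-up matched to claim-month
summaries (non-event mean 31.5, SD 19.2; event patients gain ~19 extra
post-event months, lengthening their records); 8 diagnosis + 12 procedure
synthetic code groups with Poisson monthly rates cycling 0.6/0.4/0.25/0.15.
Five designated signal groups (rare at baseline, 0.12/month) carry the
event signature: ×3 in the two months before the event (diagnostic work-up,
which is what enables early — negative — timing errors) and
1 + 7·0.9^(months since event) from the event month (treatment signature
decaying toward baseline, so discrimination degrades long after the event).
Monthly counts are expanded to day-level coded claims (uniform days within
the month, two codes per group) so parsing, deduplication, rare-code
filtering and grouping are exercised. With these defaults roughly 19% of
patients have an observed event. `SimConfig.null()` sets all multipliers
and hazard ratios to 1, yielding a cohort whose claims and covariates are
independent of the event.

What the simulator does **not** emulate: real ICD-9/CPT semantics, coding
drift over calendar time, coverage gaps, correlated group firing, or
overdispersed counts. Passing end-to-end tests therefore demonstrates that
the machinery recovers a planted signal of plausible shape, not that the
reported clinical operating characteristics transfer to real claims.

## A structural note on null cohorts

Even with no claims signal whatsoever, month-level discrimination does not
collapse to exactly 0.5: post-event months are by definition later months of
follow-up, so any time-tracking feature (months since diagnosis, or
end-of-window proximity reflected in `until_g = −1`) carries genuine label
information under every generative null. On the default null cohort, month
index alone scores about 0.67 AUC and the full model's out-of-fold AUC sits
at or below that floor — which is precisely the leakage diagnostic: the
claims-derived features add nothing beyond the unavoidable time trend. The
leakage test in the suite is framed accordingly (full model vs
time-and-registry-only model on a null cohort).

## Problem sizes

The shipped tests and the acceptance script run the full pipeline on
600-patient cohorts (~120 test patients), simulator calibration checks on
3000-patient registry draws, and oracle equivalences on hundreds of small
random panels — sizes chosen so the whole suite completes in well under a
minute while keeping Monte-Carlo error small relative to the asserted
margins.

## Known limitations

- Monthly resolution bounds timing accuracy at ±1 month around calendar
  boundaries; the jitter additionally smears day-level signal across
  adjacent calendar months.
- The rare-code filter is cohort-dependent: the same code can survive in one
  cohort and be dropped in another, so fitted models should only score
  panels built with the same preprocessing run.
- Probabilities are used as scores; no calibration is performed, so PT
  values are operating points, not risk estimates.
- Persisted models use pickle; load only artifacts you produced.
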