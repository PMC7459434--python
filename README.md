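# recurmine

Population-based cancer registries record primary diagnoses and deaths, but
not recurrences. `recurmine` implements a claims-mining method for detecting
the occurrence **and timing** of second breast cancer events (SBCE — a
recurrence of the original tumour or a new breast primary) from linked
registry records and longitudinal medical claims, for registry operators and
epidemiologists who need recurrence information without chart abstraction of
every case.

## Method

The person-level time-to-event problem is recast as binary classification of
**person-months**: every calendar month in a patient's valid claims window
(starting 6 months after diagnosis, censored 3 months before any non-breast
second primary and 1 month before any second breast event) is labelled
pre-SBCE (0) or post-SBCE (1, including the event month). For each month *t*
and each clinical code group *g* (ICD-9-CM diagnosis and CPT/HCPCS procedure
codes, deduplicated per day and summed per calendar month) the features are

- `count_g(t)` — claims of group *g* in month *t*,
- `since_g(t)` — months since the last prior occurrence of *g* (−1 if none),
- `until_g(t)` — months until the next later occurrence of *g* (−1 if none),
- `frac_g(t)` — fraction of prior in-window months containing *g*,

plus baseline registry covariates (stage, grade, ER/PR status, site), months
since diagnosis, and age in the month. A gradient-boosted tree ensemble
(XGBoost) is trained on an 80:20 patient-level stratified split with 5-fold
patient-level cross-validation, producing a monthly probability *p(t)* of
being post-SBCE. Person-level inference applies a probability threshold PT:
a patient is called positive if any *p(t)* > PT, and the predicted event
month is the first month with *p(t)* > PT (a max-adjacent-increase rule is
also provided). Evaluation reports month-level ROC/AUC, per-threshold
sensitivity/specificity/PPV/NPV over the grid PT = 0.10 … 0.75, signed
timing errors, and observed-vs-predicted Kaplan–Meier curves.

Because the linked clinical data that motivated the method are restricted,
the package ships a calibrated synthetic-cohort simulator (`recurmine.simulate`)
producing registry records and day-level coded claims with a pre-event
diagnostic-workup bump and a decaying post-event treatment signature, so the
whole pipeline is testable end to end.

## Worked example

```python
from recurmine import RunConfig, SimConfig, run_all

result = run_all(RunConfig(seed=1, sim=SimConfig(n_patients=600)))
print(f"month-level AUC: {result.report['month_auc']:.3f}")
table = result.evaluation.threshold_table
row = table[table.threshold == 0.5].iloc[0]
print(f"PT=0.5: sensitivity {row.sensitivity:.3f}, specificity {row.specificity:.3f}, "
      f"ppv {row.ppv:.3f}, npv {row.npv:.3f}")
timing = result.evaluation.timing_table
trow = timing[timing.threshold == 0.5].iloc[0]
print(f"timing diff (months): median {trow.median_diff}, mean {trow.mean_diff:.2f}")
```

prints

```
month-level AUC: 0.999
PT=0.5: sensitivity 1.000, specificity 0.969, ppv 0.889, npv 1.000
timing diff (months): median 0.0, mean 0.62
```

i.e. on a 600-patient synthetic cohort (~20% with an event, held-out test
set of 120 patients) the classifier separates pre- from post-event months
almost perfectly; at PT = 0.5 it recovers every event patient while flagging
3% of event-free ones, and the predicted event month matches the true one in
the median case (a positive mean means predictions land slightly late on
average).

The same run is available from the shell:

```bash
recurmine simulate --seed 3 --n-patients 600 --out-dir cohort/
recurmine preprocess --registry cohort/registry.csv --claims cohort/claims.csv \
    --groups cohort/groupmap.csv --out panel.csv
recurmine train   --panel panel.csv --registry cohort/registry.csv --groups cohort/groupmap.csv --out model.bin
recurmine predict --model model.bin --panel panel.csv --registry cohort/registry.csv \
    --groups cohort/groupmap.csv --out probs.csv
recurmine infer    --probs probs.csv --out persons.csv
recurmine evaluate --probs probs.csv --registry cohort/registry.csv --out report.json
```

or as one reproducible run: `recurmine run --config run.yaml` (see
`RunConfig` for the schema).

## Input formats

Three UTF-8 CSVs, pre-linked by `patient_id` (all dates are stored as days
since the primary diagnosis; see `recurmine/cohort.py` for the full column
lists):

- `registry.csv` — one row per patient: covariates, gold-standard event
  day, censoring days, end of follow-up;
- `claims.csv` — one row per claim line: `patient_id, day, system
  (ICD9CM|CPT|HCPCS), code, code_class (diagnosis|procedure)`;
- `groupmap.csv` — `code, group_id, code_class`, mapping codes to clinical
  groups. A synthetic example map is produced by `recurmine simulate`; with
  real data supply your own grouping.

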