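# msaccrual

Configurable annotation of confirmed disability-accrual events — RAW,
PIRA, PIRA with relapse during confirmation, and undefined worsening — in
longitudinal EDSS trajectories from people with relapsing multiple
sclerosis.

## Why

Whether an EDSS increase counts as disability accrual, and whether it is
attributed to relapse-associated worsening (RAW) or progression
independent of relapse activity (PIRA), depends on many definitional
choices that vary across studies: the reference ("baseline") handling,
confirmation requirements, the relapse-proximity window, re-baselining
rules, and the treatment of ambiguous events. `msaccrual` implements a
single deterministic annotation engine parameterized over a definition
space of **1440** variants (with **360** and **144** variants remaining
under recently proposed *harmonized* and *standardized* PIRA criteria),
so that researchers can state a definition precisely, sweep whole
definition grids, and quantify how much their event rates and RAW/PIRA
attributions depend on these choices.

The core rules, for one follow-up period scanned left to right against a
maintained reference score *r*:

* **candidate**: score *s* ≥ *r* + Δmin(*r*), with Δmin = 1.5 / 1.0 / 0.5
  for *r* = 0 / 0 < *r* < 5.5 / *r* ≥ 5.5;
* **confirmation**: none, 12/24 weeks (all values or only the last value
  of the interval), or sustained to end of follow-up (optionally with a
  minimal post-event duration); the confirmation condition is score ≥
  *r* + Δmin, and the confirmed **event score** is the minimum over
  candidate and confirmation scores — an increase 3.0 → 4.5 confirmed by
  4.0 is an event with score 4.0;
* **classification**: RAW inside a relapse window (e.g. 30 days before
  to 90 days after a relapse), PIRA outside with relapse-free
  confirmation, *PIRA with relapse during confirmation* when only the
  confirmation touches a window, UNDEFINED at post-relapse re-baselining
  assessments;
* **re-baselining**: the confirmed event score, post-relapse residual
  disability (unconfirmed), and optionally a roving reference confirmed
  at the next visit.

## Worked example

Simulate a 200-patient registry-like cohort, annotate it under a
12-week-last-confirmed, roving-baseline definition, and summarize:

```bash
msaccrual simulate --seed 7 --out cohort
printf 'confirmation_mode: w12_last\nbaseline_mode: roving_next_confirmed\nraw_window: [30, 90]\n' > definition.yaml
msaccrual annotate --config definition.yaml \
    --assessments cohort/assessments.csv --relapses cohort/relapses.csv \
    --out events.csv
head -4 events.csv
```

```
patient_id,period_index,detection_day,event_type,reference_score,event_score,delta_edss,confirmation_days,merged_from
sim00002,1,282,PIRA_RELAPSE_DURING_CONFIRMATION,4.0,5.0,1.0,389,1
sim00002,1,523,UNDEFINED,5.0,6.5,1.5,638,1
sim00004,1,1846,RAW,1.5,2.5,1.0,1960,1
```

Patient `sim00002` worsens at day 282 (4.0 → 5.0 confirmed), but the
confirming assessment at day 389 sits in a relapse window, so the event
is PIRA *with relapse during confirmation*; the later worsening at day
523 is read at a post-relapse re-baselining assessment and is therefore
*undefined*.

```bash
msaccrual metrics summarize --config definition.yaml \
    --assessments cohort/assessments.csv --relapses cohort/relapses.csv | head -5
```

```
n_periods: 200
n_events: 74
total_delta: 80.5
overall_event_rate: 0.305
km_median_years: inf
```

Under this definition 30.5% of follow-up periods have at least one event
(74 events, 80.5 EDSS points in total); fewer than half the periods ever
have an event, so the Kaplan-Meier median time to first event is not
reached (`inf`). Sweeping the 144 definitions compatible with the
standardized PIRA proposal shows how much the numbers move with the
remaining free choices:

```bash
msaccrual grid run --preset standardized \
    --assessments cohort/assessments.csv --relapses cohort/relapses.csv \
    --out grid.csv --summary-json summary.json
msaccrual metrics compare --results grid.csv --axis baseline_mode \
    --value-a fixed --value-b roving_next_confirmed --seed 1
```

```
overall_event_rate    {'min': 0.185, 'mean': 0.287, 'max': 0.305}
count_contribution_PIRA {'min': 0.459, 'mean': 0.515, 'max': 0.795}
{"axis": "baseline_mode", "metric": "overall_event_rate",
 "mean_difference": -0.0108..., "p_value": 0.0002, "n_pairs": 72}
```

On this synthetic cohort the overall event rate still spans 18.5%–30.5%
across the 144 "standardized" definitions, PIRA's share of events spans
46%–80%, and a roving baseline detects significantly more events than a
fixed one (paired sign-flip permutation test over the 72 matched
definition pairs).

The same operations are available as a library: `segment_followups` /
`subgroup_filter` (eligibility screening), `annotate_followup` (the
engine), `enumerate_full_grid` and friends, `summarize_cohort` /
`summarize_grid` / `paired_parameter_test`, and `generate_cohort` (the
simulator with ground truth). File schemas are documented in
`docs/formats.md`, the science in `docs/methods.md`.

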