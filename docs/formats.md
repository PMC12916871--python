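# File formats

All tables are UTF-8, comma-separated CSV with dot decimals; time is
integer days relative to the follow-up-period start. Results go to
files; logs go to stderr.

## Assessments

`assessments.csv` — one row per EDSS assessment.

| column       | type  | notes                                   |
|--------------|-------|-----------------------------------------|
| patient_id   | str   | opaque identifier                       |
| period_index | int   | ≥ 1; one patient may have several periods |
| day          | int   | ≥ 0, strictly increasing within a period |
| edss         | float | 0.0 or 1.0–10.0 in 0.5 steps (0.5 itself is an error in strict mode, a warning in permissive mode) |

Duplicate days keep the last record (with a warning).

## Relapses

`relapses.csv` — one row per relapse onset.

| column       | type | notes                                        |
|--------------|------|----------------------------------------------|
| patient_id   | str  |                                              |
| period_index | int  |                                              |
| day          | int  | may be negative (context relapse before the period start) or beyond the last assessment |

A missing relapse file is treated as a relapse-free cohort (warning).

## Annotations

`annotations.csv` — one row per detected event.

| column            | type  | notes                                  |
|-------------------|-------|----------------------------------------|
| patient_id        | str   |                                        |
| period_index      | int   |                                        |
| detection_day     | int   | day of the candidate assessment        |
| event_type        | str   | RAW, PIRA, PIRA_RELAPSE_DURING_CONFIRMATION, UNDEFINED |
| reference_score   | float | baseline the event was measured against |
| event_score       | float | confirmed score (minimum over candidate + confirmation) |
| delta_edss        | float | event_score − reference_score          |
| confirmation_days | str   | semicolon-joined day list (empty for unconfirmed definitions) |
| merged_from       | int   | constituent events after merging (1 = unmerged) |

## Ground truth (simulator)

`ground_truth.csv` — one row per latent component.

| column     | type  | notes                                         |
|------------|-------|-----------------------------------------------|
| patient_id | str   |                                               |
| kind       | str   | relapse, residual, progression                |
| day        | int   |                                               |
| delta      | float | EDSS step size (empty for kind=relapse)       |

## Definition configuration

YAML or JSON mapping; keys and spellings are the
`msaccrual.DefinitionConfig` fields, e.g.

```yaml
event_merging: false
undefined_mode: rebaselining_only    # never | all | end
undefined_constraint: greater_only   # equal_or_greater | unconstrained
baseline_mode: fixed                 # roving_next_confirmed
confirmation_mode: w12_last          # none | w12_all | w24_all | w24_last
                                     # | sustained | sustained_min12 | sustained_min24
raw_window: [30, 90]                 # days (pre, post) relapse
allow_relapse_in_confirmation: false # true only with *_last modes
eligibility:                         # optional screening thresholds
  min_span_days: 730
  min_assessments: 3
  max_gap_days: 365
```

The machine-readable JSON Schema is available as
`msaccrual.DefinitionConfig.model_json_schema()`.

## Grid results and manifests

`grid run` writes one row per definition: the six axis columns
(`raw_window` as `"pre/post"`) followed by the flattened metrics of
`msaccrual.CohortSummary.as_row()`. Every CLI run writes a
`*.manifest.json` with the command, config hash, SHA-256 digests of the
inputs, package version, seeds and a timestamp.
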