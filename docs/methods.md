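# Methods

## The problem

In relapsing multiple sclerosis (RMS), disability measured on the Expanded
Disability Status Scale (EDSS, ordinal 0–10 in 0.5 steps with no 0.5
level) accumulates through two mechanisms: incomplete recovery from
relapses (relapse-associated worsening, RAW) and worsening independent of
relapse activity (PIRA). Whether a confirmed EDSS increase counts as an
event at all — and whether it is attributed to RAW or PIRA — depends on a
surprisingly large space of definitional choices: magnitude thresholds,
fixed versus roving baselines, confirmation requirements, the size of the
relapse-proximity window, re-baselining rules, handling of ambiguous
events and of sequential events. `msaccrual` implements one deterministic
annotation engine parameterized over that space, so that any study's
definition can be stated as a configuration object and whole definition
grids can be swept for sensitivity analysis.

## The annotation algorithm

Time is integer days from the start of a follow-up period ("12 weeks" =
84 days, "24 weeks" = 168 days, "1 year" = 365 days, "24 months" = 730
days — fixed conversions for reproducibility). The engine scans the
assessments of one period left to right while maintaining a reference
score, initialized at the first assessment.

**Candidate test.** An assessment with score *s* against reference *r* is
a worsening candidate when *s* ≥ *r* + Δmin(*r*), with Δmin = 1.5 for
*r* = 0, 1.0 for 0 < *r* < 5.5, and 0.5 for *r* ≥ 5.5.

**Confirmation.** Eight modes. `none` accepts the candidate alone.
`w12_all`/`w24_all` require every assessment after the candidate up to and
including the first one at ≥ 84/168 days to satisfy the confirmation
condition (score ≥ *r* + Δmin; left tolerance 0, right tolerance
unbounded). `w12_last`/`w24_last` check only that first assessment at
≥ 84/168 days. `sustained` requires every remaining assessment to
qualify; `sustained_min12`/`sustained_min24` additionally require the last
assessment to lie ≥ 84/168 days after the candidate. The confirmed
**event score** is the minimum over the candidate and all confirmation
scores (confirmation type "minimum"), and the event's ΔEDSS is event
score minus reference — so an increase 3.0 → 4.5 confirmed by 4.0 is an
event with score 4.0 and ΔEDSS 1.0. Whenever a confirmation is required,
a candidate with no eligible confirmation assessment (e.g. at the final
visit) is not an event.

**Classification.** Relapses define proximity ("RAW") windows — (pre,
post) days around each relapse, inclusive on both ends, unioned across
relapses. A confirmed candidate is RAW if detected inside a window; PIRA
if detection and all confirmation assessments are outside; *PIRA with
relapse during confirmation* if only the confirmation touches a window
(unless the definition explicitly allows relapses during confirmation, in
which case the event is plain PIRA — legal only for last-confirmed
modes); and UNDEFINED when the worsening is read at a *post-relapse
re-baselining assessment*.

**Re-baselining.** After a confirmed event the event score becomes the
new reference. After a relapse, the first assessment beyond all RAW
windows is the re-baselining assessment: residual disability (score above
the reference) becomes the new reference *without* confirmation. With a
roving baseline, a score strictly below the reference becomes the new
reference once the immediately following assessment does not exceed it
(next-confirmed); an unconfirmed variant that adopts the lower score
immediately is available as an engine extension (`roving_confirmation =
"immediate"`).

**Undefined-event handling.** Four modes govern re-baselining
assessments: `rebaselining_only` checks them as UNDEFINED candidates
(gated by the undefined constraint, then confirmed like any candidate);
`never` skips the check entirely; `all` and `end` extend UNDEFINED
eligibility to other assessments, where RAW/PIRA classification takes
precedence. Two deliberate consequences of this design:

* Re-baselining at a re-baselining assessment always follows the
  residual-disability rule, whether or not an UNDEFINED event was
  recorded there. This makes `never` and `rebaselining_only` provably
  identical on their RAW/PIRA output — they differ only in the UNDEFINED
  annotations — which is the documented intent of the `never` option.
* Because every confirmed candidate away from a re-baselining assessment
  receives RAW, PIRA or PIRA-with-relapse-during-confirmation (the
  ambiguous-confirmation case carries its own label rather than falling
  through to UNDEFINED), the `all` and `end` modes coincide with
  `rebaselining_only` in this engine. They are retained as distinct grid
  cells because the definition space counts them as options; engines
  with stricter PIRA criteria would separate them.

The undefined constraint (`greater_only` / `equal_or_greater` /
`unconstrained`) is implemented as a comparison of the candidate score
with the current reference, applied on top of the magnitude rule, and is
isolated in a single predicate (`_undefined_gate`). Since the magnitude
rule already forces the candidate strictly above the reference, the three
readings admit the same candidates here; the predicate exists so an
alternative interpretation can be swapped in without touching the scan.

**Event merging.** When enabled, consecutive events of the same type
whose references chain (the later event's reference equals the earlier
one's event score) are fused, with ΔEDSS = last event score − first
reference. Merging is broken by stabilization: any intervening assessment
below the earlier event's confirmation threshold, or a plateau of
identical scores lasting longer than the maximal repetition time (set to
the post-relapse window size, in days). There is no maximal merge
distance.

**Standardized confirmation handling.** The engine extension
`confirmation_score_handling = "skip_relapse_proximal"` removes
relapse-proximal assessments from the confirmation sequence before any
rule is applied — the confirmation implementation of the recently
proposed "standardized" criteria. It is not an axis of the definition
grid, so the standardized *sub-grid* below keeps the default handling.

## The definition grid

The full grid is the product of six free axes — event merging (2) ×
undefined handling (4) × undefined constraint (3) × baseline (2) ×
confirmation (8 modes + 2 relapse-allowed variants of the last-confirmed
modes = 10) × RAW window ∈ {(30,30), (30,90), (90,90)} (3) — 1440
definitions, enumerated in stable lexicographic order. Two sub-grids are
*reconstructed* from published harmonization proposals via the
factorizations 1440/4 = 360 (harmonized: fixes event merging and
baseline; defaults: merging off, roving baseline) and 1440/10 = 144
(standardized: fixes the confirmation combination; default: 12-week
all-confirmed, relapses not allowed). The exact fixed values the
proposals mandate are held in their supplements, so both presets accept
overrides.

## Eligibility screening

A registry-style screen: follow-up span ≥ 730 days, ≥ 3 EDSS scores, and
≥ 1 assessment per year implemented as a rolling rule (every
inter-assessment gap ≤ 365 days) — stricter than any calendar-year
reading and deterministic. Timelines are split at gaps > 365 days into
maximal runs, each screened separately, so a patient can contribute
several periods; this greedy-from-the-left decomposition is exactly the
set of maximal eligible windows because an over-long gap can never be
interior to one. Relapses within 90 days (the largest post-relapse
window) before a period's first assessment are retained as context with
negative days, since their windows can cover early assessments.
Subgroups: `with_relapse` (≥ 1 relapse inside the span) and `dense`
(≥ 4 assessments, all gaps ≤ 183 days); both operate on already-eligible
periods, so the 24-month minimum continues to hold inside subgroups.

## Cohort metrics

Rates use follow-up periods as the denominator. Per-type contributions
are shares of the total event count and of the total ΔEDSS (sum of event
deltas); both sum to 1 whenever events exist. Exclusive rates (PIRA-only,
RAW-only) use event-bearing periods as the denominator. Median time to
first event is a Kaplan-Meier estimate (lifelines) on the detection day
of the first event of any type, censored at the last assessment day,
reported in years (day/365); undefined events start the clock by default
and are excludable by flag. Note one numerical edge: with an even number
of fully observed times the survival curve touches 0.5 exactly and the
product-limit median is representation-sensitive at machine precision;
the KM-equals-naive-median identity is therefore exercised at odd sample
sizes.

Axis comparisons pair definitions identical on all other axes and apply
a two-sided paired sign-flip permutation test to the per-pair metric
differences (statistic: mean difference). The 2^n sign-flip null is
enumerated exactly for ≤ 12 pairs and sampled (seeded, via SciPy) above
that; differences are sorted first, which makes the p-value invariant to
pair ordering without changing the statistic or the null. Leave-one-out
sensitivity subsets are formed for every treatment label carried by at
least 100 periods.

## The synthetic cohort generator

Real registry data cannot be redistributed, so testing runs on simulated
cohorts with known ground truth. Latent disability is a step function —
chosen over a drift model precisely so that true events are unambiguous
and recovery can be asserted exactly. Components: baseline EDSS from a
registry-like categorical distribution (median 2.0); relapses as a
Poisson process (default 0.12/year, leaving roughly 40% of 2–8-year
periods with ≥ 1 relapse); each relapse leaves a permanent +1.0 residual
with probability 0.4 and, by default, a transient +1.0 peak resolving in
60 days (inside every tested RAW window) to exercise the window logic;
relapse-independent progression as a second Poisson process (default
0.05/year) of permanent +1.0 steps. Visits sample the latent value every
120 ± 40 days (≈ 13 visits over a median-length follow-up), with
probability `noise_p` (default 0.1) of a ±0.5 measurement jitter; every
emitted score is clamped to the valid EDSS grid, with the nonexistent 0.5
level snapping to 0.0.

What the generator does *not* emulate: EDSS-dependent relapse rates and
visit schedules, rater disagreement beyond ±0.5, informative censoring,
treatment effects, and the long-tailed relapse-count distribution of real
registries. Passing tests therefore demonstrate correctness of the
annotation logic under the stated data model, not calibration of event
rates to any real cohort.

The recovery guarantee used in testing: with zero noise, dense visits
(30-day intervals), no confirmation, a fixed baseline, baselines off 0
and a staircase below the EDSS ceiling (so every +1.0 step clears the
magnitude rule), the engine detects exactly one PIRA event per
visit-interval containing ≥ 1 true progression step outside all RAW
windows.

## Verification strategy

Beyond unit tests of every rule, the engine is checked event-for-event
against an independent brute-force annotator (tests/oracle.py) that
recomputes window membership, re-baselining status and confirmation sets
by explicit enumeration, on 10,000 random small periods across 100 random
definitions, and against four structural invariants on 1,000 random
periods each: relapse-free periods yield only PIRA; `never` equals
`rebaselining_only` on RAW/PIRA with zero UNDEFINED; no
relapse-during-confirmation label without a confirmation interval; and
first-event monotonicity across confirmation strictness (24-week
all-confirmed ⇒ 12-week all-confirmed ⇒ unconfirmed) under a fixed
baseline. Problem sizes (period lengths 4–10 visits, the counts above)
keep the whole suite in a few seconds while covering every branch of the
scan.

## Known limitations

* The `all`/`end` undefined modes and the three undefined constraints
  are output-equivalent in this engine (see above); sweeps over those
  axes measure definitional redundancy, not variation.
* The harmonized/standardized sub-grid presets are reconstructions; the
  proposals' exact fixed values should be supplied as overrides when
  known.
* Confirmation tolerances are fixed (left 0, right unbounded) and the
  magnitude rule is not a free axis.
* The generator's step model cannot represent gradual sub-0.5/year
  worsening that only crosses the magnitude threshold through
  accumulation between visits.
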