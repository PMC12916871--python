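"""Brute-force reference annotator used to cross-check the engine.

Deliberately naive: every per-assessment fact (relapse-window membership,
re-baselining status, confirmation sets) is recomputed from scratch by
explicit enumeration over relapses and assessments, with no shared helpers
from the engine beyond the plain data types.  Slow but simple enough to be
audited line-by-line against the written definition.
"""

from __future__ import annotations

from msaccrual.data_model import (
    AnnotatedEvent,
    DefinitionConfig,
    EventType,
    FollowUpPeriod,
)

_DISTANCES = {"w12": 84, "w24": 168, "min12": 84, "min24": 168}


def required_increase(reference: float) -> float:
    if reference == 0.0:
        return 1.5
    if reference < 5.5:
        return 1.0
    return 0.5


def relapse_proximal(day: int, period: FollowUpPeriod, config: DefinitionConfig) -> bool:
    pre, post = config.raw_window
    for r in period.relapses:
        if r.day - pre <= day <= r.day + post:
            return True
    return False


def rebaseline_assessment_days(period: FollowUpPeriod, config: DefinitionConfig) -> set[int]:
    post = config.raw_window[1]
    days = set()
    for r in period.relapses:
        for a in period.assessments:
            if a.day > r.day + post and not relapse_proximal(a.day, period, config):
                days.add(a.day)
                break
    return days


def check_confirmation(i, reference, period, config):
    """Returns (confirmed, event_score, confirmation_days, relapse_flag)."""
    cand = period.assessments[i]
    thr = reference + required_increase(reference)
    if config.confirmation_mode == "none":
        return True, cand.edss, (), False
    later = period.assessments[i + 1 :]
    if config.confirmation_score_handling == "skip_relapse_proximal":
        later = [a for a in later if not relapse_proximal(a.day, period, config)]
    mode = config.confirmation_mode
    if mode in ("w12_all", "w12_last", "w24_all", "w24_last"):
        dist = _DISTANCES[mode[:3]]
        conf = None
        for k, a in enumerate(later):
            if a.day >= cand.day + dist:
                conf = [a] if mode.endswith("last") else list(later[: k + 1])
                break
        if conf is None:
            return False, None, (), False
    else:  # sustained family
        if len(later) == 0:
            return False, None, (), False
        if mode == "sustained_min12" and later[-1].day < cand.day + 84:
            return False, None, (), False
        if mode == "sustained_min24" and later[-1].day < cand.day + 168:
            return False, None, (), False
        conf = list(later)
    for a in conf:
        if a.edss < thr:
            return False, None, (), False
    score = cand.edss
    for a in conf:
        score = min(score, a.edss)
    flag = any(relapse_proximal(a.day, period, config) for a in conf)
    return True, score, tuple(a.day for a in conf), flag


def oracle_annotate(period: FollowUpPeriod, config: DefinitionConfig) -> list[AnnotatedEvent]:
    A = period.assessments
    if len(A) < 2:
        return []
    rb_days = rebaseline_assessment_days(period, config)
    roving = config.baseline_mode == "roving_next_confirmed"
    events: list[AnnotatedEvent] = []
    reference = A[0].edss
    pending = None  # roving candidate awaiting next-visit confirmation

    for i in range(1, len(A)):
        a = A[i]
        if pending is not None:
            if a.edss <= pending and pending < reference:
                reference = pending
            pending = None
        thr = reference + required_increase(reference)

        def lower(score):
            nonlocal pending, reference
            if roving and score < reference:
                if config.roving_confirmation == "immediate":
                    reference = score
                else:
                    pending = score

        if a.day in rb_days:
            if config.undefined_mode != "never" and a.edss >= thr:
                gate = {
                    "greater_only": a.edss > reference,
                    "equal_or_greater": a.edss >= reference,
                    "unconstrained": True,
                }[config.undefined_constraint]
                if gate:
                    ok, score, cdays, _ = check_confirmation(i, reference, period, config)
                    if ok:
                        events.append(
                            AnnotatedEvent(
                                a.day, EventType.UNDEFINED, reference, score,
                                round(score - reference, 1), cdays,
                            )
                        )
            if a.edss > reference:
                reference = a.edss
            else:
                lower(a.edss)
            continue

        if a.edss >= thr:
            ok, score, cdays, flag = check_confirmation(i, reference, period, config)
            if ok:
                if relapse_proximal(a.day, period, config):
                    etype = EventType.RAW
                elif (
                    flag
                    and not config.allow_relapse_in_confirmation
                    and config.confirmation_score_handling == "use_all"
                ):
                    etype = EventType.PIRA_RELAPSE_DURING_CONFIRMATION
                else:
                    etype = EventType.PIRA
                events.append(
                    AnnotatedEvent(
                        a.day, etype, reference, score, round(score - reference, 1), cdays
                    )
                )
                reference = score
                pending = None
                continue
        lower(a.edss)

    if not config.event_merging:
        return events

    merged: list[AnnotatedEvent] = []
    for ev in events:
        if merged and _mergeable(merged[-1], ev, period, config):
            prev = merged[-1]
            merged[-1] = AnnotatedEvent(
                prev.detection_day, prev.event_type, prev.reference_score,
                ev.event_score, round(ev.event_score - prev.reference_score, 1),
                prev.confirmation_days + ev.confirmation_days,
                prev.merged_from + ev.merged_from,
            )
        else:
            merged.append(ev)
    return merged


def _mergeable(prev, nxt, period, config) -> bool:
    if prev.event_type != nxt.event_type or nxt.reference_score != prev.event_score:
        return False
    thr = prev.reference_score + required_increase(prev.reference_score)
    run_score, run_start = None, None
    for a in period.assessments:
        if not (prev.detection_day < a.day < nxt.detection_day):
            continue
        if a.edss < thr:
            return False
        if a.edss == run_score:
            if a.day - run_start > config.raw_window[1]:
                return False
        else:
            run_score, run_start = a.edss, a.day
    return True
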