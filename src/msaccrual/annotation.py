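"""Detection and classification of confirmed EDSS worsening events.

The engine performs a deterministic left-to-right scan over the
assessments of one follow-up period while maintaining a reference score
(the "baseline").  At each assessment it applies, in order:

1. the *candidate test* — the score must exceed the reference by at least
   the reference-dependent minimal increase (+1.5 from reference 0, +1.0
   below 5.5, +0.5 from 5.5 up);
2. the *confirmation rule* — depending on the definition, the increase must
   be confirmed at later assessments (12/24 weeks, all values or only the
   last, or sustained to the end of follow-up); the confirmed event score
   is the minimum over the candidate and all confirmation scores;
3. the *classification rule* — RAW if the detection falls inside a
   relapse-proximity window, PIRA if detection and confirmation are
   relapse-free, PIRA-with-relapse-during-confirmation if only the
   confirmation touches a relapse window, UNDEFINED for worsening at a
   post-relapse re-baselining assessment.

Re-baselining: after a confirmed RAW/PIRA event the confirmed event score
becomes the new reference; at the first assessment after a relapse's RAW
window, residual disability (a score above the reference) becomes the new
reference without confirmation.  With a roving baseline, a score below the
reference becomes the new reference once the immediately following
assessment does not exceed it.

All rules are driven by a :class:`~msaccrual.data_model.DefinitionConfig`;
the engine contains no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .data_model import (
    WEEKS_12_DAYS,
    WEEKS_24_DAYS,
    AnnotatedEvent,
    Assessment,
    DefinitionConfig,
    EventType,
    FollowUpPeriod,
    ReferenceOrigin,
    ReferenceState,
    Relapse,
    VALID_EDSS_PERMISSIVE,
)

_CONFIRMATION_DISTANCE = {
    "w12_all": WEEKS_12_DAYS,
    "w12_last": WEEKS_12_DAYS,
    "w24_all": WEEKS_24_DAYS,
    "w24_last": WEEKS_24_DAYS,
    "sustained_min12": WEEKS_12_DAYS,
    "sustained_min24": WEEKS_24_DAYS,
}


def minimal_required_increase(reference: float) -> float:
    """Minimal EDSS increase for a worsening candidate, given the reference.

    1.5 points from reference 0, 1.0 points for references below 5.5,
    0.5 points from 5.5 upward (the usual reference-dependent magnitude
    rule for EDSS worsening).
    """
    if reference not in VALID_EDSS_PERMISSIVE:
        raise ValueError(f"invalid reference EDSS: {reference!r}")
    if reference == 0.0:
        return 1.5
    if reference < 5.5:
        return 1.0
    return 0.5


def raw_windows(
    relapses: Sequence[Relapse], window: tuple[int, int]
) -> list[tuple[int, int]]:
    """Merged union of per-relapse proximity intervals, inclusive bounds."""
    pre, post = window
    intervals = sorted((r.day - pre, r.day + post) for r in relapses)
    merged: list[tuple[int, int]] = []
    for lo, hi in intervals:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def in_raw_window(
    day: int, relapses: Sequence[Relapse], window: tuple[int, int]
) -> bool:
    """True iff ``day`` lies inside any relapse's proximity window.

    Boundaries are inclusive on both ends; a relapse on the same day as an
    assessment places that assessment inside the window.
    """
    pre, post = window
    return any(r.day - pre <= day <= r.day + post for r in relapses)


def post_relapse_rebaseline_day(
    relapse: Relapse,
    assessments: Sequence[Assessment],
    relapses: Sequence[Relapse],
    window: tuple[int, int],
) -> Optional[int]:
    """Day of the post-relapse re-baselining assessment for one relapse.

    The first assessment strictly after the relapse's window that is not
    inside *any* relapse's window (overlapping windows from successive
    relapses defer re-baselining until outside all of them); ``None`` if
    follow-up ends first.
    """
    post = window[1]
    for a in assessments:
        if a.day > relapse.day + post and not in_raw_window(a.day, relapses, window):
            return a.day
    return None


def rebaseline_days(period: FollowUpPeriod, window: tuple[int, int]) -> set[int]:
    """All post-relapse re-baselining assessment days of a period."""
    days: set[int] = set()
    for r in period.relapses:
        d = post_relapse_rebaseline_day(r, period.assessments, period.relapses, window)
        if d is not None:
            days.add(d)
    return days


@dataclass(frozen=True)
class ConfirmationResult:
    """Outcome of the confirmation check for one candidate assessment."""

    confirmed: bool
    event_score: Optional[float] = None
    confirmation_days: tuple[int, ...] = ()
    relapse_in_confirmation: bool = False


def confirm_event(
    candidate_index: int,
    reference: float,
    period: FollowUpPeriod,
    config: DefinitionConfig,
) -> ConfirmationResult:
    """Apply the configured confirmation rule to a candidate assessment.

    The candidate at ``candidate_index`` must already satisfy the magnitude
    rule against ``reference``.  The confirmation condition is
    ``score >= reference + minimal increase`` for every score entering the
    check; the confirmed event score is the minimum over the candidate and
    those scores (confirmation type "minimum").

    With ``confirmation_score_handling = skip_relapse_proximal``,
    assessments inside RAW windows are removed from the confirmation
    sequence before any rule is applied (the "standardized" confirmation
    implementation); otherwise relapse-proximal confirmation scores are
    used and flagged via ``relapse_in_confirmation``.

    A candidate with no eligible confirmation assessment is never confirmed
    when a confirmation is required (this includes candidates at the final
    visit); with confirmation mode ``none`` the candidate confirms itself.
    """
    candidate = period.assessments[candidate_index]
    threshold = reference + minimal_required_increase(reference)
    mode = config.confirmation_mode

    if mode == "none":
        return ConfirmationResult(True, candidate.edss, (), False)

    later = list(period.assessments[candidate_index + 1 :])
    if config.confirmation_score_handling == "skip_relapse_proximal":
        later = [
            a for a in later if not in_raw_window(a.day, period.relapses, config.raw_window)
        ]

    confirmation: list[Assessment]
    if mode in ("w12_all", "w12_last", "w24_all", "w24_last"):
        distance = _CONFIRMATION_DISTANCE[mode]
        j = next(
            (k for k, a in enumerate(later) if a.day >= candidate.day + distance),
            None,
        )
        if j is None:
            return ConfirmationResult(False)
        confirmation = [later[j]] if mode.endswith("_last") else later[: j + 1]
    elif mode in ("sustained", "sustained_min12", "sustained_min24"):
        if not later:
            return ConfirmationResult(False)
        if mode != "sustained":
            distance = _CONFIRMATION_DISTANCE[mode]
            if later[-1].day < candidate.day + distance:
                return ConfirmationResult(False)
        confirmation = later
    else:  # pragma: no cover - exhaustive over ConfirmationMode
        raise ValueError(f"unknown confirmation mode: {mode!r}")

    if any(a.edss < threshold for a in confirmation):
        return ConfirmationResult(False)
    event_score = min([candidate.edss] + [a.edss for a in confirmation])
    relapse_prox = any(
        in_raw_window(a.day, period.relapses, config.raw_window) for a in confirmation
    )
    return ConfirmationResult(
        True, event_score, tuple(a.day for a in confirmation), relapse_prox
    )


def classify_event(
    candidate_day: int,
    confirmation: ConfirmationResult,
    period: FollowUpPeriod,
    config: DefinitionConfig,
    rebaseline: set[int],
) -> EventType:
    """Assign the event type to a confirmed candidate.

    Post-relapse re-baselining assessments yield UNDEFINED candidates;
    detection inside a RAW window yields RAW; relapse-touched confirmation
    (when not allowed by the definition and not skipped by the
    standardized handling) yields PIRA-with-relapse-during-confirmation;
    everything else is PIRA.
    """
    if candidate_day in rebaseline:
        return EventType.UNDEFINED
    if in_raw_window(candidate_day, period.relapses, config.raw_window):
        return EventType.RAW
    if (
        confirmation.relapse_in_confirmation
        and not config.allow_relapse_in_confirmation
        and config.confirmation_score_handling == "use_all"
    ):
        return EventType.PIRA_RELAPSE_DURING_CONFIRMATION
    return EventType.PIRA


def _undefined_gate(score: float, reference: float, constraint: str) -> bool:
    """Constraint gating undefined-worsening candidates at re-baselining
    assessments, compared against the current reference.  Note that any
    candidate passing the magnitude rule is strictly above the reference,
    so `greater_only` and `equal_or_greater` admit the same candidates;
    the predicate is kept isolated so an alternative reading can be
    swapped in."""
    if constraint == "greater_only":
        return score > reference
    if constraint == "equal_or_greater":
        return score >= reference
    if constraint == "unconstrained":
        return True
    raise ValueError(f"unknown undefined constraint: {constraint!r}")


def update_reference(
    state: ReferenceState,
    trigger: str,
    *,
    score: float,
    day: int,
    config: DefinitionConfig,
) -> ReferenceState:
    """Advance the reference state for one re-baselining trigger.

    ``event_confirmed``: the confirmed event score becomes the reference.
    ``post_relapse``: residual disability above the reference becomes the
    reference without confirmation; a lower score leaves a fixed baseline
    unchanged (roving handling is done by the scan via
    ``lower_score_observed``).  ``lower_score_observed``: a roving
    reference drop, applied by the scan once next-visit-confirmed (or
    immediately, for the unconfirmed roving variant).
    """
    if trigger == "event_confirmed":
        return ReferenceState(score, ReferenceOrigin.POST_EVENT, day)
    if trigger == "post_relapse":
        if score > state.current_reference:
            return ReferenceState(score, ReferenceOrigin.POST_RELAPSE_RESIDUAL, day)
        return state
    if trigger == "lower_score_observed":
        if config.baseline_mode != "roving_next_confirmed":
            return state
        return ReferenceState(score, ReferenceOrigin.ROVING_IMPROVEMENT, day)
    raise ValueError(f"unknown trigger: {trigger!r}")


def annotate_followup(
    period: FollowUpPeriod, config: DefinitionConfig
) -> list[AnnotatedEvent]:
    """Annotate one follow-up period under one definition.

    Deterministic scan as described in the module docstring.  The first
    assessment sets the initial reference.  Handling of post-relapse
    re-baselining assessments depends on ``undefined_mode``:

    * ``never`` — not checked for worsening at all (re-baselining only);
    * ``rebaselining_only`` / ``all`` / ``end`` — checked as UNDEFINED
      candidates, gated by ``undefined_constraint`` and confirmed like any
      other candidate.  RAW/PIRA take precedence at all other assessments,
      so in this engine the three modes admit the same undefined events.

    Re-baselining at these assessments always follows the residual-
    disability rule, whether or not an UNDEFINED event was recorded; this
    guarantees that ``never`` and ``rebaselining_only`` produce identical
    RAW/PIRA events and differ only in the undefined annotations.

    Returns events sorted by detection day, merged per the definition when
    ``event_merging`` is on.  A period can legitimately yield zero events.
    """
    assessments = period.assessments
    if len(assessments) < 2:
        return []
    rb_days = rebaseline_days(period, config.raw_window)
    roving = config.baseline_mode == "roving_next_confirmed"

    state = ReferenceState(
        assessments[0].edss, ReferenceOrigin.PERIOD_START, assessments[0].day
    )
    pending_roving: Optional[float] = None
    events: list[AnnotatedEvent] = []

    def note_improvement(score: float, day: int) -> None:
        nonlocal state, pending_roving
        if not roving or score >= state.current_reference:
            return
        if config.roving_confirmation == "immediate":
            state = update_reference(
                state, "lower_score_observed", score=score, day=day, config=config
            )
        else:
            pending_roving = score

    for i in range(1, len(assessments)):
        a = assessments[i]
        # resolve a pending roving-reference candidate: confirmed iff the
        # immediately following assessment does not exceed it
        if pending_roving is not None:
            if a.edss <= pending_roving and pending_roving < state.current_reference:
                state = update_reference(
                    state,
                    "lower_score_observed",
                    score=pending_roving,
                    day=a.day,
                    config=config,
                )
            pending_roving = None

        reference = state.current_reference
        threshold = reference + minimal_required_increase(reference)

        if a.day in rb_days:
            if (
                config.undefined_mode != "never"
                and a.edss >= threshold
                and _undefined_gate(a.edss, reference, config.undefined_constraint)
            ):
                conf = confirm_event(i, reference, period, config)
                if conf.confirmed:
                    events.append(
                        AnnotatedEvent(
                            detection_day=a.day,
                            event_type=EventType.UNDEFINED,
                            reference_score=reference,
                            event_score=conf.event_score,
                            delta_edss=round(conf.event_score - reference, 1),
                            confirmation_days=conf.confirmation_days,
                        )
                    )
            # residual-disability re-baselining, identical across
            # undefined modes (keeps "never" equivalent on RAW/PIRA)
            state = update_reference(
                state, "post_relapse", score=a.edss, day=a.day, config=config
            )
            note_improvement(a.edss, a.day)
            continue

        if a.edss >= threshold:
            conf = confirm_event(i, reference, period, config)
            if conf.confirmed:
                etype = classify_event(a.day, conf, period, config, rb_days)
                events.append(
                    AnnotatedEvent(
                        detection_day=a.day,
                        event_type=etype,
                        reference_score=reference,
                        event_score=conf.event_score,
                        delta_edss=round(conf.event_score - reference, 1),
                        confirmation_days=conf.confirmation_days,
                    )
                )
                state = update_reference(
                    state, "event_confirmed", score=conf.event_score, day=a.day,
                    config=config,
                )
                pending_roving = None
                continue

        note_improvement(a.edss, a.day)

    return merge_events(events, config, period)


def merge_events(
    events: list[AnnotatedEvent],
    config: DefinitionConfig,
    period: FollowUpPeriod,
) -> list[AnnotatedEvent]:
    """Fuse sequential events of the same type into one larger event.

    Active only when ``event_merging`` is on.  Two consecutive events merge
    when the later one's reference equals the earlier one's event score
    (i.e. re-baselining chained them directly) and nothing in between
    signals stabilization.  Stabilization between two events means either
    an assessment below the earlier event's confirmation threshold, or a
    plateau of identical scores lasting longer than the maximal repetition
    time (= the post-relapse window size in days).  There is no maximal
    merge distance.  The merged event keeps the first event's detection day
    and reference; its delta is last event score minus first reference.
    """
    if not config.event_merging or len(events) < 2:
        return list(events)

    max_rep = config.max_repetition_days
    merged: list[AnnotatedEvent] = []
    for ev in events:
        if merged and _can_merge(merged[-1], ev, period, max_rep):
            prev = merged[-1]
            merged[-1] = AnnotatedEvent(
                detection_day=prev.detection_day,
                event_type=prev.event_type,
                reference_score=prev.reference_score,
                event_score=ev.event_score,
                delta_edss=round(ev.event_score - prev.reference_score, 1),
                confirmation_days=prev.confirmation_days + ev.confirmation_days,
                merged_from=prev.merged_from + ev.merged_from,
            )
        else:
            merged.append(ev)
    return merged


def _can_merge(
    prev: AnnotatedEvent,
    nxt: AnnotatedEvent,
    period: FollowUpPeriod,
    max_repetition_days: int,
) -> bool:
    if prev.event_type is not nxt.event_type:
        return False
    if nxt.reference_score != prev.event_score:
        return False
    threshold = prev.reference_score + minimal_required_increase(prev.reference_score)
    between = [
        a
        for a in period.assessments
        if prev.detection_day < a.day < nxt.detection_day
    ]
    run_start: Optional[int] = None
    run_score: Optional[float] = None
    for a in between:
        if a.edss < threshold:  # stabilization below the confirmed level
            return False
        if a.edss == run_score:
            if a.day - run_start > max_repetition_days:
                return False  # plateau too long: treated as stabilization
        else:
            run_score, run_start = a.edss, a.day
    return True
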