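"""Screening of raw longitudinal records into eligible follow-up periods.

Inclusion criteria mirror a registry-style screen: at least 24 months of
clinical follow-up, at least 3 EDSS scores, and at least one assessment
per year.  "One per year" is implemented as a rolling rule: every
inter-assessment gap at most 365 days (stricter than any calendar-year
reading, and deterministic).  A patient whose timeline violates the gap
rule is split into maximal gap-compliant runs, each screened separately,
so one patient can contribute several follow-up periods.

Two subgroup screens are supported on already-eligible periods:
``with_relapse`` (at least one relapse inside the period span) and
``dense`` (at least 4 assessments with every gap at most 183 days, i.e.
roughly one assessment per 6 months).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pydantic import BaseModel

from .data_model import (
    DAYS_PER_YEAR,
    MONTHS_24_DAYS,
    Assessment,
    FollowUpPeriod,
    Relapse,
    normalize_assessments,
)

#: max gap for the "dense" (>=1 assessment per 6 months) subgroup
DENSE_GAP_DAYS = 183

SUBGROUPS = ("all", "with_relapse", "dense")


class EligibilityCriteria(BaseModel):
    """Thresholds for follow-up-period eligibility.

    ``relapse_context_days`` extends the period span to the left when
    assigning relapses: a relapse shortly before the first assessment is
    retained (with a negative day) because its proximity window can cover
    early assessments.  The default equals the largest post-relapse window
    in the definition grid.
    """

    min_span_days: int = MONTHS_24_DAYS
    min_assessments: int = 3
    max_gap_days: int = DAYS_PER_YEAR
    subgroup: str = "all"
    relapse_context_days: int = 90

    def model_post_init(self, __context) -> None:
        for name in ("min_span_days", "min_assessments", "max_gap_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"unknown subgroup {self.subgroup!r}; one of {SUBGROUPS}")


@dataclass
class PatientRecord:
    """Raw (unsegmented) timeline for one patient, absolute days."""

    patient_id: str
    assessments: list[Assessment]
    relapses: list[Relapse] = field(default_factory=list)
    dmt_label: str | None = None


def _gap_runs(assessments: Sequence[Assessment], max_gap: int) -> list[list[Assessment]]:
    """Maximal runs of consecutive assessments with gaps <= max_gap.

    Runs grow greedily from the left; because a gap > max_gap can never be
    interior to an eligible window, these runs are exactly the maximal
    candidate windows."""
    runs: list[list[Assessment]] = []
    current: list[Assessment] = []
    for a in assessments:
        if current and a.day - current[-1].day > max_gap:
            runs.append(current)
            current = []
        current.append(a)
    if current:
        runs.append(current)
    return runs


def segment_patient(
    record: PatientRecord, criteria: EligibilityCriteria | None = None
) -> list[FollowUpPeriod]:
    """Extract eligible follow-up periods from one patient's timeline.

    Each returned period is re-anchored to day 0 at its first assessment.
    Relapses are assigned to the period whose span — extended to the left
    by ``relapse_context_days`` — contains them; context relapses carry
    negative days.
    """
    criteria = criteria or EligibilityCriteria()
    assessments, _ = normalize_assessments(record.assessments)
    periods: list[FollowUpPeriod] = []
    for run in _gap_runs(assessments, criteria.max_gap_days):
        if len(run) < criteria.min_assessments:
            continue
        if run[-1].day - run[0].day < criteria.min_span_days:
            continue
        start = run[0].day
        relapses = sorted(
            Relapse(r.day - start)
            for r in record.relapses
            if start - criteria.relapse_context_days <= r.day <= run[-1].day
        )
        periods.append(
            FollowUpPeriod(
                patient_id=record.patient_id,
                assessments=[Assessment(a.day - start, a.edss) for a in run],
                relapses=relapses,
                period_index=len(periods) + 1,
                dmt_label=record.dmt_label,
            )
        )
    return periods


def segment_followups(
    records: Iterable[PatientRecord], criteria: EligibilityCriteria | None = None
) -> list[FollowUpPeriod]:
    """Screen many patients; see :func:`segment_patient`.  Empty input
    yields an empty list."""
    criteria = criteria or EligibilityCriteria()
    out: list[FollowUpPeriod] = []
    for record in records:
        out.extend(segment_patient(record, criteria))
    return out


def subgroup_filter(
    periods: Sequence[FollowUpPeriod], subgroup: str
) -> list[FollowUpPeriod]:
    """Restrict eligible periods to a subgroup.

    ``all`` is the identity; ``with_relapse`` keeps periods with at least
    one relapse inside [0, last assessment day] (context relapses before
    day 0 do not count); ``dense`` keeps periods with >= 4 assessments and
    every inter-assessment gap <= 183 days.
    """
    if subgroup == "all":
        return list(periods)
    if subgroup == "with_relapse":
        return [
            p for p in periods if any(0 <= r.day <= p.last_day for r in p.relapses)
        ]
    if subgroup == "dense":
        return [
            p
            for p in periods
            if len(p.assessments) >= 4
            and all(
                b.day - a.day <= DENSE_GAP_DAYS
                for a, b in zip(p.assessments, p.assessments[1:])
            )
        ]
    raise ValueError(f"unknown subgroup {subgroup!r}; one of {SUBGROUPS}")
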