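"""Domain types for EDSS disability-accrual annotation.

The Expanded Disability Status Scale (EDSS) is an ordinal disability score
for multiple sclerosis ranging from 0 to 10 in half-point steps; the step
0.5 does not exist on the standard scale (it jumps from 0.0 to 1.0).
Everything downstream — eligibility screening, event annotation, definition
grids, cohort metrics — operates on the types defined here:

* :class:`Assessment` / :class:`Relapse` — time-stamped observations, with
  time measured in integer days since the start of a follow-up period.
* :class:`FollowUpPeriod` — one eligible observation window for one patient.
* :class:`DefinitionConfig` — one point in the definitional parameter space
  of disability-accrual definitions (baseline handling, confirmation rules,
  relapse-proximity windows, undefined-event handling, event merging).
* :class:`AnnotatedEvent` — one detected, confirmed worsening event.

Validation never raises for data problems; it returns :class:`Finding`
objects with ``error`` / ``warning`` severity so callers can decide whether
to run permissively (registry data contain entry errors) or strictly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, field_validator

# --- time conventions -------------------------------------------------------
# Time is integer days relative to the follow-up-period start.  Week- and
# month-based definition parameters are fixed day counts for reproducibility.
WEEKS_12_DAYS = 84
WEEKS_24_DAYS = 168
DAYS_PER_YEAR = 365
MONTHS_24_DAYS = 730

# --- EDSS grid --------------------------------------------------------------
VALID_EDSS_PERMISSIVE = frozenset(i * 0.5 for i in range(21))
#: Standard EDSS values: 0.0 and 1.0, 1.5, ..., 10.0 (no 0.5 step).
VALID_EDSS_STRICT = VALID_EDSS_PERMISSIVE - {0.5}


def is_valid_edss(value: float, permissive: bool = False) -> bool:
    """Whether ``value`` lies on the (strict or permissive) EDSS grid."""
    grid = VALID_EDSS_PERMISSIVE if permissive else VALID_EDSS_STRICT
    return value in grid


class Severity(str, enum.Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``code`` is a stable machine-readable tag."""

    severity: Severity
    code: str
    message: str

    @property
    def is_error(self) -> bool:
        return self.severity is Severity.ERROR


def has_errors(findings: Iterable[Finding]) -> bool:
    return any(f.is_error for f in findings)


# --- observations -----------------------------------------------------------
@dataclass(frozen=True, order=True)
class Assessment:
    """One EDSS assessment at ``day`` days since period start (day >= 0)."""

    day: int
    edss: float


@dataclass(frozen=True, order=True)
class Relapse:
    """One relapse onset.  ``day`` may be negative: relapses shortly before
    a period start are retained as context because their proximity window
    can cover early assessments."""

    day: int


@dataclass
class FollowUpPeriod:
    """One eligible observation window for one patient.

    ``assessments`` are sorted with strictly increasing days; ``relapses``
    are sorted ascending and may precede the first or follow the last
    assessment.  A patient may contribute several periods, numbered by
    ``period_index`` starting at 1.
    """

    patient_id: str
    assessments: list[Assessment]
    relapses: list[Relapse] = field(default_factory=list)
    period_index: int = 1
    dmt_label: Optional[str] = None

    @property
    def span_days(self) -> int:
        if not self.assessments:
            return 0
        return self.assessments[-1].day - self.assessments[0].day

    @property
    def last_day(self) -> int:
        return self.assessments[-1].day

    def relapse_days(self) -> list[int]:
        return [r.day for r in self.relapses]


class EventType(str, enum.Enum):
    """Mutually exclusive classes of confirmed disability-accrual events.

    RAW
        Relapse-associated worsening: detected inside a relapse-proximity
        ("RAW") window, not at a post-relapse re-baselining assessment.
    PIRA
        Progression independent of relapse activity: detected outside all
        RAW windows with relapse-free confirmation.
    PIRA_RELAPSE_DURING_CONFIRMATION
        Fulfils PIRA except that confirmation assessment(s) fall inside a
        RAW window of a later relapse.
    UNDEFINED
        Confirmed worsening attributable to neither RAW nor PIRA, typically
        at a post-relapse re-baselining assessment (a follow-up-quality
        issue: no assessment close to the relapse).
    """

    RAW = "RAW"
    PIRA = "PIRA"
    PIRA_RELAPSE_DURING_CONFIRMATION = "PIRA_RELAPSE_DURING_CONFIRMATION"
    UNDEFINED = "UNDEFINED"


@dataclass(frozen=True)
class AnnotatedEvent:
    """One detected accrual event.

    ``event_score`` is the *confirmed* score (minimum over the candidate
    score and every score entering the confirmation check), so
    ``delta_edss = event_score - reference_score`` can be smaller than the
    raw increase at the detection visit.  ``merged_from`` counts constituent
    events after sequential-event merging (1 if unmerged).
    """

    detection_day: int
    event_type: EventType
    reference_score: float
    event_score: float
    delta_edss: float
    confirmation_days: tuple[int, ...] = ()
    merged_from: int = 1


class ReferenceOrigin(str, enum.Enum):
    PERIOD_START = "period_start"
    POST_EVENT = "post_event"
    POST_RELAPSE_RESIDUAL = "post_relapse_residual"
    ROVING_IMPROVEMENT = "roving_improvement"


@dataclass
class ReferenceState:
    """The maintained comparison score ("baseline") during a scan."""

    current_reference: float
    origin: ReferenceOrigin
    origin_day: int


# --- definition configuration -----------------------------------------------
ConfirmationMode = Literal[
    "none",
    "w12_all",
    "w12_last",
    "w24_all",
    "w24_last",
    "sustained",
    "sustained_min12",
    "sustained_min24",
]
UndefinedMode = Literal["rebaselining_only", "never", "all", "end"]
UndefinedConstraint = Literal["greater_only", "equal_or_greater", "unconstrained"]
BaselineMode = Literal["fixed", "roving_next_confirmed"]

#: RAW-window sizes (days before, days after a relapse) in the tested grid.
RAW_WINDOW_CHOICES: tuple[tuple[int, int], ...] = ((30, 30), (30, 90), (90, 90))

#: Confirmation modes in which only the last value of the confirmation
#: interval is considered; the only modes that may allow relapses inside
#: the confirmation interval.
LAST_CONFIRMED_MODES = ("w12_last", "w24_last")


class DefinitionConfig(BaseModel):
    """One disability-accrual definition.

    The free axes (the ones enumerated in definition grids) are
    ``event_merging``, ``undefined_mode``, ``undefined_constraint``,
    ``baseline_mode``, ``confirmation_mode`` (+ ``allow_relapse_in_confirmation``)
    and ``raw_window``.  The magnitude rule, confirmation type (minimum),
    requirement of confirmation for last-visit candidates and confirmation
    tolerances (left 0, right unbounded) are fixed.

    ``confirmation_score_handling`` and ``roving_confirmation`` are engine
    extensions, not grid axes: ``skip_relapse_proximal`` drops
    relapse-proximal assessments from the confirmation set (the
    "standardized" confirmation implementation), and ``immediate`` adopts a
    lower roving reference without next-visit confirmation.
    """

    model_config = ConfigDict(frozen=True)

    event_merging: bool = False
    undefined_mode: UndefinedMode = "rebaselining_only"
    undefined_constraint: UndefinedConstraint = "greater_only"
    baseline_mode: BaselineMode = "fixed"
    confirmation_mode: ConfirmationMode = "w12_all"
    raw_window: tuple[int, int] = (30, 90)
    allow_relapse_in_confirmation: bool = False
    confirmation_score_handling: Literal["use_all", "skip_relapse_proximal"] = "use_all"
    roving_confirmation: Literal["next_confirmed", "immediate"] = "next_confirmed"
    # fixed (non-axis) parameters, recorded for transparency
    confirmation_type: Literal["minimum"] = "minimum"
    require_confirmation_for_last_visit: Literal[True] = True
    left_confirmation_tolerance_days: Literal[0] = 0

    @field_validator("raw_window", mode="before")
    @classmethod
    def _coerce_window(cls, v):
        if isinstance(v, (list, tuple)):
            return tuple(int(x) for x in v)
        return v

    @property
    def max_repetition_days(self) -> int:
        """Merging repetition limit = post-relapse RAW-window size (days)."""
        return self.raw_window[1]

    def axis_key(self) -> tuple:
        """Stable identity over the grid axes (for pairing and dedup)."""
        return (
            self.event_merging,
            self.undefined_mode,
            self.undefined_constraint,
            self.baseline_mode,
            self.confirmation_mode,
            self.allow_relapse_in_confirmation,
            self.raw_window,
        )


# --- validation --------------------------------------------------------------
def validate_config(config: DefinitionConfig) -> list[Finding]:
    """Check cross-field consistency of a definition.

    Allowing relapses inside the confirmation interval is only legal when
    only the last value of the interval is considered (last-confirmed
    modes).  Engine extensions and non-standard RAW windows are flagged as
    warnings: such configs are valid but are not cells of the canonical
    definition grid.
    """
    findings: list[Finding] = []
    if config.allow_relapse_in_confirmation and config.confirmation_mode not in LAST_CONFIRMED_MODES:
        findings.append(
            Finding(
                Severity.ERROR,
                "allow-relapse-requires-last-confirmed",
                "allow_relapse_in_confirmation=true requires a last-confirmed "
                f"confirmation mode {LAST_CONFIRMED_MODES}, got "
                f"{config.confirmation_mode!r}",
            )
        )
    if config.raw_window not in RAW_WINDOW_CHOICES:
        findings.append(
            Finding(
                Severity.WARNING,
                "non-standard-raw-window",
                f"RAW window {config.raw_window} is outside the tested grid "
                f"{RAW_WINDOW_CHOICES}",
            )
        )
    if config.confirmation_score_handling != "use_all":
        findings.append(
            Finding(
                Severity.WARNING,
                "engine-extension-confirmation-handling",
                "confirmation_score_handling=skip_relapse_proximal is an engine "
                "extension, not a cell of the definition grid",
            )
        )
    if config.roving_confirmation != "next_confirmed":
        findings.append(
            Finding(
                Severity.WARNING,
                "engine-extension-roving",
                "roving_confirmation=immediate is an engine extension, not a "
                "cell of the definition grid",
            )
        )
    return findings


def normalize_assessments(
    assessments: Sequence[Assessment],
) -> tuple[list[Assessment], list[Finding]]:
    """Sort assessments by day and resolve duplicate days.

    Duplicate days keep the *last* record in input order (a deterministic
    rule for registry double entries) and emit a warning per dropped record.
    """
    findings: list[Finding] = []
    by_day: dict[int, Assessment] = {}
    for a in assessments:
        if a.day in by_day:
            findings.append(
                Finding(
                    Severity.WARNING,
                    "duplicate-assessment-day",
                    f"duplicate assessment at day {a.day}: keeping last record "
                    f"(EDSS {a.edss})",
                )
            )
        by_day[a.day] = a
    return [by_day[d] for d in sorted(by_day)], findings


def edss_findings(value: float, permissive: bool = False) -> list[Finding]:
    """Findings for one EDSS value under strict or permissive validation."""
    if value in VALID_EDSS_STRICT:
        return []
    if value == 0.5:
        sev = Severity.WARNING if permissive else Severity.ERROR
        return [
            Finding(sev, "edss-half-point", "EDSS 0.5 is not on the standard scale")
        ]
    if permissive and value in VALID_EDSS_PERMISSIVE:
        return []
    return [
        Finding(
            Severity.ERROR,
            "edss-off-grid",
            f"EDSS {value} is not a multiple of 0.5 in [0, 10]",
        )
    ]


def validate_period(period: FollowUpPeriod, permissive: bool = False) -> list[Finding]:
    """Check a follow-up period against the structural invariants.

    Returns an empty list iff all invariants hold.  Errors: fewer than
    3 assessments, non-increasing or negative days, off-grid EDSS values,
    unsorted relapses.  Permissive mode downgrades EDSS 0.5 to a warning.
    """
    findings: list[Finding] = []
    n = len(period.assessments)
    if n < 3:
        findings.append(
            Finding(
                Severity.ERROR,
                "too-few-assessments",
                f"period has {n} assessments; at least 3 EDSS scores required",
            )
        )
    prev_day = None
    for a in period.assessments:
        if a.day < 0:
            findings.append(
                Finding(Severity.ERROR, "negative-day", f"assessment day {a.day} < 0")
            )
        if prev_day is not None and a.day <= prev_day:
            findings.append(
                Finding(
                    Severity.ERROR,
                    "non-increasing-days",
                    f"assessment days not strictly increasing at day {a.day}",
                )
            )
        prev_day = a.day
        findings.extend(edss_findings(a.edss, permissive=permissive))
    if any(
        r2.day < r1.day for r1, r2 in zip(period.relapses, period.relapses[1:])
    ):
        findings.append(
            Finding(Severity.ERROR, "unsorted-relapses", "relapse days not ascending")
        )
    return findings
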