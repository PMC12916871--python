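"""Synthetic cohorts with ground-truth disability-accrual labels.

Latent disability is modelled as a *step function* (not a drift) so that
true events are unambiguous: a trajectory starts from a baseline EDSS
drawn from a realistic registry-like distribution and accumulates

* relapse residuals — relapses arrive as a Poisson process; each leaves a
  permanent step increase with probability ``p_residual``;
* transient relapse peaks — an optional temporary elevation from relapse
  onset that resolves within the relapse-proximity window (exercises the
  RAW-window logic without changing the permanent level);
* relapse-independent progression steps — a second, slower Poisson
  process of permanent step increases (the PIRA substrate).

Visits sample the latent value on an irregular schedule (mean interval
plus jitter), with optional measurement noise of +-0.5, and every emitted
score is clamped to the valid EDSS grid (values landing exactly on the
nonexistent 0.5 step snap down to 0.0).  Relapse days are recorded
independently of visit days, as in a registry.

Defaults emulate a treatment-registry cohort: follow-up 2-8 years, about
one visit per four months (≈13 visits over a median-length follow-up),
baseline EDSS centred on 2.0, and a relapse intensity that leaves roughly
40% of follow-up periods with at least one relapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict

from .data_model import (
    DAYS_PER_YEAR,
    Assessment,
    FollowUpPeriod,
    Relapse,
)

#: registry-like baseline EDSS distribution (median 2.0)
DEFAULT_BASELINE_EDSS = {
    0.0: 0.05,
    1.0: 0.17,
    1.5: 0.10,
    2.0: 0.25,
    2.5: 0.10,
    3.0: 0.12,
    3.5: 0.07,
    4.0: 0.06,
    5.0: 0.04,
    6.0: 0.04,
}


class SimulationParams(BaseModel):
    """Generator settings; see the module docstring for the model.

    Rates are per-year intensities; steps are EDSS points (multiples of
    0.5).  ``noise_p`` is the probability that a visit's emitted score is
    jittered by +-0.5 around the latent value.
    """

    model_config = ConfigDict(frozen=True)

    n_patients: int = 200
    followup_years: tuple[float, float] = (2.0, 8.0)
    visit_interval_days: float = 120.0
    visit_jitter_days: float = 40.0
    baseline_edss: dict[float, float] = DEFAULT_BASELINE_EDSS
    relapse_rate: float = 0.12
    p_residual: float = 0.4
    residual_step: float = 1.0
    transient_peaks: bool = True
    peak_height: float = 1.0
    peak_duration_days: int = 60
    pira_rate: float = 0.05
    pira_step: float = 1.0
    noise_p: float = 0.1
    dmt_labels: Optional[dict[str, float]] = None
    seed: int = 0

    def model_post_init(self, __context) -> None:
        for name in ("noise_p", "p_residual"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("residual_step", "pira_step", "peak_height"):
            v = getattr(self, name)
            if v < 0 or round(v * 2) != v * 2:
                raise ValueError(f"{name} must be a non-negative multiple of 0.5")
        if self.followup_years[0] <= 0 or self.followup_years[1] < self.followup_years[0]:
            raise ValueError("followup_years must be a positive (lo, hi) range")
        if self.visit_interval_days <= 0 or self.n_patients <= 0:
            raise ValueError("visit_interval_days and n_patients must be > 0")
        if self.visit_interval_days > self.followup_years[0] * DAYS_PER_YEAR:
            raise ValueError("visit interval longer than the shortest follow-up")
        if abs(sum(self.baseline_edss.values()) - 1.0) > 1e-9:
            raise ValueError("baseline_edss probabilities must sum to 1")


@dataclass
class PatientTruth:
    """Latent ground truth for one simulated patient."""

    patient_id: str
    baseline: float
    relapse_days: list[int] = field(default_factory=list)
    residual_steps: list[tuple[int, float]] = field(default_factory=list)
    progression_steps: list[tuple[int, float]] = field(default_factory=list)
    peak_windows: list[tuple[int, int, float]] = field(default_factory=list)

    def latent(self, day: int) -> float:
        """Latent (noise-free, unclamped) disability at ``day``."""
        value = self.baseline
        value += sum(delta for d, delta in self.residual_steps if d <= day)
        value += sum(delta for d, delta in self.progression_steps if d <= day)
        value += sum(h for lo, hi, h in self.peak_windows if lo <= day <= hi)
        return value


@dataclass
class GroundTruth:
    patients: list[PatientTruth]


def clamp_edss(value: float) -> float:
    """Snap to the valid EDSS grid: round to the nearest half point within
    [0, 10]; the nonexistent 0.5 step snaps down to 0.0."""
    v = min(10.0, max(0.0, round(value * 2) / 2))
    return 0.0 if v == 0.5 else v


def _poisson_days(rng: np.random.Generator, rate_per_year: float, span_days: int) -> list[int]:
    n = rng.poisson(rate_per_year * span_days / DAYS_PER_YEAR)
    return sorted(int(d) for d in rng.integers(1, span_days, size=n)) if n else []


def generate_cohort(
    params: SimulationParams | None = None,
) -> tuple[list[FollowUpPeriod], GroundTruth]:
    """Generate a cohort of follow-up periods plus its ground truth.

    Reproducible: the same ``params`` (including ``params.seed``) always
    produce the same cohort.  At ``noise_p = 0`` every emitted score
    equals the clamped latent value, so the ground truth reconstructs the
    trajectory exactly (provided steps keep the latent value off the
    nonexistent 0.5 level).
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    baseline_values = np.array(sorted(params.baseline_edss))
    baseline_probs = np.array([params.baseline_edss[v] for v in baseline_values])
    dmt_values = sorted(params.dmt_labels) if params.dmt_labels else None

    periods: list[FollowUpPeriod] = []
    truths: list[PatientTruth] = []
    for idx in range(params.n_patients):
        pid = f"sim{idx:05d}"
        span = int(
            rng.uniform(params.followup_years[0], params.followup_years[1])
            * DAYS_PER_YEAR
        )
        baseline = float(rng.choice(baseline_values, p=baseline_probs))

        truth = PatientTruth(patient_id=pid, baseline=baseline)
        truth.relapse_days = _poisson_days(rng, params.relapse_rate, span)
        for rd in truth.relapse_days:
            if params.p_residual and rng.random() < params.p_residual:
                truth.residual_steps.append((rd, params.residual_step))
            if params.transient_peaks:
                truth.peak_windows.append(
                    (rd, rd + params.peak_duration_days, params.peak_height)
                )
        truth.progression_steps = [
            (d, params.pira_step) for d in _poisson_days(rng, params.pira_rate, span)
        ]

        visit_days = [0]
        while True:
            gap = int(
                max(7.0, rng.normal(params.visit_interval_days, params.visit_jitter_days))
            )
            nxt = visit_days[-1] + gap
            if nxt > span:
                break
            visit_days.append(nxt)
        if len(visit_days) < 3:
            raise ValueError(
                "infeasible visit schedule: fewer than 3 visits in a follow-up"
            )

        assessments = []
        for day in visit_days:
            value = truth.latent(day)
            if params.noise_p and rng.random() < params.noise_p:
                value += 0.5 if rng.random() < 0.5 else -0.5
            assessments.append(Assessment(day, clamp_edss(value)))

        dmt = (
            str(
                rng.choice(
                    dmt_values,
                    p=[params.dmt_labels[v] for v in dmt_values],
                )
            )
            if dmt_values
            else None
        )
        periods.append(
            FollowUpPeriod(
                patient_id=pid,
                assessments=assessments,
                relapses=[Relapse(d) for d in truth.relapse_days],
                period_index=1,
                dmt_label=dmt,
            )
        )
        truths.append(truth)
    return periods, GroundTruth(truths)
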