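"""Shared fixtures: random small follow-up periods and random definitions
for property and equivalence testing."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from msaccrual.data_model import (
    VALID_EDSS_STRICT,
    Assessment,
    DefinitionConfig,
    FollowUpPeriod,
    Relapse,
)
from msaccrual.grid import CONFIRMATION_AXIS, RAW_WINDOW_CHOICES

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

_EDSS_GRID = sorted(VALID_EDSS_STRICT)


def snap_edss(value: float) -> float:
    v = min(10.0, max(0.0, round(value * 2) / 2))
    return 1.0 if v == 0.5 else v


def random_period(rng: np.random.Generator, max_visits: int = 10) -> FollowUpPeriod:
    """A small random trajectory: EDSS random walk on the valid grid over
    an irregular schedule, with 0-3 relapses anywhere around the span."""
    n = int(rng.integers(4, max_visits + 1))
    gaps = rng.integers(10, 150, size=n - 1)
    days = [0] + list(np.cumsum(gaps))
    score = float(rng.choice(_EDSS_GRID[:14]))  # start at most at 6.5
    assessments = []
    for d in days:
        assessments.append(Assessment(int(d), score))
        score = snap_edss(score + float(rng.choice([-1.0, -0.5, 0.0, 0.0, 0.5, 0.5, 1.0, 1.5])))
    n_rel = int(rng.integers(0, 4))
    relapses = sorted(
        Relapse(int(d))
        for d in rng.integers(-60, int(days[-1]) + 60, size=n_rel)
    )
    return FollowUpPeriod("rand", assessments, relapses)


def random_config(rng: np.random.Generator, extensions: bool = True) -> DefinitionConfig:
    """A random definition; with ``extensions``, occasionally uses the
    engine extensions outside the canonical grid."""
    cmode, allow = CONFIRMATION_AXIS[int(rng.integers(len(CONFIRMATION_AXIS)))]
    return DefinitionConfig(
        event_merging=bool(rng.integers(2)),
        undefined_mode=str(rng.choice(["rebaselining_only", "never", "all", "end"])),
        undefined_constraint=str(
            rng.choice(["greater_only", "equal_or_greater", "unconstrained"])
        ),
        baseline_mode=str(rng.choice(["fixed", "roving_next_confirmed"])),
        confirmation_mode=cmode,
        allow_relapse_in_confirmation=allow,
        raw_window=RAW_WINDOW_CHOICES[int(rng.integers(3))],
        confirmation_score_handling=(
            "skip_relapse_proximal" if extensions and rng.random() < 0.2 else "use_all"
        ),
        roving_confirmation=(
            "immediate" if extensions and rng.random() < 0.2 else "next_confirmed"
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture
def simple_period() -> FollowUpPeriod:
    """Relapse-free period with one clean confirmed worsening (3.0 -> 4.5
    confirmed by 4.0)."""
    return FollowUpPeriod(
        "p1",
        [
            Assessment(0, 3.0),
            Assessment(100, 3.0),
            Assessment(200, 4.5),
            Assessment(300, 4.0),
            Assessment(400, 4.0),
        ],
    )
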