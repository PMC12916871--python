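"""Enumeration of the definitional parameter space.

The tested definition space is the Cartesian product of six free axes:

========================  =======================================  ==
event merging             off, on                                   2
undefined-event handling  rebaselining_only, never, all, end        4
undefined constraint      greater_only, equal_or_greater,
                          unconstrained                             3
baseline                  fixed, roving (next-confirmed)            2
confirmation              none; 12/24 weeks all- or last-
                          confirmed; sustained, sustained >=12w,
                          sustained >=24w; the two last-confirmed
                          modes additionally with relapses allowed
                          in the confirmation interval             10
RAW window (pre, post)    (30,30), (30,90), (90,90)                 3
========================  =======================================  ==

for a total of 2 x 4 x 3 x 2 x 10 x 3 = 1440 definitions.  Relapses in the
confirmation interval may only be allowed when only the last value of the
interval is considered, hence 8 + 2 = 10 confirmation combinations.

Two published harmonization proposals pin down some axes but not others;
the corresponding sub-grids are *reconstructed* here from the free-axis
factorizations (1440 / 4 = 360 for the harmonized proposal, which fixes
event merging and the baseline; 1440 / 10 = 144 for the standardized
proposal, which fixes the confirmation combination) with overridable
default fixed values.

Enumeration order is stable: lexicographic over the axes in the table's
order, with each axis in the order listed above.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

from .data_model import (
    DefinitionConfig,
    RAW_WINDOW_CHOICES,
    has_errors,
    validate_config,
)

EVENT_MERGING_AXIS = (False, True)
UNDEFINED_MODE_AXIS = ("rebaselining_only", "never", "all", "end")
UNDEFINED_CONSTRAINT_AXIS = ("greater_only", "equal_or_greater", "unconstrained")
BASELINE_AXIS = ("fixed", "roving_next_confirmed")
#: (confirmation_mode, allow_relapse_in_confirmation) combinations; the
#: allow flag is only generated for last-confirmed modes.
CONFIRMATION_AXIS = (
    ("none", False),
    ("w12_all", False),
    ("w12_last", False),
    ("w12_last", True),
    ("w24_all", False),
    ("w24_last", False),
    ("w24_last", True),
    ("sustained", False),
    ("sustained_min12", False),
    ("sustained_min24", False),
)


@dataclass(frozen=True)
class GridSpec:
    """One enumerable definition grid: free axes, in enumeration order.

    Fixing an axis to a single value restricts the grid; constraints
    (currently only the last-confirmed rule, already encoded in
    ``confirmation`` pairs) are respected by construction.
    """

    event_merging: tuple[bool, ...] = EVENT_MERGING_AXIS
    undefined_mode: tuple[str, ...] = UNDEFINED_MODE_AXIS
    undefined_constraint: tuple[str, ...] = UNDEFINED_CONSTRAINT_AXIS
    baseline_mode: tuple[str, ...] = BASELINE_AXIS
    confirmation: tuple[tuple[str, bool], ...] = CONFIRMATION_AXIS
    raw_window: tuple[tuple[int, int], ...] = RAW_WINDOW_CHOICES

    def enumerate(self) -> list[DefinitionConfig]:
        configs = [
            DefinitionConfig(
                event_merging=merging,
                undefined_mode=umode,
                undefined_constraint=uconstraint,
                baseline_mode=baseline,
                confirmation_mode=cmode,
                allow_relapse_in_confirmation=allow,
                raw_window=window,
            )
            for merging, umode, uconstraint, baseline, (cmode, allow), window
            in itertools.product(
                self.event_merging,
                self.undefined_mode,
                self.undefined_constraint,
                self.baseline_mode,
                self.confirmation,
                self.raw_window,
            )
        ]
        bad = [c for c in configs if has_errors(validate_config(c))]
        if bad:  # pragma: no cover - guarded by axis construction
            raise ValueError(f"grid produced {len(bad)} invalid configs")
        return configs


def enumerate_full_grid() -> list[DefinitionConfig]:
    """All 1440 tested definitions, in stable lexicographic order."""
    return GridSpec().enumerate()


def enumerate_harmonized_subgrid(
    event_merging: bool = False,
    baseline_mode: str = "roving_next_confirmed",
) -> list[DefinitionConfig]:
    """The 360 definitions compatible with the harmonized proposal
    (reconstructed: the proposal fixes event merging and the baseline;
    undefined handling, undefined constraint, confirmation and RAW window
    remain free)."""
    return GridSpec(
        event_merging=(event_merging,),
        baseline_mode=(baseline_mode,),
    ).enumerate()


def enumerate_standardized_subgrid(
    confirmation_mode: str = "w12_all",
    allow_relapse_in_confirmation: bool = False,
) -> list[DefinitionConfig]:
    """The 144 definitions compatible with the standardized proposal
    (reconstructed: the proposal fixes the confirmation combination; event
    merging, undefined handling, undefined constraint, baseline and RAW
    window remain free)."""
    return GridSpec(
        confirmation=((confirmation_mode, allow_relapse_in_confirmation),),
    ).enumerate()


PRESETS = {
    "full": enumerate_full_grid,
    "harmonized": enumerate_harmonized_subgrid,
    "standardized": enumerate_standardized_subgrid,
}


def enumerate_preset(name: str) -> list[DefinitionConfig]:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; one of {sorted(PRESETS)}") from None
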