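"""Cohort-level summaries of annotated events and grid-wide comparisons.

Rates use follow-up periods (not patients) as the unit.  The metrics are:

* overall event rate — fraction of periods with >=1 event of any type;
* per-type event rates — fraction of periods with >=1 event of that type;
* per-type contributions — share of the total event count, and share of
  the total confirmed EDSS increase (sum of event deltas), by event type;
* exclusive rates — among event-bearing periods, the fraction with only
  PIRA events or only RAW events;
* median time to first event — Kaplan-Meier estimate in years, censoring
  event-free periods at their last assessment.

Grid comparisons pair definitions that are identical except on one axis
and apply a paired sign-flip permutation test (two-sided; exact
enumeration for small numbers of pairs) to the per-pair metric
differences.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .annotation import annotate_followup
from .data_model import (
    DAYS_PER_YEAR,
    AnnotatedEvent,
    DefinitionConfig,
    EventType,
    FollowUpPeriod,
)

_EXCLUSIVE_TYPES = (EventType.PIRA, EventType.RAW)


@dataclass
class CohortSummary:
    n_periods: int
    n_events: int
    total_delta: float
    overall_event_rate: float
    per_type_event_rate: dict[EventType, float]
    per_type_count_contribution: dict[EventType, float]
    per_type_delta_contribution: dict[EventType, float]
    exclusive_rates: dict[EventType, float]
    km_median_years: float
    events_per_period_distribution: dict[int, int]

    def as_row(self) -> dict[str, float]:
        """Flatten into scalar columns for tidy tables."""
        row: dict[str, float] = {
            "n_periods": self.n_periods,
            "n_events": self.n_events,
            "total_delta": self.total_delta,
            "overall_event_rate": self.overall_event_rate,
            "km_median_years": self.km_median_years,
        }
        for et in EventType:
            row[f"event_rate_{et.value}"] = self.per_type_event_rate[et]
            row[f"count_contribution_{et.value}"] = self.per_type_count_contribution[et]
            row[f"delta_contribution_{et.value}"] = self.per_type_delta_contribution[et]
        for et in _EXCLUSIVE_TYPES:
            row[f"only_{et.value}_rate"] = self.exclusive_rates[et]
        return row


def summarize_cohort(
    annotations: Sequence[Sequence[AnnotatedEvent]],
    periods: Sequence[FollowUpPeriod],
    include_undefined_in_tte: bool = True,
) -> CohortSummary:
    """Aggregate per-period annotations (all from one definition) into the
    cohort metrics.

    Time to first event uses the detection day of the first event of any
    type (undefined events excludable via ``include_undefined_in_tte``);
    event-free periods are right-censored at their last assessment day.
    The Kaplan-Meier median is ``inf`` when the survival curve never
    reaches 0.5.
    """
    if len(periods) == 0:
        raise ValueError("cannot summarize an empty cohort")
    if len(annotations) != len(periods):
        raise ValueError("annotations and periods must align one-to-one")

    n = len(periods)
    all_events = [e for events in annotations for e in events]
    n_events = len(all_events)
    total_delta = float(sum(e.delta_edss for e in all_events))

    with_any = sum(1 for events in annotations if events)
    per_type_rate = {
        et: sum(1 for events in annotations if any(e.event_type is et for e in events)) / n
        for et in EventType
    }
    count_by_type = Counter(e.event_type for e in all_events)
    delta_by_type: dict[EventType, float] = {
        et: float(sum(e.delta_edss for e in all_events if e.event_type is et))
        for et in EventType
    }
    count_contrib = {
        et: (count_by_type.get(et, 0) / n_events if n_events else 0.0)
        for et in EventType
    }
    delta_contrib = {
        et: (delta_by_type[et] / total_delta if total_delta else 0.0)
        for et in EventType
    }
    exclusive = {
        et: (
            sum(
                1
                for events in annotations
                if events and all(e.event_type is et for e in events)
            )
            / with_any
            if with_any
            else 0.0
        )
        for et in _EXCLUSIVE_TYPES
    }

    durations, observed = [], []
    for events, period in zip(annotations, periods):
        firsts = [
            e
            for e in events
            if include_undefined_in_tte or e.event_type is not EventType.UNDEFINED
        ]
        if firsts:
            durations.append(firsts[0].detection_day / DAYS_PER_YEAR)
            observed.append(1)
        else:
            durations.append(period.last_day / DAYS_PER_YEAR)
            observed.append(0)
    if any(observed):
        kmf = KaplanMeierFitter()
        kmf.fit(durations, event_observed=observed)
        km_median = float(kmf.median_survival_time_)
    else:
        km_median = float("inf")

    histogram = dict(sorted(Counter(len(events) for events in annotations).items()))

    return CohortSummary(
        n_periods=n,
        n_events=n_events,
        total_delta=total_delta,
        overall_event_rate=with_any / n,
        per_type_event_rate=per_type_rate,
        per_type_count_contribution=count_contrib,
        per_type_delta_contribution=delta_contrib,
        exclusive_rates=exclusive,
        km_median_years=km_median,
        events_per_period_distribution=histogram,
    )


def annotate_cohort(
    periods: Sequence[FollowUpPeriod], config: DefinitionConfig
) -> list[list[AnnotatedEvent]]:
    """Annotate every period of a cohort under one definition."""
    return [annotate_followup(p, config) for p in periods]


_CONFIG_COLUMNS = (
    "event_merging",
    "undefined_mode",
    "undefined_constraint",
    "baseline_mode",
    "confirmation_mode",
    "allow_relapse_in_confirmation",
    "raw_window",
)


def config_row(config: DefinitionConfig) -> dict[str, object]:
    row = {c: getattr(config, c) for c in _CONFIG_COLUMNS}
    row["raw_window"] = f"{config.raw_window[0]}/{config.raw_window[1]}"
    return row


def summarize_grid(
    periods: Sequence[FollowUpPeriod],
    grid: Sequence[DefinitionConfig],
    progress: Optional[Callable[[int, int], None]] = None,
) -> pd.DataFrame:
    """One summary row per definition: config axes plus flattened metrics.

    Per-config failures are re-raised with the config identity attached.
    """
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    rows = []
    for k, config in enumerate(grid):
        try:
            summary = summarize_cohort(annotate_cohort(periods, config), periods)
        except Exception as exc:
            raise RuntimeError(
                f"summarization failed for config {config.axis_key()}"
            ) from exc
        rows.append({**config_row(config), **summary.as_row()})
        if progress is not None:
            progress(k + 1, len(grid))
    return pd.DataFrame(rows)


def grid_extremes(grid_results: pd.DataFrame) -> pd.DataFrame:
    """min / mean / max of every metric column across a grid."""
    metrics = grid_results.drop(columns=list(_CONFIG_COLUMNS), errors="ignore")
    numeric = metrics.select_dtypes("number")
    return numeric.agg(["min", "mean", "max"])


@dataclass(frozen=True)
class PairedTestResult:
    p_value: float
    mean_difference: float
    n_pairs: int


def paired_parameter_test(
    grid_results: pd.DataFrame,
    axis: str,
    value_a,
    value_b,
    metric: str = "overall_event_rate",
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
) -> PairedTestResult:
    """Paired sign-flip permutation test for one definition axis.

    Every definition with ``axis == value_a`` must have exactly one partner
    identical on all other axes with ``axis == value_b``; unmatched configs
    raise with the orphans listed.  The statistic is the mean of the
    per-pair differences (a minus b); the two-sided p-value is computed by
    sign-flipping, with exact enumeration when there are at most 12 pairs,
    otherwise ``n_permutations`` random flips from ``seed``.
    """
    key_cols = [c for c in _CONFIG_COLUMNS if c != axis and c in grid_results.columns]
    a = grid_results[grid_results[axis] == value_a].set_index(key_cols)
    b = grid_results[grid_results[axis] == value_b].set_index(key_cols)
    orphans = a.index.symmetric_difference(b.index)
    if len(orphans) > 0:
        raise ValueError(f"unmatched pairs on axis {axis!r}: {list(orphans)}")
    if a.index.has_duplicates or b.index.has_duplicates:
        raise ValueError(f"duplicate configs within a level of axis {axis!r}")
    diffs = (a[metric] - b.loc[a.index, metric]).to_numpy(dtype=float)
    # sorting makes the p-value invariant to pair ordering without
    # affecting the observed statistic or the sign-flip null
    diffs = np.sort(diffs)
    observed = float(np.mean(diffs))
    if len(diffs) <= 12:
        # exact enumeration of all 2^n sign assignments
        signs = np.array(
            list(itertools.product((1.0, -1.0), repeat=len(diffs)))
        )
        null = signs @ diffs / len(diffs)
        tol = 1e-12 * max(1.0, abs(observed))
        p_value = float(np.mean(np.abs(null) >= abs(observed) - tol))
    else:
        result = stats.permutation_test(
            (diffs,),
            lambda d, axis=-1: np.mean(d, axis=axis),
            permutation_type="samples",
            n_resamples=n_permutations,
            alternative="two-sided",
            rng=np.random.default_rng(seed),
        )
        p_value = float(result.pvalue)
    return PairedTestResult(
        p_value=p_value,
        mean_difference=observed,
        n_pairs=len(diffs),
    )


@dataclass
class LeaveOneOutSubset:
    left_out: str
    periods: list[FollowUpPeriod]


def leave_one_out_groups(
    periods: Sequence[FollowUpPeriod],
    group_field: str = "dmt_label",
    min_group: int = 100,
) -> list[LeaveOneOutSubset]:
    """Sensitivity subsets: for each group label carried by at least
    ``min_group`` periods, the cohort minus that group.  Periods without a
    label never define a group.  Returns an empty list when no label
    reaches the threshold."""
    labels = Counter(
        getattr(p, group_field)
        for p in periods
        if getattr(p, group_field, None) is not None
    )
    subsets = []
    for label, count in sorted(labels.items()):
        if count < min_group:
            continue
        subsets.append(
            LeaveOneOutSubset(
                left_out=label,
                periods=[p for p in periods if getattr(p, group_field) != label],
            )
        )
    return subsets


def plot_metric_distributions(
    grid_results: pd.DataFrame,
    metrics: Sequence[str] = ("overall_event_rate", "count_contribution_PIRA"),
):
    """Histogram panels of metric distributions across a grid (one axis
    per metric).  Returns the matplotlib Figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3))
    axes = np.atleast_1d(axes)
    for ax, metric in zip(axes, metrics):
        ax.hist(grid_results[metric].replace([np.inf], np.nan).dropna(), bins=30)
        ax.set_xlabel(metric)
        ax.set_ylabel("definitions")
    fig.tight_layout()
    return fig
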