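"""CSV / YAML readers and writers plus run manifests.

Schemas (UTF-8, comma-separated, dot decimal, days as integers; see
docs/formats.md):

* assessments.csv — patient_id, period_index, day, edss
* relapses.csv    — patient_id, period_index, day
* annotations.csv — patient_id, period_index, detection_day, event_type,
  reference_score, event_score, delta_edss, confirmation_days
  (semicolon-joined), merged_from
* ground_truth.csv — patient_id, kind {relapse, residual, progression},
  day, delta

Definition configs are YAML or JSON mappings using the exact enum
spellings of :class:`~msaccrual.data_model.DefinitionConfig`; an
``eligibility:`` key in the same file configures screening.  Every CLI run
writes a :class:`RunManifest` next to its output.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .data_model import (
    AnnotatedEvent,
    Assessment,
    DefinitionConfig,
    EventType,
    Finding,
    FollowUpPeriod,
    Relapse,
    has_errors,
    validate_period,
)
from .eligibility import EligibilityCriteria
from .simulate import GroundTruth

logger = logging.getLogger("msaccrual")

ASSESSMENT_COLUMNS = ["patient_id", "period_index", "day", "edss"]
RELAPSE_COLUMNS = ["patient_id", "period_index", "day"]
ANNOTATION_COLUMNS = [
    "patient_id",
    "period_index",
    "detection_day",
    "event_type",
    "reference_score",
    "event_score",
    "delta_edss",
    "confirmation_days",
    "merged_from",
]


class CohortReadError(ValueError):
    """Malformed input data; message names the offending file and row."""


def _read_table(path: Path, columns: list[str], numeric: dict[str, type]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CohortReadError(f"{path}: missing columns {missing}")
    for col, kind in numeric.items():
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) > 0:
            row = int(bad[0]) + 2  # header is line 1
            raise CohortReadError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} in column "
                f"{col!r} at line {row}"
            )
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0]) + 2
            raise CohortReadError(f"{path}: empty {col!r} at line {row}")
        df[col] = coerced.astype(kind)
    return df


def read_cohort(
    assessments_path: str | Path,
    relapses_path: Optional[str | Path] = None,
    permissive: bool = False,
) -> list[FollowUpPeriod]:
    """Read follow-up periods from the standard CSV pair.

    A missing relapse file yields a relapse-free cohort with a warning.
    Validation findings are logged; in strict mode (``permissive=False``)
    any error finding raises :class:`CohortReadError`.
    """
    a_df = _read_table(
        Path(assessments_path),
        ASSESSMENT_COLUMNS,
        {"period_index": int, "day": int, "edss": float},
    )
    if relapses_path is not None and Path(relapses_path).exists():
        r_df = _read_table(
            Path(relapses_path), RELAPSE_COLUMNS, {"period_index": int, "day": int}
        )
    else:
        if relapses_path is not None:
            logger.warning("relapse file %s not found: assuming no relapses", relapses_path)
        r_df = pd.DataFrame(columns=RELAPSE_COLUMNS)

    relapse_groups = {
        key: sorted(Relapse(int(d)) for d in grp["day"])
        for key, grp in r_df.groupby(["patient_id", "period_index"])
    }
    periods = []
    for (pid, pindex), grp in a_df.groupby(["patient_id", "period_index"], sort=True):
        grp = grp.sort_values("day")
        period = FollowUpPeriod(
            patient_id=str(pid),
            period_index=int(pindex),
            assessments=[
                Assessment(int(r.day), float(r.edss)) for r in grp.itertuples()
            ],
            relapses=relapse_groups.get((pid, pindex), []),
        )
        findings = validate_period(period, permissive=permissive)
        for f in findings:
            logger.log(
                logging.ERROR if f.is_error else logging.WARNING,
                "%s/%s: %s", pid, pindex, f.message,
            )
        if has_errors(findings) and not permissive:
            raise CohortReadError(
                f"invalid period {pid}/{pindex}: "
                + "; ".join(f.message for f in findings if f.is_error)
            )
        periods.append(period)
    return periods


def write_cohort(
    periods: Sequence[FollowUpPeriod],
    assessments_path: str | Path,
    relapses_path: str | Path,
) -> None:
    a_rows, r_rows = [], []
    for p in periods:
        for a in p.assessments:
            a_rows.append((p.patient_id, p.period_index, a.day, a.edss))
        for r in p.relapses:
            r_rows.append((p.patient_id, p.period_index, r.day))
    pd.DataFrame(a_rows, columns=ASSESSMENT_COLUMNS).to_csv(assessments_path, index=False)
    pd.DataFrame(r_rows, columns=RELAPSE_COLUMNS).to_csv(relapses_path, index=False)


def write_annotations(
    annotations: Sequence[Sequence[AnnotatedEvent]],
    periods: Sequence[FollowUpPeriod],
    path: str | Path,
) -> None:
    rows = []
    for events, p in zip(annotations, periods):
        for e in events:
            rows.append(
                (
                    p.patient_id,
                    p.period_index,
                    e.detection_day,
                    e.event_type.value,
                    e.reference_score,
                    e.event_score,
                    e.delta_edss,
                    ";".join(str(d) for d in e.confirmation_days),
                    e.merged_from,
                )
            )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "confirmation_days": str})
    df["event_type"] = df["event_type"].map(EventType)
    return df


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = []
    for pt in truth.patients:
        for d in pt.relapse_days:
            rows.append((pt.patient_id, "relapse", d, ""))
        for d, delta in pt.residual_steps:
            rows.append((pt.patient_id, "residual", d, delta))
        for d, delta in pt.progression_steps:
            rows.append((pt.patient_id, "progression", d, delta))
    pd.DataFrame(rows, columns=["patient_id", "kind", "day", "delta"]).to_csv(
        path, index=False
    )


# --- configuration files ----------------------------------------------------
def load_config_file(
    path: str | Path,
) -> tuple[DefinitionConfig, Optional[EligibilityCriteria]]:
    """Load a YAML/JSON definition file.  Top-level keys are
    DefinitionConfig fields, with screening thresholds under an optional
    ``eligibility:`` key."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    eligibility = raw.pop("eligibility", None)
    criteria = EligibilityCriteria(**eligibility) if eligibility else None
    return DefinitionConfig(**raw), criteria


def dump_config(config: DefinitionConfig) -> dict:
    data = config.model_dump()
    data["raw_window"] = list(config.raw_window)
    return data


# --- run manifests -----------------------------------------------------------
@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every CLI output: identical
    manifests (ignoring the timestamp) imply identical outputs."""

    command: str
    config_hash: Optional[str]
    input_digests: dict[str, str]
    version: str
    seeds: dict[str, int]
    timestamp: str

    @classmethod
    def build(
        cls,
        command: str,
        config: Optional[DefinitionConfig] = None,
        inputs: Sequence[str | Path] = (),
        seeds: Optional[dict[str, int]] = None,
    ) -> "RunManifest":
        config_hash = None
        if config is not None:
            canonical = json.dumps(dump_config(config), sort_keys=True)
            config_hash = hashlib.sha256(canonical.encode()).hexdigest()
        digests = {}
        for p in inputs:
            p = Path(p)
            if p.exists():
                digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        return cls(
            command=command,
            config_hash=config_hash,
            input_digests=digests,
            version=__version__,
            seeds=seeds or {},
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def manifest_path(output: str | Path) -> Path:
    output = Path(output)
    return output.with_name(output.name + ".manifest.json")
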