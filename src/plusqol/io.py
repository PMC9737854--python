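"""Reading, validating and writing PLUS records and results.

The on-disk interchange format is delimited text (comma-separated by
default, UTF-8, ``.`` decimal mark) with one row per subject-assessment.
Required columns: ``subject_id`` plus the six scale scores (``pss10``,
``swls``, ``nmq``, ``mbi_ee``, ``mbi_dp``, ``mbi_pa``).  ``group`` and
``timepoint`` are optional and default to ``all`` / ``t1``.  Header
matching is case-insensitive and order-free.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
import yaml

from .model import (
    SCALE_ORDER,
    SCALES,
    PlusModel,
    PlusResult,
    ScoreVector,
    default_model,
)
from .monitoring import (
    DEFAULT_THRESHOLD,
    AssessmentSeries,
    DeteriorationReport,
    GroupSummary,
    detect_deterioration,
    summarize_group,
)

__all__ = [
    "ValidationError",
    "RunConfig",
    "ScoredRecord",
    "DEFAULT_TIMEPOINT_ORDER",
    "read_records",
    "validate_records",
    "score_records",
    "results_frame",
    "write_results",
    "build_series",
    "monitor_records",
]

log = logging.getLogger("plusqol")

REQUIRED_COLUMNS = ("subject_id",) + SCALE_ORDER
OPTIONAL_COLUMNS = {"group": "all", "timepoint": "t1"}

#: Assessment order of the three-wave study design: before the pandemic,
#: during its second year, during the war in the neighboring country.
DEFAULT_TIMEPOINT_ORDER = ("t1", "t2", "t3")


class ValidationError(ValueError):
    """One or more rows failed validation; ``errors`` lists all reasons."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        preview = "\n  ".join(self.errors[:20])
        more = "" if len(self.errors) <= 20 else f"\n  ... {len(self.errors) - 20} more"
        super().__init__(f"{len(self.errors)} validation error(s):\n  {preview}{more}")


@dataclass(frozen=True)
class RunConfig:
    """Validated run-time options for the command-line pipelines."""

    model: str = "default"  # "default" or a path to a model YAML/JSON file
    threshold: float = DEFAULT_THRESHOLD
    cog_mode: str = "analytic"
    extended_boundaries: bool = True
    quartile_convention: str = "linear"
    seed: int = 0
    output_format: str = "csv"
    delimiter: str = ","
    timepoint_order: tuple[str, ...] = DEFAULT_TIMEPOINT_ORDER
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.cog_mode != "analytic":
            raise ValueError(
                "only the closed-form 'analytic' COG mode drives inference; "
                "grid integration is available as plusqol.fuzzy.numeric_centroid "
                "for verification"
            )
        if self.quartile_convention != "linear":
            raise ValueError("only the 'linear' ((n-1)*p) quartile convention is supported")
        if self.output_format not in ("csv", "json"):
            raise ValueError(f"output format must be csv or json, got {self.output_format!r}")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"unknown log level {self.log_level!r}")

    def load_model(self) -> PlusModel:
        if self.model == "default":
            return default_model()
        return PlusModel.load(self.model)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "timepoint_order" in raw:
            raw["timepoint_order"] = tuple(raw["timepoint_order"])
        return cls(**raw)


@dataclass(frozen=True)
class ScoredRecord:
    """One subject-assessment with its full PLUS evaluation."""

    subject_id: str
    group: str
    timepoint: str
    result: PlusResult


def read_records(path, delimiter: str = ",") -> pd.DataFrame:
    """Read and validate a delimited records file.

    Returns a typed table with canonical lower-case column names.  All row
    errors are aggregated into one :class:`ValidationError` carrying line
    numbers (line 1 is the header).
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    return validate_records(df, source=str(path))


def validate_records(df: pd.DataFrame, source: str = "<records>") -> pd.DataFrame:
    """Type and range checks for a records table; aggregates row errors."""
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            [f"{source}: missing required column {c!r}" for c in missing]
        )
    for col, default in OPTIONAL_COLUMNS.items():
        if col not in df.columns:
            df[col] = default
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header occupies line 1
        for sid in SCALE_ORDER:
            raw = row[sid]
            try:
                value = float(raw)
            except (TypeError, ValueError):
                errors.append(f"{source}, line {line}: {sid} value {raw!r} is not a number")
                continue
            lo, hi = SCALES[sid].domain
            if not lo <= value <= hi:
                errors.append(
                    f"{source}, line {line}: {sid} score {value:g} outside "
                    f"legal interval [{lo:g}, {hi:g}]"
                )
            df.at[idx, sid] = value
    if not errors:
        dup = df.duplicated(subset=["subject_id", "timepoint"], keep=False)
        for idx in df.index[dup]:
            errors.append(
                f"{source}, line {idx + 2}: duplicate (subject_id, timepoint) "
                f"pair ({df.at[idx, 'subject_id']!r}, {df.at[idx, 'timepoint']!r})"
            )
    if errors:
        raise ValidationError(errors)
    for sid in SCALE_ORDER:
        df[sid] = df[sid].astype(float)
    ordered = ["subject_id", "group", "timepoint", *SCALE_ORDER]
    return df[ordered]


def score_records(
    records: pd.DataFrame, model: PlusModel | None = None
) -> list[ScoredRecord]:
    """Evaluate every validated row through the PLUS hierarchy."""
    model = model or default_model()
    out = []
    for _, row in records.iterrows():
        sv = ScoreVector.from_mapping(row)
        out.append(
            ScoredRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                timepoint=str(row["timepoint"]),
                result=model.evaluate(sv),
            )
        )
    return out


_VALUE_COLUMNS = [f"norm_{sid}" for sid in SCALE_ORDER] + [
    "module_mental",
    "module_physical",
    "module_burnout",
    "plus_score",
]


def results_frame(scored: Sequence[ScoredRecord]) -> pd.DataFrame:
    """Flat results table: identifiers plus the ten model values per row."""
    rows = []
    for rec in scored:
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "timepoint": rec.timepoint,
        }
        row.update(rec.result.flat_values())
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "group", "timepoint", *_VALUE_COLUMNS])


def write_results(scored: Sequence[ScoredRecord], path, format: str = "csv") -> None:
    """Write scored records as CSV (flat values) or JSON (full traces).

    CSV serializes floats at 12 significant digits, enough to round-trip
    the scores losslessly for downstream comparison.
    """
    if not scored:
        raise ValueError("no results to write")
    if format == "csv":
        results_frame(scored).to_csv(path, index=False, float_format="%.12g")
    elif format == "json":
        payload = [
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "timepoint": rec.timepoint,
                "scores": rec.result.scores.as_dict(),
                "normalized": rec.result.normalized,
                "module_mental": rec.result.module_mental,
                "module_physical": rec.result.module_physical,
                "module_burnout": rec.result.module_burnout,
                "plus_score": rec.result.plus_score,
                "trace": rec.result.trace,
            }
            for rec in scored
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}; use csv or json")


def build_series(
    scored: Sequence[ScoredRecord],
    timepoint_order: Sequence[str] = DEFAULT_TIMEPOINT_ORDER,
) -> list[AssessmentSeries]:
    """Group scored records into per-subject longitudinal series.

    Timepoints are ordered by their position in ``timepoint_order`` (labels
    are not sortable strings); unknown labels are an error.
    """
    order = {tp: i for i, tp in enumerate(timepoint_order)}
    by_subject: dict[str, list[ScoredRecord]] = {}
    for rec in scored:
        if rec.timepoint not in order:
            raise ValidationError(
                [
                    f"subject {rec.subject_id!r}: timepoint {rec.timepoint!r} not in "
                    f"configured order {tuple(timepoint_order)}"
                ]
            )
        by_subject.setdefault(rec.subject_id, []).append(rec)
    series = []
    for subject_id, recs in by_subject.items():
        recs = sorted(recs, key=lambda r: order[r.timepoint])
        series.append(
            AssessmentSeries(
                subject_id=subject_id,
                group=recs[0].group,
                timepoints=tuple(r.timepoint for r in recs),
                scores=tuple(r.result.scores for r in recs),
                results=tuple(r.result for r in recs),
            )
        )
    return series


def monitor_records(
    records: pd.DataFrame,
    model: PlusModel | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    timepoint_order: Sequence[str] = DEFAULT_TIMEPOINT_ORDER,
) -> tuple[list[DeteriorationReport], list[GroupSummary]]:
    """Longitudinal pipeline: score, per-subject reports, per-group summaries."""
    scored = score_records(records, model)
    series = build_series(scored, timepoint_order)
    reports = [detect_deterioration(s, threshold) for s in series]
    summaries = []
    frame = results_frame(scored)
    for (group, timepoint), sub in frame.groupby(["group", "timepoint"], sort=True):
        if len(sub) >= 2:
            summaries.append(
                summarize_group(sub["plus_score"].to_numpy(), group, timepoint)
            )
    order = {tp: i for i, tp in enumerate(timepoint_order)}
    summaries.sort(key=lambda s: (s.group, order.get(s.timepoint, len(order))))
    return reports, summaries
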