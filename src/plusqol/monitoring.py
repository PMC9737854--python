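"""Longitudinal and group-level analytics over PLUS results.

Given repeated assessments of the same subjects, this module computes
per-step deltas, classifies trends, flags deterioration, summarizes a
group's score distribution per timepoint, and correlates changes in the
composite score with changes in the underlying questionnaires.

Conventions pinned by the reference cohort's published summary statistics:
quartiles use linear interpolation at position ``(n - 1) * p`` and the
standard deviation is the sample (n - 1) estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .model import SCALE_ORDER, PlusResult, ScoreVector

__all__ = [
    "InsufficientDataError",
    "AssessmentSeries",
    "DeteriorationReport",
    "GroupSummary",
    "DEFAULT_THRESHOLD",
    "SIGNIFICANCE_LEVEL",
    "compute_deltas",
    "detect_deterioration",
    "summarize_group",
    "change_correlation",
]


class InsufficientDataError(ValueError):
    """A longitudinal operation needs more assessments than were provided."""


#: Default decline on the PLUS scale treated as deterioration.  The value
#: separates a clearly declining trajectory (mean per-step decline of the
#: deteriorating reference group: 0.060 and 0.113) from a stable one
#: (reference group: -0.044 and +0.035).
DEFAULT_THRESHOLD = 0.05

#: Two-sided significance level used when reporting correlations.
SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class AssessmentSeries:
    """Ordered repeated assessments of one subject."""

    subject_id: str
    group: str
    timepoints: tuple[str, ...]
    scores: tuple[ScoreVector, ...]
    results: tuple[PlusResult, ...]

    def __post_init__(self) -> None:
        n = len(self.timepoints)
        if n < 1:
            raise ValueError("series needs at least one assessment")
        if len(self.scores) != n or len(self.results) != n:
            raise ValueError("timepoints, scores and results must align")
        if len(set(self.timepoints)) != n:
            raise ValueError(
                f"subject {self.subject_id!r}: duplicate timepoints {self.timepoints}"
            )

    @property
    def plus_scores(self) -> tuple[float, ...]:
        return tuple(r.plus_score for r in self.results)


@dataclass(frozen=True)
class DeteriorationReport:
    """Per-subject longitudinal verdict."""

    subject_id: str
    group: str
    plus_scores: tuple[float, ...]
    deltas: tuple[float, ...]
    trend: str  # deteriorating | improving | stable | mixed
    deteriorated: bool
    largest_decline: float
    threshold: float

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "plus_scores": list(self.plus_scores),
            "deltas": list(self.deltas),
            "trend": self.trend,
            "deteriorated": self.deteriorated,
            "largest_decline": self.largest_decline,
            "threshold": self.threshold,
        }


@dataclass(frozen=True)
class GroupSummary:
    """Distribution summary of one group's PLUS scores at one timepoint."""

    group: str
    timepoint: str
    n: int
    total: float
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    mean: float
    sd: float

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "timepoint": self.timepoint,
            "n": self.n,
            "sum": self.total,
            "min": self.minimum,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "max": self.maximum,
            "mean": self.mean,
            "sd": self.sd,
        }


def compute_deltas(series: AssessmentSeries) -> dict[str, tuple[float, ...]]:
    """Consecutive-assessment differences for PLUS and each raw scale.

    ``delta[i] = value[i + 1] - value[i]``.  Requires at least two
    assessments.
    """
    if len(series.timepoints) < 2:
        raise InsufficientDataError(
            f"subject {series.subject_id!r}: need >= 2 assessments to compute "
            f"changes, got {len(series.timepoints)}"
        )
    out: dict[str, tuple[float, ...]] = {
        "plus": tuple(np.diff(series.plus_scores))
    }
    for sid in SCALE_ORDER:
        vals = [getattr(sv, sid) for sv in series.scores]
        out[sid] = tuple(np.diff(vals))
    return out


def detect_deterioration(
    series: AssessmentSeries, threshold: float = DEFAULT_THRESHOLD
) -> DeteriorationReport:
    """Flag a subject whose PLUS score dropped by at least ``threshold``.

    The flag is raised iff some per-step delta is an actual decline of at
    least ``threshold`` (so a flat trajectory is never flagged, even at
    threshold 0).  The trend
    label summarizes the whole trajectory: strictly negative deltas ->
    deteriorating, strictly positive -> improving, all within the threshold
    band -> stable, anything else -> mixed.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    deltas = compute_deltas(series)["plus"]
    arr = np.asarray(deltas)
    flag = bool(np.any((arr < 0) & (arr <= -threshold)))
    if np.all(arr < 0):
        trend = "deteriorating"
    elif np.all(arr > 0):
        trend = "improving"
    elif np.all(np.abs(arr) <= threshold):
        trend = "stable"
    else:
        trend = "mixed"
    return DeteriorationReport(
        subject_id=series.subject_id,
        group=series.group,
        plus_scores=series.plus_scores,
        deltas=deltas,
        trend=trend,
        deteriorated=flag,
        largest_decline=float(max(0.0, -arr.min())),
        threshold=threshold,
    )


def summarize_group(
    scores: Sequence[float], group: str = "", timepoint: str = ""
) -> GroupSummary:
    """Sum / min / Q1 / median / Q3 / max / mean / SD of one group-timepoint.

    Quartiles interpolate linearly between order statistics at positions
    ``(n - 1) * p``; SD uses the n - 1 denominator.  Values are kept at
    full precision (round only for display).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"need >= 2 subjects to summarize a group, got {arr.size}"
        )
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])  # linear interpolation
    return GroupSummary(
        group=group,
        timepoint=timepoint,
        n=int(arr.size),
        total=float(arr.sum()),
        minimum=float(arr.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(arr.max()),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
    )


def change_correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t",
    n_permutations: int = 9999,
    seed: int | None = None,
) -> dict:
    """Spearman rank correlation between two change series.

    Ranks use midranks for ties.  With ``method='t'`` the two-sided p-value
    comes from the t-distribution approximation (what common statistics
    packages report); ``method='permutation'`` uses a permutation test on
    the pairings instead, which is preferable at very small n.
    Returns rho, the p-value and a significance flag at the 0.05 level.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if xa.size < 3:
        raise InsufficientDataError(
            f"need >= 3 paired changes for a correlation, got {xa.size}"
        )
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("correlation undefined for a constant input series")
    if method == "t":
        res = stats.spearmanr(xa, ya)
        rho, p = float(res.statistic), float(res.pvalue)
    elif method == "permutation":
        perm = stats.permutation_test(
            (xa, ya),
            lambda a, b: stats.spearmanr(a, b).statistic,
            permutation_type="pairings",
            n_resamples=n_permutations,
            alternative="two-sided",
            rng=np.random.default_rng(seed),
        )
        rho = float(stats.spearmanr(xa, ya).statistic)
        p = float(perm.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}; use 't' or 'permutation'")
    return {"rho": rho, "p": p, "significant": bool(p < SIGNIFICANCE_LEVEL)}
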