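"""Seeded synthetic cohorts with the study design of the PLUS evaluation.

The original evaluation followed two occupational groups (physiotherapists
and IT professionals, n = 20 each) across three assessments: before the
COVID-19 pandemic, during its second year, and during the war in the
neighboring country.  The raw per-subject questionnaire data were never
published, so this module generates cohorts with the same structure whose
group-level location/scale and drift directions follow the published
summary statistics.  It is a fixture factory for exercising the pipeline,
not a psychometric claim.

Scores are drawn from a normal distribution per scale and timepoint,
rounded to the instruments' integer granularity and clamped to each legal
interval; within-subject correlation across timepoints comes from a shared
subject-level offset whose SD defaults to half the cross-sectional SD.

Reconstructions baked into the presets (see docs/methods.md for details):

* the published group summaries report only an MBI aggregate; the presets
  split it into emotional-exhaustion / depersonalization / personal-
  accomplishment components, with PA drifting opposite to EE and DP;
* the published group-2 life-satisfaction column exceeds the SWLS legal
  range (an apparent column corruption) and is rescaled into range;
* group-2 burnout is made to worsen at the second assessment and recover
  below baseline afterwards, matching the published model-outcome dip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import SCALES, SCALE_ORDER

__all__ = ["CohortSpec", "preset_specs", "generate_cohort", "TIMEPOINTS"]

TIMEPOINTS = ("t1", "t2", "t3")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic group.

    ``means``/``sds`` map each scale id to its per-timepoint location and
    cross-sectional scale.  ``drift`` records the intended sign of the
    endpoint change (+1 up, -1 down, 0 none) and is metadata consistent
    with ``means`` by construction.
    """

    group: str
    n: int
    means: Mapping[str, tuple[float, float, float]]
    sds: Mapping[str, tuple[float, float, float]]
    drift: Mapping[str, int] = field(default_factory=dict)
    subject_offset_frac: float = 0.5
    timepoints: tuple[str, ...] = TIMEPOINTS

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"cohort needs n >= 2 subjects, got {self.n}")
        for sid in SCALE_ORDER:
            if sid not in self.means or sid not in self.sds:
                raise ValueError(f"spec for group {self.group!r} missing scale {sid!r}")
            if len(self.means[sid]) != len(self.timepoints):
                raise ValueError(f"{sid}: need one mean per timepoint")
            if any(s < 0 for s in self.sds[sid]):
                raise ValueError(f"{sid}: SDs must be non-negative")
        if not 0.0 <= self.subject_offset_frac <= 1.0:
            raise ValueError("subject_offset_frac must be in [0, 1]")


def preset_specs() -> dict[str, CohortSpec]:
    """The two built-in cohort presets.

    ``group1-like`` emulates the physiotherapist group: steadily rising
    stress, exhaustion, depersonalization and musculoskeletal complaints,
    with falling life satisfaction and sense of accomplishment.
    ``group2-like`` emulates the IT-professional group: a transient dip in
    burnout-related scales at the second assessment with mild overall
    improvement, and essentially unchanged musculoskeletal complaints.
    """
    group1 = CohortSpec(
        group="group1-like",
        n=20,
        means={
            "pss10": (29.20, 30.85, 33.20),
            "swls": (16.30, 14.90, 10.95),
            "nmq": (0.55, 0.70, 0.85),
            "mbi_ee": (26.80, 31.20, 34.90),
            "mbi_dp": (12.20, 14.20, 15.90),
            "mbi_pa": (30.30, 27.40, 24.90),
        },
        sds={
            "pss10": (2.71, 2.25, 2.19),
            "swls": (3.57, 3.42, 2.26),
            "nmq": (0.73, 0.73, 0.73),
            "mbi_ee": (8.53, 6.97, 4.94),
            "mbi_dp": (3.88, 3.17, 2.25),
            "mbi_pa": (4.65, 3.80, 2.70),
        },
        drift={
            "pss10": +1,
            "swls": -1,
            "nmq": +1,
            "mbi_ee": +1,
            "mbi_dp": +1,
            "mbi_pa": -1,
        },
    )
    group2 = CohortSpec(
        group="group2-like",
        n=20,
        means={
            "pss10": (18.55, 16.10, 18.05),
            "swls": (21.40, 25.00, 22.40),
            "nmq": (0.45, 0.50, 0.50),
            "mbi_ee": (9.50, 13.00, 8.90),
            "mbi_dp": (4.30, 5.90, 4.00),
            "mbi_pa": (41.70, 39.50, 42.30),
        },
        sds={
            "pss10": (3.50, 2.75, 3.53),
            "swls": (7.02, 6.56, 5.62),
            "nmq": (0.51, 0.51, 0.51),
            "mbi_ee": (2.90, 2.40, 2.10),
            "mbi_dp": (1.50, 1.50, 1.20),
            "mbi_pa": (3.00, 3.00, 3.00),
        },
        drift={
            "pss10": -1,
            "swls": +1,
            "nmq": 0,
            "mbi_ee": -1,
            "mbi_dp": -1,
            "mbi_pa": +1,
        },
    )
    return {"group1-like": group1, "group2-like": group2}


def _check_truncation(spec: CohortSpec) -> None:
    for sid in SCALE_ORDER:
        lo, hi = SCALES[sid].domain
        for t, (mu, sd) in enumerate(zip(spec.means[sid], spec.sds[sid])):
            if sd == 0:
                inside = 1.0 if lo <= mu <= hi else 0.0
            else:
                inside = norm.cdf(hi, mu, sd) - norm.cdf(lo, mu, sd)
            if inside < 0.5:
                warnings.warn(
                    f"group {spec.group!r}, scale {sid!r}, timepoint "
                    f"{spec.timepoints[t]!r}: mean {mu} / SD {sd} places "
                    f"{(1 - inside):.0%} of the mass outside [{lo}, {hi}]",
                    stacklevel=3,
                )


def generate_cohort(
    spec: CohortSpec, seed: int, n: int | None = None
) -> pd.DataFrame:
    """Draw one synthetic cohort as a long-format records table.

    One row per subject and timepoint with columns ``subject_id``,
    ``group``, ``timepoint`` and the six scale scores.  Fully reproducible
    from ``seed``; ``n`` overrides the spec's subject count.
    """
    _check_truncation(spec)
    n_subj = spec.n if n is None else int(n)
    if n_subj < 2:
        raise ValueError(f"need n >= 2 subjects, got {n_subj}")
    rng = np.random.default_rng(seed)
    n_tp = len(spec.timepoints)
    width = len(str(n_subj))
    rows = []
    columns: dict[str, np.ndarray] = {}
    for sid in SCALE_ORDER:
        lo, hi = SCALES[sid].domain
        mus = np.asarray(spec.means[sid], dtype=float)
        sds = np.asarray(spec.sds[sid], dtype=float)
        offset_sd = spec.subject_offset_frac * sds.mean()
        resid_sd = np.sqrt(np.maximum(sds**2 - offset_sd**2, 0.0))
        offsets = rng.normal(0.0, offset_sd, size=n_subj) if offset_sd > 0 else np.zeros(n_subj)
        noise = rng.normal(0.0, 1.0, size=(n_subj, n_tp)) * resid_sd
        vals = mus[None, :] + offsets[:, None] + noise
        columns[sid] = np.clip(np.rint(vals), lo, hi)
    for s in range(n_subj):
        sid_label = f"{spec.group}-{s + 1:0{width}d}"
        for t, tp in enumerate(spec.timepoints):
            row = {"subject_id": sid_label, "group": spec.group, "timepoint": tp}
            for scale in SCALE_ORDER:
                row[scale] = float(columns[scale][s, t])
            rows.append(row)
    return pd.DataFrame(rows)
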