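"""The PLUS three-tier fuzzy hierarchy.

PLUS ("personal living usual satisfaction") aggregates four clinimetric
questionnaires into a single life-satisfaction score in [0, 1]:

* tier 1 -- per-scale fuzzy normalization of the six raw inputs (PSS10,
  SWLS, NMQ, and the three MBI subscales) onto a common
  "the higher, the better" [0, 1] axis;
* tier 2 -- three context modules: mental state (PSS10 + SWLS), physical
  condition (NMQ alone, passed through unchanged), and occupational
  burnout (the three MBI subscales);
* tier 3 -- a final aggregator with the same structure as the burnout
  module, combining the three module outputs with equal importance.

Every tier is a Mamdani system with product premises, min implication,
max accumulation and centre-of-gravity defuzzification.  Boundary output
sets are extended symmetrically past 0 and 1 so that the centroid can
reach exactly 0 and exactly 1 at the extremes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .fuzzy import (
    FuzzyRule,
    LinguisticVariable,
    MamdaniSystem,
    TrapezoidSet,
)

__all__ = [
    "SCALES",
    "SCALE_ORDER",
    "ScalePartition",
    "ScoreVector",
    "PlusResult",
    "PlusModel",
    "build_default_model",
    "default_model",
    "normalize_score",
    "eval_two_input_module",
    "eval_three_input_module",
    "evaluate_plus",
    "plus_score_grid",
    "three_level_output",
    "four_level_output",
    "unit_interval_input",
]

THIRD = 1.0 / 3.0


@dataclass(frozen=True)
class ScalePartition:
    """Low/medium/high trapezoids of one questionnaire scale."""

    scale_id: str
    domain: tuple[float, float]
    low: tuple[float, float, float, float]
    medium: tuple[float, float, float, float]
    high: tuple[float, float, float, float]
    higher_is_better: bool

    def variable(self) -> LinguisticVariable:
        return LinguisticVariable(
            name=self.scale_id,
            domain=self.domain,
            sets=(
                TrapezoidSet("low", *self.low),
                TrapezoidSet("medium", *self.medium),
                TrapezoidSet("high", *self.high),
            ),
        )


#: The published partitions of the six input scales.  Only SWLS and the MBI
#: personal-accomplishment subscale run "higher is better"; the other four
#: measure stress/complaints and are reversed during normalization.  Note
#: the personal-accomplishment sets reach 49 although the subscale maxes at
#: 48; the published parameters are kept verbatim, so a perfect PA score
#: normalizes to slightly below 1.
SCALES: dict[str, ScalePartition] = {
    "pss10": ScalePartition(
        "pss10", (0, 40), (0, 0, 0, 14), (0, 14, 26, 40), (26, 40, 40, 40), False
    ),
    "swls": ScalePartition(
        "swls", (5, 35), (5, 5, 5, 15), (5, 15, 24, 35), (24, 35, 35, 35), True
    ),
    "nmq": ScalePartition(
        "nmq", (0, 40), (0, 0, 0, 14), (0, 14, 26, 40), (26, 40, 40, 40), False
    ),
    "mbi_ee": ScalePartition(
        "mbi_ee", (0, 54), (0, 0, 0, 16), (0, 16, 27, 54), (27, 54, 54, 54), False
    ),
    "mbi_dp": ScalePartition(
        "mbi_dp", (0, 30), (0, 0, 0, 8), (0, 8, 14, 30), (14, 30, 30, 30), False
    ),
    "mbi_pa": ScalePartition(
        "mbi_pa", (0, 48), (0, 0, 0, 31), (0, 31, 39, 49), (39, 49, 49, 49), True
    ),
}

SCALE_ORDER = ("pss10", "swls", "nmq", "mbi_ee", "mbi_dp", "mbi_pa")


def three_level_output(extended: bool = True) -> LinguisticVariable:
    """Three-level output partition of [0, 1] (tier-1 normalizers, mental module).

    With ``extended=True`` the boundary sets become symmetric triangles
    centred on 0 and 1 so their centroids sit exactly at the endpoints.
    """
    low = (-0.5, 0, 0, 0.5) if extended else (0, 0, 0, 0.5)
    high = (0.5, 1, 1, 1.5) if extended else (0.5, 1, 1, 1)
    return LinguisticVariable(
        name="e",
        domain=(0.0, 1.0),
        sets=(
            TrapezoidSet("low", *low),
            TrapezoidSet("medium", 0, 0.5, 0.5, 1),
            TrapezoidSet("high", *high),
        ),
    )


def four_level_output(extended: bool = True) -> LinguisticVariable:
    """Four-level output partition of [0, 1] (three-input modules, final tier).

    Interior breakpoints are exact thirds.
    """
    low = (-THIRD, 0, 0, THIRD) if extended else (0, 0, 0, THIRD)
    high = (2 * THIRD, 1, 1, 1 + THIRD) if extended else (2 * THIRD, 1, 1, 1)
    return LinguisticVariable(
        name="o",
        domain=(0.0, 1.0),
        sets=(
            TrapezoidSet("low", *low),
            TrapezoidSet("medium_low", 0, THIRD, THIRD, 2 * THIRD),
            TrapezoidSet("medium_high", THIRD, 2 * THIRD, 2 * THIRD, 1),
            TrapezoidSet("high", *high),
        ),
    )


def unit_interval_input(name: str) -> LinguisticVariable:
    """Two-valued (low/high) Ruspini partition of a normalized [0, 1] input."""
    return LinguisticVariable(
        name=name,
        domain=(0.0, 1.0),
        sets=(TrapezoidSet("low", 0, 0, 0, 1), TrapezoidSet("high", 0, 1, 1, 1)),
    )


_TIER1_DEFUZZ = (-0.5, 1.5)
_MODULE_DEFUZZ = (-THIRD, 1 + THIRD)


def build_tier1_system(partition: ScalePartition, extended: bool = True) -> MamdaniSystem:
    """Single-input normalizer mapping one raw scale onto [0, 1], higher = better."""
    if partition.higher_is_better:
        mapping = {"low": "low", "medium": "medium", "high": "high"}
    else:
        mapping = {"low": "high", "medium": "medium", "high": "low"}
    rules = tuple(
        FuzzyRule(((partition.scale_id, ant),), cons) for ant, cons in mapping.items()
    )
    return MamdaniSystem(
        name=f"normalize_{partition.scale_id}",
        inputs=(partition.variable(),),
        output=three_level_output(extended),
        rules=rules,
        defuzz_domain=_TIER1_DEFUZZ if extended else None,
    )


def build_two_input_system(
    name: str, in1: str, in2: str, extended: bool = True
) -> MamdaniSystem:
    """Two-input aggregator: LL -> low, LH/HL -> medium, HH -> high.

    The three-level output partition mirrors the tier-1 one; the rule base
    is the minimal two-input analogue of the three-input module below and
    preserves mirror symmetry under input complementation.
    """
    rules = tuple(
        FuzzyRule(
            ((in1, a), (in2, b)),
            ("low", "medium", "high")[(a == "high") + (b == "high")],
        )
        for a in ("low", "high")
        for b in ("low", "high")
    )
    return MamdaniSystem(
        name=name,
        inputs=(unit_interval_input(in1), unit_interval_input(in2)),
        output=three_level_output(extended),
        rules=rules,
        defuzz_domain=_TIER1_DEFUZZ if extended else None,
    )


def build_three_input_system(
    name: str, in1: str, in2: str, in3: str, extended: bool = True
) -> MamdaniSystem:
    """Three-input aggregator with the published 8-rule base.

    The consequent level equals the number of inputs that are "high":
    LLL -> low, one high -> medium_low, two high -> medium_high,
    HHH -> high.
    """
    levels = ("low", "medium_low", "medium_high", "high")
    rules = tuple(
        FuzzyRule(
            ((in1, a), (in2, b), (in3, c)),
            levels[(a == "high") + (b == "high") + (c == "high")],
        )
        for a in ("low", "high")
        for b in ("low", "high")
        for c in ("low", "high")
    )
    return MamdaniSystem(
        name=name,
        inputs=(
            unit_interval_input(in1),
            unit_interval_input(in2),
            unit_interval_input(in3),
        ),
        output=four_level_output(extended),
        rules=rules,
        defuzz_domain=_MODULE_DEFUZZ if extended else None,
    )


@dataclass(frozen=True)
class ScoreVector:
    """One subject-assessment's six raw questionnaire scores.

    Scores are accepted as reals (half-point scoring occurs in practice)
    and validated against each instrument's legal closed interval.
    """

    pss10: float
    swls: float
    nmq: float
    mbi_ee: float
    mbi_dp: float
    mbi_pa: float

    def __post_init__(self) -> None:
        for scale_id in SCALE_ORDER:
            value = getattr(self, scale_id)
            lo, hi = SCALES[scale_id].domain
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ValueError(f"{scale_id}: score must be a finite number, got {value!r}")
            if not lo <= value <= hi:
                raise ValueError(
                    f"{scale_id}: score {value} outside legal interval [{lo}, {hi}]"
                )

    def as_dict(self) -> dict[str, float]:
        return {sid: float(getattr(self, sid)) for sid in SCALE_ORDER}

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "ScoreVector":
        return cls(**{sid: float(m[sid]) for sid in SCALE_ORDER})


@dataclass(frozen=True)
class PlusResult:
    """Full evaluation trace of one score vector through the hierarchy."""

    scores: ScoreVector
    normalized: dict[str, float]
    module_mental: float
    module_physical: float
    module_burnout: float
    plus_score: float
    trace: dict

    def flat_values(self) -> dict[str, float]:
        out = {f"norm_{sid}": self.normalized[sid] for sid in SCALE_ORDER}
        out.update(
            module_mental=self.module_mental,
            module_physical=self.module_physical,
            module_burnout=self.module_burnout,
            plus_score=self.plus_score,
        )
        return out


def _clamp01(v: float) -> float:
    # centroids of these systems lie in [0, 1] mathematically; this only
    # removes sub-1e-15 floating-point residue at the exact endpoints
    return min(1.0, max(0.0, v))


class PlusModel:
    """The wired hierarchy: six normalizers, three modules, final aggregator.

    Inference results are memoized per raw input value, which makes dense
    grid sweeps cheap (a 5-level 6-axis grid touches only 30 distinct
    tier-1 inferences).
    """

    def __init__(
        self,
        tier1: Mapping[str, MamdaniSystem],
        mental: MamdaniSystem,
        burnout: MamdaniSystem,
        final: MamdaniSystem,
    ):
        missing = set(SCALE_ORDER) - set(tier1)
        if missing:
            raise ValueError(f"tier-1 systems missing for scales: {sorted(missing)}")
        self.tier1 = dict(tier1)
        self.mental = mental
        self.burnout = burnout
        self.final = final
        self._cache: dict[tuple, object] = {}

    # -- single-stage evaluations ------------------------------------------

    def _cached(self, key, system: MamdaniSystem, inputs: dict):
        hit = self._cache.get(key)
        if hit is None:
            hit = system.infer(inputs)
            self._cache[key] = hit
        return hit

    def normalize(self, scale_id: str, value: float) -> float:
        """Tier-1 normalization of one raw score onto [0, 1], higher = better."""
        if scale_id not in self.tier1:
            raise KeyError(f"unknown scale {scale_id!r}")
        system = self.tier1[scale_id]
        trace = self._cached(("t1", scale_id, value), system, {scale_id: value})
        return _clamp01(trace.value)

    def eval_mental(self, norm_pss10: float, norm_swls: float) -> float:
        names = [v.name for v in self.mental.inputs]
        trace = self._cached(
            ("mental", norm_pss10, norm_swls),
            self.mental,
            dict(zip(names, (norm_pss10, norm_swls))),
        )
        return _clamp01(trace.value)

    def eval_burnout(self, norm_ee: float, norm_dp: float, norm_pa: float) -> float:
        names = [v.name for v in self.burnout.inputs]
        trace = self._cached(
            ("burnout", norm_ee, norm_dp, norm_pa),
            self.burnout,
            dict(zip(names, (norm_ee, norm_dp, norm_pa))),
        )
        return _clamp01(trace.value)

    def eval_final(self, mental: float, physical: float, burnout: float) -> float:
        names = [v.name for v in self.final.inputs]
        trace = self._cached(
            ("final", mental, physical, burnout),
            self.final,
            dict(zip(names, (mental, physical, burnout))),
        )
        return _clamp01(trace.value)

    # -- full hierarchy ----------------------------------------------------

    def evaluate(self, scores: ScoreVector, keep_trace: bool = True) -> PlusResult:
        """Run one score vector through all three tiers.

        The physical module has a single input, so the normalized NMQ value
        is transmitted to the final tier unchanged.
        """
        normalized = {
            sid: self.normalize(sid, getattr(scores, sid)) for sid in SCALE_ORDER
        }
        mental = self.eval_mental(normalized["pss10"], normalized["swls"])
        physical = normalized["nmq"]
        burnout = self.eval_burnout(
            normalized["mbi_ee"], normalized["mbi_dp"], normalized["mbi_pa"]
        )
        plus = self.eval_final(mental, physical, burnout)
        trace: dict = {}
        if keep_trace:
            trace = {
                "tier1": {
                    sid: self._cache[("t1", sid, getattr(scores, sid))].to_dict()
                    for sid in SCALE_ORDER
                },
                "modules": {
                    "mental": self._cache[
                        ("mental", normalized["pss10"], normalized["swls"])
                    ].to_dict(),
                    "physical": {"passthrough": physical},
                    "burnout": self._cache[
                        (
                            "burnout",
                            normalized["mbi_ee"],
                            normalized["mbi_dp"],
                            normalized["mbi_pa"],
                        )
                    ].to_dict(),
                },
                "final": self._cache[("final", mental, physical, burnout)].to_dict(),
            }
        return PlusResult(
            scores=scores,
            normalized=normalized,
            module_mental=mental,
            module_physical=physical,
            module_burnout=burnout,
            plus_score=plus,
            trace=trace,
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "plusqol-model",
            "version": 1,
            "tier1": {sid: self.tier1[sid].to_dict() for sid in SCALE_ORDER},
            "mental": self.mental.to_dict(),
            "burnout": self.burnout.to_dict(),
            "final": self.final.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlusModel":
        if d.get("format") != "plusqol-model":
            raise ValueError("not a plusqol model definition")
        return cls(
            tier1={sid: MamdaniSystem.from_dict(s) for sid, s in d["tier1"].items()},
            mental=MamdaniSystem.from_dict(d["mental"]),
            burnout=MamdaniSystem.from_dict(d["burnout"]),
            final=MamdaniSystem.from_dict(d["final"]),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PlusModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_default_model(extended: bool = True) -> PlusModel:
    """Construct the PLUS hierarchy from the published partitions and rules."""
    tier1 = {
        sid: build_tier1_system(SCALES[sid], extended=extended) for sid in SCALE_ORDER
    }
    mental = build_two_input_system("mental_state", "pss10", "swls", extended=extended)
    burnout = build_three_input_system(
        "burnout", "mbi_ee", "mbi_dp", "mbi_pa", extended=extended
    )
    final = build_three_input_system(
        "plus", "mental", "physical", "burnout", extended=extended
    )
    return PlusModel(tier1=tier1, mental=mental, burnout=burnout, final=final)


_DEFAULT: PlusModel | None = None


def default_model() -> PlusModel:
    """Shared default model instance (memoization accumulates across calls)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = build_default_model()
    return _DEFAULT


def normalize_score(scale_id: str, value: float, model: PlusModel | None = None) -> float:
    """Tier-1 normalization of one raw score using the default model."""
    return (model or default_model()).normalize(scale_id, value)


def eval_two_input_module(a: float, b: float, model: PlusModel | None = None) -> float:
    """Two-input aggregation of normalized values (the mental-state structure)."""
    return (model or default_model()).eval_mental(a, b)


def eval_three_input_module(
    a: float, b: float, c: float, model: PlusModel | None = None
) -> float:
    """Three-input aggregation of normalized values (burnout / final structure)."""
    return (model or default_model()).eval_burnout(a, b, c)


def evaluate_plus(scores: ScoreVector, model: PlusModel | None = None) -> PlusResult:
    """Evaluate one score vector through the default PLUS hierarchy."""
    return (model or default_model()).evaluate(scores)


def plus_score_grid(levels: int = 5, model: PlusModel | None = None):
    """PLUS scores over a full factorial grid of raw inputs.

    Each of the six scales is sampled at ``levels`` evenly spaced points
    including both endpoints of its legal range.  Returns a flat numpy
    array of ``levels ** 6`` scores (C order over SCALE_ORDER axes).
    """
    import itertools

    import numpy as np

    model = model or build_default_model()
    axes = []
    for sid in SCALE_ORDER:
        lo, hi = SCALES[sid].domain
        axes.append(np.linspace(lo, hi, levels))
    out = np.empty(levels ** len(SCALE_ORDER))
    for i, combo in enumerate(itertools.product(*axes)):
        sv = ScoreVector(*combo)
        out[i] = model.evaluate(sv, keep_trace=False).plus_score
    return out
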