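"""Generic Mamdani fuzzy-inference machinery.

This module implements the small core every tier of the PLUS hierarchy is
built from: trapezoidal fuzzy sets, linguistic variables, rule bases with
product premise aggregation, min-implication clipping, max accumulation and
exact centre-of-gravity (COG) defuzzification over piecewise-linear curves.

The operator configuration is deliberately rigid: ``PROD`` for premise
aggregation, ``MIN`` for implication, ``MAX`` for accumulation and ``COG``
for defuzzification.  These are the operators the PLUS model was designed
and validated with; anything else is rejected at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FuzzyError",
    "DomainError",
    "DegenerateInferenceError",
    "TrapezoidSet",
    "LinguisticVariable",
    "FuzzyRule",
    "OperatorConfig",
    "PiecewiseLinearFunction",
    "MamdaniSystem",
    "InferenceTrace",
]


class FuzzyError(Exception):
    """Base class for fuzzy-engine errors."""


class DomainError(FuzzyError):
    """An input value lies outside a linguistic variable's domain."""


class DegenerateInferenceError(FuzzyError):
    """No rule fired with positive degree, or the accumulated curve has zero area."""


@dataclass(frozen=True)
class TrapezoidSet:
    """Trapezoidal fuzzy set ``(l, k1, k2, r)``.

    Membership is 0 outside ``[l, r]``, 1 on the kernel ``[k1, k2]`` and
    linear on the two ramps.  Degenerate shoulders (``l == k1`` or
    ``k2 == r``) make the corresponding edge a jump: the kernel point keeps
    membership 1.  This jump convention is what lets a set like
    ``(0, 0, 0, 14)`` assign full membership to a raw score of exactly 0.
    """

    label: str
    l: float
    k1: float
    k2: float
    r: float

    def __post_init__(self) -> None:
        if not (self.l <= self.k1 <= self.k2 <= self.r):
            raise ValueError(
                f"trapezoid {self.label!r}: need l <= k1 <= k2 <= r, "
                f"got ({self.l}, {self.k1}, {self.k2}, {self.r})"
            )

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.l, self.k1, self.k2, self.r)

    def membership(self, x):
        """Membership degree at ``x`` (scalar or ndarray)."""
        arr = np.asarray(x, dtype=float)
        out = np.zeros_like(arr)
        out[(arr >= self.k1) & (arr <= self.k2)] = 1.0
        if self.l < self.k1:
            rising = (arr > self.l) & (arr < self.k1)
            out[rising] = (arr[rising] - self.l) / (self.k1 - self.l)
        if self.k2 < self.r:
            falling = (arr > self.k2) & (arr < self.r)
            out[falling] = (self.r - arr[falling]) / (self.r - self.k2)
        if np.isscalar(x) or np.ndim(x) == 0:
            return float(out)
        return out

    def clipped(self, height: float, lo: float, hi: float) -> "PiecewiseLinearFunction":
        """min(height, membership) as a piecewise-linear curve on ``[lo, hi]``.

        Jump shoulders produce duplicated x breakpoints (a vertical step);
        the integration routines treat zero-width segments as zero area.
        """
        if not 0.0 <= height <= 1.0:
            raise ValueError(f"clip height must be in [0, 1], got {height}")
        l, k1, k2, r = self.params
        if l < lo or r > hi:
            raise ValueError(
                f"support [{l}, {r}] of {self.label!r} exceeds integration "
                f"interval [{lo}, {hi}]"
            )
        pts: list[tuple[float, float]] = [(lo, 0.0)]
        if l > lo:
            pts.append((l, 0.0))
        # plateau bounds of the clipped trapezoid
        p_lo = l + height * (k1 - l)
        p_hi = k2 + (1.0 - height) * (r - k2)
        pts.append((p_lo, height))
        if p_hi > p_lo:
            pts.append((p_hi, height))
        if r < hi:
            pts.append((r, 0.0))
            pts.append((hi, 0.0))
        else:
            pts.append((hi, 0.0 if k2 < r else height))
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        keep = np.concatenate(([True], (np.diff(xs) > 0) | (np.abs(np.diff(ys)) > 0)))
        return PiecewiseLinearFunction(xs[keep], ys[keep])

    def to_dict(self) -> dict:
        return {"label": self.label, "params": [self.l, self.k1, self.k2, self.r]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrapezoidSet":
        l, k1, k2, r = (float(v) for v in d["params"])
        return cls(str(d["label"]), l, k1, k2, r)


@dataclass(frozen=True)
class LinguisticVariable:
    """A named domain interval carrying an ordered family of labeled sets.

    The support of a set may overshoot the nominal domain (the published
    partition for the personal-accomplishment subscale reaches 49 on a
    0-48 scale); overshoot is tolerated because only in-domain points are
    ever fuzzified.
    """

    name: str
    domain: tuple[float, float]
    sets: tuple[TrapezoidSet, ...]

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError(f"variable {self.name!r}: empty domain {self.domain}")
        if not self.sets:
            raise ValueError(f"variable {self.name!r}: needs at least one set")
        labels = [s.label for s in self.sets]
        if len(set(labels)) != len(labels):
            raise ValueError(f"variable {self.name!r}: duplicate set labels {labels}")
        object.__setattr__(self, "sets", tuple(self.sets))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sets)

    def set(self, label: str) -> TrapezoidSet:
        for s in self.sets:
            if s.label == label:
                return s
        raise KeyError(f"variable {self.name!r} has no set labeled {label!r}")

    def fuzzify(self, x: float) -> dict[str, float]:
        """Membership degree of ``x`` in every labeled set."""
        lo, hi = self.domain
        if not lo <= x <= hi:
            raise DomainError(
                f"value {x} outside domain [{lo}, {hi}] of variable {self.name!r}"
            )
        return {s.label: s.membership(x) for s in self.sets}

    def membership_matrix(self, xs: np.ndarray) -> np.ndarray:
        """len(sets) x len(xs) matrix of membership degrees (for property checks)."""
        return np.vstack([s.membership(xs) for s in self.sets])

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "domain": [self.domain[0], self.domain[1]],
            "sets": [s.to_dict() for s in self.sets],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinguisticVariable":
        return cls(
            name=str(d["name"]),
            domain=(float(d["domain"][0]), float(d["domain"][1])),
            sets=tuple(TrapezoidSet.from_dict(s) for s in d["sets"]),
        )


@dataclass(frozen=True)
class FuzzyRule:
    """IF <conjunction of (variable, label) clauses> THEN output is <label>."""

    antecedent: tuple[tuple[str, str], ...]
    consequent: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "antecedent", tuple((str(v), str(s)) for v, s in self.antecedent)
        )

    def to_dict(self) -> dict:
        return {
            "if": [[v, s] for v, s in self.antecedent],
            "then": self.consequent,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FuzzyRule":
        return cls(tuple((v, s) for v, s in d["if"]), str(d["then"]))


_SUPPORTED = {
    "premise_aggregation": "prod",
    "implication": "min",
    "accumulation": "max",
    "defuzzification": "cog",
}


@dataclass(frozen=True)
class OperatorConfig:
    """Operator suite of the inference engine.

    Only the configuration the PLUS model was validated with is accepted:
    product premises, min implication, max accumulation, COG defuzzification.
    """

    premise_aggregation: str = "prod"
    implication: str = "min"
    accumulation: str = "max"
    defuzzification: str = "cog"

    def __post_init__(self) -> None:
        for fld, allowed in _SUPPORTED.items():
            got = getattr(self, fld)
            if got != allowed:
                raise ValueError(
                    f"unsupported {fld} operator {got!r}; only {allowed!r} is available"
                )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _SUPPORTED}

    @classmethod
    def from_dict(cls, d: Mapping) -> "OperatorConfig":
        return cls(**{k: str(v) for k, v in d.items()})


class PiecewiseLinearFunction:
    """Continuous piecewise-linear curve given by breakpoints (x, mu).

    Breakpoint abscissae are non-decreasing; a repeated x encodes a vertical
    step (which contributes nothing to integrals).  Used to represent
    clipped consequents and their max envelope exactly, so that the centroid
    can be integrated in closed form segment by segment.
    """

    __slots__ = ("xs", "ys")

    def __init__(self, xs: Sequence[float], ys: Sequence[float]):
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        if xs.ndim != 1 or xs.shape != ys.shape or xs.size < 2:
            raise ValueError("need matching 1-D breakpoint arrays of length >= 2")
        if np.any(np.diff(xs) < 0):
            raise ValueError("breakpoint x values must be non-decreasing")
        if np.any((ys < -1e-12) | (ys > 1 + 1e-12)):
            raise ValueError("membership breakpoints must lie in [0, 1]")
        self.xs = xs
        self.ys = np.clip(ys, 0.0, 1.0)

    def __call__(self, x):
        return np.interp(x, self.xs, self.ys)

    def area(self) -> float:
        """Exact integral of mu over the curve's domain."""
        dx = np.diff(self.xs)
        return float(np.sum(dx * (self.ys[:-1] + self.ys[1:]) / 2.0))

    def moment(self) -> float:
        """Exact integral of x * mu(x); closed form per linear segment."""
        x0, x1 = self.xs[:-1], self.xs[1:]
        y0, y1 = self.ys[:-1], self.ys[1:]
        seg = (x1 - x0) / 6.0 * (x0 * (2.0 * y0 + y1) + x1 * (y0 + 2.0 * y1))
        return float(np.sum(seg))

    def moment_about(self, c: float) -> float:
        """Exact integral of (x - c) * mu(x)."""
        x0, x1 = self.xs[:-1] - c, self.xs[1:] - c
        y0, y1 = self.ys[:-1], self.ys[1:]
        seg = (x1 - x0) / 6.0 * (x0 * (2.0 * y0 + y1) + x1 * (y0 + 2.0 * y1))
        return float(np.sum(seg))

    def centroid(self) -> float:
        """Centre of gravity; raises on zero total area.

        Integrated about the midpoint of the curve's positive support, so
        mirror-symmetric envelopes defuzzify to their symmetry point without
        floating-point residue (this is what makes the boundary outputs of
        the extended partitions exactly 0 and exactly 1).
        """
        a = self.area()
        if a <= 0.0:
            raise DegenerateInferenceError("accumulated output curve has zero area")
        nz = np.nonzero(self.ys > 0.0)[0]
        left = self.xs[max(nz[0] - 1, 0)]
        right = self.xs[min(nz[-1] + 1, len(self.xs) - 1)]
        ref = 0.5 * (left + right)
        return ref + self.moment_about(ref) / a

    @staticmethod
    def max_envelope(
        curves: Sequence["PiecewiseLinearFunction"],
    ) -> "PiecewiseLinearFunction":
        """Exact pointwise maximum of curves sharing a common domain.

        Candidate breakpoints are the union of all curves' breakpoints plus
        every pairwise crossing inside the intervals they induce; between
        two consecutive candidates every curve is linear, so the maximum is
        linear there as well.
        """
        if not curves:
            raise DegenerateInferenceError("no curves to accumulate")
        if len(curves) == 1:
            return curves[0]
        xs = np.unique(np.concatenate([c.xs for c in curves]))
        extra: list[float] = []
        vals = np.vstack([c(xs) for c in curves])  # n_curves x n_points
        n = len(curves)
        for i in range(n):
            for j in range(i + 1, n):
                d0 = vals[i, :-1] - vals[j, :-1]
                d1 = vals[i, 1:] - vals[j, 1:]
                cross = (d0 * d1) < 0
                if np.any(cross):
                    idx = np.nonzero(cross)[0]
                    t = d0[idx] / (d0[idx] - d1[idx])
                    extra.extend(xs[idx] + t * (xs[idx + 1] - xs[idx]))
        if extra:
            xs = np.unique(np.concatenate([xs, np.asarray(extra)]))
        ys = np.max(np.vstack([c(xs) for c in curves]), axis=0)
        return PiecewiseLinearFunction(xs, ys)


def numeric_centroid(curve: PiecewiseLinearFunction, step: float = 1e-4) -> float:
    """Grid-based COG via trapezoidal integration (verification oracle).

    Evaluates the curve on an even grid of the given step, augmented with
    the curve's own breakpoints (quadrature nodes must straddle the kinks
    of a piecewise integrand), and integrates numerically.  Kept separate
    from the closed-form path so the two can cross-check each other.
    """
    grid = np.arange(curve.xs[0], curve.xs[-1] + step / 2, step)
    xs = np.unique(np.concatenate([grid, curve.xs]))
    ys = curve(xs)
    area = np.trapezoid(ys, xs)
    if area <= 0.0:
        raise DegenerateInferenceError("curve has zero area")
    return float(np.trapezoid(xs * ys, xs) / area)


@dataclass(frozen=True)
class InferenceTrace:
    """Record of one inference: fuzzified degrees, activations, output curve."""

    memberships: dict[str, dict[str, float]]
    activations: tuple[tuple[FuzzyRule, float], ...]
    envelope: PiecewiseLinearFunction
    value: float

    def to_dict(self) -> dict:
        return {
            "memberships": {k: dict(v) for k, v in self.memberships.items()},
            "activations": [
                {"rule": r.to_dict(), "degree": a} for r, a in self.activations
            ],
            "value": self.value,
        }


@dataclass(frozen=True)
class MamdaniSystem:
    """One multi-input single-output Mamdani inference unit.

    ``defuzz_domain`` is the interval the accumulated curve is integrated
    over; it may extend beyond the output variable's nominal domain so that
    boundary consequent sets (the extended triangles at 0 and 1) integrate
    fully and the crisp output can reach the exact endpoints.
    """

    name: str
    inputs: tuple[LinguisticVariable, ...]
    output: LinguisticVariable
    rules: tuple[FuzzyRule, ...]
    operators: OperatorConfig = field(default_factory=OperatorConfig)
    defuzz_domain: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "rules", tuple(self.rules))
        by_name = {v.name for v in self.inputs}
        out_labels = set(self.output.labels)
        for rule in self.rules:
            for var, lab in rule.antecedent:
                if var not in by_name:
                    raise ValueError(
                        f"system {self.name!r}: rule references unknown variable {var!r}"
                    )
                self._input(var).set(lab)  # raises KeyError on bad label
            if rule.consequent not in out_labels:
                raise ValueError(
                    f"system {self.name!r}: rule consequent {rule.consequent!r} "
                    f"not among output labels {sorted(out_labels)}"
                )

    def _input(self, name: str) -> LinguisticVariable:
        for v in self.inputs:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def integration_interval(self) -> tuple[float, float]:
        return self.defuzz_domain if self.defuzz_domain is not None else self.output.domain

    def fire_rules(
        self, memberships: Mapping[str, Mapping[str, float]]
    ) -> list[tuple[FuzzyRule, float]]:
        """Activation degree per rule: product over antecedent clause degrees."""
        fired = []
        for rule in self.rules:
            act = 1.0
            for var, lab in rule.antecedent:
                if var not in memberships:
                    raise FuzzyError(
                        f"system {self.name!r}: missing input variable {var!r}"
                    )
                act *= memberships[var][lab]
            fired.append((rule, act))
        return fired

    def clip_and_accumulate(
        self, fired: Iterable[tuple[FuzzyRule, float]]
    ) -> PiecewiseLinearFunction:
        """Max envelope of min-clipped consequents over the defuzzification domain."""
        lo, hi = self.integration_interval
        curves = [
            self.output.set(rule.consequent).clipped(act, lo, hi)
            for rule, act in fired
            if act > 0.0
        ]
        if not curves:
            raise DegenerateInferenceError(
                f"system {self.name!r}: no rule fired with positive degree"
            )
        return PiecewiseLinearFunction.max_envelope(curves)

    def infer(self, inputs: Mapping[str, float]) -> InferenceTrace:
        """Fuzzify -> fire rules -> clip/accumulate -> defuzzify (COG)."""
        memberships = {v.name: v.fuzzify(inputs[v.name]) for v in self.inputs}
        fired = self.fire_rules(memberships)
        envelope = self.clip_and_accumulate(fired)
        value = envelope.centroid()
        return InferenceTrace(
            memberships=memberships,
            activations=tuple(fired),
            envelope=envelope,
            value=value,
        )

    def __call__(self, *values: float) -> float:
        if len(values) != len(self.inputs):
            raise FuzzyError(
                f"system {self.name!r} expects {len(self.inputs)} inputs, got {len(values)}"
            )
        return self.infer(
            {v.name: x for v, x in zip(self.inputs, values)}
        ).value

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "inputs": [v.to_dict() for v in self.inputs],
            "output": self.output.to_dict(),
            "rules": [r.to_dict() for r in self.rules],
            "operators": self.operators.to_dict(),
        }
        if self.defuzz_domain is not None:
            d["defuzz_domain"] = [self.defuzz_domain[0], self.defuzz_domain[1]]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "MamdaniSystem":
        dd = d.get("defuzz_domain")
        return cls(
            name=str(d["name"]),
            inputs=tuple(LinguisticVariable.from_dict(v) for v in d["inputs"]),
            output=LinguisticVariable.from_dict(d["output"]),
            rules=tuple(FuzzyRule.from_dict(r) for r in d["rules"]),
            operators=OperatorConfig.from_dict(d["operators"]),
            defuzz_domain=None if dd is None else (float(dd[0]), float(dd[1])),
        )
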