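"""Unit and property tests for the Mamdani inference engine."""

import numpy as np
import pytest

from conftest import random_envelope
from plusqol.fuzzy import (
    DegenerateInferenceError,
    DomainError,
    FuzzyRule,
    LinguisticVariable,
    MamdaniSystem,
    OperatorConfig,
    PiecewiseLinearFunction,
    TrapezoidSet,
    numeric_centroid,
)
from plusqol.model import (
    SCALES,
    build_three_input_system,
    build_tier1_system,
    four_level_output,
    three_level_output,
    unit_interval_input,
)


@pytest.mark.parametrize(
    "params, x, expected",
    [
        ((0, 14, 26, 40), 20, 1.0),      # kernel point
        ((0, 0, 0, 14), 7, 0.5),         # midpoint of descending ramp
        ((26, 40, 40, 40), 33, 0.5),     # midpoint of ascending ramp
        ((0, 0, 0, 14), 14, 0.0),        # support edge
        ((0, 0, 0, 14), 0, 1.0),         # degenerate shoulder: jump convention
        ((26, 40, 40, 40), 40, 1.0),
        ((0, 14, 26, 40), -1, 0.0),
        ((0, 14, 26, 40), 41, 0.0),
        ((0, 14, 26, 40), 7, 0.5),
        ((0, 14, 26, 40), 33, 0.5),
    ],
)
def test_trapezoid_membership(params, x, expected):
    assert TrapezoidSet("t", *params).membership(x) == pytest.approx(expected, abs=1e-15)


def test_trapezoid_membership_vectorized():
    t = TrapezoidSet("t", 0, 14, 26, 40)
    xs = np.array([-1.0, 0.0, 7.0, 14.0, 20.0, 26.0, 33.0, 40.0, 41.0])
    np.testing.assert_allclose(
        t.membership(xs), [0, 0, 0.5, 1, 1, 1, 0.5, 0, 0], atol=1e-15
    )


def test_trapezoid_rejects_disordered_params():
    with pytest.raises(ValueError, match="l <= k1 <= k2 <= r"):
        TrapezoidSet("bad", 1, 0, 2, 3)


@pytest.mark.parametrize(
    "scale_id, x, expected",
    [
        ("pss10", 7, {"low": 0.5, "medium": 0.5, "high": 0.0}),
        ("swls", 35, {"low": 0.0, "medium": 0.0, "high": 1.0}),
        ("mbi_pa", 44, {"low": 0.0, "medium": 0.5, "high": 0.5}),
    ],
)
def test_fuzzify_scale_partitions(scale_id, x, expected):
    degrees = SCALES[scale_id].variable().fuzzify(x)
    assert degrees == pytest.approx(expected, abs=1e-12)


def test_fuzzify_out_of_domain_raises():
    var = SCALES["swls"].variable()
    with pytest.raises(DomainError, match="outside domain"):
        var.fuzzify(36)


def test_operator_config_rejects_alternatives():
    with pytest.raises(ValueError, match="unsupported"):
        OperatorConfig(implication="prod")


class TestFireRules:
    def test_single_rule_fires_fully_at_corner(self):
        system = build_three_input_system("m", "a", "b", "c")
        mem = {v.name: v.fuzzify(x) for v, x in zip(system.inputs, (1.0, 1.0, 0.0))}
        fired = {tuple(l for _, l in r.antecedent): a for r, a in system.fire_rules(mem)}
        assert fired[("high", "high", "low")] == 1.0
        assert sum(a > 0 for a in fired.values()) == 1

    def test_center_activates_all_rules_at_product_of_halves(self):
        system = build_three_input_system("m", "a", "b", "c")
        mem = {v.name: v.fuzzify(0.5) for v in system.inputs}
        acts = [a for _, a in system.fire_rules(mem)]
        assert len(acts) == 8
        assert acts == pytest.approx([0.125] * 8)

    def test_zero_degree_clause_annihilates(self):
        system = build_three_input_system("m", "a", "b", "c")
        mem = {v.name: v.fuzzify(x) for v, x in zip(system.inputs, (0.0, 0.3, 0.7))}
        for rule, act in system.fire_rules(mem):
            if dict(rule.antecedent)["a"] == "high":
                assert act == 0.0

    def test_missing_variable_is_configuration_error(self):
        system = build_three_input_system("m", "a", "b", "c")
        with pytest.raises(Exception, match="missing input"):
            system.fire_rules({"a": {"low": 1, "high": 0}})


class TestClipAndAccumulate:
    @staticmethod
    def _mid_triangle():
        return TrapezoidSet("mid", 0, 0.5, 0.5, 1)

    def test_full_activation_returns_unclipped_shape(self):
        curve = self._mid_triangle().clipped(1.0, -0.5, 1.5)
        xs = np.linspace(-0.5, 1.5, 401)
        np.testing.assert_allclose(curve(xs), self._mid_triangle().membership(xs), atol=1e-15)

    def test_half_activation_flattens_kernel(self):
        curve = self._mid_triangle().clipped(0.5, -0.5, 1.5)
        assert curve(0.25) == pytest.approx(0.5)
        assert curve(0.5) == pytest.approx(0.5)
        assert curve(0.75) == pytest.approx(0.5)
        assert curve(0.1) == pytest.approx(0.2)  # below the clip: original ramp

    def test_two_rule_envelope_matches_dense_grid(self):
        """Envelope of mid and extended-high clipped at 0.5: ramp, plateau, ramp."""
        mid = self._mid_triangle()
        high = TrapezoidSet("high", 0.5, 1, 1, 1.5)
        env = PiecewiseLinearFunction.max_envelope(
            [mid.clipped(0.5, -0.5, 1.5), high.clipped(0.5, -0.5, 1.5)]
        )
        xs = np.linspace(-0.5, 1.5, 2001)
        expected = np.maximum(
            np.minimum(0.5, mid.membership(xs)), np.minimum(0.5, high.membership(xs))
        )
        np.testing.assert_allclose(env(xs), expected, atol=1e-12)
        # plateau at 0.5 between 0.25 and 1.25
        assert env(0.25) == pytest.approx(0.5)
        assert env(1.25) == pytest.approx(0.5)
        assert env(1.4) == pytest.approx(0.2)

    def test_no_positive_activation_is_degenerate(self):
        system = build_tier1_system(SCALES["pss10"])
        with pytest.raises(DegenerateInferenceError):
            system.clip_and_accumulate([(system.rules[0], 0.0)])


class TestDefuzzify:
    def test_symmetric_triangle_centroid(self):
        curve = TrapezoidSet("mid", 0, 0.5, 0.5, 1).clipped(1.0, -0.5, 1.5)
        assert curve.centroid() == 0.5

    def test_extended_boundary_triangle_gives_exact_zero(self):
        curve = TrapezoidSet("low", -0.5, 0, 0, 0.5).clipped(1.0, -0.5, 1.5)
        assert curve.centroid() == 0.0

    def test_three_segment_envelope_centroid(self):
        mid = TrapezoidSet("mid", 0, 0.5, 0.5, 1)
        high = TrapezoidSet("high", 0.5, 1, 1, 1.5)
        env = PiecewiseLinearFunction.max_envelope(
            [mid.clipped(0.5, -0.5, 1.5), high.clipped(0.5, -0.5, 1.5)]
        )
        assert env.centroid() == pytest.approx(0.75, abs=1e-12)
        assert env.centroid() == pytest.approx(numeric_centroid(env), abs=1e-6)

    def test_zero_area_raises(self):
        flat = PiecewiseLinearFunction([0.0, 1.0], [0.0, 0.0])
        with pytest.raises(DegenerateInferenceError):
            flat.centroid()


@pytest.mark.parametrize("x, expected", [(20, 0.5), (0, 1.0), (40, 0.0), (7, 0.75)])
def test_tier1_stress_normalizer_inference(x, expected):
    system = build_tier1_system(SCALES["pss10"])
    assert system(x) == pytest.approx(expected, abs=1e-12)


def _ruspini_variables():
    for sid, part in SCALES.items():
        yield sid, part.variable()
    yield "module_input", unit_interval_input("i")
    yield "three_level", three_level_output(extended=False)
    yield "four_level", four_level_output(extended=False)


@pytest.mark.parametrize("name, var", list(_ruspini_variables()))
def test_ruspini_partition_sums_to_one(name, var):
    """Label memberships sum to 1 at 10,001 evenly spaced domain points."""
    xs = np.linspace(var.domain[0], var.domain[1], 10_001)
    sums = var.membership_matrix(xs).sum(axis=0)
    assert np.max(np.abs(sums - 1.0)) < 1e-12


def test_analytic_cog_matches_numeric_oracle():
    """Closed-form centroid vs trapezoid-grid integration at step 1e-4."""
    rng = np.random.default_rng(20260925)
    worst = 0.0
    for _ in range(200):
        env = random_envelope(rng)
        if env.area() < 1e-6:
            continue
        worst = max(worst, abs(env.centroid() - numeric_centroid(env, step=1e-4)))
    assert worst < 1e-6


def test_mirror_symmetry_of_three_input_structure():
    """f(1-a, 1-b, 1-c) == 1 - f(a, b, c): the rule base maps L<->H onto
    output sets that are mirror images of each other."""
    system = build_three_input_system("m", "a", "b", "c")
    rng = np.random.default_rng(7)
    for _ in range(200):
        a, b, c = rng.random(3)
        assert system(1 - a, 1 - b, 1 - c) == pytest.approx(
            1.0 - system(a, b, c), abs=1e-9
        )


def test_inference_stays_within_nominal_output_interval():
    system = build_three_input_system("m", "a", "b", "c")
    rng = np.random.default_rng(11)
    for _ in range(200):
        v = system(*rng.random(3))
        assert -1e-12 <= v <= 1 + 1e-12


def test_system_serialization_round_trip():
    system = build_three_input_system("m", "a", "b", "c")
    clone = MamdaniSystem.from_dict(system.to_dict())
    assert clone.to_dict() == system.to_dict()
    assert clone(0.2, 0.8, 0.5) == system(0.2, 0.8, 0.5)


def test_rule_validation_catches_unknown_labels():
    var = unit_interval_input("a")
    out = three_level_output()
    with pytest.raises(ValueError, match="consequent"):
        MamdaniSystem(
            name="bad",
            inputs=(var,),
            output=out,
            rules=(FuzzyRule((("a", "low"),), "nonexistent"),),
        )
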