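"""Mamdani engine: firing, aggregation, centroid defuzzification."""

import numpy as np
import pytest

from npkfis import (
    FiringRecord,
    InferenceError,
    NoRuleFiredError,
    InputLevel as I,
    OutputLevel as O,
    SampledFuzzySet,
    TriangularMF,
    aggregate,
    defuzzify_centroid,
    fire_rule,
    infer,
)
from npkfis.rulebase import make_rule


def _fuzzified(n, p, k):
    def degmap(cls, active):
        return {lvl: active.get(lvl, 0.0) for lvl in cls}

    return {
        "N": degmap(I, n),
        "P": degmap(I, p),
        "K": degmap(I, k),
    }


RULE_AAA = make_rule(I.ADEQUATE, I.ADEQUATE, I.ADEQUATE)


@pytest.mark.parametrize(
    "degrees,expected",
    [
        ((1.0, 1.0, 1.0), 1.0),
        ((0.5, 1.0, 0.25), 0.25),
        ((0.7, 0.0, 0.9), 0.0),
    ],
)
def test_fire_rule_is_min_over_antecedents(degrees, expected):
    dn, dp, dk = degrees
    fz = _fuzzified({I.ADEQUATE: dn}, {I.ADEQUATE: dp}, {I.ADEQUATE: dk})
    assert fire_rule(RULE_AAA, fz) == expected


def test_fire_rule_missing_input_raises():
    fz = _fuzzified({I.ADEQUATE: 1.0}, {I.ADEQUATE: 1.0}, {I.ADEQUATE: 1.0})
    del fz["K"]
    with pytest.raises(InferenceError):
        fire_rule(RULE_AAA, fz)


class TestAggregate:
    def test_full_strength_copies_the_consequent_set(self, system):
        out = system.outputs["R.N"]
        fset = aggregate([FiringRecord(RULE_AAA, 1.0)], out, resolution=1001)
        expected = out.mf(O.AVERAGE)(fset.grid)
        assert np.array_equal(fset.degrees, expected)

    def test_half_strength_clips_at_half(self, system):
        out = system.outputs["R.N"]
        fset = aggregate([FiringRecord(RULE_AAA, 0.5)], out, resolution=1001)
        expected = np.minimum(out.mf(O.AVERAGE)(fset.grid), 0.5)
        assert np.array_equal(fset.degrees, expected)

    def test_max_aggregation_keeps_the_stronger_clip(self, system):
        out = system.outputs["R.N"]
        weak = aggregate([FiringRecord(RULE_AAA, 0.3)], out)
        strong = aggregate(
            [FiringRecord(RULE_AAA, 0.3), FiringRecord(RULE_AAA, 0.6)], out
        )
        only_strong = aggregate([FiringRecord(RULE_AAA, 0.6)], out)
        assert np.array_equal(strong.degrees, only_strong.degrees)
        assert np.all(strong.degrees >= weak.degrees)

    def test_nil_and_zero_strength_contribute_nothing(self, system):
        out = system.outputs["R.N"]
        rule_eee = make_rule(I.EXCESSIVE, I.EXCESSIVE, I.EXCESSIVE)  # R.N is NIL
        fset = aggregate(
            [FiringRecord(rule_eee, 1.0), FiringRecord(RULE_AAA, 0.0)], out
        )
        assert np.all(fset.degrees == 0.0)


class TestDefuzzifyCentroid:
    def grid_set(self, mf, lo=0.0, hi=100.0, r=10001):
        grid = np.linspace(lo, hi, r)
        return SampledFuzzySet("X", grid, mf(grid))

    def test_symmetric_triangle_centroid_is_the_peak(self):
        fset = self.grid_set(TriangularMF(30, 50, 70))
        assert defuzzify_centroid(fset) == pytest.approx(50.0, abs=1e-3)

    def test_degenerate_right_half_triangle(self):
        # analytic centroid of a triangle is (a + b + c) / 3
        fset = self.grid_set(TriangularMF(0, 0, 30))
        assert defuzzify_centroid(fset) == pytest.approx(10.0, abs=1e-3)

    def test_all_zero_set_raises_with_variable_name(self):
        grid = np.linspace(0, 100, 101)
        with pytest.raises(NoRuleFiredError) as err:
            defuzzify_centroid(SampledFuzzySet("R.K", grid, np.zeros_like(grid)))
        assert err.value.variable == "R.K"

    def test_matches_analytic_centroid_for_random_triangles(self):
        rng = np.random.default_rng(20240915)
        for _ in range(100):
            a, b, c = np.sort(rng.uniform(0, 100, size=3))
            if c - a < 1e-3:
                continue
            fset = self.grid_set(TriangularMF(a, b, c))
            assert defuzzify_centroid(fset) == pytest.approx((a + b + c) / 3, abs=1e-3)


class TestInfer:
    def test_adequate_prototypes_fire_exactly_one_rule(self, system):
        result = infer(system, {"N": 30.55, "P": 30.05, "K": 200.05})
        assert len(result.trace) == 1
        assert result.trace[0].strength == 1.0
        assert result.trace[0].rule == RULE_AAA
        # each output is then the centroid of a single full consequent set
        out = system.outputs["R.N"]
        expected = defuzzify_centroid(
            aggregate([FiringRecord(RULE_AAA, 1.0)], out, system.resolution)
        )
        assert result.values["R.N"] == expected

    def test_outputs_always_inside_their_domains(self, system):
        rng = np.random.default_rng(7)
        for _ in range(25):
            sample = {
                name: float(rng.uniform(*var.domain))
                for name, var in system.inputs.items()
            }
            values = infer(system, sample).values
            for name, v in values.items():
                lo, hi = system.outputs[name].domain
                assert lo <= v <= hi

    def test_aggregated_degrees_bounded_by_max_strength(self, system):
        sample = {"N": 25.0, "P": 33.0, "K": 400.0}
        from npkfis.membership import fuzzify

        fuzzified = {n: fuzzify(v, sample[n]) for n, v in system.inputs.items()}
        firings = [
            FiringRecord(rule, fire_rule(rule, fuzzified)) for rule in system.rules
        ]
        cap = max(rec.strength for rec in firings)
        for out in system.outputs.values():
            fset = aggregate(firings, out)
            assert np.max(fset.degrees) <= cap + 1e-12

    def test_deterministic_at_fixed_resolution(self, system):
        sample = {"N": 12.3, "P": 45.6, "K": 789.0}
        a = infer(system, sample)
        b = infer(system, sample)
        assert a.values == b.values

    def test_grid_refinement_changes_little(self, system):
        sample = {"N": 37.0, "P": 88.0, "K": 140.0}
        coarse = infer(system, sample, resolution=1001).values
        fine = infer(system, sample, resolution=100001).values
        for name in coarse:
            assert abs(coarse[name] - fine[name]) < 0.1

    def test_missing_input_raises(self, system):
        with pytest.raises(InferenceError):
            infer(system, {"N": 10.0, "P": 10.0})

    def test_continuity_under_tiny_perturbations(self, system):
        """No dead-zone cliffs: a 1e-6 ppm nudge moves outputs < 1e-3."""
        rng = np.random.default_rng(11)
        for _ in range(40):
            sample = {
                name: float(rng.uniform(*var.domain))
                for name, var in system.inputs.items()
            }
            base = infer(system, sample).values
            for name, var in system.inputs.items():
                nudged = dict(sample)
                nudged[name] = min(nudged[name] + 1e-6, var.domain[1])
                moved = infer(system, nudged).values
                for out in base:
                    assert abs(moved[out] - base[out]) < 1e-3

    def test_monotone_across_requirement_prototypes(self, system):
        """At the measured-level prototypes the required-nutrient output is
        non-increasing in the measured level (the full continuous sweep is
        not monotone under centroid defuzzification; see docs)."""
        base = {"N": 30.55, "P": 30.05, "K": 200.05}
        protos = {
            "N": [9.5, 30.55, 55.55, 85.05],
            "P": [9.5, 30.05, 70.05, 125.05],
            "K": [75.0, 200.05, 525.05, 1150.05],
        }
        for nut, out in (("N", "R.N"), ("P", "R.P"), ("K", "R.K")):
            values = []
            for x in protos[nut]:
                sample = dict(base)
                sample[nut] = x
                values.append(infer(system, sample).values[out])
            assert all(b <= a + 1e-9 for a, b in zip(values, values[1:]))

    def test_all_nil_output_defaults_to_domain_floor(self, system):
        # unambiguously EXCESSIVE nitrogen: every firing rule has R.N = NIL
        result = infer(system, {"N": 95.0, "P": 30.05, "K": 200.05})
        assert result.values["R.N"] == 0.0
        assert "R.N" in result.nil_defaults
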