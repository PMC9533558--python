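"""Diet scoring: energy adjustment, standardization, index, servings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from dietmetals.dii import (
    DIIScorer,
    compute_dii,
    compute_fv_servings,
    energy_adjust,
    standardize,
)
from dietmetals.registries import DIIComponent, DIIWeightRegistry, ServingEntry, ServingRegistry


@pytest.fixture
def two_comp_registry():
    return DIIWeightRegistry(
        [
            DIIComponent("comp_a", weight=0.5, energy_adjust=True),
            DIIComponent("comp_b", weight=-0.2, energy_adjust=False),
        ]
    )


class TestRegistries:
    def test_default_registry_has_24_unique_components(self):
        reg = DIIWeightRegistry.default()
        assert len(reg) == 24
        assert len(set(reg.names)) == 24

    def test_registry_yaml_roundtrip(self, tmp_path, two_comp_registry):
        p = tmp_path / "reg.yaml"
        two_comp_registry.to_yaml(p)
        back = DIIWeightRegistry.from_yaml(p)
        assert back.names == two_comp_registry.names
        assert np.allclose(back.weights, two_comp_registry.weights)

    def test_duplicate_component_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            DIIWeightRegistry([DIIComponent("a", 0.1), DIIComponent("a", 0.2)])

    def test_serving_registry_rejects_nonpositive_serving(self):
        with pytest.raises(ValueError, match="positive"):
            ServingRegistry([ServingEntry("1", "fruit", 0.0)])

    def test_serving_registry_yaml_roundtrip(self, tmp_path):
        reg = ServingRegistry.default()
        p = tmp_path / "serv.yaml"
        reg.to_yaml(p)
        back = ServingRegistry.from_yaml(p)
        assert set(back.codes()) == set(reg.codes())


class TestEnergyAdjust:
    def test_density_scaling_and_passthrough(self, tiny_diet, two_comp_registry):
        out = energy_adjust(tiny_diet, two_comp_registry)
        # 60 g at 2000 kcal -> 30 per 1000 kcal; comp_b passes through
        assert out.loc["p1", "comp_a"] == pytest.approx(30.0)
        assert out.loc["p2", "comp_a"] == pytest.approx(20.0)
        assert np.array_equal(out["comp_b"].to_numpy(), tiny_diet["comp_b"].to_numpy())

    def test_zero_intake_stays_zero(self, tiny_diet, two_comp_registry):
        tiny = tiny_diet.copy()
        tiny.loc["p1", "comp_a"] = 0.0
        assert energy_adjust(tiny, two_comp_registry).loc["p1", "comp_a"] == 0.0

    def test_nonpositive_energy_names_participant(self, tiny_diet, two_comp_registry):
        tiny = tiny_diet.copy()
        tiny.loc["p2", "total_energy"] = 0.0
        with pytest.raises(ValueError, match="p2"):
            energy_adjust(tiny, two_comp_registry)


class TestStandardize:
    def test_two_point_hand_computation(self):
        df = pd.DataFrame({"c": [1.0, 3.0]})
        z = standardize(df)
        # population-SD convention: sd = 1, z = {-1, +1}
        assert np.allclose(z["c"].to_numpy(), [-1.0, 1.0])

    def test_weighted_moments_are_normalized(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(size=(50, 3)), columns=list("abc"))
        w = rng.uniform(0.5, 2.0, 50)
        z = standardize(df, w)
        wn = w / w.sum()
        for c in "abc":
            assert abs(wn @ z[c].to_numpy()) < 1e-10
            assert abs(wn @ z[c].to_numpy() ** 2 - 1.0) < 1e-10

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.lognormal(size=(20, 2)), columns=["a", "b"])
        w = rng.uniform(0.5, 2.0, 20)
        pd.testing.assert_frame_equal(standardize(df, w), standardize(df, 2.0 * w))

    def test_zero_variance_names_component(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(df)


class TestComputeDii:
    def test_zero_scores_and_single_component(self, two_comp_registry):
        z = pd.DataFrame({"comp_a": [0.0], "comp_b": [0.0]})
        assert compute_dii(z, two_comp_registry)[0] == 0.0
        one = DIIWeightRegistry([DIIComponent("c", weight=0.7)])
        assert compute_dii(pd.DataFrame({"c": [1.0]}), one)[0] == pytest.approx(0.7)

    def test_three_component_arithmetic(self):
        reg = DIIWeightRegistry(
            [DIIComponent("x", 0.5), DIIComponent("y", -0.2), DIIComponent("z", 0.1)]
        )
        z = pd.DataFrame({"x": [1.0], "y": [2.0], "z": [-1.0]})
        # 0.5*1 + (-0.2)*2 + 0.1*(-1) = 0.0
        assert compute_dii(z, reg)[0] == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention_flip_negates(self, two_comp_registry):
        z = pd.DataFrame({"comp_a": [1.0, -2.0], "comp_b": [0.5, 1.5]})
        adapted = compute_dii(z, two_comp_registry, "adapted")
        classic = compute_dii(z, two_comp_registry, "classic")
        assert np.array_equal(adapted.to_numpy(), -classic.to_numpy())

    @given(
        a=st.floats(-5, 5),
        b=st.floats(-5, 5),
        z1=st.floats(-3, 3),
        z2=st.floats(-3, 3),
    )
    def test_linearity(self, a, b, z1, z2):
        reg = DIIWeightRegistry([DIIComponent("u", 0.4), DIIComponent("v", -0.3)])
        za = pd.DataFrame({"u": [z1], "v": [z2]})
        zb = pd.DataFrame({"u": [z2], "v": [z1]})
        combo = a * za + b * zb
        lhs = compute_dii(combo, reg)[0]
        rhs = a * compute_dii(za, reg)[0] + b * compute_dii(zb, reg)[0]
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_component_mismatch_rejected(self, two_comp_registry):
        z = pd.DataFrame({"comp_a": [0.0], "wrong": [0.0]})
        with pytest.raises(ValueError, match="wrong"):
            compute_dii(z, two_comp_registry)

    def test_scale_invariance_of_energy_adjusted_pipeline(self, tiny_diet, two_comp_registry):
        """Multiplying intakes AND energy by a constant leaves energy-adjusted z unchanged."""
        z1 = standardize(energy_adjust(tiny_diet, two_comp_registry))["comp_a"]
        scaled = tiny_diet.copy()
        scaled["comp_a"] *= 3.0
        scaled["total_energy"] *= 3.0
        z2 = standardize(energy_adjust(scaled, two_comp_registry))["comp_a"]
        assert np.allclose(z1.to_numpy(), z2.to_numpy())


class TestFvServings:
    @pytest.fixture
    def registry(self):
        return ServingRegistry(
            [
                ServingEntry("apple", "fruit", 150.0),
                ServingEntry("broc", "vegetable", 80.0),
                ServingEntry("sweet", "excluded", None),
            ]
        )

    def test_unit_empty_and_mixed_cases(self, registry):
        assert compute_fv_servings([("apple", 150.0)], registry) == pytest.approx(1.0)
        assert compute_fv_servings([], registry) == 0.0
        records = [("apple", 300.0), ("broc", 80.0), ("sweet", 100.0)]
        assert compute_fv_servings(records, registry) == pytest.approx(3.0)

    def test_unknown_code_listed(self, registry):
        with pytest.raises(ValueError, match="mystery"):
            compute_fv_servings([("mystery", 10.0)], registry)

    def test_json_serialized_records_accepted(self, registry):
        assert compute_fv_servings('[["apple", 75.0]]', registry) == pytest.approx(0.5)


class TestDIIScorer:
    def test_matches_functional_pipeline(self, tiny_diet, two_comp_registry):
        w = np.array([1.0, 2.0, 0.5])
        scorer = DIIScorer(registry=two_comp_registry)
        scores = scorer.score_cohort(tiny_diet, sample_weight=w)
        z = standardize(energy_adjust(tiny_diet, two_comp_registry), w)
        expected = compute_dii(z, two_comp_registry)
        assert np.allclose(scores.to_numpy(), expected.to_numpy())

    def test_sklearn_clone_and_transform_shape(self, tiny_diet, two_comp_registry):
        scorer = DIIScorer(registry=two_comp_registry, sign_convention="classic")
        cloned = clone(scorer)
        assert cloned.sign_convention == "classic"
        out = cloned.fit(tiny_diet).transform(tiny_diet)
        assert out.shape == (3, 1)

    def test_transform_before_fit_rejected(self, tiny_diet, two_comp_registry):
        with pytest.raises(ValueError, match="not fitted"):
            DIIScorer(registry=two_comp_registry).transform(tiny_diet)
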