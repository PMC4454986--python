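"""Scenario graph validation and outflow normalization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nanomfa import (
    Compartment,
    DistributionSpec as D,
    ScenarioConfig,
    Transfer,
    normalize_outflows,
    validate_scenario,
)
from nanomfa.flow_system import (
    ConfigurationError,
    normalize_coefficient_block,
    point_mass_config,
)


def two_comp(transfers=None, residuals=None, inputs=None) -> ScenarioConfig:
    return ScenarioConfig(
        enm_name="toy",
        compartments=[
            Compartment("a", "A", "source"),
            Compartment("b", "B", "sink"),
        ],
        transfers=transfers if transfers is not None else [Transfer("a", "b", D.point(1.0))],
        input_flows=inputs if inputs is not None else {"a": D.point(1.0)},
        residuals=residuals or {},
    )


class TestValidateScenario:
    def test_well_formed_toy_is_valid(self):
        assert validate_scenario(two_comp()) == []

    def test_dangling_destination_reported(self):
        cfg = two_comp(transfers=[Transfer("a", "stp", D.point(1.0))])
        v = validate_scenario(cfg)
        assert len([m for m in v if "dangling" in m and "stp" in m]) == 1

    def test_sink_with_outgoing_transfer_is_role_violation(self):
        cfg = two_comp(
            transfers=[Transfer("a", "b", D.point(1.0)), Transfer("b", "a", D.point(0.5))]
        )
        v = validate_scenario(cfg)
        assert any("sink" in m and "no outgoing" in m for m in v)

    def test_coefficient_support_outside_unit_interval(self):
        cfg = two_comp(transfers=[Transfer("a", "b", D.uniform(0.5, 1.5))])
        assert any("outside [0, 1]" in m for m in validate_scenario(cfg))

    def test_flowthrough_without_outgoing(self):
        cfg = ScenarioConfig(
            "toy",
            [Compartment("a", "A", "source"), Compartment("m", "M", "flowthrough"),
             Compartment("b", "B", "sink")],
            [Transfer("a", "m", D.point(1.0))],
            {"a": D.point(1.0)},
        )
        assert any("no outgoing" in m and "'m'" in m for m in validate_scenario(cfg))

    def test_missing_input_flows(self):
        cfg = two_comp(inputs={})
        assert any("input_flows" in m for m in validate_scenario(cfg))

    def test_idempotent_and_side_effect_free(self, toy_chain):
        first = validate_scenario(toy_chain)
        second = validate_scenario(toy_chain)
        assert first == second == []

    def test_invalid_distribution_collected_not_raised(self):
        cfg = two_comp(transfers=[Transfer("a", "b", D.uniform(1, 0))])
        assert any("upper" in m for m in validate_scenario(cfg))


class TestNormalizeOutflows:
    def test_already_normalized_unchanged(self):
        out = normalize_outflows({"a": 0.6, "b": 0.4})
        assert out == {"a": 0.6, "b": 0.4}

    def test_over_unity_renormalized_proportionally(self):
        out = normalize_outflows({"a": 0.8, "b": 0.6})
        assert out["a"] == pytest.approx(0.8 / 1.4, abs=1e-12)
        assert out["b"] == pytest.approx(0.6 / 1.4, abs=1e-12)

    def test_deficit_routed_to_residual(self):
        assert normalize_outflows({"a": 0.5}, residual_to="elim") == {"a": 0.5, "elim": 0.5}

    def test_deficit_without_residual_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="residual"):
            normalize_outflows({"a": 0.5})

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=6),
    )
    def test_output_sums_to_one(self, draws):
        sampled = {f"d{i}": c for i, c in enumerate(draws)}
        out = normalize_outflows(sampled, residual_to="resid")
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)

    def test_block_normalization_matches_scalar_on_random_draws(self):
        rng = np.random.default_rng(0)
        draws = rng.uniform(0, 0.6, size=(1000, 3))
        block, residual = normalize_coefficient_block(draws, has_residual=True)
        total = block.sum(axis=1) + residual
        np.testing.assert_allclose(total, 1.0, atol=1e-12)
        # spot-check a few rows against the scalar path
        for i in (0, 17, 999):
            out = normalize_outflows(
                {f"d{j}": draws[i, j] for j in range(3)}, residual_to="r"
            )
            np.testing.assert_allclose(block[i], [out[f"d{j}"] for j in range(3)], atol=1e-12)


class TestPointMassTwin:
    def test_uniform_coefficient_becomes_mean(self, toy_chain_stochastic):
        twin = point_mass_config(toy_chain_stochastic)
        stp_eff = [t for t in twin.transfers if (t.origin, t.destination) == ("stp", "effluent")][0]
        assert stp_eff.coefficient == D.point(0.1)

    def test_triangular_becomes_third_of_sum(self):
        cfg = two_comp(transfers=[Transfer("a", "b", D.triangular(0, 1 / 3, 2 / 3))])
        twin = point_mass_config(cfg)
        assert twin.transfers[0].coefficient.params["value"] == pytest.approx(1 / 3)

    def test_twin_is_idempotent(self, toy_chain_stochastic):
        once = point_mass_config(toy_chain_stochastic)
        twice = point_mass_config(once)
        assert [t.coefficient for t in twice.transfers] == [t.coefficient for t in once.transfers]
        assert validate_scenario(twice) == []
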