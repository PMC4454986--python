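"""Shared fixtures: toy scenarios and random small flow systems."""

import numpy as np
import pytest
from hypothesis import settings

from nanomfa import (
    Compartment,
    DistributionSpec as D,
    GeometryDescriptor,
    ScenarioConfig,
    Transfer,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_toy_chain(stochastic_effluent: bool = False) -> ScenarioConfig:
    """use → STP → {sludge 0.9, effluent 0.1}; effluent and sludge carry
    Denmark-toy geometries (1e12 L/y water, 1e8 kg/y sludge)."""
    split = D.uniform(0.0, 0.2) if stochastic_effluent else D.point(0.1)
    return ScenarioConfig(
        enm_name="toy-chain",
        compartments=[
            Compartment("use", "Use", "source"),
            Compartment("stp", "STP", "flowthrough"),
            Compartment(
                "sludge", "Sludge", "flowthrough", "technical",
                GeometryDescriptor("annual_throughput_mass", D.point(1e8, "kg/y"), "kg/y"),
                "mg/kg",
            ),
            Compartment(
                "effluent", "Effluent", "flowthrough", "technical",
                GeometryDescriptor("annual_throughput_volume", D.point(1e12, "L/y"), "L/y"),
                "µg/L",
            ),
            Compartment("water", "Receiving water", "sink", "freshwater",
                        GeometryDescriptor("stock_mass", D.point(1e12, "kg"), "kg")),
        ],
        transfers=[
            Transfer("use", "stp", D.point(1.0)),
            Transfer("stp", "effluent", split),
            Transfer("sludge", "water", D.point(1.0)),
            Transfer("effluent", "water", D.point(1.0)),
        ],
        input_flows={"use": D.point(100.0, "t/y")},
        residuals={"stp": "sludge"},
    )


@pytest.fixture
def toy_chain() -> ScenarioConfig:
    return make_toy_chain()


@pytest.fixture
def toy_chain_stochastic() -> ScenarioConfig:
    return make_toy_chain(stochastic_effluent=True)


def random_system(rng: np.random.Generator, max_nodes: int = 12):
    """Random leaking flow system: a DAG chain plus one recycling cycle.

    Returns (inputs, coefficients) dicts for the mass-balance solvers.
    Every origin's outgoing coefficients sum to 1; the cycle leaks because
    each cycle node routes a positive fraction to a terminal.
    """
    n_flow = int(rng.integers(3, max_nodes - 1))
    nodes = [f"n{i}" for i in range(n_flow)] + ["sink"]
    coeffs: dict[tuple[str, str], float] = {}
    for i in range(n_flow):
        targets = [f"n{j}" for j in range(i + 1, n_flow)] + ["sink"]
        k = int(rng.integers(1, min(3, len(targets)) + 1))
        chosen = list(rng.choice(targets, size=k, replace=False))
        if "sink" not in chosen:
            chosen.append("sink")
        w = rng.dirichlet(np.ones(len(chosen)))
        for t, wi in zip(chosen, w):
            coeffs[(f"n{i}", t)] = float(wi)
    # one backward edge to close a recycling cycle, with leakage kept:
    # take mass from the sink share of a later node
    if n_flow >= 2:
        j = int(rng.integers(1, n_flow))
        back = float(rng.uniform(0.05, 0.6)) * coeffs[(f"n{j}", "sink")]
        coeffs[(f"n{j}", "sink")] -= back
        coeffs[(f"n{j}", "n0")] = coeffs.get((f"n{j}", "n0"), 0.0) + back
    inputs = {"n0": float(rng.uniform(1, 1000))}
    if rng.random() < 0.5:
        inputs[f"n{int(rng.integers(1, n_flow))}"] = float(rng.uniform(0, 100))
    return inputs, coeffs
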