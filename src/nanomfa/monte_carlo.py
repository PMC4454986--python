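"""Stochastic layer: sample every model input, solve every realization.

Each Monte-Carlo iteration draws one value from every input-flow,
transfer-coefficient and compartment-geometry distribution, normalizes the
outflow fractions of every origin (proportional renormalization above 1,
residual routing below 1), and solves the steady-state mass balance.  The
default of 100,000 iterations gives a stable picture of both the central
tendency and the tails of the resulting flow and concentration
distributions.

All randomness flows through a single seeded :class:`numpy.random.Generator`
so a run is reproducible bit-for-bit from (scenario, n_iter, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .distributions import sample_distribution
from .flow_system import (
    ConfigurationError,
    ScenarioConfig,
    TERMINAL_ROLES,
    normalize_coefficient_block,
    validate_scenario,
)
from .mass_balance import SingularSystemError, solve_batch

_SOLVE_CHUNK = 20_000  # realizations per batched linear solve (memory cap)


def scenario_fingerprint(config: ScenarioConfig) -> str:
    """SHA-256 over the canonical serialized form of the scenario."""
    from .scenario_io import scenario_to_dict  # local import avoids cycle

    blob = json.dumps(scenario_to_dict(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class MCResult:
    """Materialized per-iteration samples of one Monte-Carlo run."""

    scenario: ScenarioConfig
    n_iter: int
    seed: int | None
    compartment_ids: list[str]
    edges: list[tuple[str, str]]  # explicit transfers + residual edges
    coefficients: np.ndarray  # (n_iter, n_edges) normalized draws
    edge_flows: np.ndarray  # (n_iter, n_edges) t/y
    inflows: np.ndarray  # (n_iter, n_compartments) t/y entering each
    input_samples: dict[str, np.ndarray]  # external inputs, t/y
    geometry_samples: dict[str, np.ndarray]  # compartment id → (n_iter,)
    fingerprint: str

    def edge_index(self, origin: str, destination: str) -> int:
        return self.edges.index((origin, destination))

    def inflow(self, cid: str) -> np.ndarray:
        return self.inflows[:, self.compartment_ids.index(cid)]

    def terminal_ids(self) -> list[str]:
        byid = self.scenario.by_id()
        return [cid for cid in self.compartment_ids if byid[cid].role in TERMINAL_ROLES]

    def conservation_errors(self) -> np.ndarray:
        """Per-iteration relative imbalance |input − absorbed| / input."""
        total_in = np.sum([s for s in self.input_samples.values()], axis=0)
        cols = [self.compartment_ids.index(c) for c in self.terminal_ids()]
        absorbed = self.inflows[:, cols].sum(axis=1)
        return np.abs(total_in - absorbed) / np.where(total_in == 0, 1.0, total_in)


def run_monte_carlo(
    scenario: ScenarioConfig,
    n_iter: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> MCResult:
    """Sample and solve ``n_iter`` independent mass-balance realizations.

    ``rng`` may be passed to thread an existing generator through a larger
    pipeline; otherwise a fresh ``default_rng(seed)`` is created.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    violations = validate_scenario(scenario)
    if violations:
        raise ConfigurationError(
            "scenario is invalid:\n  " + "\n  ".join(violations)
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    byid = scenario.by_id()
    ids = [c.id for c in scenario.compartments]
    col = {cid: i for i, cid in enumerate(ids)}
    k = len(ids)

    # edge list: explicit transfers first, then implicit residual-only edges
    edges: list[tuple[str, str]] = []
    for t in scenario.transfers:
        if (t.origin, t.destination) in edges:
            raise ConfigurationError(f"duplicate transfer {t.origin!r}→{t.destination!r}")
        edges.append((t.origin, t.destination))
    implicit: set[int] = set()
    for origin, resid in scenario.residuals.items():
        if (origin, resid) not in edges:
            implicit.add(len(edges))
            edges.append((origin, resid))
    eix = {e: i for i, e in enumerate(edges)}

    # sample external inputs (order of sampling fixed by config order)
    input_samples = {
        cid: sample_distribution(spec, n_iter, rng)
        for cid, spec in scenario.input_flows.items()
    }
    u = np.zeros((n_iter, k))
    for cid, draws in input_samples.items():
        u[:, col[cid]] += draws

    # sample raw coefficients, then normalize per origin
    coeff = np.zeros((n_iter, len(edges)))
    for t in scenario.transfers:
        coeff[:, eix[(t.origin, t.destination)]] = sample_distribution(
            t.coefficient, n_iter, rng
        )
    origins: dict[str, list[int]] = {}
    for i, (o, _) in enumerate(edges):
        origins.setdefault(o, []).append(i)
    for o, idxs in origins.items():
        resid = scenario.residuals.get(o)
        explicit = [i for i in idxs if i not in implicit]
        try:
            block, residual = normalize_coefficient_block(
                coeff[:, explicit], has_residual=resid is not None
            )
        except ConfigurationError as err:
            raise ConfigurationError(f"origin {o!r}: {err}") from None
        coeff[:, explicit] = block
        if resid is not None:
            j = eix[(o, resid)]
            if j in explicit:  # residual target also has an explicit transfer
                coeff[:, j] += residual
            else:
                coeff[:, j] = residual

    # batched steady-state solves
    inflows = np.empty((n_iter, k))
    oi = np.array([col[o] for o, _ in edges])
    di = np.array([col[d] for _, d in edges])
    for lo in range(0, n_iter, _SOLVE_CHUNK):
        hi = min(lo + _SOLVE_CHUNK, n_iter)
        n = hi - lo
        T = np.zeros((n, k, k))
        T[:, oi, di] = coeff[lo:hi]
        try:
            inflows[lo:hi] = solve_batch(u[lo:hi], T)
        except SingularSystemError as err:
            raise SingularSystemError(f"iterations {lo}–{hi}: {err}") from None
    if inflows.min(initial=0.0) < 0:
        # round-off can leave ~-1e-20 on unreached compartments
        scale = max(float(np.abs(inflows).max(initial=0.0)), 1.0)
        if inflows.min() < -1e-9 * scale:
            raise SingularSystemError("negative throughput in Monte-Carlo batch")
        np.clip(inflows, 0.0, None, out=inflows)

    edge_flows = inflows[:, oi] * coeff

    geometry_samples = {
        c.id: sample_distribution(c.geometry.value, n_iter, rng)
        for c in scenario.compartments
        if c.geometry is not None
    }

    return MCResult(
        scenario=scenario,
        n_iter=n_iter,
        seed=seed,
        compartment_ids=ids,
        edges=edges,
        coefficients=coeff,
        edge_flows=edge_flows,
        inflows=inflows,
        input_samples=input_samples,
        geometry_samples=geometry_samples,
        fingerprint=scenario_fingerprint(scenario),
    )
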