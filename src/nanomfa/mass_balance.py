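"""Steady-state mass balance for one sampled realization.

With external inputs u (t/y per compartment) and a per-origin-normalized
transfer-coefficient matrix T (T[i, j] = fraction of compartment i's
throughput routed to j), the annual throughput m of every compartment
satisfies the linear fixed point

    m = u + Tᵀ m

which the production path solves directly as (I − Tᵀ) m = u.  Cycles
(e.g. recycling loops) are admissible as long as they leak — formally the
spectral radius of the sub-matrix over non-terminal compartments is < 1.
A Jacobi-style fixed-point iteration is provided as an independent oracle.

Edge flows are m_origin · T[origin, destination]; every terminal
compartment (sink / elimination / export) absorbs its inflow, so total
input equals total absorption exactly (machine precision).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np


class SingularSystemError(ValueError):
    """A retention cycle keeps mass forever; the steady state does not exist."""


@dataclass
class BalanceSolution:
    """One deterministic solve: throughputs, edge flows and balance totals."""

    throughput: dict[str, float]  # mass/y entering each compartment
    edge_flows: dict[tuple[str, str], float]
    total_input: float
    total_absorbed: float  # into compartments with no outgoing edge

    @property
    def conservation_error(self) -> float:
        """Relative imbalance |input − absorbed| / input (0 for zero input)."""
        if self.total_input == 0.0:
            return abs(self.total_absorbed)
        return abs(self.total_input - self.total_absorbed) / self.total_input


def _system_arrays(
    inputs: Mapping[str, float], coefficients: Mapping[tuple[str, str], float]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Node ordering, input vector u and dense coefficient matrix T."""
    nodes: list[str] = []
    seen = set()
    for cid in list(inputs) + [c for e in coefficients for c in e]:
        if cid not in seen:
            seen.add(cid)
            nodes.append(cid)
    idx = {cid: i for i, cid in enumerate(nodes)}
    k = len(nodes)
    u = np.zeros(k)
    for cid, val in inputs.items():
        if val < 0:
            raise ValueError(f"negative input flow for {cid!r}: {val}")
        u[idx[cid]] += float(val)
    T = np.zeros((k, k))
    for (o, d), c in coefficients.items():
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"coefficient {o!r}→{d!r} outside [0, 1]: {c}")
        if o == d:
            raise ValueError(f"self-transfer {o!r}→{d!r} not allowed")
        T[idx[o], idx[d]] += float(c)
    return nodes, u, T


def _retention_cycles(nodes: Sequence[str], T: np.ndarray) -> list[list[str]]:
    """Cycles in the positive-coefficient graph, for singularity diagnostics."""
    g = nx.DiGraph()
    g.add_nodes_from(range(len(nodes)))
    for i, j in zip(*np.nonzero(T > 0)):
        g.add_edge(int(i), int(j))
    return [[nodes[i] for i in comp] for comp in nx.strongly_connected_components(g) if len(comp) > 1]


def _check_leakage(nodes: Sequence[str], T: np.ndarray) -> None:
    if T.shape[0] == 0:
        return
    rho = float(np.max(np.abs(np.linalg.eigvals(T))))
    if rho >= 1.0 - 1e-12:
        cycles = _retention_cycles(nodes, T)
        names = "; ".join(", ".join(c) for c in cycles) or "unknown"
        raise SingularSystemError(
            f"cycle with total retention (spectral radius {rho:.6g}); involved compartments: {names}"
        )


def _solution(
    nodes: Sequence[str], u: np.ndarray, T: np.ndarray, m: np.ndarray
) -> BalanceSolution:
    scale = max(float(np.abs(m).max(initial=0.0)), 1.0)
    if float(m.min(initial=0.0)) < -1e-9 * scale:
        raise SingularSystemError("negative throughput — system is not a leaking flow graph")
    m = np.clip(m, 0.0, None)  # scrub round-off negatives / signed zeros
    flows = {}
    for i, j in zip(*np.nonzero(T > 0)):
        flows[(nodes[i], nodes[j])] = float(m[i] * T[i, j])
    has_out = T.sum(axis=1) > 0
    absorbed = float(m[~has_out].sum())
    return BalanceSolution(
        throughput={cid: float(m[i]) for i, cid in enumerate(nodes)},
        edge_flows=flows,
        total_input=float(u.sum()),
        total_absorbed=absorbed,
    )


def solve_steady_state(
    inputs: Mapping[str, float], coefficients: Mapping[tuple[str, str], float]
) -> BalanceSolution:
    """Solve (I − Tᵀ) m = u directly.

    ``coefficients`` must already be normalized per origin (every
    non-terminal origin's outgoing coefficients sum to 1).
    """
    nodes, u, T = _system_arrays(inputs, coefficients)
    _check_leakage(nodes, T)
    m = np.linalg.solve(np.eye(len(nodes)) - T.T, u)
    return _solution(nodes, u, T, m)


def iterative_propagate(
    inputs: Mapping[str, float],
    coefficients: Mapping[tuple[str, str], float],
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> BalanceSolution:
    """Fixed-point iteration m ← u + Tᵀ m from m⁰ = u.

    Kept as an independent oracle for :func:`solve_steady_state`; converges
    whenever every cycle leaks mass.
    """
    nodes, u, T = _system_arrays(inputs, coefficients)
    m = u.copy()
    floor = max(u.max(initial=0.0) * 1e-12, 1e-300)  # negligible-mass floor
    for _ in range(max_iter):
        m_next = u + T.T @ m
        delta = np.max(np.abs(m_next - m) / np.maximum(np.abs(m_next), floor))
        m = m_next
        if delta < tol:
            return _solution(nodes, u, T, m)
    raise SingularSystemError(
        f"fixed-point iteration did not converge in {max_iter} steps (last residual {delta:.3g})"
    )


def solve_batch(u: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Batched direct solve: u (n, k), T (n, k, k) → throughput m (n, k).

    Used by the Monte-Carlo driver; falls back to row-by-row solves to
    identify the offending realization when the batch is singular.
    """
    A = np.eye(u.shape[1])[None, :, :] - np.swapaxes(T, 1, 2)
    try:
        return np.linalg.solve(A, u[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        out = np.empty_like(u)
        for i in range(u.shape[0]):
            try:
                out[i] = np.linalg.solve(A[i], u[i])
            except np.linalg.LinAlgError:
                raise SingularSystemError(
                    f"singular mass balance in batch row {i}"
                ) from None
        return out
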