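"""Compartment graph of one material's lifecycle and its transfer coefficients.

A scenario is a directed graph: *source* compartments receive external
input (production/consumption, t/y), *flow-through* compartments pass all
mass on within the reference year, and *terminal* compartments absorb mass
permanently — accumulating *sinks* (soils, sediments, landfill),
*elimination* (chemical transformation of the nano-form, e.g. sulfidation
during sewage treatment), and *export* out of the system boundary.  Each
edge carries a transfer coefficient, itself a distribution on [0, 1] giving
the fraction of the origin's throughput routed to the destination.

Because independently sampled outflow fractions of an origin rarely sum to
exactly one, each origin may designate a *residual* compartment that
receives the unallocated remainder (1 − Σ coefficients); when sampled
coefficients sum above one they are renormalized proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

from .distributions import DistributionSpec

ROLES = ("source", "flowthrough", "sink", "elimination", "export")
TERMINAL_ROLES = frozenset({"sink", "elimination", "export"})

MEDIA = (
    "technical",
    "freshwater",
    "seawater",
    "sediment_fresh",
    "sediment_marine",
    "soil",
    "air",
    "none",
)
#: media counted as the natural environment (everything except technical plumbing)
ENV_MEDIA = frozenset(MEDIA) - {"technical", "none"}

GEOMETRY_MODES = ("annual_throughput_volume", "annual_throughput_mass", "stock_mass")


class ConfigurationError(ValueError):
    """A scenario is structurally unusable for the requested operation."""


@dataclass(frozen=True)
class GeometryDescriptor:
    """Compartment size used to turn mass flows into concentrations.

    ``annual_throughput_volume`` (L/y or m³/y) and ``annual_throughput_mass``
    (kg/y) describe flow-through compartments whose content is renewed every
    year; ``stock_mass`` (kg) describes an accumulating sink.
    """

    mode: str
    value: DistributionSpec
    unit: str  # "L/y", "m³/y", "kg/y" or "kg"


@dataclass(frozen=True)
class Compartment:
    id: str
    name: str
    role: str
    medium: str = "none"
    geometry: Optional[GeometryDescriptor] = None
    conc_unit: Optional[str] = None  # native concentration unit, e.g. "µg/L"


@dataclass(frozen=True)
class Transfer:
    origin: str
    destination: str
    coefficient: DistributionSpec


@dataclass
class ScenarioConfig:
    """One material's complete model.

    ``input_flows`` maps compartment id → external inflow distribution (t/y);
    ``residuals`` maps origin id → the compartment receiving that origin's
    unallocated outflow fraction.
    """

    enm_name: str
    compartments: list[Compartment]
    transfers: list[Transfer]
    input_flows: dict[str, DistributionSpec]
    residuals: dict[str, str] = field(default_factory=dict)
    reference_year: int = 2014
    release_start_year: int = 2000
    meta: dict = field(default_factory=dict)

    def by_id(self) -> dict[str, Compartment]:
        return {c.id: c for c in self.compartments}

    def compartment(self, cid: str) -> Compartment:
        for c in self.compartments:
            if c.id == cid:
                return c
        raise KeyError(cid)


def validate_scenario(config: ScenarioConfig) -> list[str]:
    """Collect every structural violation in ``config``; [] means valid.

    Side-effect free and never raises on a merely-invalid configuration.
    """
    v: list[str] = []
    ids = [c.id for c in config.compartments]
    seen = set()
    for cid in ids:
        if cid in seen:
            v.append(f"compartments: duplicate id {cid!r}")
        seen.add(cid)
    byid = config.by_id()

    for c in config.compartments:
        if c.role not in ROLES:
            v.append(f"compartment {c.id!r}: unknown role {c.role!r}")
        if c.medium not in MEDIA:
            v.append(f"compartment {c.id!r}: unknown medium {c.medium!r}")
        if c.geometry is not None:
            g = c.geometry
            if g.mode not in GEOMETRY_MODES:
                v.append(f"compartment {c.id!r}: unknown geometry mode {g.mode!r}")
            else:
                if c.role == "flowthrough" and g.mode == "stock_mass":
                    v.append(
                        f"compartment {c.id!r}: flow-through compartment with stock_mass geometry"
                    )
                if c.role == "sink" and g.mode != "stock_mass":
                    v.append(f"compartment {c.id!r}: sink with throughput geometry")
            v.extend(g.value.problems(prefix=f"compartment {c.id!r} geometry."))
            if not g.value.problems() and g.value.support()[1] <= 0:
                v.append(f"compartment {c.id!r}: geometry value must be positive")
        if c.conc_unit is not None and c.geometry is None:
            v.append(
                f"compartment {c.id!r}: concentration unit given but no geometry to convert with"
            )

    outgoing: dict[str, int] = {cid: 0 for cid in ids}
    incoming: dict[str, int] = {cid: 0 for cid in ids}
    for i, t in enumerate(config.transfers):
        where = f"transfers[{i}] ({t.origin!r}→{t.destination!r})"
        if t.origin == t.destination:
            v.append(f"{where}: origin equals destination")
        for end, cid in (("origin", t.origin), ("destination", t.destination)):
            if cid not in byid:
                v.append(f"{where}: dangling {end} id {cid!r}")
        if t.origin in byid:
            outgoing[t.origin] += 1
            role = byid[t.origin].role
            if role in TERMINAL_ROLES:
                v.append(f"{where}: {role} compartment {t.origin!r} must have no outgoing transfer")
        if t.destination in byid:
            incoming[t.destination] += 1
            if byid[t.destination].role == "source":
                v.append(f"{where}: source compartment {t.destination!r} must have no incoming transfer")
        v.extend(t.coefficient.problems(prefix=f"{where}.coefficient."))
        lo, hi = (0.0, 0.0)
        if not t.coefficient.problems():
            lo, hi = t.coefficient.support()
            if lo < 0 or hi > 1:
                v.append(f"{where}: coefficient support [{lo}, {hi}] outside [0, 1]")

    for origin, resid in config.residuals.items():
        if origin not in byid:
            v.append(f"residuals: unknown origin id {origin!r}")
        if resid not in byid:
            v.append(f"residuals[{origin!r}]: unknown residual compartment {resid!r}")
        elif resid == origin:
            v.append(f"residuals[{origin!r}]: residual compartment equals origin")
        if origin in byid and byid[origin].role in TERMINAL_ROLES:
            v.append(f"residuals[{origin!r}]: terminal compartments have no outflow")

    for c in config.compartments:
        has_out = outgoing.get(c.id, 0) > 0 or c.id in config.residuals
        if c.role == "flowthrough" and not has_out:
            v.append(f"compartment {c.id!r}: flow-through compartment with no outgoing transfer")

    if not config.input_flows:
        v.append("input_flows: at least one external input flow is required")
    for cid, spec in config.input_flows.items():
        if cid not in byid:
            v.append(f"input_flows: unknown compartment id {cid!r}")
        v.extend(spec.problems(prefix=f"input_flows[{cid!r}]."))

    return v


def normalize_outflows(
    sampled: Mapping[str, float], residual_to: Optional[str] = None
) -> dict[str, float]:
    """Adjust one origin's sampled outflow fractions to sum to exactly 1.

    If the draws sum above 1 each is divided by the sum (relative magnitudes
    preserved); if they sum below 1 the deficit is routed to ``residual_to``.
    """
    draws = {k: float(c) for k, c in sampled.items()}
    for k, c in draws.items():
        if not (0.0 <= c <= 1.0):
            raise ConfigurationError(f"coefficient for {k!r} outside [0, 1]: {c}")
    s = sum(draws.values())
    if s > 1.0:
        out = {k: c / s for k, c in draws.items()}
        if residual_to is not None:
            out[residual_to] = out.get(residual_to, 0.0)
        return out
    deficit = 1.0 - s
    if deficit > 0.0 and residual_to is None:
        raise ConfigurationError(
            f"outflows sum to {s} < 1 but no residual compartment is configured"
        )
    out = dict(draws)
    if residual_to is not None:
        out[residual_to] = out.get(residual_to, 0.0) + deficit
    return out


def normalize_coefficient_block(
    coeffs: np.ndarray, has_residual: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`normalize_outflows` over an (n, d) block of draws.

    Returns the adjusted (n, d) block and the (n,) residual fractions.
    Raises :class:`ConfigurationError` if a deficit occurs without a
    residual destination.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    s = coeffs.sum(axis=1)
    over = s > 1.0
    if over.any():
        coeffs = coeffs.copy()
        coeffs[over] /= s[over, None]
    residual = np.clip(1.0 - s, 0.0, None)
    residual[over] = 0.0
    if not has_residual and residual.max(initial=0.0) > 1e-12:
        raise ConfigurationError(
            "sampled outflows sum below 1 but no residual compartment is configured"
        )
    return coeffs, residual


def point_mass_config(config: ScenarioConfig) -> ScenarioConfig:
    """Replace every distribution by a point mass at its mean.

    The twin validates and makes the whole pipeline deterministic; used as
    a recovery fixture against stochastic runs.  Idempotent.
    """

    def _pt(spec: DistributionSpec) -> DistributionSpec:
        return DistributionSpec.point(spec.mean(), spec.unit)

    comps = []
    for c in config.compartments:
        g = c.geometry
        if g is not None:
            g = GeometryDescriptor(g.mode, _pt(g.value), g.unit)
        comps.append(replace(c, geometry=g))
    return ScenarioConfig(
        enm_name=config.enm_name,
        compartments=comps,
        transfers=[replace(t, coefficient=_pt(t.coefficient)) for t in config.transfers],
        input_flows={k: _pt(s) for k, s in config.input_flows.items()},
        residuals=dict(config.residuals),
        reference_year=config.reference_year,
        release_start_year=config.release_start_year,
        meta={**config.meta, "point_mass_twin": True},
    )
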