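"""From mass flows to predicted environmental concentrations (PEC).

Flow-through compartments (effluent, freshwater, incinerated waste, air)
renew their content annually: the concentration is the annual inflow
divided by the compartment's annual throughput (volume or mass).  Sink
compartments (soils, sediments) accumulate: the annual inflow divided by
the stock mass gives the *yearly increase* in concentration.

For sinks a deposition history is additionally modeled: release starts in
2000 at zero-history and ramps linearly up to the level computed for the
reference year 2014, so the deposition in year 1999+k is (k/15) of the
2014 rate.  The 15-year accumulated concentration is then

    Σₖ₌₁¹⁵ (k/15) · D = 8 · D

where D is the 2014 annual increase.  A constant-rate variant (15 · D) is
kept as a sensitivity ramp.

Internal mass-flow unit is t/y throughout; concentration units are strings
"<mass>/<amount>" with mass in {t, kg, g, mg, µg, ng, pg} and amount in
{L, m³, kg}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .flow_system import GeometryDescriptor
from .monte_carlo import MCResult

ArrayLike = Union[float, np.ndarray]

GRAMS = {"t": 1e6, "kg": 1e3, "g": 1.0, "mg": 1e-3, "µg": 1e-6, "ug": 1e-6,
         "ng": 1e-9, "pg": 1e-12}
LITRES = {"L": 1.0, "l": 1.0, "m³": 1e3, "m3": 1e3}

LINEAR_RAMP_YEARS = 15  # 2000 .. 2014 inclusive
#: Σ_{k=1..15} k/15 — accumulated years-equivalent of the linear ramp
LINEAR_RAMP_FACTOR = (LINEAR_RAMP_YEARS + 1) / 2.0  # = 8 exactly


class UnitError(ValueError):
    """Unit string cannot be parsed or is incompatible with the geometry."""


def _split_unit(unit: str) -> tuple[str, str]:
    try:
        num, den = unit.split("/")
    except ValueError:
        raise UnitError(f"concentration unit must look like 'µg/L', got {unit!r}") from None
    if num not in GRAMS:
        raise UnitError(f"unknown mass unit {num!r} in {unit!r}")
    if den not in LITRES and den not in ("kg",):
        raise UnitError(f"unknown denominator unit {den!r} in {unit!r}")
    return num, den


def _denominator_amount(geometry: GeometryDescriptor, den: str, value: ArrayLike) -> ArrayLike:
    """Geometry value converted into the requested denominator unit."""
    gunit = geometry.unit.removesuffix("/y")
    if den == "kg":
        if gunit != "kg":
            raise UnitError(f"mass-based unit needs kg geometry, got {geometry.unit!r}")
        return value
    if gunit not in LITRES:
        raise UnitError(f"volume-based unit needs L or m³ geometry, got {geometry.unit!r}")
    return np.asarray(value) * (LITRES[gunit] / LITRES[den])


def _convert(annual_inflow_t: ArrayLike, geometry: GeometryDescriptor,
             geometry_value: ArrayLike, out_unit: str) -> ArrayLike:
    num, den = _split_unit(out_unit)
    amount = _denominator_amount(geometry, den, geometry_value)
    amount = np.asarray(amount, dtype=float)
    if np.any(amount <= 0):
        raise UnitError("compartment geometry must be positive")
    mass = np.asarray(annual_inflow_t, dtype=float) * (GRAMS["t"] / GRAMS[num])
    out = mass / amount
    return float(out) if np.ndim(out) == 0 else out


def pec_flowthrough(
    annual_inflow_t: ArrayLike,
    geometry: GeometryDescriptor,
    out_unit: str,
    geometry_value: ArrayLike | None = None,
) -> ArrayLike:
    """Concentration in a flow-through compartment: inflow ÷ annual throughput.

    ``geometry_value`` overrides the geometry's own (sampled) value; by
    default the geometry distribution's mean is used, so pass the per-
    iteration samples for Monte-Carlo output.
    """
    if geometry.mode not in ("annual_throughput_volume", "annual_throughput_mass"):
        raise UnitError(f"flow-through conversion needs throughput geometry, got {geometry.mode!r}")
    if geometry_value is None:
        geometry_value = geometry.value.mean()
    return _convert(annual_inflow_t, geometry, geometry_value, out_unit)


def sink_annual_increase(
    annual_inflow_t: ArrayLike,
    geometry: GeometryDescriptor,
    out_unit: str,
    geometry_value: ArrayLike | None = None,
) -> ArrayLike:
    """Yearly concentration increase in a sink: inflow ÷ stock mass (per year)."""
    if geometry.mode != "stock_mass":
        raise UnitError(f"sink conversion needs stock_mass geometry, got {geometry.mode!r}")
    if geometry_value is None:
        geometry_value = geometry.value.mean()
    return _convert(annual_inflow_t, geometry, geometry_value, out_unit)


def accumulate_2000_2014(annual_increase_2014: ArrayLike, ramp: str = "linear_from_2000") -> ArrayLike:
    """Accumulated sink concentration at the end of 2014.

    ``linear_from_2000``: deposition scales linearly from (1/15)·D in 2000
    to D in 2014, accumulating 8·D.  ``constant``: D every year, 15·D.
    """
    x = np.asarray(annual_increase_2014, dtype=float)
    if np.any(x < 0):
        raise ValueError("annual increase must be >= 0")
    if ramp == "linear_from_2000":
        out = LINEAR_RAMP_FACTOR * x
    elif ramp == "constant":
        out = float(LINEAR_RAMP_YEARS) * x
    else:
        raise ValueError(f"unknown ramp {ramp!r}")
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class ConcentrationSample:
    """Per-iteration concentration samples for one compartment and basis."""

    compartment_id: str
    basis: str  # annual_flowthrough | annual_increase | accumulated_2000_2014
    unit: str  # accumulated/flowthrough: unit; annual_increase: unit per year
    values: np.ndarray


def concentration_samples(mc: MCResult, ramp: str = "linear_from_2000") -> list[ConcentrationSample]:
    """Concentration sample vectors for every compartment with a geometry
    and a native concentration unit, using the run's sampled geometries.

    Flow-through compartments yield one ``annual_flowthrough`` entry; sinks
    yield ``annual_increase`` plus the ramped ``accumulated_2000_2014``.
    """
    out: list[ConcentrationSample] = []
    for comp in mc.scenario.compartments:
        if comp.geometry is None or comp.conc_unit is None:
            continue
        inflow = mc.inflow(comp.id)
        gval = mc.geometry_samples[comp.id]
        if comp.geometry.mode == "stock_mass":
            inc = sink_annual_increase(inflow, comp.geometry, comp.conc_unit, gval)
            out.append(ConcentrationSample(comp.id, "annual_increase", comp.conc_unit + "/y", inc))
            out.append(
                ConcentrationSample(
                    comp.id, "accumulated_2000_2014", comp.conc_unit, accumulate_2000_2014(inc, ramp)
                )
            )
        else:
            val = pec_flowthrough(inflow, comp.geometry, comp.conc_unit, gval)
            out.append(ConcentrationSample(comp.id, "annual_flowthrough", comp.conc_unit, val))
    return out
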