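"""Synthetic scenario generator: archetypal nanomaterial lifecycles.

Real parameterizations of this model are survey-based (production volumes,
product allocation, release factors per material).  The generator emits
complete, validating scenarios with the *structural* release patterns
observed for the nine studied materials, so the whole pipeline is testable
and demonstrable without the survey data:

``cosmetics_dominated``
    most use-phase mass to wastewater (photostable TiO₂ / ZnO pattern);
``composite_dominated``
    ≥90% of use-phase mass to recycling/incineration/landfill (CNT);
``wood_preservative``
    environmental release almost entirely direct-to-soil (CuCO₃,
    ~98% of environmental release into soils);
``tire_wear``
    kt/y-scale production with wear-and-tear release to water and
    roadside soils (carbon black);
``low_volume_electronics``
    kg/y-scale production, almost no release during use (quantum dots).

All archetypes share one Denmark-plausible compartment backbone:
production → manufacturing → use, sewage treatment with high particle
removal to sludge, waste incineration splitting to bottom/fly ash with
near-complete particle retention, landfill and recycling as no-release
stores, export, and the environmental compartments freshwater/seawater,
their sediments, agricultural/natural/urban/sludge-treated soils and air.
Compartment geometries are fabricated at Denmark-plausible magnitudes and
tagged ``synthetic`` in the config metadata; the generator reproduces the
qualitative release structure, not any particular survey's numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .distributions import DistributionSpec as D
from .flow_system import (
    Compartment,
    GeometryDescriptor,
    ScenarioConfig,
    Transfer,
    point_mass_config,
)

ARCHETYPES = (
    "cosmetics_dominated",
    "composite_dominated",
    "wood_preservative",
    "tire_wear",
    "low_volume_electronics",
)


@dataclass(frozen=True)
class ScenarioTemplate:
    """Recipe for one synthetic scenario.

    ``production_scale`` overrides the archetype's default production
    magnitude (t/y); ``seed`` is recorded in the scenario metadata for
    provenance (generation itself is deterministic).
    """

    archetype: str
    production_scale: Optional[float] = None
    seed: Optional[int] = None


def _geom(mode: str, lower: float, upper: float, unit: str) -> GeometryDescriptor:
    return GeometryDescriptor(mode, D.uniform(lower, upper, unit), unit)


def _base_compartments() -> list[Compartment]:
    vol = "annual_throughput_volume"
    mas = "annual_throughput_mass"
    stk = "stock_mass"
    return [
        Compartment("production", "ENM production", "source"),
        Compartment("manufacturing", "Product manufacturing", "flowthrough"),
        Compartment("use", "Product use & consumption", "flowthrough"),
        # wastewater branch
        Compartment("stp", "Sewage treatment plant", "flowthrough"),
        Compartment(
            "effluent", "STP effluent", "flowthrough", "technical",
            _geom(vol, 6e11, 8e11, "L/y"), "µg/L",
        ),
        Compartment(
            "sludge", "Sewage sludge", "flowthrough", "technical",
            _geom(mas, 1.1e8, 1.5e8, "kg/y"), "mg/kg",
        ),
        Compartment("stp_elim", "Transformation in sewage treatment", "elimination"),
        # solid-waste branch
        Compartment(
            "wip", "Waste incineration plant", "flowthrough", "technical",
            _geom(mas, 3.0e9, 3.8e9, "kg/y"), "mg/kg",
        ),
        Compartment(
            "bottom_ash", "Bottom ash", "flowthrough", "technical",
            _geom(mas, 5e8, 7e8, "kg/y"), "mg/kg",
        ),
        Compartment(
            "fly_ash", "Fly ash", "flowthrough", "technical",
            _geom(mas, 0.8e8, 1.2e8, "kg/y"), "mg/kg",
        ),
        Compartment("wip_elim", "Destruction during incineration", "elimination"),
        Compartment("landfill", "Landfill (no modeled release)", "sink"),
        Compartment("recycling", "Recycling (no modeled release)", "sink"),
        Compartment("export", "Export out of system boundary", "export"),
        # environment
        Compartment(
            "air", "Atmosphere over Denmark", "flowthrough", "air",
            _geom(vol, 5e14, 2e15, "m³/y"), "ng/m³",
        ),
        Compartment(
            "freshwater", "Freshwater", "flowthrough", "freshwater",
            _geom(vol, 1e13, 3e13, "L/y"), "ng/L",
        ),
        Compartment(
            "seawater", "Danish marine waters", "flowthrough", "seawater",
            _geom(vol, 1e14, 5e14, "L/y"), "ng/L",
        ),
        Compartment(
            "sediment_fresh", "Freshwater sediment", "sink", "sediment_fresh",
            _geom(stk, 1e9, 5e9, "kg"), "µg/kg",
        ),
        Compartment(
            "sediment_marine", "Marine sediment", "sink", "sediment_marine",
            _geom(stk, 1e10, 5e10, "kg"), "µg/kg",
        ),
        Compartment(
            "agricultural_soil", "Agricultural soil", "sink", "soil",
            _geom(stk, 5e12, 7e12, "kg"), "µg/kg",
        ),
        Compartment(
            "natural_soil", "Natural soil", "sink", "soil",
            _geom(stk, 0.8e12, 1.5e12, "kg"), "µg/kg",
        ),
        Compartment(
            "urban_soil", "Urban soil", "sink", "soil",
            _geom(stk, 2e11, 4e11, "kg"), "µg/kg",
        ),
        Compartment(
            "sludge_treated_soil", "Sludge-treated soil", "sink", "soil",
            _geom(stk, 0.8e12, 1.2e12, "kg"), "µg/kg",
        ),
    ]


#: per-archetype default production-volume distributions (t/y)
_PRODUCTION = {
    "cosmetics_dominated": D.triangular(20, 60, 200, "t/y"),
    "composite_dominated": D.triangular(0.5, 2, 10, "t/y"),
    "wood_preservative": D.triangular(5, 15, 40, "t/y"),
    "tire_wear": D.uniform(1000, 3000, "t/y"),
    "low_volume_electronics": D.uniform(0.001, 0.05, "t/y"),
}

#: use-phase allocation per archetype: explicit edges + residual pathway.
#: (destination, lower, upper) as uniform coefficient bands.
_USE_SPLITS: dict[str, tuple[list[tuple[str, float, float]], str]] = {
    # most use-phase mass down the drain (cosmetics rinse-off)
    "cosmetics_dominated": (
        [
            ("wip", 0.05, 0.15),
            ("landfill", 0.02, 0.08),
            ("recycling", 0.0, 0.05),
            ("air", 0.0, 0.01),
            ("freshwater", 0.01, 0.05),  # storm-water overflow / direct
        ],
        "stp",
    ),
    # composites: overwhelmingly solid-waste routes
    "composite_dominated": (
        [
            ("recycling", 0.25, 0.40),
            ("wip", 0.30, 0.45),
            ("stp", 0.0, 0.02),
            ("air", 0.0, 0.002),
        ],
        "landfill",
    ),
    # impregnated wood: leaching into soil dominates environmental release,
    # discarded wood dominates total mass
    "wood_preservative": (
        [
            ("natural_soil", 0.03, 0.08),
            ("urban_soil", 0.02, 0.05),
            ("freshwater", 0.0005, 0.002),
            ("stp", 0.0005, 0.002),
            ("landfill", 0.10, 0.30),
            ("recycling", 0.05, 0.15),
        ],
        "wip",
    ),
    # tire abrasion: diffuse release to runoff and roadside soils
    "tire_wear": (
        [
            ("freshwater", 0.02, 0.06),
            ("urban_soil", 0.05, 0.12),
            ("natural_soil", 0.01, 0.04),
            ("stp", 0.05, 0.15),
            ("air", 0.001, 0.01),
            ("recycling", 0.10, 0.20),
        ],
        "wip",
    ),
    # encapsulated electronics: WEEE collection, near-zero release in use
    "low_volume_electronics": (
        [
            ("wip", 0.10, 0.20),
            ("landfill", 0.02, 0.08),
            ("stp", 0.0, 1e-4),
            ("air", 0.0, 1e-5),
        ],
        "recycling",
    ),
}

#: archetypes whose material burns in the incinerator (carbon-based);
#: the rest are mineral and report to the ashes nearly completely.
_COMBUSTIBLE = {"composite_dominated", "tire_wear"}


def generate_scenario(template: ScenarioTemplate) -> ScenarioConfig:
    """Build a complete validating scenario for the template's archetype."""
    a = template.archetype
    if a not in ARCHETYPES:
        raise ValueError(f"unknown archetype {a!r}; expected one of {ARCHETYPES}")

    production = _PRODUCTION[a]
    if template.production_scale is not None:
        s = float(template.production_scale)
        production = D.uniform(0.5 * s, 2.0 * s, "t/y")

    transfers: list[Transfer] = []
    residuals: dict[str, str] = {}

    def edge(o: str, d: str, spec: D) -> None:
        transfers.append(Transfer(o, d, spec))

    # production: small process losses, bulk to manufacturing
    edge("production", "stp", D.uniform(0.0, 0.01))
    edge("production", "air", D.uniform(0.0, 0.005))
    residuals["production"] = "manufacturing"

    # manufacturing: small losses, some product export, bulk to use
    edge("manufacturing", "stp", D.uniform(0.0, 0.01))
    edge("manufacturing", "air", D.uniform(0.0, 0.002))
    edge("manufacturing", "export", D.uniform(0.05, 0.25))
    residuals["manufacturing"] = "use"

    # use phase: archetype-specific
    splits, residual = _USE_SPLITS[a]
    for dest, lo, hi in splits:
        edge("use", dest, D.uniform(lo, hi))
    residuals["use"] = residual

    # sewage treatment: high particle removal to sludge; remainder effluent
    edge("stp", "sludge", D.uniform(0.85, 0.97))
    edge("stp", "stp_elim", D.uniform(0.0, 0.05))
    residuals["stp"] = "effluent"
    edge("effluent", "freshwater", D.point(1.0))
    # sludge: agricultural application, co-incineration, rest landfilled
    edge("sludge", "sludge_treated_soil", D.uniform(0.40, 0.60))
    edge("sludge", "wip", D.uniform(0.20, 0.40))
    residuals["sludge"] = "landfill"

    # incineration: near-complete particle retention in the ashes for
    # mineral ENM; combustion (elimination) for carbon-based ENM
    if a in _COMBUSTIBLE:
        edge("wip", "bottom_ash", D.uniform(0.005, 0.02))
        edge("wip", "fly_ash", D.uniform(0.005, 0.02))
        edge("wip", "air", D.uniform(1e-5, 1e-4))
        residuals["wip"] = "wip_elim"
    else:
        edge("wip", "bottom_ash", D.uniform(0.75, 0.85))
        edge("wip", "fly_ash", D.uniform(0.10, 0.20))
        edge("wip", "air", D.uniform(1e-4, 1e-3))
        residuals["wip"] = "wip_elim"
    edge("bottom_ash", "recycling", D.uniform(0.3, 0.7))
    residuals["bottom_ash"] = "landfill"
    edge("fly_ash", "export", D.uniform(0.4, 0.8))  # hazardous-waste export
    residuals["fly_ash"] = "landfill"

    # atmospheric settling: almost 100% removal over the modeling timescale,
    # split across surfaces by area share; remainder advected out
    edge("air", "agricultural_soil", D.uniform(0.36, 0.40))
    edge("air", "natural_soil", D.uniform(0.13, 0.17))
    edge("air", "urban_soil", D.uniform(0.05, 0.09))
    edge("air", "freshwater", D.uniform(0.01, 0.02))
    edge("air", "seawater", D.uniform(0.27, 0.33))
    residuals["air"] = "export"

    # water column: zero to complete sedimentation; remainder flows on
    edge("freshwater", "sediment_fresh", D.uniform(0.0, 1.0))
    residuals["freshwater"] = "seawater"
    edge("seawater", "sediment_marine", D.uniform(0.0, 1.0))
    residuals["seawater"] = "export"

    return ScenarioConfig(
        enm_name=f"synthetic-{a}",
        compartments=_base_compartments(),
        transfers=transfers,
        input_flows={"production": production},
        residuals=residuals,
        reference_year=2014,
        release_start_year=2000,
        meta={
            "provenance": "synthetic",
            "archetype": a,
            "template_seed": template.seed,
            "schema_version": 1,
        },
    )


def generate_point_mass_twin(config: ScenarioConfig) -> ScenarioConfig:
    """Deterministic twin: every distribution replaced by its mean.

    Engine output on the twin is a single deterministic solve; stochastic
    runs of the original should bracket it within their 95% intervals.
    """
    return point_mass_config(config)
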