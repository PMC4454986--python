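"""Scenario files, result tables and run provenance.

Scenario files are YAML (JSON is a subset and also accepted), one document
per material, schema version 1.  Distribution literals are tagged
mappings, e.g. ``{kind: uniform, lower: 0, upper: 1}``.  All tabular
output is CSV with units carried in explicit columns; every run writes a
manifest (seed, iteration count, config hash, timestamps) sufficient to
reproduce any published table.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .distributions import DistributionError, DistributionSpec
from .flow_system import (
    Compartment,
    GeometryDescriptor,
    ScenarioConfig,
    Transfer,
    validate_scenario,
)
from .monte_carlo import MCResult

SCHEMA_VERSION = 1


class ScenarioParseError(ValueError):
    """File unreadable or structurally not a scenario document."""


class ScenarioValidationError(ValueError):
    """Scenario parsed but violates structural invariants."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("scenario is invalid:\n  " + "\n  ".join(violations))


# -- dict <-> dataclasses ----------------------------------------------------

def scenario_to_dict(config: ScenarioConfig) -> dict:
    def comp(c: Compartment) -> dict:
        d: dict[str, Any] = {"id": c.id, "name": c.name, "role": c.role, "medium": c.medium}
        if c.geometry is not None:
            d["geometry"] = {
                "mode": c.geometry.mode,
                "value": c.geometry.value.to_dict(),
                "unit": c.geometry.unit,
            }
        if c.conc_unit is not None:
            d["conc_unit"] = c.conc_unit
        return d

    return {
        "schema_version": SCHEMA_VERSION,
        "enm_name": config.enm_name,
        "reference_year": config.reference_year,
        "release_start_year": config.release_start_year,
        "compartments": [comp(c) for c in config.compartments],
        "transfers": [
            {"origin": t.origin, "destination": t.destination,
             "coefficient": t.coefficient.to_dict()}
            for t in config.transfers
        ],
        "input_flows": {k: v.to_dict() for k, v in config.input_flows.items()},
        "residuals": dict(config.residuals),
        "meta": dict(config.meta),
    }


def _expect_mapping(obj: Any, where: str) -> Mapping:
    if not isinstance(obj, Mapping):
        raise ScenarioParseError(f"{where}: expected a mapping, got {type(obj).__name__}")
    return obj


def scenario_from_dict(doc: Mapping) -> ScenarioConfig:
    doc = _expect_mapping(doc, "document")
    try:
        comps = []
        for i, cd in enumerate(doc.get("compartments", [])):
            cd = _expect_mapping(cd, f"compartments[{i}]")
            geometry = None
            if "geometry" in cd and cd["geometry"] is not None:
                gd = _expect_mapping(cd["geometry"], f"compartments[{i}].geometry")
                geometry = GeometryDescriptor(
                    mode=str(gd.get("mode", "")),
                    value=DistributionSpec.from_dict(
                        gd.get("value", {}), where=f"compartments[{i}].geometry.value"
                    ),
                    unit=str(gd.get("unit", "")),
                )
            comps.append(
                Compartment(
                    id=str(cd.get("id", "")),
                    name=str(cd.get("name", cd.get("id", ""))),
                    role=str(cd.get("role", "")),
                    medium=str(cd.get("medium", "none")),
                    geometry=geometry,
                    conc_unit=cd.get("conc_unit"),
                )
            )
        transfers = []
        for i, td in enumerate(doc.get("transfers", [])):
            td = _expect_mapping(td, f"transfers[{i}]")
            transfers.append(
                Transfer(
                    origin=str(td.get("origin", "")),
                    destination=str(td.get("destination", "")),
                    coefficient=DistributionSpec.from_dict(
                        td.get("coefficient", {}), where=f"transfers[{i}].coefficient"
                    ),
                )
            )
        flows = {
            str(k): DistributionSpec.from_dict(v, where=f"input_flows[{k!r}]")
            for k, v in _expect_mapping(doc.get("input_flows", {}), "input_flows").items()
        }
    except DistributionError as err:
        raise ScenarioParseError(str(err)) from None
    return ScenarioConfig(
        enm_name=str(doc.get("enm_name", "unnamed")),
        compartments=comps,
        transfers=transfers,
        input_flows=flows,
        residuals={str(k): str(v) for k, v in _expect_mapping(doc.get("residuals", {}), "residuals").items()},
        reference_year=int(doc.get("reference_year", 2014)),
        release_start_year=int(doc.get("release_start_year", 2000)),
        meta=dict(_expect_mapping(doc.get("meta", {}), "meta")),
    )


# -- files -------------------------------------------------------------------

def save_scenario(config: ScenarioConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        yaml.safe_dump(scenario_to_dict(config), sort_keys=True, allow_unicode=True)
    )
    return path


def load_scenario(path: str | Path, validate: bool = True) -> ScenarioConfig:
    """Parse and (by default) validate a scenario file.

    Raises :class:`ScenarioParseError` for unreadable/ill-formed documents
    and :class:`ScenarioValidationError` listing all structural violations.
    """
    path = Path(path)
    if not path.exists():
        raise ScenarioParseError(f"{path}: no such file")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ScenarioParseError(f"{path}: {err}") from None
    if doc is None:
        raise ScenarioParseError(f"{path}: empty document")
    config = scenario_from_dict(doc)
    if validate:
        violations = validate_scenario(config)
        if violations:
            raise ScenarioValidationError(violations)
    return config


def config_hash(config: ScenarioConfig) -> str:
    blob = json.dumps(scenario_to_dict(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


# -- run manifest & result files ---------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    n_iter: int
    software_version: str = __version__
    started: str = ""
    finished: str = ""
    outputs: list[str] = field(default_factory=list)

    @staticmethod
    def now() -> str:
        return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


def write_results(
    mc: MCResult,
    out_dir: str | Path,
    ramp: str = "linear_from_2000",
    dump_samples: bool = False,
    started: str | None = None,
) -> RunManifest:
    """Write the standard result file set for one run.

    ``concentrations.csv`` (mode/q2.5/q97.5 per compartment & basis),
    ``flows.csv`` (per-edge modal flow and 95% interval),
    ``source_receiver_shares.csv`` (modal share per technical source and
    environmental receiver), optionally ``edge_flow_samples.csv``, and
    ``manifest.json``.  Content is deterministic for a fixed seed.
    """
    from .summary_stats import concentration_table, flow_table, source_receiver_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=mc.fingerprint,
        seed=mc.seed,
        n_iter=mc.n_iter,
        started=started or RunManifest.now(),
    )

    files = {
        "concentrations.csv": concentration_table(mc, ramp=ramp),
        "flows.csv": flow_table(mc),
        "source_receiver_shares.csv": source_receiver_table(mc),
    }
    for name, df in files.items():
        df.to_csv(out / name, index=False)
        manifest.outputs.append(name)
    if dump_samples:
        import pandas as pd

        cols = {f"{o}->{d}": mc.edge_flows[:, i] for i, (o, d) in enumerate(mc.edges)}
        pd.DataFrame(cols).to_csv(out / "edge_flow_samples.csv", index=False)
        manifest.outputs.append("edge_flow_samples.csv")

    save_scenario(mc.scenario, out / "scenario.yaml")
    manifest.outputs.append("scenario.yaml")
    manifest.finished = RunManifest.now()
    # atomic-ish: write to temp then rename
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(asdict(manifest), indent=2))
    tmp.replace(out / "manifest.json")
    return manifest
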