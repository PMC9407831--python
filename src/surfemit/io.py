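"""Configuration reading/writing and result serialization.

Scenarios are described by a structured text configuration with sections
``[chemical]``, ``[surface]``, ``[room]``, ``[liquid]``, ``[simulation]``
and an optional ``[numerics]``; field names mirror the domain types and all
values are SI (µg, m, s).  TOML and JSON dialects are both accepted (by
file extension).  Reading is strict: unknown sections or keys are rejected
with a full listing.  Time series go to CSV with units baked into the
column headers; metrics and run manifests go to JSON.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, fields as dataclass_fields
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    ChemicalProps,
    Finding,
    LiquidApplication,
    RoomSpec,
    Scenario,
    ScenarioError,
    SurfaceSpec,
    validate_scenario,
)
from .solver import NumericsConfig, SimulationResult

__all__ = [
    "ConfigError",
    "load_config",
    "dump_config",
    "scenario_to_dict",
    "scenario_from_dict",
    "write_timeseries",
    "read_timeseries",
    "write_metrics",
    "RunManifest",
]

TIMESERIES_COLUMNS = [
    "time_s",
    "Ca_ug_m3",
    "ml_ug",
    "substrate_mass_ug",
    "exhaust_cumulative_ug",
    "stage",
]


class ConfigError(ValueError):
    """Raised for unparseable or inconsistent configuration files."""


_SECTION_TYPES = {
    "chemical": ChemicalProps,
    "surface": SurfaceSpec,
    "room": RoomSpec,
    "liquid": LiquidApplication,
}
_SIMULATION_KEYS = {"mode", "t_end", "output_interval"}
_NUMERICS_KEYS = {f.name for f in dataclass_fields(NumericsConfig)}


def scenario_to_dict(s: Scenario) -> dict:
    """Sectioned plain-dict form of a scenario (round-trips losslessly)."""
    out = {}
    for section, typ in _SECTION_TYPES.items():
        value = getattr(s, section)
        if value is None:
            continue
        d = asdict(value)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items() if v is not None}
        out[section] = d
    out["simulation"] = {
        "mode": s.mode,
        "t_end": s.t_end,
        "output_interval": s.output_interval,
    }
    return out


def _build_section(section: str, data: dict, problems: list):
    typ = _SECTION_TYPES[section]
    known = {f.name for f in dataclass_fields(typ)}
    unknown = set(data) - known
    if unknown:
        problems.append(f"[{section}]: unknown keys {sorted(unknown)}")
        return None
    try:
        kwargs = dict(data)
        if section == "surface" and "Cs0_profile" in kwargs and kwargs["Cs0_profile"] is not None:
            kwargs["Cs0_profile"] = tuple(kwargs["Cs0_profile"])
        return typ(**kwargs)
    except TypeError as exc:
        problems.append(f"[{section}]: {exc}")
        return None


def scenario_from_dict(data: dict) -> Tuple[Scenario, NumericsConfig]:
    """Strictly parse the sectioned dict form; returns the scenario and numerics."""
    problems: list = []
    known_sections = set(_SECTION_TYPES) | {"simulation", "numerics"}
    unknown = set(data) - known_sections
    if unknown:
        problems.append(f"unknown sections {sorted(unknown)}")

    for required in ("chemical", "surface", "room", "simulation"):
        if required not in data:
            problems.append(f"missing required section [{required}]")
    if problems:
        raise ConfigError("; ".join(problems))

    chemical = _build_section("chemical", data["chemical"], problems)
    surface = _build_section("surface", data["surface"], problems)
    room = _build_section("room", data["room"], problems)
    liquid = _build_section("liquid", data["liquid"], problems) if "liquid" in data else None

    sim = dict(data["simulation"])
    unknown = set(sim) - _SIMULATION_KEYS
    if unknown:
        problems.append(f"[simulation]: unknown keys {sorted(unknown)}")

    numerics = NumericsConfig()
    if "numerics" in data:
        num = dict(data["numerics"])
        unknown = set(num) - _NUMERICS_KEYS
        if unknown:
            problems.append(f"[numerics]: unknown keys {sorted(unknown)}")
        else:
            numerics = NumericsConfig(**num)
    if problems:
        raise ConfigError("; ".join(problems))

    scenario = Scenario(
        chemical=chemical,
        surface=surface,
        room=room,
        liquid=liquid,
        mode=sim.get("mode", "full"),
        t_end=float(sim.get("t_end", 12 * 3600.0)),
        output_interval=float(sim.get("output_interval", 60.0)),
    )
    return scenario, numerics


def load_config(path) -> Tuple[Scenario, NumericsConfig]:
    """Read a TOML (``.toml``) or JSON (``.json``) scenario configuration.

    The returned scenario has its ``Kls`` default resolved and carries no
    blocking validation findings; otherwise :class:`ConfigError` (parse /
    unknown keys) or :class:`~surfemit.core.ScenarioError` (aggregated
    validation errors) is raised.
    """
    path = Path(path)
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(path.read_text())
        else:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
    except (json.JSONDecodeError, tomllib.TOMLDecodeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc

    scenario, numerics = scenario_from_dict(data)
    scenario = scenario.resolved()
    errors = [f for f in validate_scenario(scenario) if f.severity == "error"]
    if errors:
        raise ScenarioError(errors)
    return scenario, numerics


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)  # JSON string escaping is valid TOML
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v).__name__} to TOML")


def dump_config(s: Scenario, numerics: Optional[NumericsConfig] = None) -> str:
    """Render a scenario (and optional numerics) as TOML text."""
    data = scenario_to_dict(s)
    if numerics is not None:
        data["numerics"] = {k: v for k, v in asdict(numerics).items() if v is not None}
    lines = []
    for section, body in data.items():
        lines.append(f"[{section}]")
        for key, value in body.items():
            lines.append(f"{key} = {_toml_value(value)}")
        lines.append("")
    return "\n".join(lines)


def write_timeseries(result: SimulationResult, path) -> Path:
    """Write the reported series as CSV, one row per reporting interval.

    Floats are written in full-precision scientific notation so a re-read
    reproduces the series bit-for-bit at the printed precision.
    """
    path = Path(path)
    frame = pd.DataFrame(
        {
            "time_s": result.times,
            "Ca_ug_m3": result.Ca_series,
            "ml_ug": result.ml_series,
            "substrate_mass_ug": result.substrate_mass_series,
            "exhaust_cumulative_ug": result.exhaust_cumulative,
            "stage": result.stage_series,
        }
    )
    frame.to_csv(path, index=False, float_format="%.17e")
    return path


def read_timeseries(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(TIMESERIES_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns {sorted(missing)}")
    return frame


def write_metrics(metrics, path) -> Path:
    path = Path(path)
    path.write_text(metrics.to_json() + "\n")
    return path


@dataclass
class RunManifest:
    """Provenance of one CLI run: inputs, numerics and produced files."""

    tool_version: str
    scenario_source: str
    numerics: dict
    started_utc: str
    finished_utc: str
    outputs: list

    @classmethod
    def begin(cls, scenario_source: str, numerics: NumericsConfig) -> "RunManifest":
        now = datetime.now(timezone.utc).isoformat()
        return cls(
            tool_version=__version__,
            scenario_source=scenario_source,
            numerics={k: v for k, v in asdict(numerics).items() if v is not None},
            started_utc=now,
            finished_utc=now,
            outputs=[],
        )

    def finish(self, outputs) -> "RunManifest":
        self.finished_utc = datetime.now(timezone.utc).isoformat()
        self.outputs = [str(p) for p in outputs]
        missing = [p for p in self.outputs if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")
        return self

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path
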