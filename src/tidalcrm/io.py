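"""Configuration parsing and CSV readers/writers.

The run configuration is YAML or JSON.  Geometry and mortality settings are
top-level and shared by every scenario; each scenario entry carries its own
approach speed, RPM, lattice and time-lag count.  Unknown keys are rejected
with their full key path.

Two CSV outputs per run: ``instances.csv`` (one row per transit, with the
collided flag, so non-collision denominators are recoverable) and
``collisions.csv`` (one row per individual collision, the published
extraction format).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import risk
from .engine import (GridSpec, Scenario, ScenarioResult,
                     APPROACH_SPEEDS, ROTATION_RPMS)
from .geometry import BladeSpec, FoundationSpec, RotorSpec, SealSpec


class ConfigError(ValueError):
    """Configuration schema violation (reported with its key path)."""


COLLISION_CSV_COLUMNS = [
    "scenario_id", "sim_id", "start_y_m", "start_z_m", "phase_rad",
    "t_contact_s", "collision_speed_ms",
    "contact_x_m", "contact_y_m", "contact_z_m",
    "body_x_m", "body_y_m", "body_z_m",
    "nose_distance_m", "region", "component_id", "device_point_speed_ms",
]

INSTANCE_CSV_COLUMNS = ["scenario_id", "sim_id", "start_y_m", "start_z_m",
                        "phase_idx", "phase_rad", "collided"]


@dataclass(frozen=True)
class MortalityConfig:
    thresholds_ms: tuple = tuple(float(t) for t in range(8))
    head_boundary_m: float = 0.4
    head_rules: tuple = (False, True)

    def __post_init__(self):
        if not self.thresholds_ms:
            raise ConfigError("mortality.thresholds_ms must not be empty")
        if any(t < 0 for t in self.thresholds_ms):
            raise ConfigError("mortality thresholds must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    scenarios: tuple
    seal: SealSpec = field(default_factory=SealSpec)
    rotor: RotorSpec = field(default_factory=RotorSpec)
    blade: BladeSpec = field(default_factory=BladeSpec)
    foundation: FoundationSpec | None = field(default_factory=FoundationSpec)
    hub_radius_m: float = 1.0
    mortality: MortalityConfig = field(default_factory=MortalityConfig)
    output_dir: str = "runs"

    def __post_init__(self):
        ids = [s.id for s in self.scenarios]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"scenario ids must be unique, got {ids}")

    def build_scenarios(self) -> list[Scenario]:
        """Scenarios with the shared geometry applied."""
        out = []
        for s in self.scenarios:
            out.append(dataclasses.replace(
                s, seal=self.seal, rotor=self.rotor, blade=self.blade,
                foundation=self.foundation, hub_radius_m=self.hub_radius_m))
        return out


_SCENARIO_KEYS = {"id", "approach_speed_ms", "rpm", "grid", "n_time_lags",
                  "release_distance_m", "random_phases", "seed"}


def _build(cls, data, path):
    """Construct a (frozen) dataclass from a mapping, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _build_scenario(entry, idx):
    path = f"scenarios[{idx}]"
    if not isinstance(entry, dict):
        raise ConfigError(f"{path}: expected a mapping")
    unknown = set(entry) - _SCENARIO_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    entry = dict(entry)
    sid = entry.get("id", f"scenario_{idx}")
    # Table-1 codes default their speed/RPM
    if sid[:2] in APPROACH_SPEEDS and "approach_speed_ms" not in entry:
        entry["approach_speed_ms"] = APPROACH_SPEEDS[sid[:2]]
    if sid[2:4] in ROTATION_RPMS and "rpm" not in entry:
        entry["rpm"] = ROTATION_RPMS[sid[2:4]]
    entry["id"] = sid
    grid = entry.pop("grid", None)
    try:
        sc = Scenario(grid=_build(GridSpec, grid, f"{path}.grid"), **entry)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return sc


_TOP_KEYS = {"scenarios", "seal", "rotor", "blade", "foundation",
             "hub_radius_m", "mortality", "output_dir"}


def parse_config(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("top level: expected a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"top level: unknown key(s) {sorted(unknown)}")
    entries = data.get("scenarios")
    if not entries:
        raise ConfigError("scenarios: at least one scenario is required")
    scenarios = tuple(_build_scenario(e, i) for i, e in enumerate(entries))
    foundation = data.get("foundation", "default")
    if foundation == "default":
        foundation = FoundationSpec()
    elif foundation is not None:
        foundation = _build(FoundationSpec, foundation, "foundation")
    mort = data.get("mortality", {})
    if mort and "thresholds_ms" in mort:
        mort = dict(mort)
        mort["thresholds_ms"] = tuple(float(t) for t in mort["thresholds_ms"])
    if mort and "head_rules" in mort:
        mort = dict(mort)
        mort["head_rules"] = tuple(bool(h) for h in mort["head_rules"])
    rotor = data.get("rotor", {})
    if rotor:
        rotor = dict(rotor)
        for key in ("hub_center", "axis"):
            if key in rotor:
                rotor[key] = tuple(float(x) for x in rotor[key])
    return RunConfig(
        scenarios=scenarios,
        seal=_build(SealSpec, data.get("seal"), "seal"),
        rotor=_build(RotorSpec, rotor, "rotor"),
        blade=_build(BladeSpec, data.get("blade"), "blade"),
        foundation=foundation,
        hub_radius_m=float(data.get("hub_radius_m", 1.0)),
        mortality=_build(MortalityConfig, mort, "mortality"),
        output_dir=str(data.get("output_dir", "runs")),
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return parse_config(data)


def dump_config(config: RunConfig) -> dict:
    """Normalized plain-dict form of a RunConfig (dump(load(x)) round-trips)."""

    def spec_dict(obj):
        return {f.name: getattr(obj, f.name)
                for f in dataclasses.fields(obj)}

    out = {
        "scenarios": [],
        "seal": spec_dict(config.seal),
        "rotor": spec_dict(config.rotor),
        "blade": spec_dict(config.blade),
        "foundation": (spec_dict(config.foundation)
                       if config.foundation is not None else None),
        "hub_radius_m": config.hub_radius_m,
        "mortality": {
            "thresholds_ms": list(config.mortality.thresholds_ms),
            "head_boundary_m": config.mortality.head_boundary_m,
            "head_rules": list(config.mortality.head_rules),
        },
        "output_dir": config.output_dir,
    }
    for s in config.scenarios:
        out["scenarios"].append({
            "id": s.id,
            "approach_speed_ms": s.approach_speed_ms,
            "rpm": s.rpm,
            "grid": spec_dict(s.grid),
            "n_time_lags": s.n_time_lags,
            "release_distance_m": s.release_distance_m,
            "random_phases": s.random_phases,
            "seed": s.seed,
        })
    return out


# ---------------------------------------------------------------------------
# CSV writers / readers
# ---------------------------------------------------------------------------

def collisions_frame(result: ScenarioResult,
                     head_boundary_m: float = 0.4) -> pd.DataFrame:
    """Per-collision rows in the published extraction layout."""
    rec = risk.add_region(result.records, head_boundary_m)
    return rec[COLLISION_CSV_COLUMNS].copy()


def write_collisions_csv(results, path, head_boundary_m: float = 0.4) -> None:
    """Write one CSV row per collision (multiple scenarios concatenate)."""
    if isinstance(results, ScenarioResult):
        results = [results]
    frames = [collisions_frame(r, head_boundary_m) for r in results]
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=COLLISION_CSV_COLUMNS))
    df.to_csv(path, index=False, lineterminator="\n")


def read_collisions_csv(path) -> pd.DataFrame:
    """Read a collisions CSV back; numeric fields are validated per line."""
    df = pd.read_csv(path, dtype={"scenario_id": str, "region": str,
                                  "component_id": str})
    missing = set(COLLISION_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    numeric = [c for c in COLLISION_CSV_COLUMNS
               if c not in ("scenario_id", "region", "component_id")]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(coerced.isna().to_numpy()
                         & df[col].notna().to_numpy())[0]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at line "
                f"{bad[0] + 2}")
        df[col] = coerced
    return df


def write_instances_csv(results, path) -> None:
    if isinstance(results, ScenarioResult):
        results = [results]
    frames = [r.instances[INSTANCE_CSV_COLUMNS] for r in results]
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=INSTANCE_CSV_COLUMNS))
    df.to_csv(path, index=False, lineterminator="\n")


def read_instances_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"scenario_id": str})
    missing = set(INSTANCE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df
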