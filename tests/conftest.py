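"""Shared fixtures: coarse scenario runs and synthetic result builders."""

import numpy as np
import pandas as pd
import pytest

from tidalcrm import engine


#: coarse desk-scale lattice used by the trend/QC checks: 1 m spacing,
#: 50 time-lags over the full 22 x 23 m release area
COARSE_GRID = engine.GridSpec(spacing_m=1.0)
COARSE_LAGS = 50


def coarse_scenario(code: str) -> engine.Scenario:
    return engine.scenario_from_code(code, grid=COARSE_GRID,
                                     n_time_lags=COARSE_LAGS)


@pytest.fixture(scope="session")
def coarse_a1r1() -> engine.ScenarioResult:
    """Slow-approach cut-in scenario on the coarse lattice."""
    return engine.run_scenario(coarse_scenario("A1R1"), log_every=0)


@pytest.fixture(scope="session")
def coarse_speed_series(coarse_a1r1):
    """A1R1/A2R1/A3R1 on the same coarse lattice (fixed RPM, rising speed)."""
    return {
        "A1R1": coarse_a1r1,
        "A2R1": engine.run_scenario(coarse_scenario("A2R1"), log_every=0),
        "A3R1": engine.run_scenario(coarse_scenario("A3R1"), log_every=0),
    }


def make_synthetic_result(cells, n_time_lags=10,
                          grid=None) -> engine.ScenarioResult:
    """Build a ScenarioResult from hand-written records (synthetic stand-in
    for an engine run; used to test the aggregation layer in isolation).

    ``cells`` is a list of dicts with keys start_y_m, start_z_m, phase_idx,
    collision_speed_ms, nose_distance_m (one dict per collision record).
    """
    if grid is None:
        grid = engine.GridSpec(width_m=2.0, height_m=2.0, spacing_m=1.0)
    scenario = engine.Scenario(id="synthetic", grid=grid,
                               n_time_lags=n_time_lags)
    instances = engine.enumerate_instances(scenario)
    y0 = grid.y_values()[0]
    z0 = grid.z_values()[0]
    n_y = grid.n_y
    rows = []
    for c in cells:
        iy = round((c["start_y_m"] - y0) / grid.spacing_m)
        iz = round((c["start_z_m"] - z0) / grid.spacing_m)
        cell_idx = iz * n_y + iy
        sim_id = cell_idx * n_time_lags + c["phase_idx"]
        phase = 2 * np.pi * c["phase_idx"] / n_time_lags
        speed = c["collision_speed_ms"]
        rows.append({
            "sim_id": sim_id, "scenario_id": scenario.id,
            "start_y_m": c["start_y_m"], "start_z_m": c["start_z_m"],
            "phase_idx": c["phase_idx"], "phase_rad": phase,
            "t_contact_s": 1.0, "contact_x_m": 0.0, "contact_y_m": 0.0,
            "contact_z_m": 0.0, "body_x_m": 0.0, "body_y_m": 0.0,
            "body_z_m": 0.0, "nose_distance_m": c["nose_distance_m"],
            "component_id": c.get("component_id", "blade_0"),
            "v_seal_x_ms": 0.5, "v_seal_y_ms": 0.0, "v_seal_z_ms": 0.0,
            "v_device_x_ms": 0.0, "v_device_y_ms": 0.0, "v_device_z_ms": 0.0,
            "collision_speed_ms": speed, "device_point_speed_ms": 0.0,
        })
    records = pd.DataFrame(rows, columns=engine.RECORD_COLUMNS)
    collided = instances["sim_id"].isin(records["sim_id"])
    instances = instances.assign(collided=collided)
    return engine.ScenarioResult(scenario=scenario, instances=instances,
                                 records=records)
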