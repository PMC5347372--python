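"""Shared fixtures: reduced-scale simulation runs reused across test modules.

The desk-scale geometry (4-6 um box, R = 1-2 um cell, r_bind = 0.05 um,
D = 5 um^2/s, 1 ms fine step, gamma ~ 2 with a recalibrated binding
probability) keeps the full physics pipeline -- calibration, binding,
unbinding, clamped boundaries, surface receptor diffusion -- while fitting
minutes of wall time.  The exact specular sphere reflection is selected for
these runs because the diffusive step length is a few percent of the cell
radius; at the standard full-scale parameters (step/R ~ 0.6%) the default
radial mirror is equivalent.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gradsense import SimulationConfig, run_simulation
from gradsense.calibration import calibrate

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: desk-scale microscopic parameters shared by the simulation fixtures
DESK = dict(
    d_ligand=5.0,
    d_receptor=0.0025,
    dt=1e-3,
    dtau=1e-2,
    r_bind=0.05,
    r_unbind=0.05,
    k_on=5.0e7,          # (M.s)^-1 -> K_D = 10 nM with k_off = 0.5 s^-1
    k_off=0.5,
    sphere_reflection="specular",
    boundary_method="method1",
    gradient=0.0,
    record_interval=0.05,
)


@pytest.fixture(scope="session")
def desk_cal():
    """Binding-probability calibration for the desk parameter set."""
    return calibrate(
        k_on=DESK["k_on"], dt=DESK["dt"], r_bind=DESK["r_bind"],
        r_unbind=DESK["r_unbind"], d_ligand=DESK["d_ligand"],
        d_receptor=DESK["d_receptor"],
    )


@pytest.fixture(scope="session")
def table1_cal():
    """Calibration at the standard (full-scale) parameter set."""
    return calibrate(
        k_on=1.6e5, dt=1e-6, r_bind=0.004, r_unbind=0.004,
        d_ligand=125.0, d_receptor=0.0025,
    )


@pytest.fixture(scope="session")
def equilibrium_runs(desk_cal):
    """Three replicate equilibrium runs at c = K_D in a clamped uniform box.

    Geometry: (6 um)^3 box, R = 2 um, 200 receptors, 10 nM background.
    Used for rate recovery, equilibrium occupancy moments and counters.
    """
    cfg = SimulationConfig(
        box_lengths=(6.0, 6.0, 6.0), cell_radius=2.0, n_receptors=200,
        concentration=10.0, burn_in=10.0, duration=240.0, **DESK,
    )
    frames = []
    for seed in (31, 32, 33):
        res = run_simulation(
            cfg.replace(seed=seed), p_bind_override=desk_cal.p_bind,
            check_invariants=(seed == 31),
        )
        frames.append(res.to_dataframe())
    return {"config": cfg, "frames": frames, "cal": desk_cal}


@pytest.fixture(scope="session")
def cv2_runs(desk_cal):
    """Three replicate equilibrium runs at c = 7 K_D for time-averaging
    statistics (short relaxation time tau_N = 0.25 s)."""
    cfg = SimulationConfig(
        box_lengths=(4.0, 4.0, 4.0), cell_radius=1.0, n_receptors=100,
        concentration=70.0, burn_in=10.0, duration=240.0, **DESK,
    )
    series = []
    for seed in (41, 42, 43):
        res = run_simulation(
            cfg.replace(seed=seed), p_bind_override=desk_cal.p_bind,
        )
        series.append(res.to_dataframe()["n_bound"].to_numpy(dtype=float))
    return {"config": cfg, "series": series}


def _no_cell_config(**kw):
    base = dict(
        box_lengths=(4.0, 4.0, 4.0), cell_radius=0.0, n_receptors=0,
        d_ligand=5.0, d_receptor=0.0, dt=1e-3, dtau=1e-3, k_on=0.0, k_off=0.0,
        concentration=5.0, gradient=1.0, record_interval=0.2,
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def m1_profile_run():
    """Method-1 (both faces clamped) run without a cell: the defining test
    of the concentration clamp and the linear steady profile."""
    cfg = _no_cell_config(boundary_method="method1", seed=51,
                          burn_in=10.0, duration=60.0)
    return run_simulation(cfg, snapshot_interval=0.2)


@pytest.fixture(scope="session")
def m2_profile_run():
    """Method-2 (one-sided source, partially absorbing far face) run
    without a cell, starting from an empty box."""
    cfg = _no_cell_config(boundary_method="method2", seed=52,
                          burn_in=0.0, duration=80.0)
    return run_simulation(cfg, init_mode="empty_receptors",
                          snapshot_interval=0.2)
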