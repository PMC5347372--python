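"""Named scenario presets mirroring the study designs, plus the run driver
that executes a preset and writes a reproducible output bundle.

The full-scale presets (10 um box, 10^4 receptors, 1 us fine step, tens of
simulated minutes) are *cluster-scale* jobs: a 60-minute production run
advances the fine loop ~3.6e9 times.  They are registered here so that the
exact study conditions are executable and auditable; quick validation and CI
use the reduced `desk_small` preset or purpose-built small configurations.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .config import SimulationConfig, derive_parameters
from .run import run_simulation

__all__ = ["Scenario", "SCENARIOS", "list_scenarios", "run_scenario"]

_SLOW = dict(k_on=1.6e5, k_off=0.0011)
_FAST = dict(k_on=1.6e6, k_off=0.011)

_BASE = SimulationConfig()  # Table-style standard parameter set (slow rates)


@dataclass(frozen=True)
class Scenario:
    """An immutable preset: configuration, replicate count, initialization
    mode and the analyses its output is meant for."""

    name: str
    config: SimulationConfig
    replicates: int
    init_mode: str = "equilibrium"
    analyses: tuple = ()
    description: str = ""
    companion: Optional[SimulationConfig] = None  # paired comparison run


def _std(replicates, init_mode="equilibrium", analyses=(), description="",
         companion=None, **overrides) -> Scenario:
    cfg = _BASE.replace(**overrides)
    return Scenario(
        name="",  # filled by register
        config=cfg,
        replicates=replicates,
        init_mode=init_mode,
        analyses=tuple(analyses),
        description=description,
        companion=companion,
    )


SCENARIOS: dict[str, Scenario] = {}


def _register(name: str, scenario: Scenario) -> None:
    SCENARIOS[name] = dataclasses.replace(scenario, name=name)


# -- equilibrium, uniform concentration --------------------------------
_register("uniform_fast_eq", _std(
    16, gradient=0.0, burn_in=1800.0, duration=3600.0, **_FAST,
    analyses=("occupancy", "cv2"),
    description="Equilibrium occupancy fluctuations and time-averaging, "
                "uniform 6.9 nM, fast rates.",
))
_register("uniform_slow_eq", _std(
    16, gradient=0.0, burn_in=1800.0, duration=3600.0, **_SLOW,
    analyses=("occupancy", "cv2"),
    description="As uniform_fast_eq with the slow measured rates.",
))
_register("cycling_vs_release", _std(
    26, gradient=0.0, burn_in=1800.0, duration=3600.0, **_SLOW,
    analyses=("occupancy", "cv2"),
    description="Ligand-releasing model vs ligand-absorbing receptor "
                "cycling (companion run) at identical turnover rate.",
    companion=_BASE.replace(
        gradient=0.0, burn_in=1800.0, duration=3600.0,
        k_on=1.6e5, k_off=0.0, receptor_cycling=True, k_endo=0.0011,
    ),
))

# -- equilibrium in a gradient -----------------------------------------
_register("gradient05_fast", _std(
    8, gradient=0.5, burn_in=1800.0, duration=3600.0, **_FAST,
    analyses=("halfcell", "profile"),
    description="0.5 nM/um gradient, fast rates; steric sharpening and "
                "front/back occupancy split.",
))
_register("gradient05_slow", _std(
    8, gradient=0.5, burn_in=1800.0, duration=3600.0, **_SLOW,
    analyses=("halfcell", "profile"),
    description="0.5 nM/um gradient, slow rates.",
))
_register("gradient05_slow_frozen_receptors", _std(
    8, gradient=0.5, d_receptor=0.0, burn_in=1800.0, duration=3600.0, **_SLOW,
    analyses=("halfcell",),
    description="0.5 nM/um gradient, slow rates, immobile receptors "
                "(receptor diffusion switched off).",
))
_register("permeable_control", _std(
    8, gradient=0.5, membrane_permeable=True, burn_in=1800.0, duration=3600.0,
    **_FAST, analyses=("halfcell", "profile"),
    description="Permeable-membrane control: the ligand profile stays "
                "linear through the cell.",
))
_register("gradient01_fast", _std(
    16, gradient=0.1, burn_in=1800.0, duration=3600.0, **_FAST,
    analyses=("direction", "thresholds"),
    description="Shallow 0.1 nM/um gradient, fast rates; angular deviation "
                "of the gradient estimate and threshold accuracy.",
))
_register("small_cell_R175", _std(
    8, gradient=0.5, cell_radius=1.75, burn_in=1800.0, duration=3600.0, **_FAST,
    analyses=("halfcell", "profile"),
    description="Smaller cell (R = 1.75 um): weaker steric sharpening.",
))

# -- gradient formation (one-sided source) -----------------------------
for rates, tag, reps in ((_SLOW, "slow", 20), (_FAST, "fast", 20)):
    _register(f"method2_formation_{tag}_6.9nM", _std(
        reps, boundary_method="method2", gradient=0.1, concentration=6.9,
        burn_in=0.0, duration=3600.0, init_mode="empty_receptors", **rates,
        analyses=("transient", "confidence"),
        description=f"Forming 0.1 nM/um gradient at 6.9 nM background, {tag} "
                    "rates; receptors start unoccupied and the box empty.",
    ))
for rates, tag in ((_SLOW, "slow"), (_FAST, "fast")):
    _register(f"method2_formation_{tag}_69nM", _std(
        8, boundary_method="method2", gradient=0.1, concentration=69.0,
        burn_in=0.0, duration=3600.0, init_mode="empty_receptors", **rates,
        analyses=("transient", "confidence"),
        description=f"Forming gradient at 69 nM (10x K_D) background, {tag} rates.",
    ))
for rates, tag in ((_SLOW, "slow"), (_FAST, "fast")):
    _register(f"bar1_{tag}", _std(
        16, boundary_method="method2", gradient=0.1, concentration=6.9,
        bar1=True, burn_in=0.0, duration=3600.0, init_mode="empty_receptors",
        **rates,
        analyses=("confidence",),
        description=f"Gradient formation with the static Bar1 protease field, "
                    f"{tag} rates.",
    ))

# -- reduced-scale preset ----------------------------------------------
_register("desk_small", _std(
    4, box_lengths=(5.0, 5.0, 5.0), cell_radius=1.0, n_receptors=1000,
    dt=5e-6, dtau=5e-5, gradient=0.0, burn_in=227.0, duration=20.0,
    record_interval=0.05, **_FAST,
    analyses=("occupancy",),
    description="Reduced geometry for quick validation: (5 um)^3 box, "
                "R = 1 um, 1000 receptors, 5 us fine step with recalibrated "
                "binding probability; burn-in is 5 relaxation times.",
))


def list_scenarios() -> dict[str, Scenario]:
    """The immutable preset catalogue."""
    return dict(SCENARIOS)


def run_scenario(
    scenario: Scenario | str,
    seed: int,
    output_dir: str | Path,
    *,
    duration: Optional[float] = None,
    burn_in: Optional[float] = None,
    replicates: Optional[int] = None,
    p_bind_override: Optional[float] = None,
    snapshot_interval: Optional[float] = None,
) -> dict:
    """Execute a scenario and write a reproducible bundle.

    Per replicate i the config seed is seed + i.  Writes config.json,
    derived.json, observables_rep<i>.csv and manifest.json into
    ``output_dir``; keyword overrides are recorded in the manifest.
    Returns the manifest dict.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    overrides = {
        k: v for k, v in {
            "duration": duration, "burn_in": burn_in, "replicates": replicates,
            "p_bind_override": p_bind_override,
        }.items() if v is not None
    }
    cfg = scenario.config
    if duration is not None:
        cfg = cfg.replace(duration=duration)
    if burn_in is not None:
        cfg = cfg.replace(burn_in=burn_in)
    n_rep = replicates if replicates is not None else scenario.replicates

    derived = derive_parameters(cfg.replace(seed=seed), p_bind_override=p_bind_override)
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(cfg.replace(seed=seed)), indent=2, default=list)
    )
    (out / "derived.json").write_text(
        json.dumps(dataclasses.asdict(derived), indent=2)
    )

    t0 = time.time()
    counters = []
    for i in range(n_rep):
        rep_cfg = cfg.replace(seed=seed + i)
        result = run_simulation(
            rep_cfg, derived=derived,  # derived quantities do not depend on the seed
            init_mode=scenario.init_mode, snapshot_interval=snapshot_interval,
        )
        result.to_dataframe().to_csv(out / f"observables_rep{i}.csv", index=False)
        counters.append(result.state.counters.as_dict())

    from . import __version__

    manifest = {
        "scenario": scenario.name,
        "description": scenario.description,
        "seed": seed,
        "replicates": n_rep,
        "init_mode": scenario.init_mode,
        "overrides": overrides,
        "package_version": __version__,
        "python": platform.python_version(),
        "runtime_s": time.time() - t0,
        "counters": counters,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
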