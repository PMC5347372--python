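"""High-level run driver: burn-in, production, observable recording."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import DerivedParameters, SimulationConfig, derive_parameters
from .engine import SimulationState, advance, initialize_state
from .observables import ObservableSeries, record_frame

__all__ = ["SimulationResult", "run_simulation"]


@dataclass
class SimulationResult:
    """Everything a single run produced."""

    config: SimulationConfig
    derived: DerivedParameters
    series: ObservableSeries
    state: SimulationState
    snapshots: list = field(default_factory=list)       # ligand position arrays
    snapshot_times: list = field(default_factory=list)

    def to_dataframe(self):
        return self.series.to_dataframe()


def run_simulation(
    config: SimulationConfig,
    *,
    derived: Optional[DerivedParameters] = None,
    init_mode: str = "equilibrium",
    p_bind_override: Optional[float] = None,
    snapshot_interval: Optional[float] = None,
    check_invariants: bool = False,
) -> SimulationResult:
    """Run burn-in then production, recording observables every
    ``config.record_interval`` (and, optionally, ligand snapshots every
    ``snapshot_interval``) during production.

    The first recorded frame is at the start of production (t = burn_in).
    Setting ``check_invariants`` validates the structural invariants
    (receptor radius/count, ligand exclusion) at every recorded frame.
    """
    if derived is None:
        derived = derive_parameters(config, p_bind_override=p_bind_override)
    state = initialize_state(config, derived, mode=init_mode)

    chunk = config.record_interval / config.dt
    if abs(chunk - round(chunk)) > 1e-6 * max(chunk, 1.0) or round(chunk) < 1:
        raise ValueError("record_interval must be a positive multiple of dt")
    chunk = int(round(chunk))

    if config.burn_in > 0:
        n_burn = int(round(config.burn_in / config.dt))
        advance(state, n_burn)

    series = ObservableSeries()
    result = SimulationResult(
        config=config, derived=derived, series=series, state=state
    )

    def maybe_snapshot():
        if snapshot_interval is None:
            return
        k = max(1, int(round(snapshot_interval / config.record_interval)))
        frame_idx = len(series.times) - 1
        if frame_idx % k == 0:
            result.snapshots.append(state.ligands.copy())
            result.snapshot_times.append(state.time)

    record_frame(state, series)
    maybe_snapshot()
    n_chunks = int(round(config.duration / config.record_interval))
    for _ in range(n_chunks):
        advance(state, chunk)
        record_frame(state, series)
        maybe_snapshot()
        if check_invariants:
            state.check_invariants()
    return result
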