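"""Estimate the gradient direction from the bound-receptor distribution.

Runs a reduced cell in a steep gradient, takes the centre of mass of the
active receptors as the cell's directional estimate g_est, and reports the
angular deviation from the true gradient axis (+x) with and without
time-averaging, plus the confidence measure against its uniform baseline.
Takes a couple of minutes.
"""

import math

import numpy as np

from gradsense import (
    SimulationConfig, angular_deviation, run_simulation, threshold_probability,
    time_average,
)
from gradsense.calibration import calibrate

cfg = SimulationConfig(
    box_lengths=(4.0, 4.0, 4.0), cell_radius=1.0, n_receptors=200,
    d_ligand=5.0, d_receptor=0.0025, dt=1e-3, dtau=1e-2,
    r_bind=0.05, r_unbind=0.05, k_on=5.0e7, k_off=0.5,
    concentration=10.0, gradient=2.0, boundary_method="method1",
    sphere_reflection="specular", seed=3, burn_in=10.0, duration=120.0,
    record_interval=0.05,
)
cal = calibrate(k_on=cfg.k_on, dt=cfg.dt, r_bind=cfg.r_bind,
                r_unbind=cfg.r_unbind, d_ligand=cfg.d_ligand,
                d_receptor=cfg.d_receptor)
res = run_simulation(cfg, p_bind_override=cal.p_bind)
df = res.to_dataframe()
com = df[["com_x", "com_y", "com_z"]].to_numpy(dtype=float)

inst = angular_deviation(com)
avg = angular_deviation(time_average(com, 10.0, cfg.record_interval))
print(f"instantaneous deviation: mean {np.nanmean(inst):5.1f} deg")
print(f"10 s time-averaged:      mean {np.nanmean(avg):5.1f} deg")
tp = threshold_probability([com], (90.0, 60.0, 30.0), [0.05, 10.0],
                           cfg.record_interval)
for _, row in tp.iterrows():
    print(f"T = {row['T']:5.2f} s: P(deviation < {row['threshold_deg']:.0f} deg)"
          f" = {row['prob']:.2f}")

n_frac = df["n_bound"].mean() / cfg.n_receptors
baseline = math.sqrt(8.0 / (3.0 * math.pi)) * math.sqrt(
    df["n_bound"].mean()) / cfg.n_receptors
print(f"\nconfidence: measured {df['confidence'].mean():.3e}, uniform "
      f"baseline {baseline:.3e}")
print("Averaging the estimate vector tightens its direction; a confidence")
print("above the uniform baseline means the bound receptors are polarized")
print("toward the gradient rather than pure shot noise.")
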