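"""Watch a gradient form from a one-sided source (method 2).

Molecules are injected only at the x = +L/2 face; the far face reflects
with probability p_ref and absorbs otherwise.  Starting from an empty box,
the profile fills in and converges to a linear gradient with the target
slope and far-face concentration.  Runs in about a minute.
"""

import numpy as np

from gradsense import (
    SimulationConfig, concentration_profile, derive_parameters, run_simulation,
)

cfg = SimulationConfig(
    box_lengths=(4.0, 4.0, 4.0), cell_radius=0.0, n_receptors=0,
    d_ligand=5.0, dt=1e-3, dtau=1e-3, k_on=0.0, k_off=0.0,
    concentration=5.0, gradient=1.0, boundary_method="method2",
    seed=1, burn_in=0.0, duration=60.0, record_interval=0.2,
)
d = derive_parameters(cfg, p_bind_override=0.0)
print(f"source face: {d.c_high} nM (mean injection {d.n_inj_high:.2f}/step); "
      f"absorbing face target {d.c_low} nM, p_ref = {d.p_ref:.4f}")

res = run_simulation(cfg, init_mode="empty_receptors", snapshot_interval=0.2)
edges = np.linspace(-2, 2, 9)
for t_lo, t_hi in ((0, 5), (5, 15), (40, 60)):
    snaps = [s for s, t in zip(res.snapshots, res.snapshot_times)
             if t_lo <= t < t_hi]
    prof = concentration_profile(snaps, edges, np.array([0.0, 2.0]))
    c = prof.concentration[:, 0]
    slope = np.polyfit(prof.x_centers, c, 1)[0]
    print(f"t = {t_lo:2d}-{t_hi:2d} s: c(-2 um) ~ {c[0]:5.2f} nM, "
          f"slope {slope:5.2f} nM/um")
print("\nEarly on the box is still filling from the source side; at steady")
print("state the slope matches the 1 nM/um design and the absorbing face")
print("sits at its 3 nM target.")
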