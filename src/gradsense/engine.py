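"""Particle engine: state containers and the two-timescale stepping loop.

Every fine step dt executes, in order:

  I    binding        - each free receptor may capture one nearby ligand
  II   unbinding      - each bound receptor may release its ligand
       (or endocytosis, in the receptor-cycling variant)
  IIB  Bar1 catalysis - each free ligand may be degraded (if enabled)
  III  ligand diffusion (Gaussian step; walls and cell surface reflect)

and after every dtau/dt fine steps:

  IV   receptor diffusion (3D Gaussian step projected back to the sphere)
  V    ejection at the x faces
  VI   injection at the x faces

Ligands are free point particles in the box; receptors live on the cell
sphere (|r| = R) and carry a bound/unbound flag.  The receptor count is
constant under every variant, including cycling.  All randomness flows
through named, seeded substreams so that runs are exactly reproducible and
individual process stages can be tested in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .boundaries import BoundarySpec
from .config import DerivedParameters, SimulationConfig, derive_parameters
from .units import molecules_from_concentration

__all__ = [
    "Counters",
    "SimulationState",
    "initialize_state",
    "diffuse_ligands",
    "reflect_sphere",
    "binding_step",
    "unbinding_step",
    "endocytosis_step",
    "bar1_field",
    "bar1_degradation_step",
    "diffuse_receptors",
    "inject",
    "eject",
    "eject_m1",
    "eject_m2",
    "sample_sphere_surface",
    "advance",
]

_RNG_STAGES = ("init", "binding", "unbinding", "ligand", "receptor", "boundary", "bar1")


@dataclass
class Counters:
    """Cumulative event counts; all non-decreasing."""

    bindings: int = 0
    unbindings: int = 0
    endocytoses: int = 0
    degradations: int = 0
    injections: int = 0
    ejections: int = 0

    def copy(self) -> "Counters":
        return replace(self)

    def as_dict(self) -> dict:
        return {
            "bindings": self.bindings,
            "unbindings": self.unbindings,
            "endocytoses": self.endocytoses,
            "degradations": self.degradations,
            "injections": self.injections,
            "ejections": self.ejections,
        }


def _spawn_rngs(seed: int) -> dict:
    seqs = np.random.SeedSequence(seed).spawn(len(_RNG_STAGES))
    return {name: np.random.Generator(np.random.PCG64(s))
            for name, s in zip(_RNG_STAGES, seqs)}


def sample_sphere_surface(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """n points uniform on a sphere of given radius (Gaussian projection)."""
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1)
    bad = norms == 0.0
    while np.any(bad):
        v[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1)
        bad = norms == 0.0
    return radius * v / norms[:, None]


@dataclass
class SimulationState:
    """Positions, receptor states, RNG streams and event counters."""

    config: SimulationConfig
    derived: DerivedParameters
    boundary: BoundarySpec
    ligands: np.ndarray          # (n_lig, 3) um
    receptors: np.ndarray        # (N, 3) um, |r| = R
    bound: np.ndarray            # (N,) bool
    rngs: dict
    time: float = 0.0
    step_index: int = 0
    counters: Counters = field(default_factory=Counters)
    initial_free_ligands: int = 0

    @property
    def n_ligands(self) -> int:
        return int(self.ligands.shape[0])

    @property
    def n_bound(self) -> int:
        return int(self.bound.sum())

    def bound_positions(self) -> np.ndarray:
        return self.receptors[self.bound]

    def check_invariants(self, atol: float = 1e-9) -> None:
        """Raise AssertionError if a structural invariant is violated."""
        cfg = self.config
        hx, hy, hz = cfg.half_box
        if self.n_ligands:
            p = self.ligands
            assert np.all(np.abs(p[:, 1]) <= hy + atol), "ligand outside y walls"
            assert np.all(np.abs(p[:, 2]) <= hz + atol), "ligand outside z walls"
            if cfg.cell_radius > 0 and not cfg.membrane_permeable:
                rr = np.einsum("ij,ij->i", p, p)
                assert np.all(rr >= (cfg.cell_radius - atol) ** 2), "ligand inside cell"
        if cfg.n_receptors:
            radii = np.linalg.norm(self.receptors, axis=1)
            assert np.allclose(radii, cfg.cell_radius, rtol=1e-9), "receptor off sphere"
            assert self.receptors.shape[0] == cfg.n_receptors, "receptor count changed"


def initialize_state(
    config: SimulationConfig,
    derived: Optional[DerivedParameters] = None,
    mode: str = "equilibrium",
    p_bind_override: Optional[float] = None,
) -> SimulationState:
    """Build the initial state.

    mode="equilibrium": receptors uniformly on the sphere with the mean-field
    expected number already bound; ligands placed by rejection sampling from
    the linear-gradient density over the box minus the cell.

    mode="empty_receptors": all receptors free; for method2 the box also
    starts empty of ligand (the gradient then forms from the source face).
    """
    if mode not in ("equilibrium", "empty_receptors"):
        raise ValueError(f"unknown initialization mode {mode!r}")
    if derived is None:
        derived = derive_parameters(config, p_bind_override=p_bind_override)
    rngs = _spawn_rngs(config.seed)
    rng = rngs["init"]
    R = config.cell_radius

    receptors = sample_sphere_surface(config.n_receptors, R, rng) if config.n_receptors \
        else np.empty((0, 3))
    bound = np.zeros(config.n_receptors, dtype=bool)
    if mode == "equilibrium" and config.n_receptors and np.isfinite(derived.K_D):
        c0 = config.concentration
        n0 = int(round(config.n_receptors * c0 / (derived.K_D + c0)))
        bound[rng.choice(config.n_receptors, size=n0, replace=False)] = True

    if mode == "empty_receptors" and config.boundary_method == "method2":
        ligands = np.empty((0, 3))
    else:
        ligands = _sample_gradient_ligands(config, rng)

    state = SimulationState(
        config=config,
        derived=derived,
        boundary=BoundarySpec.from_config(config, derived),
        ligands=ligands,
        receptors=receptors,
        bound=bound,
        rngs=rngs,
        initial_free_ligands=int(ligands.shape[0]),
    )
    return state


def _sample_gradient_ligands(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample ligand positions with density prop. to c0 + g*x over
    the box minus the cell sphere."""
    c0, g = config.concentration, config.gradient
    vol = config.box_volume
    if config.cell_radius > 0:
        vol -= 4.0 / 3.0 * math.pi * config.cell_radius ** 3
    n_total = int(round(molecules_from_concentration(c0, vol))) if c0 > 0 else 0
    if n_total == 0:
        return np.empty((0, 3))
    hx, hy, hz = config.half_box
    c_max = max(config.c_high, config.c_low)
    out = np.empty((n_total, 3))
    filled = 0
    while filled < n_total:
        m = 2 * (n_total - filled) + 16
        pts = rng.uniform(-1.0, 1.0, (m, 3)) * np.array([hx, hy, hz])
        keep = rng.random(m) * c_max <= c0 + g * pts[:, 0]
        if config.cell_radius > 0:
            keep &= np.einsum("ij,ij->i", pts, pts) >= config.cell_radius ** 2
        pts = pts[keep]
        take = min(pts.shape[0], n_total - filled)
        out[filled:filled + take] = pts[:take]
        filled += take
    return out


# ---------------------------------------------------------------- diffusion

def _fold(x: np.ndarray, half: float) -> np.ndarray:
    """Mirror-fold coordinates into [-half, half] (exact multi-reflection)."""
    period = 4.0 * half
    y = np.mod(x + half, period)
    y = np.where(y > 2.0 * half, period - y, y)
    return y - half


def reflect_sphere(
    origin: np.ndarray, proposed: np.ndarray, radius: float, mode: str = "radial"
) -> np.ndarray:
    """Reflect proposed ligand positions that fall inside the cell sphere.

    "radial": mirror the radius about the surface, |r| -> 2R - |r|, keeping
    the direction.  For step sizes much smaller than R this agrees with the
    exact specular construction to O(step^2 / R).

    "specular": intersect the segment origin->proposed with the sphere and
    mirror the remainder of the step about the tangent plane (iterated up to
    8 times for grazing re-entries).
    """
    proposed = np.array(proposed, dtype=float, copy=True)
    rr = np.einsum("ij,ij->i", proposed, proposed)
    inside = rr < radius * radius
    if not np.any(inside):
        return proposed
    if mode == "radial":
        r = np.sqrt(rr[inside])
        degenerate = r < 1e-12
        if np.any(degenerate):
            # re-mirror through the origin using the incoming direction
            idx = np.flatnonzero(inside)[degenerate]
            o = origin[idx]
            on = np.linalg.norm(o, axis=1, keepdims=True)
            proposed[idx] = o / on * (2.0 * radius)
            rr = np.einsum("ij,ij->i", proposed, proposed)
            inside = rr < radius * radius
            if not np.any(inside):
                return proposed
            r = np.sqrt(rr[inside])
        scale = (2.0 * radius - r) / r
        proposed[inside] *= scale[:, None]
        return proposed
    # specular
    idx = np.flatnonzero(inside)
    proposed[idx] = _specular_reflect_batch(origin[idx], proposed[idx], radius)
    return proposed


def _specular_reflect_batch(o: np.ndarray, p: np.ndarray, R: float) -> np.ndarray:
    """Vectorized segment-intersection mirror for points that crossed into
    the sphere; grazing re-entries are iterated, with a radial-mirror
    fallback for pathological geometry."""
    o = o.copy()
    p = p.copy()
    active = np.arange(p.shape[0])
    for _ in range(8):
        d = p[active] - o[active]
        a = np.einsum("ij,ij->i", d, d)
        b = 2.0 * np.einsum("ij,ij->i", o[active], d)
        c = np.einsum("ij,ij->i", o[active], o[active]) - R * R
        disc = b * b - 4.0 * a * c
        ok = (a > 0) & (disc >= 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (-b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * a)
        ok &= (t >= 0.0) & (t <= 1.0)
        if not np.any(ok):
            break
        sub = active[ok]
        tt = t[ok][:, None]
        hit = o[sub] + tt * (p[sub] - o[sub])
        n = hit / np.linalg.norm(hit, axis=1, keepdims=True)
        rest = p[sub] - hit
        p[sub] = hit + rest - 2.0 * np.einsum("ij,ij->i", rest, n)[:, None] * n
        o[sub] = hit
        still = np.einsum("ij,ij->i", p[active], p[active]) < R * R
        active = active[still]
        if active.size == 0:
            break
    if active.size:
        rr = np.linalg.norm(p[active], axis=1)
        safe = rr > 1e-12
        scale = np.where(safe, (2.0 * R - rr) / np.where(safe, rr, 1.0), 0.0)
        p[active] = np.where(
            safe[:, None], p[active] * scale[:, None],
            o[active] / np.linalg.norm(o[active], axis=1, keepdims=True) * 2.0 * R,
        )
    return p


def diffuse_ligands(
    state: SimulationState,
    d_ligand: Optional[float] = None,
    dt: Optional[float] = None,
) -> SimulationState:
    """Advance every ligand by one Gaussian step and apply the reflecting
    boundaries (y/z walls, the cell sphere, and the x walls only in the
    closed-box mode; x excursions are otherwise handled at ejection)."""
    cfg = state.config
    n = state.n_ligands
    if n == 0:
        return state
    D = cfg.d_ligand if d_ligand is None else d_ligand
    step_dt = cfg.dt if dt is None else dt
    if D == 0.0 or step_dt == 0.0:
        return state
    sd = math.sqrt(2.0 * D * step_dt)
    rng = state.rngs["ligand"]
    old = state.ligands
    pos = old + rng.standard_normal((n, 3)) * sd

    hx, hy, hz = cfg.half_box
    reflect_x = cfg.boundary_method == "closed"
    R = cfg.cell_radius
    impermeable = R > 0 and not cfg.membrane_permeable
    # wall folding is an exact multi-reflection, so one pass suffices;
    # the sphere mirror afterwards can only re-violate a wall if the step
    # reaches from the sphere to a wall, which the loop below catches.
    for _ in range(10):
        m = np.abs(pos[:, 1]) > hy
        if m.any():
            pos[m, 1] = _fold(pos[m, 1], hy)
        m = np.abs(pos[:, 2]) > hz
        if m.any():
            pos[m, 2] = _fold(pos[m, 2], hz)
        if reflect_x:
            m = np.abs(pos[:, 0]) > hx
            if m.any():
                pos[m, 0] = _fold(pos[m, 0], hx)
        if impermeable:
            rr = np.einsum("ij,ij->i", pos, pos)
            if np.any(rr < R * R):
                pos = reflect_sphere(old, pos, R, cfg.sphere_reflection)
            else:
                break
            bad = (np.abs(pos[:, 1]) > hy) | (np.abs(pos[:, 2]) > hz)
            if reflect_x:
                bad |= np.abs(pos[:, 0]) > hx
            if not np.any(bad):
                break
        else:
            break
    else:
        # pathological multi-boundary case: retract the offending steps
        bad = (np.abs(pos[:, 1]) > hy) | (np.abs(pos[:, 2]) > hz)
        if impermeable:
            bad |= np.einsum("ij,ij->i", pos, pos) < R * R
        pos[bad] = old[bad]
    state.ligands = pos
    return state


# ---------------------------------------------------------------- reactions

def binding_step(
    state: SimulationState,
    p_bind: Optional[float] = None,
    r_bind: Optional[float] = None,
) -> SimulationState:
    """Process I: each free receptor with at least one live ligand within
    r_bind makes one Bernoulli(p_bind) attempt on its nearest such ligand.

    Receptors are visited in a fresh random permutation and a ligand can be
    consumed at most once per step; at physiological densities multi-
    candidate collisions are vanishingly rare, so the nearest-ligand rule is
    effectively the textbook pairwise scheme while staying reproducible.
    """
    cfg = state.config
    p = state.derived.p_bind if p_bind is None else p_bind
    rb = cfg.r_bind if r_bind is None else r_bind
    if p == 0.0 or state.n_ligands == 0 or cfg.n_receptors == 0:
        return state
    R = cfg.cell_radius
    lig = state.ligands
    rr = np.einsum("ij,ij->i", lig, lig)
    lo, hi = (R - rb), (R + rb)
    shell = (rr >= lo * lo) & (rr <= hi * hi)
    if not np.any(shell):
        return state
    lig_idx = np.flatnonzero(shell)
    d = cdist(state.receptors, lig[lig_idx])
    rec_has, cand_cols = np.nonzero(d <= rb)
    if rec_has.size == 0:
        return state
    rng = state.rngs["binding"]
    # group candidates per receptor
    order = np.argsort(rec_has, kind="stable")
    rec_has, cand_cols = rec_has[order], cand_cols[order]
    uniq, starts = np.unique(rec_has, return_index=True)
    perm = rng.permutation(len(uniq))
    consumed: set[int] = set()
    newly_bound = []
    for k in perm:
        r = uniq[k]
        if state.bound[r]:
            continue
        s = starts[k]
        e = starts[k + 1] if k + 1 < len(uniq) else len(rec_has)
        cols = cand_cols[s:e]
        cols = cols[np.argsort(d[r, cols])]
        target = next((c for c in cols if lig_idx[c] not in consumed), None)
        if target is None:
            continue
        if rng.random() < p:
            consumed.add(int(lig_idx[target]))
            state.bound[r] = True
            newly_bound.append(r)
    if consumed:
        keep = np.ones(state.n_ligands, dtype=bool)
        keep[list(consumed)] = False
        state.ligands = state.ligands[keep]
        state.counters.bindings += len(consumed)
    return state


def unbinding_step(
    state: SimulationState,
    p_unbind: Optional[float] = None,
    r_unbind: Optional[float] = None,
) -> SimulationState:
    """Process II: each bound receptor releases its ligand with probability
    p_unbind; the released molecule is placed at distance r_unbind in a
    uniformly random direction, resampled until it lies outside the cell."""
    cfg = state.config
    p = state.derived.p_unbind if p_unbind is None else p_unbind
    ru = cfg.r_unbind if r_unbind is None else r_unbind
    if p == 0.0:
        return state
    bound_idx = np.flatnonzero(state.bound)
    if bound_idx.size == 0:
        return state
    rng = state.rngs["unbinding"]
    release = bound_idx[rng.random(bound_idx.size) < p]
    if release.size == 0:
        return state
    R = cfg.cell_radius
    check_inside = R > 0 and not cfg.membrane_permeable
    new_pos = np.empty((release.size, 3))
    for i, r in enumerate(release):
        base = state.receptors[r]
        while True:
            direction = rng.standard_normal(3)
            nrm = np.linalg.norm(direction)
            if nrm == 0.0:
                continue
            pos = base + direction / nrm * ru
            if not check_inside or pos @ pos >= R * R:
                new_pos[i] = pos
                break
    state.bound[release] = False
    state.ligands = np.concatenate([state.ligands, new_pos]) \
        if state.n_ligands else new_pos
    state.counters.unbindings += int(release.size)
    return state


def endocytosis_step(state: SimulationState, p_endo: Optional[float] = None) -> SimulationState:
    """Receptor-cycling variant of process II: a bound receptor is removed
    together with its ligand (which never returns to solution) and replaced
    by a free receptor at a uniformly random surface point, keeping the
    receptor count constant."""
    p = state.derived.p_endo if p_endo is None else p_endo
    if p == 0.0:
        return state
    bound_idx = np.flatnonzero(state.bound)
    if bound_idx.size == 0:
        return state
    rng = state.rngs["unbinding"]
    endo = bound_idx[rng.random(bound_idx.size) < p]
    if endo.size == 0:
        return state
    state.receptors[endo] = sample_sphere_surface(
        endo.size, state.config.cell_radius, rng
    )
    state.bound[endo] = False
    state.counters.endocytoses += int(endo.size)
    return state


def bar1_field(r, bar1_surface_conc: float, cell_radius: float):
    """Static Bar1 protease concentration field, [Bar1]0 * R / r (nM)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < cell_radius):
        raise ValueError("Bar1 field is undefined inside the cell (r < R)")
    return bar1_surface_conc * cell_radius / r


def bar1_degradation_step(
    state: SimulationState, k_cat: Optional[float] = None, dt: Optional[float] = None
) -> SimulationState:
    """Process IIB: each free ligand at radius r is degraded with
    probability k_cat * [Bar1](r) * dt; receptor-bound ligand is immune."""
    cfg = state.config
    kc = cfg.k_cat if k_cat is None else k_cat
    step_dt = cfg.dt if dt is None else dt
    if kc == 0.0 or state.n_ligands == 0:
        return state
    p_surface = kc * (cfg.bar1_surface_conc * 1e-9) * step_dt
    if p_surface > 1.0:
        raise ValueError(
            f"Bar1 degradation probability {p_surface:.3g} > 1; reduce dt"
        )
    r = np.linalg.norm(state.ligands, axis=1)
    r = np.maximum(r, cfg.cell_radius if cfg.cell_radius > 0 else r)
    prob = p_surface * (cfg.cell_radius / r) if cfg.cell_radius > 0 \
        else np.full_like(r, p_surface)
    rng = state.rngs["bar1"]
    kill = rng.random(r.size) < prob
    if np.any(kill):
        state.ligands = state.ligands[~kill]
        state.counters.degradations += int(kill.sum())
    return state


def diffuse_receptors(
    state: SimulationState,
    d_receptor: Optional[float] = None,
    dtau: Optional[float] = None,
) -> SimulationState:
    """Process IV: 3D Gaussian step followed by radial projection back onto
    the sphere (accurate for steps much smaller than R)."""
    cfg = state.config
    if cfg.n_receptors == 0:
        return state
    D = cfg.d_receptor if d_receptor is None else d_receptor
    step = cfg.dtau if dtau is None else dtau
    if D == 0.0 or step == 0.0:
        return state
    rng = state.rngs["receptor"]
    sd = math.sqrt(2.0 * D * step)
    pos = state.receptors + rng.standard_normal(state.receptors.shape) * sd
    norms = np.linalg.norm(pos, axis=1)
    bad = norms == 0.0
    while np.any(bad):
        pos[bad] = state.receptors[bad] + rng.standard_normal((int(bad.sum()), 3)) * sd
        norms = np.linalg.norm(pos, axis=1)
        bad = norms == 0.0
    state.receptors = pos * (cfg.cell_radius / norms)[:, None]
    return state


# ---------------------------------------------------------------- boundaries

def eject(state: SimulationState) -> SimulationState:
    """Process V at both x faces.

    method1: remove everything beyond either face.
    method2: remove beyond the high (source) face; beyond the low face,
    mirror-reflect back with probability p_ref, else remove.
    closed:  nothing to do (the x walls reflect during diffusion).
    """
    spec = state.boundary
    if spec.method == "closed" or state.n_ligands == 0:
        return state
    cfg = state.config
    hx = cfg.x_max
    x = state.ligands[:, 0]
    if spec.method == "method1":
        out = np.abs(x) > hx
        if np.any(out):
            state.counters.ejections += int(out.sum())
            state.ligands = state.ligands[~out]
        return state
    # method2
    rng = state.rngs["boundary"]
    out_high = x > hx
    out_low = x < -hx
    remove = out_high.copy()
    if np.any(out_low):
        reflect = rng.random(int(out_low.sum())) < spec.p_ref
        low_idx = np.flatnonzero(out_low)
        refl_idx = low_idx[reflect]
        state.ligands[refl_idx, 0] = -2.0 * hx - state.ligands[refl_idx, 0]
        remove[low_idx[~reflect]] = True
    if np.any(remove):
        state.counters.ejections += int(remove.sum())
        state.ligands = state.ligands[~remove]
    return state


def inject(state: SimulationState, side: str, spec: Optional[BoundarySpec] = None) -> SimulationState:
    """Process VI at one x face.

    Creates K ~ Poisson(n_inj_side) molecules with y, z uniform over the
    face and x a random injection depth into the domain.  A point landing
    inside the cell sphere has its y, z resampled.
    """
    spec = state.boundary if spec is None else spec
    if spec.method == "closed":
        return state
    if side not in ("high", "low"):
        raise ValueError("side must be 'high' or 'low'")
    mean = spec.n_inj_high if side == "high" else spec.n_inj_low
    if mean == 0.0:
        return state
    cfg = state.config
    rng = state.rngs["boundary"]
    k = int(rng.poisson(mean))
    if k == 0:
        return state
    hx, hy, hz = cfg.half_box
    d = spec.sampler.sample(k, rng)
    x = hx - d if side == "high" else -hx + d
    pts = np.empty((k, 3))
    pts[:, 0] = x
    pts[:, 1] = rng.uniform(-hy, hy, k)
    pts[:, 2] = rng.uniform(-hz, hz, k)
    if cfg.cell_radius > 0 and not cfg.membrane_permeable:
        for _ in range(100):
            rr = np.einsum("ij,ij->i", pts, pts)
            bad = rr < cfg.cell_radius ** 2
            if not np.any(bad):
                break
            nb = int(bad.sum())
            pts[bad, 1] = rng.uniform(-hy, hy, nb)
            pts[bad, 2] = rng.uniform(-hz, hz, nb)
    state.ligands = np.concatenate([state.ligands, pts]) if state.n_ligands else pts
    state.counters.injections += k
    return state


def eject_m1(state: SimulationState) -> SimulationState:
    """Fixed-concentration ejection: remove every ligand beyond either x
    face (requires boundary method1)."""
    if state.boundary.method != "method1":
        raise ValueError("eject_m1 requires boundary method1")
    return eject(state)


def eject_m2(state: SimulationState) -> SimulationState:
    """Partially absorbing ejection: clamp at the high face, reflect with
    probability p_ref at the low face (requires boundary method2)."""
    if state.boundary.method != "method2":
        raise ValueError("eject_m2 requires boundary method2")
    return eject(state)


# ---------------------------------------------------------------- main loop

def advance(state: SimulationState, n_fine_steps: int) -> SimulationState:
    """Run the six-process algorithm for ``n_fine_steps`` fine steps.

    The coarse block (IV receptor diffusion, V ejection, VI injection) runs
    after every dtau/dt fine steps, counted from the start of the run.
    """
    if n_fine_steps < 1:
        raise ValueError("n_fine_steps must be >= 1")
    cfg = state.config
    spc = cfg.steps_per_coarse
    cycling = cfg.receptor_cycling
    use_bar1 = cfg.bar1
    for _ in range(n_fine_steps):
        binding_step(state)
        if cycling:
            endocytosis_step(state)
        else:
            unbinding_step(state)
        if use_bar1:
            bar1_degradation_step(state)
        diffuse_ligands(state)
        state.step_index += 1
        if state.step_index % spc == 0:
            diffuse_receptors(state)
            eject(state)
            inject(state, "high")
            inject(state, "low")
    state.time = state.step_index * cfg.dt
    return state
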