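"""Particle engine: stepping rules, reflections, reactions, bookkeeping."""

import math

import numpy as np
import pytest
from scipy import stats

from gradsense import (
    SimulationConfig,
    bar1_field,
    initialize_state,
    reflect_sphere,
    run_simulation,
    theory_mean_occupancy,
    theory_std_occupancy,
)
from gradsense.engine import (
    _fold,
    advance,
    bar1_degradation_step,
    binding_step,
    diffuse_ligands,
    diffuse_receptors,
    endocytosis_step,
    sample_sphere_surface,
    unbinding_step,
)


def _bare_state(n_receptors=0, cell_radius=0.0, box=40.0, seed=0, **kw):
    """Minimal state for exercising individual process stages."""
    cfg = SimulationConfig(
        box_lengths=(box, box, box), cell_radius=cell_radius,
        n_receptors=n_receptors, concentration=0.0, gradient=0.0,
        k_on=0.0, k_off=0.0, boundary_method="closed",
        dt=1e-3, dtau=1e-2, d_ligand=5.0, seed=seed, **kw,
    )
    return initialize_state(cfg, mode="empty_receptors", p_bind_override=0.0)


class TestInitialization:
    def test_equilibrium_mode_binds_expected_fraction(self):
        # c equal to the (unrounded) K_D of the configured rates -> N/2 bound
        cfg = SimulationConfig(concentration=6.875, n_receptors=10000)
        state = initialize_state(cfg, mode="equilibrium", p_bind_override=0.002)
        assert state.n_bound == 5000

    def test_receptor_x_coordinates_uniform(self):
        """The area element of a sphere is uniform in x, so receptor x/R
        must pass a KS test against U(-1, 1)."""
        cfg = SimulationConfig(n_receptors=10000, concentration=0.0,
                               gradient=0.0)
        state = initialize_state(cfg, mode="empty_receptors",
                                 p_bind_override=0.0)
        x = state.receptors[:, 0] / cfg.cell_radius
        p = stats.kstest(x, stats.uniform(loc=-1, scale=2).cdf).pvalue
        assert p > 0.01

    def test_ligands_follow_linear_gradient_density(self):
        cfg = SimulationConfig(
            box_lengths=(4.0, 4.0, 4.0), cell_radius=0.0, n_receptors=0,
            concentration=5.0, gradient=1.0, k_on=0.0, k_off=0.0,
            dt=1e-3, dtau=1e-3, seed=5,
        )
        state = initialize_state(cfg, p_bind_override=0.0)
        x = state.ligands[:, 0]

        def cdf(v):
            # density prop. to (5 + x) on [-2, 2]
            return (5.0 * (v + 2.0) + (v**2 - 4.0) / 2.0) / 20.0

        assert stats.kstest(x, cdf).pvalue > 0.01

    def test_method2_formation_starts_empty(self):
        cfg = SimulationConfig(
            boundary_method="method2", concentration=6.9, gradient=0.1,
        )
        state = initialize_state(cfg, mode="empty_receptors",
                                 p_bind_override=0.0)
        assert state.n_ligands == 0
        assert state.n_bound == 0


class TestLigandDiffusion:
    def test_zero_diffusivity_is_identity(self):
        state = _bare_state()
        state.ligands = np.zeros((100, 3))
        before = state.ligands.copy()
        diffuse_ligands(state, d_ligand=0.0)
        assert np.array_equal(state.ligands, before)

    def test_free_space_msd(self):
        """Mean squared displacement after k steps is 6 D k dt (box made
        large enough that no boundary is touched)."""
        state = _bare_state(box=1000.0)
        state.ligands = np.zeros((100_000, 3))
        for _ in range(5):
            diffuse_ligands(state)
        msd = np.mean(np.einsum("ij,ij->i", state.ligands, state.ligands))
        assert msd == pytest.approx(6.0 * 5.0 * 5 * 1e-3, rel=0.01)

    def test_wall_mirror_rule(self):
        assert _fold(np.array([5.2]), 5.0)[0] == pytest.approx(4.8)
        assert _fold(np.array([-5.3]), 5.0)[0] == pytest.approx(-4.7)
        # multiple crossings stay inside
        assert abs(_fold(np.array([23.7]), 5.0)[0]) <= 5.0


class TestSphereReflection:
    def test_outside_point_unchanged(self):
        origin = np.array([[3.0, 0.0, 0.0]])
        proposed = np.array([[2.9, 0.1, 0.0]])
        out = reflect_sphere(origin, proposed, 2.5)
        assert np.allclose(out, proposed)

    def test_radial_mirror(self):
        origin = np.array([[2.6, 0.0, 0.0]])
        proposed = np.array([[2.4, 0.0, 0.0]])
        out = reflect_sphere(origin, proposed, 2.5)
        assert np.allclose(out, [[2.6, 0.0, 0.0]])

    def test_specular_head_on(self):
        origin = np.array([[0.0, 0.0, 2.6]])
        proposed = np.array([[0.0, 0.0, 2.3]])
        # the segment hits the surface at 2.5 with 0.2 of travel left,
        # which is reflected back outward to 2.7
        out = reflect_sphere(origin, proposed, 2.5, mode="specular")
        assert np.allclose(out, [[0.0, 0.0, 2.7]])
        assert np.linalg.norm(out) >= 2.5

    @pytest.mark.parametrize("mode", ["radial", "specular"])
    def test_result_never_inside(self, mode):
        rng = np.random.default_rng(9)
        origin = sample_sphere_surface(500, 1.0, rng) * 1.02
        proposed = origin + rng.standard_normal((500, 3)) * 0.05
        out = reflect_sphere(origin, proposed, 1.0, mode=mode)
        assert np.all(np.linalg.norm(out, axis=1) >= 1.0 - 1e-12)

    def test_no_flux_preserves_uniform_density(self):
        """A reflecting sphere in a closed box must leave a uniform ligand
        density uniform: chi-square test on radial shells."""
        cfg = SimulationConfig(
            box_lengths=(4.0, 4.0, 4.0), cell_radius=1.0, n_receptors=0,
            concentration=83.0, gradient=0.0, k_on=0.0, k_off=0.0,
            d_ligand=0.5, dt=1e-3, dtau=1e-2, boundary_method="closed",
            sphere_reflection="specular", seed=11, burn_in=0.0,
            duration=3.0, record_interval=0.1,
        )
        res = run_simulation(cfg, p_bind_override=0.0, snapshot_interval=0.1)
        radii = np.concatenate(
            [np.linalg.norm(s, axis=1) for s in res.snapshots]
        )
        edges = np.linspace(1.0, 2.0, 6)
        counts, _ = np.histogram(radii, edges)
        vols = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        expected = counts.sum() * vols / vols.sum()
        chi2 = float(np.sum((counts - expected) ** 2 / expected))
        p = 1.0 - stats.chi2.cdf(chi2, df=len(counts) - 1)
        assert p > 0.01


class TestReactions:
    def test_binding_certain_hit(self):
        state = _bare_state(n_receptors=1, cell_radius=2.5, box=10.0)
        state.receptors[0] = [2.5, 0.0, 0.0]
        state.ligands = np.array([[2.53, 0.0, 0.0]])
        binding_step(state, p_bind=1.0, r_bind=0.05)
        assert state.n_bound == 1
        assert state.n_ligands == 0
        assert state.counters.bindings == 1

    def test_binding_zero_probability_is_noop(self):
        state = _bare_state(n_receptors=1, cell_radius=2.5, box=10.0)
        state.receptors[0] = [2.5, 0.0, 0.0]
        state.ligands = np.array([[2.53, 0.0, 0.0]])
        binding_step(state, p_bind=0.0, r_bind=0.05)
        assert state.n_bound == 0 and state.n_ligands == 1

    def test_ligand_consumed_at_most_once(self):
        state = _bare_state(n_receptors=2, cell_radius=2.5, box=10.0)
        state.receptors[0] = [2.5, 0.0, 0.0]
        state.receptors[1] = [2.5, 0.02, 0.0]
        state.ligands = np.array([[2.51, 0.01, 0.0]])
        binding_step(state, p_bind=1.0, r_bind=0.05)
        assert state.n_bound == 1
        assert state.n_ligands == 0

    def test_unbinding_survival_law(self):
        """With binding disabled, the bound fraction decays as
        exp(-k_off t)."""
        k_off, dt = 1.0, 1e-3
        p_unbind = 1.0 - math.exp(-k_off * dt)
        state = _bare_state(n_receptors=10_000, cell_radius=2.5, box=10.0)
        state.bound[:] = True
        checkpoints = {1000: None, 2000: None, 3000: None}
        for step in range(1, 3001):
            unbinding_step(state, p_unbind=p_unbind, r_unbind=0.004)
            if step in checkpoints:
                checkpoints[step] = state.n_bound
        for step, n in checkpoints.items():
            t = step * dt
            expect = 10_000 * math.exp(-k_off * t)
            se = math.sqrt(10_000 * math.exp(-k_off * t)
                           * (1 - math.exp(-k_off * t)))
            assert abs(n - expect) < 4.0 * se

    def test_released_ligand_outside_cell(self):
        state = _bare_state(n_receptors=5000, cell_radius=2.5, box=10.0)
        state.bound[:] = True
        unbinding_step(state, p_unbind=0.5, r_unbind=0.004)
        assert state.n_ligands > 0
        assert np.all(np.linalg.norm(state.ligands, axis=1) >= 2.5)

    def test_endocytosis_conserves_receptors_and_consumes_ligand(self):
        state = _bare_state(n_receptors=1000, cell_radius=2.5, box=10.0)
        state.bound[:] = True
        for _ in range(50):
            endocytosis_step(state, p_endo=0.05)
        assert state.receptors.shape[0] == 1000
        assert np.allclose(np.linalg.norm(state.receptors, axis=1), 2.5)
        # endocytosed ligand is removed from the world, not released
        assert state.n_ligands == 0
        assert state.counters.endocytoses == 1000 - state.n_bound


class TestBar1:
    def test_field_examples(self):
        assert bar1_field(2.5, 0.85, 2.5) == pytest.approx(0.85)
        assert bar1_field(5.0, 0.85, 2.5) == pytest.approx(0.425)
        assert bar1_field(1e9, 0.85, 2.5) < 1e-8

    def test_field_undefined_inside_cell(self):
        with pytest.raises(ValueError):
            bar1_field(2.0, 0.85, 2.5)

    def test_degradation_probability_scale(self):
        """At the surface the one-step removal probability is
        k_cat [Bar1]0 dt; at radius r it is reduced by R/r."""
        state = _bare_state(n_receptors=0, cell_radius=1.0, box=10.0)
        state.config = state.config.replace(
            bar1=True, bar1_surface_conc=0.85, k_cat=2.5e8, cell_radius=1.0
        )
        n = 40_000
        pts = sample_sphere_surface(n, 2.0, np.random.default_rng(3))
        state.ligands = pts
        bar1_degradation_step(state, k_cat=2.5e8, dt=1.0)
        p_expect = 2.5e8 * 0.85e-9 * 1.0 * (1.0 / 2.0)
        removed = n - state.n_ligands
        se = math.sqrt(n * p_expect * (1 - p_expect))
        assert abs(removed - n * p_expect) < 4.0 * se

    def test_per_step_probability_matches_reference_scale(self):
        # k_cat = 2.5e8 (M s)^-1, 0.85 nM at the surface, 1 us step
        assert 2.5e8 * 0.85e-9 * 1e-6 == pytest.approx(2.125e-7)

    def test_too_coarse_time_step_rejected(self):
        state = _bare_state(n_receptors=0, cell_radius=1.0, box=10.0)
        state.ligands = np.array([[1.5, 0.0, 0.0]])
        with pytest.raises(ValueError, match="reduce dt"):
            bar1_degradation_step(state, k_cat=2.5e8, dt=1e10)


class TestReceptorDiffusion:
    def test_zero_diffusivity_is_identity(self):
        state = _bare_state(n_receptors=100, cell_radius=2.5, box=10.0)
        before = state.receptors.copy()
        diffuse_receptors(state, d_receptor=0.0)
        assert np.array_equal(state.receptors, before)

    def test_projection_returns_to_surface(self):
        state = _bare_state(n_receptors=1000, cell_radius=2.5, box=10.0)
        diffuse_receptors(state, d_receptor=0.01, dtau=1.0)
        assert np.allclose(np.linalg.norm(state.receptors, axis=1), 2.5)

    def test_surface_msd_small_angle(self):
        """Great-circle displacement obeys <theta^2> = 4 D t / R^2 for
        D t / R^2 << 1."""
        state = _bare_state(n_receptors=20_000, cell_radius=1.0, box=10.0)
        start = state.receptors.copy()
        n_steps, dtau, D = 10, 0.2, 0.0025
        for _ in range(n_steps):
            diffuse_receptors(state, d_receptor=D, dtau=dtau)
        cosang = np.clip(
            np.einsum("ij,ij->i", start, state.receptors), -1.0, 1.0
        )
        theta2 = np.mean(np.arccos(cosang) ** 2)
        assert theta2 == pytest.approx(4.0 * D * n_steps * dtau, rel=0.03)


class TestAdvance:
    def test_static_configuration(self):
        """No ligands, no injection: only receptor diffusion acts."""
        state = _bare_state(n_receptors=50, cell_radius=2.5, box=10.0,
                            d_receptor=0.0025)
        advance(state, 200)
        assert state.n_ligands == 0
        assert state.counters.bindings == 0
        assert state.time == pytest.approx(0.2)

    def test_determinism(self):
        cfg = SimulationConfig(
            box_lengths=(4.0, 4.0, 4.0), cell_radius=1.0, n_receptors=50,
            concentration=10.0, gradient=0.5, k_on=5.0e7, k_off=0.5,
            d_ligand=5.0, dt=1e-3, dtau=5e-3, r_bind=0.05, r_unbind=0.05,
            seed=77, burn_in=0.0, duration=2.0, record_interval=0.1,
        )
        a = run_simulation(cfg, p_bind_override=0.3).to_dataframe()
        b = run_simulation(cfg, p_bind_override=0.3).to_dataframe()
        assert a.equals(b)

    def test_ligand_conservation_identity(self):
        """free = initial + injections - ejections - (bindings - unbindings)
        - degradations, for a run with every process active."""
        cfg = SimulationConfig(
            box_lengths=(4.0, 4.0, 4.0), cell_radius=1.0, n_receptors=50,
            concentration=5.0, gradient=1.0, boundary_method="method2",
            bar1=True, bar1_surface_conc=0.85, k_cat=2.5e8,
            k_on=5.0e7, k_off=0.5, d_ligand=5.0, dt=1e-3, dtau=2e-3,
            r_bind=0.05, r_unbind=0.05, seed=13, burn_in=0.0, duration=5.0,
            record_interval=0.5,
        )
        res = run_simulation(cfg, p_bind_override=0.3)
        c = res.state.counters
        expected_free = (
            res.state.initial_free_ligands + c.injections - c.ejections
            - (c.bindings - c.unbindings) - c.degradations
        )
        assert res.state.n_ligands == expected_free
        res.state.check_invariants()


class TestEquilibriumMoments:
    def test_occupancy_mean_and_variance(self, equilibrium_runs):
        """Clamped uniform box at c = K_D: time-averaged occupancy matches
        the equilibrium mean within 3 SE and the variance is within 20% of
        the binomial prediction."""
        cfg = equilibrium_runs["config"]
        K_D = 0.5 / 5.0e7 * 1e9
        mean_th = theory_mean_occupancy(cfg.n_receptors, 10.0, K_D)
        var_th = theory_std_occupancy(cfg.n_receptors, 10.0, K_D) ** 2
        tau_n = 1.0  # 1/(k_on c + k_off) at these parameters
        total_t = 3 * cfg.duration
        se = math.sqrt(var_th * 2.0 * tau_n / total_t)
        means = [df["n_bound"].mean() for df in equilibrium_runs["frames"]]
        assert abs(np.mean(means) - mean_th) < 3.0 * se
        varis = [df["n_bound"].var() for df in equilibrium_runs["frames"]]
        assert np.mean(varis) == pytest.approx(var_th, rel=0.20)
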