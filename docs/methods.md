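# Methods

## Model

A single spherical cell of radius R sits at the centre of a cubic box.
Ligand molecules are point particles performing free Brownian motion
(independent per-axis Gaussian increments of s.d. √(2D_ligand Δt));
receptors are points confined to the sphere, each either free or bound.
The state of the system is the set of all molecular positions plus the
chemical state of each receptor. Each fine step Δt executes binding,
unbinding (or endocytosis), optional ligand degradation, and ligand
diffusion, in that order; every Δτ/Δt fine steps a coarse block runs
receptor diffusion, ejection and injection. All randomness flows through
named substreams of a single seeded PCG64 generator, so runs are exactly
reproducible and each process stage can be tested in isolation.

Downstream signalling, multiple cells, advective flow and non-cubic
domains are out of scope; the membrane is a perfect hard sphere (optionally
permeable, as a control).

## Binding calibration

Association is probabilistic: a free receptor with a ligand inside
r_bind makes one Bernoulli(P_bind) attempt per step on the nearest such
ligand. P_bind is calibrated so the macroscopic association rate is k_on,
by solving the stationary radial pair-density system

    k_on Δt / r_bind³ = P ∫₀¹ 4πz² g(z) dz
    g(z) = (1−P)·∫₀¹ K g + ∫₁^∞ K g + (P/α²) K(z, α, γ) ∫₀¹ g z² dz

with K(z,z′,γ) the image-subtracted radial Gaussian transition kernel,
α = r_unbind/r_bind and γ = √(2(D_ligand+D_receptor)Δt)/r_bind. The third
term re-injects absorbed ligand at the unbinding radius; the 1/α² factor
is fixed by mass conservation (a delta of mass M released at radius α has
pair density M/α²). Because ligand approaches the membrane only from
outside, the root is doubled before use; both values are reported.

Numerics: the radial grid is split exactly at z = 1 because the
absorption factor is a step there — a quadrature cell straddling that
discontinuity biases the root by ~1%, which is visible in rate-recovery
simulations. Inner region [10⁻³, 1] gets 400 trapezoid nodes; the outer
region extends to max(10, 10γ) with the tail (g ≡ 1 beyond truncation)
added in closed form. The fixed point is solved by damped Picard
iteration (damping 0.5 on oscillation, relative tolerance 10⁻¹⁰) and the
root by bisection to 10⁻⁸. At the standard parameter set the doubled
probability is 0.00198, matching the reference value 0.002 to 1%.

## Reflections

Wall reflections use the exact closed-form mirror fold. Sphere
reflection defaults to radial mirroring |r| → 2R − |r|, with an exact
specular segment-intersection reflection selectable per config. The two
agree to O(step/R); at full scale (step/R ≈ 0.6%) the difference is
negligible, but the radial mirror is not volume-preserving on a curved
surface and over-populates the near-surface shell by O(step/R). The
reduced-scale validation runs therefore select the specular scheme (their
step/R is 5–10%); measured effective association rates then agree with
k_on to better than 1%, versus ~+5–10% with the radial mirror at those
exaggerated step sizes.

## Gradient boundaries

Method 1 (both faces clamped): every coarse step, all molecules beyond
either x face are removed and Poisson(n_inj) new molecules are injected
per face, n_inj = 0.6022·c·a·√(DΔτ/π), at uniform (y, z) and a depth
drawn from the density ∝ 1 − erf(d/√(4DΔτ)). The printed depth law is a
shape function (it integrates to √(DΔτ/π)); it is normalized before
sampling and drawn through a 4096-node inverse-CDF table — statistically
identical to, and much lighter than, a pre-computed sample list. Its
normalized mean is √(4DΔτ)·√π/4 (0.070 µm at standard parameters; the
median is 0.056 µm).

Method 2 (one-sided source): injection only at the high face with the
gradient flux term added, n_inj = 0.6022·(c·a√(DΔτ/π) + a·g·DΔτ/2); at
the low face each molecule found outside is mirror-reflected inward with
probability p_ref = 1 − g/(c_low(πDΔτ)^(−1/2) + g/2), else absorbed.
This expression is the dimensionally consistent flux balance (a linear
profile carries flux D·g into the face) and is verified directly by the
no-cell steady-state property test (fitted slope g, far-face
concentration c_low). It is valid only while c_low/g ≫ √(4DΔτ);
validation enforces ratio ≥ 3 (error) and warns below 10.

## Receptor variants

Receptor cycling replaces unbinding: a bound receptor is endocytosed with
rate k_endo, its ligand leaves the world, and a free receptor appears at
a uniform random surface point, keeping N constant (k_off must be 0 in
this variant). The default k_endo equals the unbinding rate of the
paired release-model run (0.0011 s⁻¹) so the two models differ only in
ligand fate; the measured endocytosis rate 0.0021 s⁻¹ can be configured.
Bar1 is a static 1/r concentration field [Bar1]₀R/r with [Bar1]₀ =
0.85 nM; free ligand at radius r is degraded with probability
k_cat·[Bar1](r)·Δt (k_cat = 2.5×10⁸ (M·s)⁻¹), bound ligand is immune.

## Observables and statistics

Occupancy n(t), its front/back split, the bound-receptor centre of mass
(the direction estimate g_est), and the confidence (1/R)(n/N)|⟨Ste2*⟩|
are recorded at a fixed cadence (default 0.1 s simulated; 0.05 s in the
reduced-scale runs). The empirical CV² is σ_nT²/σₙ⁴ with σ_nT² the
variance of the trailing boxcar average; replicates are pooled by
averaging per-replicate values, with standard errors from replicate
scatter. Time-averaged directions average the g_est *vector* over the
window and then take angles — the only definition that commutes with the
linearity of the centre of mass. Frames with no bound receptors emit a
NaN sentinel and are excluded from angle statistics. Theoretical CV²
curves convert concentrations to number densities (×0.6022) and k_on to a
volumetric per-molecule rate before evaluation. Half-cell occupancy
moments in a linear gradient use the closed-form x-averages of the
uniform-field expressions (receptor x is uniform on a sphere); both
reduce exactly to the uniform forms at g = 0. Concentration profiles bin
molecules on (x, ρ=√(y²+z²)); bin volumes subtract the cell-sphere
overlap by 65-point quadrature, and bins fully inside the cell are
flagged missing.

## Reduced-scale validation conditions

The cluster-scale presets keep the full study conditions (10 µm box,
R = 2.5 µm, 10⁴ receptors, Δt = 1 µs, 30-minute burn-in, 60-minute
production; ~3.6×10⁹ fine steps per run). The test suite validates the
same code paths on reduced geometries chosen once as follows:

* **Rate recovery / equilibrium moments**: (6 µm)³ box, R = 2 µm, 200
  receptors, c = K_D = 10 nM, k_off = 0.5 s⁻¹ (τ_N = 1 s), r_bind =
  0.05 µm, D = 5 µm²/s, Δt = 1 ms (γ ≈ 2), specular reflection,
  3 × 240 s productions after 10 s burn-in. These sizes give ~4.5×10⁴
  binding events (0.5% statistical error on k_on) and a 3-SE window of
  ±1% on the occupancy mean.
* **Time-averaging statistics**: (4 µm)³ box, R = 1 µm, 100 receptors,
  c = 70 nM = 7 K_D (τ_N = 0.25 s), otherwise as above; averaging windows
  of 10–20 τ_N. Windows are deliberately placed well above 5 τ_N: the
  theoretical CV² is the asymptotic (white-noise) form, which exceeds the
  exact finite-window variance of a correlated process by ~20% at
  T = 5 τ_N and ~10% at 10 τ_N. The high background keeps the diffusion
  term of the CV² below ~2% of the total, because the clamped faces of a
  small box suppress slow concentration fluctuations that the
  infinite-medium theory assumes.
* **Boundary fidelity, steric sharpening, gradient formation**: cell-free
  or reaction-free boxes at Δt = Δτ = 1 ms with steeper gradients
  (0.5–1.5 nM/µm·(scaled)) so the effects are resolvable in ~10⁵
  molecule-snapshots.

What passing these shows — and does not show: the reduced runs exercise
identical code with exaggerated per-step probabilities (P_bind up to
~0.3 versus 0.002 at full scale) and larger step/R; agreement there
bounds discretization bias pessimistically. They do not probe the
hour-long correlation structure of the slow-rate system, which only the
cluster-scale presets reach.

## Known limitations

* The half-space doubling of the binding probability treats the membrane
  as locally planar; the residual curvature correction is O(r_bind/R)
  (~0.2% at full scale, ~1% in the reduced runs) and is not corrected.
* The per-receptor nearest-ligand binding rule differs from a per-ligand
  independent-trial rule only when two candidates share a receptor in one
  step (probability ~10⁻⁶ at the densities used).
* Receptor surface diffusion by step-and-project is accurate to
  O(D_receptor Δτ/R²) per step; at the defaults this is ~10⁻⁸.
* Method 2's reflection probability assumes the near-face profile is the
  steady linear one; during early gradient formation the face is slightly
  out of balance, which is part of the transient being simulated.
* The confidence baseline for uniformly bound receptors uses the χ₃ mean
  of the centre of mass, a CLT approximation accurate to ~1% at n ≥ 100.
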