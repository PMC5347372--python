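"""Observables and the statistical / theoretical analysis layer.

Per-frame observables: receptor occupancy n(t), its front/back split
(x > 0 vs x < 0), the centre of mass of bound receptors (the cell's
gradient estimate g_est), and the confidence measure

    Confidence = (1/R) * (n/N) * |<bound receptor position>|,

which is 0 for no or uniformly spread active receptors and 1 when every
receptor is active at a single point.

Theory: equilibrium occupancy moments for a uniform concentration and
their half-cell generalisations in a linear gradient; the family of
time-averaged concentration-sensing limits (Berg-Purcell,
Bialek-Setayeshgar, Kaizu, Berezhkovskii-Szabo, Endres-Wingreen and the
perfect-absorber limit), all expressed as the squared coefficient of
variation CV^2 of the cell's concentration estimate after averaging for a
window T; and the simple binding-kinetics transient for a forming
gradient.

Empirical statistics: trailing boxcar time-averages, the empirical
CV^2 = sigma_nT^2 / sigma_n^4, angular deviation of g_est from the true
gradient axis (+x), threshold-accuracy curves, and binned concentration
profiles in (x, rho) cylindrical coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .units import number_density, rate_to_volume_rate

__all__ = [
    "ObservableSeries",
    "TheoryParams",
    "ConcentrationProfile",
    "record_frame",
    "theory_mean_occupancy",
    "theory_std_occupancy",
    "theory_halfcell",
    "time_average",
    "empirical_cv2",
    "theoretical_cv2",
    "relaxation_time",
    "gradient_estimate",
    "confidence",
    "angular_deviation",
    "threshold_probability",
    "transient_occupancy_theory",
    "delta_n_theory",
    "concentration_profile",
    "CV2_MODELS",
]

#: sentinel written where the centre of mass of bound receptors is undefined
COM_SENTINEL = np.nan


# ------------------------------------------------------------- containers

@dataclass
class ObservableSeries:
    """Column-oriented time series of per-frame observables."""

    times: list = field(default_factory=list)
    n_bound: list = field(default_factory=list)
    n_front: list = field(default_factory=list)
    n_back: list = field(default_factory=list)
    com_x: list = field(default_factory=list)
    com_y: list = field(default_factory=list)
    com_z: list = field(default_factory=list)
    confidence: list = field(default_factory=list)
    n_free_ligands: list = field(default_factory=list)
    counters: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.times,
                "n_bound": self.n_bound,
                "n_front": self.n_front,
                "n_back": self.n_back,
                "com_x": self.com_x,
                "com_y": self.com_y,
                "com_z": self.com_z,
                "confidence": self.confidence,
                "n_free_ligands": self.n_free_ligands,
            }
        )
        if self.counters:
            df = pd.concat([df, pd.DataFrame(self.counters)], axis=1)
        return df

    def com_vectors(self) -> np.ndarray:
        return np.column_stack([self.com_x, self.com_y, self.com_z])


def record_frame(state, series: Optional[ObservableSeries] = None) -> ObservableSeries:
    """Append one frame of observables for ``state``."""
    if series is None:
        series = ObservableSeries()
    bound_pos = state.bound_positions()
    n = bound_pos.shape[0]
    series.times.append(state.time)
    series.n_bound.append(n)
    series.n_front.append(int(np.sum(bound_pos[:, 0] > 0)))
    series.n_back.append(n - int(np.sum(bound_pos[:, 0] > 0)))
    if n:
        com = bound_pos.mean(axis=0)
        conf = confidence(
            bound_pos, state.config.n_receptors, state.config.cell_radius
        )
    else:
        com = np.full(3, COM_SENTINEL)
        conf = 0.0
    series.com_x.append(float(com[0]))
    series.com_y.append(float(com[1]))
    series.com_z.append(float(com[2]))
    series.confidence.append(conf)
    series.n_free_ligands.append(state.n_ligands)
    series.counters.append(state.counters.as_dict())
    return series


@dataclass(frozen=True)
class TheoryParams:
    """Parameters of the occupancy-noise theory expressions.

    Concentrations are nM (converted to molecules/um^3 internally where a
    formula needs a number density); k_on in (M.s)^-1; D in um^2/s; R in
    um; T in s.
    """

    N: int
    c: float
    k_on: float
    k_off: float
    D: float
    R: float
    T: float

    @property
    def K_D(self) -> float:
        return (self.k_off / self.k_on) * 1e9

    @property
    def c_density(self) -> float:
        return number_density(self.c)

    @property
    def k_on_vol(self) -> float:
        return rate_to_volume_rate(self.k_on)

    @property
    def binding_rate(self) -> float:
        """k_on * c in s^-1."""
        return self.k_on_vol * self.c_density


# ------------------------------------------------------------- occupancy

def theory_mean_occupancy(N: float, c: float, K_D: float) -> float:
    """Mean equilibrium occupancy N c / (K_D + c)."""
    return N * c / (K_D + c)


def theory_std_occupancy(N: float, c: float, K_D: float) -> float:
    """Equilibrium occupancy standard deviation sqrt(N K_D c) / (K_D + c)."""
    return math.sqrt(N * K_D * c) / (K_D + c)


def theory_halfcell(
    N_half: float, c0: float, K_D: float, g: float, R: float, side: str
) -> tuple[float, float]:
    """Mean and s.d. of occupancy in one half of the cell in a linear
    gradient c(x) = c0 + g x.

    Receptor x-coordinates are uniform on [-R, R] for a uniformly covered
    sphere, so the half-cell moments are x-averages of the uniform-field
    expressions over (0, R) (front) or (-R, 0) (back); both integrals have
    closed forms.  g = 0 reduces exactly to the uniform-field result.
    """
    if side == "front":
        a, b = 0.0, R
    elif side == "back":
        a, b = -R, 0.0
    else:
        raise ValueError("side must be 'front' or 'back'")
    ua, ub = K_D + c0 + g * a, K_D + c0 + g * b
    if min(ua, ub) <= 0:
        raise ValueError("K_D + c(x) must stay positive across the half-cell")
    if g == 0.0:
        return (
            theory_mean_occupancy(N_half, c0, K_D),
            theory_std_occupancy(N_half, c0, K_D),
        )
    span = b - a
    # mean: integral of c/(K_D+c) dx = span - (K_D/g) ln(ub/ua)
    mean = N_half * (1.0 - K_D / (g * span) * math.log(ub / ua))
    # variance: integral of K_D c/(K_D+c)^2 dx
    #         = (K_D/g) [ln u + K_D/u] evaluated between ua and ub
    var = N_half * (K_D / (g * span)) * (
        math.log(ub / ua) + K_D / ub - K_D / ua
    )
    return mean, math.sqrt(max(var, 0.0))


def transient_occupancy_theory(
    t, N_half: float, c_half: float, k_on: float, k_off: float
):
    """Occupancy of initially empty receptors at constant concentration:
    n(t) = N c/(c + K_D) (1 - exp(-(k_on c + k_off) t))."""
    t = np.asarray(t, dtype=float)
    rate = rate_to_volume_rate(k_on) * number_density(c_half) + k_off
    K_D = (k_off / k_on) * 1e9
    n_inf = N_half * c_half / (c_half + K_D)
    return n_inf * (1.0 - np.exp(-rate * t))


def delta_n_theory(
    t, N_half: float, c_front: float, c_back: float, k_on: float, k_off: float
):
    """Front-minus-back occupancy transient under the constant half-cell
    concentration approximation."""
    return transient_occupancy_theory(t, N_half, c_front, k_on, k_off) - \
        transient_occupancy_theory(t, N_half, c_back, k_on, k_off)


def relaxation_time(k_on: float, c: float, k_off: float) -> float:
    """Occupancy correlation time 1 / (k_on c + k_off); c in nM."""
    rate = rate_to_volume_rate(k_on) * number_density(c) + k_off
    if rate <= 0:
        raise ValueError("k_on*c + k_off must be positive")
    return 1.0 / rate


# ------------------------------------------------------------- CV^2 theory

def _cv2_berg_purcell(p: TheoryParams) -> float:
    return (1.0 + p.binding_rate / p.k_off) / (
        math.pi * p.D * p.R * p.c_density * p.T
    )


def _cv2_bialek_setayeshgar(p: TheoryParams) -> float:
    return (
        2.0 / (p.binding_rate * p.T) * (1.0 + p.binding_rate / p.k_off)
        + 1.0 / (math.pi * p.D * p.R * p.c_density * p.T)
    )


def _cv2_kaizu(p: TheoryParams) -> float:
    corr = 1.0 + p.binding_rate / p.k_off
    return (
        2.0 / (p.binding_rate * p.T) * corr
        + corr / (2.0 * math.pi * p.D * p.R * p.c_density * p.T)
    )


def _cv2_berezhkovskii_szabo(p: TheoryParams) -> float:
    return (
        2.0 / (p.N * p.binding_rate * p.T) * (1.0 + p.binding_rate / p.k_off)
        + (1.0 + p.binding_rate / (p.N * p.k_off))
        / (2.0 * math.pi * p.D * p.R * p.c_density * p.T)
    )


def _cv2_endres_wingreen(p: TheoryParams) -> float:
    return 1.0 / (4.0 * math.pi * p.D * p.R * p.c_density * p.T)


def _cv2_perfect_limit(p: TheoryParams) -> float:
    return 1.0 / (2.0 * math.pi * p.D * p.R * p.c_density * p.T)


CV2_MODELS = {
    "berg_purcell": _cv2_berg_purcell,
    "bialek_setayeshgar": _cv2_bialek_setayeshgar,
    "kaizu": _cv2_kaizu,
    "berezhkovskii_szabo": _cv2_berezhkovskii_szabo,
    "endres_wingreen": _cv2_endres_wingreen,
    "perfect_limit": _cv2_perfect_limit,
}


def theoretical_cv2(model: str, params: TheoryParams) -> float:
    """CV^2 of the time-averaged concentration estimate under ``model``.

    Models: berg_purcell, bialek_setayeshgar, kaizu, berezhkovskii_szabo
    (the many-receptor form; equals kaizu at N = 1), endres_wingreen
    (perfect absorber) and perfect_limit (the large-N, fast-binding limit
    of berezhkovskii_szabo, exactly twice endres_wingreen).
    """
    try:
        fn = CV2_MODELS[model]
    except KeyError:
        raise ValueError(f"unknown CV^2 model {model!r}") from None
    return fn(params)


def sigma_nT_from_cv2(cv2: float, N: float, c: float, K_D: float) -> float:
    """Time-averaged occupancy s.d. implied by a CV^2 value:
    sigma_nT = sqrt(CV^2) * sigma_n^2 (the relation used to compare the
    empirical curve with the theory curves)."""
    sigma_n2 = N * K_D * c / (K_D + c) ** 2
    return math.sqrt(cv2) * sigma_n2


# ------------------------------------------------------------- empirics

def time_average(values: np.ndarray, T: float, sample_dt: float) -> np.ndarray:
    """Trailing boxcar mean over a window T of a series sampled every
    sample_dt.  The first T of data produces no output (undefined)."""
    values = np.asarray(values, dtype=float)
    m = T / sample_dt
    if abs(m - round(m)) > 1e-9 * max(1.0, m):
        raise ValueError("T must be an integer multiple of sample_dt")
    m = int(round(m))
    if m < 1 or m > values.shape[0]:
        raise ValueError("averaging window outside the series span")
    if values.ndim == 1:
        kern = np.full(m, 1.0 / m)
        return np.convolve(values, kern, mode="valid")
    # vector series: average each component
    return np.column_stack(
        [np.convolve(values[:, j], np.full(m, 1.0 / m), mode="valid")
         for j in range(values.shape[1])]
    )


def empirical_cv2(
    series_list: Sequence[np.ndarray], T_list: Sequence[float], sample_dt: float
) -> pd.DataFrame:
    """Empirical CV^2 = sigma_nT^2 / sigma_n^4 per averaging window.

    Each replicate contributes its own instantaneous variance and
    windowed variance; replicates are pooled by averaging and the standard
    error comes from the replicate scatter (NaN with fewer than two
    replicates).  Returns columns T, cv2, cv2_se, sigma_nT, sigma_n.
    """
    series_list = [np.asarray(s, dtype=float) for s in series_list]
    if not series_list:
        raise ValueError("need at least one replicate series")
    rows = []
    var_inst = np.array([np.var(s) for s in series_list])
    for T in T_list:
        per_rep = []
        for s, v in zip(series_list, var_inst):
            avg = time_average(s, T, sample_dt)
            per_rep.append(np.var(avg) / v**2)
        per_rep = np.asarray(per_rep)
        cv2 = float(per_rep.mean())
        se = float(per_rep.std(ddof=1) / math.sqrt(len(per_rep))) \
            if len(per_rep) > 1 else float("nan")
        sigma_n2 = float(var_inst.mean())
        rows.append(
            {
                "T": T,
                "cv2": cv2,
                "cv2_se": se,
                "sigma_nT": math.sqrt(cv2) * sigma_n2,
                "sigma_n": math.sqrt(sigma_n2),
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- direction

def gradient_estimate(bound_positions: np.ndarray):
    """Direction statistics of the bound-receptor centre of mass.

    Returns (g_est vector, azimuth deg, elevation deg, angular deviation
    deg).  Azimuth is the counterclockwise angle from +x in the x-y plane;
    elevation the angle from the x-y plane; deviation the angle between
    g_est and the true gradient axis +x, in [0, 180].  With no bound
    receptors every angle is NaN and g_est is the NaN sentinel.
    """
    bound_positions = np.asarray(bound_positions, dtype=float)
    if bound_positions.size == 0:
        nanvec = np.full(3, COM_SENTINEL)
        return nanvec, float("nan"), float("nan"), float("nan")
    g_est = bound_positions.mean(axis=0) if bound_positions.ndim == 2 \
        else bound_positions
    norm = np.linalg.norm(g_est)
    if norm == 0.0:
        return g_est, float("nan"), float("nan"), float("nan")
    azimuth = math.degrees(math.atan2(g_est[1], g_est[0]))
    elevation = math.degrees(
        math.atan2(g_est[2], math.hypot(g_est[0], g_est[1]))
    )
    deviation = math.degrees(math.acos(np.clip(g_est[0] / norm, -1.0, 1.0)))
    return g_est, azimuth, elevation, deviation


def angular_deviation(vectors: np.ndarray) -> np.ndarray:
    """Angle (deg) between each row vector and the +x axis; NaN for zero or
    NaN vectors."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    norms = np.linalg.norm(vectors, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(norms > 0, vectors[:, 0] / norms, np.nan)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def confidence(bound_positions: np.ndarray, N: int, R: float) -> float:
    """(1/R) (n/N) |mean bound-receptor position|; 0 when n = 0."""
    bound_positions = np.asarray(bound_positions, dtype=float)
    n = bound_positions.shape[0] if bound_positions.ndim == 2 else 0
    if n == 0 or N == 0 or R <= 0:
        return 0.0
    return float(
        np.linalg.norm(bound_positions.mean(axis=0)) / R * (n / N)
    )


def threshold_probability(
    com_series_list: Sequence[np.ndarray],
    thresholds: Sequence[float],
    T_list: Sequence[float],
    sample_dt: float,
) -> pd.DataFrame:
    """Probability that the (time-averaged) gradient estimate deviates from
    the true gradient axis by less than each threshold.

    The g_est *vector* is boxcar-averaged over the window first, then the
    deviation of the averaged vector is measured; samples are pooled over
    replicates and time.  Returns a tidy frame (T, threshold_deg, prob, n).
    """
    rows = []
    for T in T_list:
        devs = []
        for com in com_series_list:
            com = np.asarray(com, dtype=float)
            avg = time_average(com, T, sample_dt)
            devs.append(angular_deviation(avg))
        devs = np.concatenate(devs)
        devs = devs[~np.isnan(devs)]
        for th in thresholds:
            rows.append(
                {
                    "T": T,
                    "threshold_deg": th,
                    "prob": float(np.mean(devs < th)) if devs.size else float("nan"),
                    "n": int(devs.size),
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- profiles

@dataclass
class ConcentrationProfile:
    """Mean concentration binned by x and by distance rho from the x axis."""

    x_edges: np.ndarray
    rho_edges: np.ndarray
    concentration: np.ndarray   # (n_x, n_rho) nM; NaN where the bin volume vanishes
    mean_counts: np.ndarray     # (n_x, n_rho) molecules per frame
    volumes: np.ndarray         # (n_x, n_rho) um^3 (cell overlap removed)
    n_frames: int

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def rho_centers(self) -> np.ndarray:
        return 0.5 * (self.rho_edges[:-1] + self.rho_edges[1:])


def _shell_bin_volume(x1, x2, r1, r2, cell_radius):
    """Volume of the cylindrical-shell bin x in [x1,x2], rho in [r1,r2],
    minus its overlap with the cell sphere (numerical x-quadrature)."""
    full = math.pi * (r2**2 - r1**2) * (x2 - x1)
    if cell_radius <= 0:
        return full
    # closest point of the bin to the origin; no overlap if outside the sphere
    x_near = 0.0 if x1 * x2 < 0 else min(abs(x1), abs(x2))
    if x_near**2 + r1**2 >= cell_radius**2:
        return full

    def overlap_area(x):
        rc2 = cell_radius**2 - x * x
        if rc2 <= r1 * r1:
            return 0.0
        return math.pi * (min(rc2, r2 * r2) - r1 * r1)

    xs = np.linspace(x1, x2, 65)
    areas = np.array([overlap_area(x) for x in xs])
    return full - np.trapezoid(areas, xs)


def concentration_profile(
    snapshots: Iterable[np.ndarray],
    x_edges: np.ndarray,
    rho_edges: np.ndarray,
    cell_radius: float = 0.0,
    permeable: bool = False,
) -> ConcentrationProfile:
    """Bin ligand snapshots on (x, rho = sqrt(y^2+z^2)) and convert mean
    counts to nM.  Bin volumes subtract the cell-sphere overlap unless the
    membrane is permeable; bins fully inside the cell are flagged NaN."""
    x_edges = np.asarray(x_edges, dtype=float)
    rho_edges = np.asarray(rho_edges, dtype=float)
    counts = np.zeros((x_edges.size - 1, rho_edges.size - 1))
    n_frames = 0
    for snap in snapshots:
        snap = np.asarray(snap, dtype=float)
        n_frames += 1
        if snap.size == 0:
            continue
        rho = np.hypot(snap[:, 1], snap[:, 2])
        h, _, _ = np.histogram2d(snap[:, 0], rho, bins=(x_edges, rho_edges))
        counts += h
    if n_frames == 0:
        raise ValueError("need at least one snapshot")
    mean_counts = counts / n_frames
    eff_radius = 0.0 if permeable else cell_radius
    vols = np.empty_like(mean_counts)
    for i in range(x_edges.size - 1):
        for j in range(rho_edges.size - 1):
            vols[i, j] = _shell_bin_volume(
                x_edges[i], x_edges[i + 1], rho_edges[j], rho_edges[j + 1],
                eff_radius,
            )
    from .units import concentration_from_molecules

    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(
            vols > 1e-12,
            concentration_from_molecules(mean_counts, np.maximum(vols, 1e-12)),
            np.nan,
        )
    return ConcentrationProfile(
        x_edges=x_edges,
        rho_edges=rho_edges,
        concentration=conc,
        mean_counts=mean_counts,
        volumes=vols,
        n_frames=n_frames,
    )
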