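"""Simulation configuration, validation and derived parameters.

A :class:`SimulationConfig` holds every free parameter of a run: geometry,
time steps, diffusivities, rate constants, the imposed ligand gradient, the
boundary treatment and the model-variant flags (receptor cycling, Bar1
field, permeable membrane).  :func:`derive_parameters` turns it into the
computed quantities the engine consumes: per-step reaction probabilities,
boundary concentrations, mean injection counts and (for the partially
absorbing boundary) the reflection probability.

Units: um, s, nM.  ``k_on`` and ``k_cat`` are given in the conventional
(M·s)^-1 and converted internally (see :mod:`gradsense.units`).

Coordinates: the box is centred on the origin, the cell sphere is centred at
the origin, and the gradient axis is +x.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .units import MOLECULES_PER_NM_UM3, molecules_from_concentration, rate_to_volume_rate

__all__ = [
    "SimulationConfig",
    "DerivedParameters",
    "ConfigError",
    "derive_parameters",
    "load_config",
    "molecules_from_concentration",
    "rate_to_volume_rate",
]


class ConfigError(ValueError):
    """Raised when a configuration violates a named invariant."""


_BOUNDARY_METHODS = ("method1", "method2", "closed")
_SPHERE_REFLECTIONS = ("radial", "specular")


@dataclass(frozen=True)
class SimulationConfig:
    """Free parameters of a particle-based gradient-sensing simulation.

    Defaults follow the standard yeast pheromone / Ste2 parameter set
    (slow measured rates, 0.1 nM/um gradient at mid-box concentration equal
    to the receptor K_D).
    """

    box_lengths: tuple[float, float, float] = (10.0, 10.0, 10.0)  # um
    dt: float = 1e-6          # fine time step, s
    dtau: float = 5e-5        # coarse time step, s
    cell_radius: float = 2.5  # um; 0 means "no cell" (boundary-only runs)
    d_ligand: float = 125.0   # pheromone diffusivity, um^2/s
    d_receptor: float = 0.0025  # receptor surface diffusivity, um^2/s
    n_receptors: int = 10000
    k_on: float = 1.6e5       # (M·s)^-1
    k_off: float = 0.0011     # s^-1
    r_bind: float = 0.004     # um
    r_unbind: float = 0.004   # um
    gradient: float = 0.1     # nM/um, along +x
    concentration: float = 6.9  # nM at the box midpoint
    boundary_method: str = "method1"
    membrane_permeable: bool = False
    receptor_cycling: bool = False
    k_endo: float = 0.0011    # s^-1, endocytosis rate of bound receptors
    bar1: bool = False
    bar1_surface_conc: float = 0.85  # nM at the cell surface
    k_cat: float = 2.5e8      # (M·s)^-1
    sphere_reflection: str = "radial"
    seed: int = 0
    duration: float = 60.0    # production time, s
    burn_in: float = 0.0      # equilibration time, s
    record_interval: float = 0.1  # observable sampling period, s

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        """Eagerly check every invariant; raise ConfigError naming the first
        violated one."""
        lx, ly, lz = self.box_lengths
        if min(lx, ly, lz) <= 0:
            raise ConfigError("box_lengths must be positive")
        if self.dt <= 0 or self.dtau <= 0:
            raise ConfigError("time steps must be positive")
        ratio = self.dtau / self.dt
        if abs(ratio - round(ratio)) > 1e-9 * ratio or round(ratio) < 1:
            raise ConfigError(
                f"dtau must be a positive integer multiple of dt "
                f"(dtau/dt = {ratio!r})"
            )
        if self.cell_radius < 0:
            raise ConfigError("cell_radius must be non-negative")
        if self.cell_radius > 0 and 2 * self.cell_radius >= min(lx, ly, lz):
            raise ConfigError(
                "cell sphere must fit strictly inside the box "
                f"(2R = {2 * self.cell_radius} vs min box length {min(lx, ly, lz)})"
            )
        if self.r_bind <= 0:
            raise ConfigError("r_bind must be positive")
        if self.r_unbind <= 0:
            raise ConfigError("r_unbind must be positive")
        if self.d_ligand <= 0:
            raise ConfigError("d_ligand must be positive")
        if self.d_receptor < 0:
            raise ConfigError("d_receptor must be non-negative")
        if self.n_receptors < 0:
            raise ConfigError("n_receptors must be non-negative")
        if self.k_on < 0 or self.k_off < 0:
            raise ConfigError("rate constants must be non-negative")
        if self.concentration < 0:
            raise ConfigError("concentration must be non-negative")
        if self.boundary_method not in _BOUNDARY_METHODS:
            raise ConfigError(
                f"boundary_method must be one of {_BOUNDARY_METHODS}"
            )
        if self.sphere_reflection not in _SPHERE_REFLECTIONS:
            raise ConfigError(
                f"sphere_reflection must be one of {_SPHERE_REFLECTIONS}"
            )
        if self.receptor_cycling and self.k_off != 0.0:
            raise ConfigError(
                "receptor_cycling requires k_off = 0 (endocytosis replaces release)"
            )
        if self.c_low < 0:
            raise ConfigError(
                f"concentration at the low boundary is negative ({self.c_low} nM)"
            )
        if self.boundary_method == "method2":
            self._validate_method2()

    def _validate_method2(self) -> None:
        # Validity condition of the partially absorbing boundary:
        # c_low / g must dominate the diffusion length sqrt(4 D dtau).
        if self.gradient <= 0:
            raise ConfigError("method2 requires a positive gradient")
        diff_len = math.sqrt(4.0 * self.d_ligand * self.dtau)
        ratio = (self.c_low / self.gradient) / diff_len
        if ratio < 3.0:
            raise ConfigError(
                "method2 validity condition violated: c_low/g = "
                f"{self.c_low / self.gradient:.4g} um is only {ratio:.2f}x the "
                f"diffusion length sqrt(4 D dtau) = {diff_len:.4g} um (need >= 3, "
                "prefer >= 10)"
            )
        if ratio < 10.0:
            warnings.warn(
                f"method2 validity condition is marginal (c_low/g is {ratio:.2f}x "
                "the coarse-step diffusion length; >= 10 recommended)",
                stacklevel=3,
            )

    # -- convenience geometry ------------------------------------------
    @property
    def half_box(self) -> tuple[float, float, float]:
        return tuple(l / 2.0 for l in self.box_lengths)  # type: ignore[return-value]

    @property
    def x_max(self) -> float:
        return self.box_lengths[0] / 2.0

    @property
    def x_min(self) -> float:
        return -self.box_lengths[0] / 2.0

    @property
    def c_high(self) -> float:
        """Concentration at the x = +L/2 face (nM)."""
        return self.concentration + self.gradient * self.x_max

    @property
    def c_low(self) -> float:
        """Concentration at the x = -L/2 face (nM)."""
        return self.concentration + self.gradient * self.x_min

    @property
    def steps_per_coarse(self) -> int:
        return int(round(self.dtau / self.dt))

    @property
    def face_area(self) -> float:
        """Area of an x face (um^2)."""
        return self.box_lengths[1] * self.box_lengths[2]

    @property
    def box_volume(self) -> float:
        lx, ly, lz = self.box_lengths
        return lx * ly * lz

    @property
    def free_volume(self) -> float:
        """Box volume minus the (impermeable) cell sphere."""
        v = self.box_volume
        if self.cell_radius > 0 and not self.membrane_permeable:
            v -= 4.0 / 3.0 * math.pi * self.cell_radius ** 3
        return v

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class DerivedParameters:
    """Quantities computed from a :class:`SimulationConfig`."""

    p_bind: float          # per-fine-step binding probability (half-space doubled)
    p_bind_raw: float      # Erban-Chapman root before the half-space doubling
    p_unbind: float        # per-fine-step unbinding probability
    p_endo: float          # per-fine-step endocytosis probability (cycling model)
    K_D: float             # k_off / k_on, nM (unrounded)
    c_high: float          # nM at x = +L/2
    c_low: float           # nM at x = -L/2
    n_inj_high: float      # mean injected molecules per coarse step, high face
    n_inj_low: float       # mean injected molecules per coarse step, low face
    p_ref: Optional[float]  # reflection probability at the absorbing face (method2)
    molecules_per_nM_um3: float = MOLECULES_PER_NM_UM3

    def __post_init__(self):
        for name in ("p_bind", "p_bind_raw", "p_unbind", "p_endo"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        if self.c_low < 0:
            raise ConfigError("c_low must be non-negative")
        if self.K_D <= 0 and not math.isinf(self.K_D):
            raise ConfigError("K_D must be positive")


def derive_parameters(
    config: SimulationConfig,
    p_bind_override: Optional[float] = None,
) -> DerivedParameters:
    """Compute all derived quantities for ``config``.

    The binding probability comes from the Erban-Chapman calibration (a
    numerical solve); pass ``p_bind_override`` to skip it, e.g. when it is
    already known for the parameter set.
    """
    from . import boundaries, calibration  # local import avoids a cycle

    config.validate()

    if p_bind_override is not None:
        p_bind = float(p_bind_override)
        p_bind_raw = p_bind / 2.0
    elif config.k_on == 0.0 or config.n_receptors == 0:
        p_bind = p_bind_raw = 0.0
    else:
        res = calibration.calibrate(
            k_on=config.k_on,
            dt=config.dt,
            r_bind=config.r_bind,
            r_unbind=config.r_unbind,
            d_ligand=config.d_ligand,
            d_receptor=config.d_receptor,
        )
        p_bind, p_bind_raw = res.p_bind, res.p_bind_raw

    p_unbind = 1.0 - math.exp(-config.k_off * config.dt)
    p_endo = (
        1.0 - math.exp(-config.k_endo * config.dt) if config.receptor_cycling else 0.0
    )
    K_D = (config.k_off / config.k_on) * 1e9 if config.k_on > 0 else math.inf

    a = config.face_area
    if config.boundary_method == "method1":
        n_inj_high = boundaries.mean_injection_count_m1(
            config.c_high, a, config.d_ligand, config.dtau
        )
        n_inj_low = boundaries.mean_injection_count_m1(
            config.c_low, a, config.d_ligand, config.dtau
        )
        p_ref = None
    elif config.boundary_method == "method2":
        n_inj_high = boundaries.mean_injection_count_m2(
            config.c_high, config.gradient, a, config.d_ligand, config.dtau
        )
        n_inj_low = 0.0
        p_ref = boundaries.reflection_probability(
            config.c_low, config.gradient, config.d_ligand, config.dtau
        )
    else:  # closed box
        n_inj_high = n_inj_low = 0.0
        p_ref = None

    return DerivedParameters(
        p_bind=p_bind,
        p_bind_raw=p_bind_raw,
        p_unbind=p_unbind,
        p_endo=p_endo,
        K_D=K_D,
        c_high=config.c_high,
        c_low=config.c_low,
        n_inj_high=n_inj_high,
        n_inj_low=n_inj_low,
        p_ref=p_ref,
    )


# -- config files ------------------------------------------------------

def load_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a TOML or YAML file.

    Field names mirror the dataclass; ``box_lengths`` may be a list of three
    numbers or a single number (cubic box).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        data = tomllib.loads(text)
    elif path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        raise ConfigError(f"unsupported config format: {path.suffix!r}")
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")

    fields = {f.name: f for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    if "box_lengths" in data:
        bl = data["box_lengths"]
        if isinstance(bl, (int, float)):
            data["box_lengths"] = (float(bl),) * 3
        else:
            data["box_lengths"] = tuple(float(v) for v in bl)
    # YAML 1.1 reads unsigned exponents like 1.6e6 as strings; coerce
    # scalars to the declared field types
    defaults = SimulationConfig()
    for name, value in list(data.items()):
        ref = getattr(defaults, name)
        try:
            if isinstance(ref, bool):
                data[name] = bool(value)
            elif isinstance(ref, int):
                data[name] = int(value)
            elif isinstance(ref, float):
                data[name] = float(value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"field {name!r}: cannot coerce {value!r}") from exc
    cfg = SimulationConfig(**data)
    cfg.validate()
    return cfg
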