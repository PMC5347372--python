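"""Gradient-generating boundary treatments at the x = +-L/2 faces.

Two schemes maintain a linear ligand gradient along x:

* **Method 1** clamps the concentration at both faces.  Every coarse step
  all molecules beyond either face are removed, and a Poisson number of new
  molecules (mean from the one-face diffusive influx of a half-space at the
  clamped concentration) is injected just inside each face.

* **Method 2** injects only at the high face (the mean acquires a gradient
  term) and makes the low face partially absorbing: a molecule found beyond
  it is mirror-reflected back with probability p_ref, otherwise removed.
  The steady state in an empty box is a linear profile with slope g and
  concentration c_low at the absorbing face.  This mimics the *formation*
  of a gradient from a one-sided source.

The injection depth d_inj of a new molecule is drawn from the density
proportional to  1 - erf(d / sqrt(4 D dtau)),  the depth distribution of
half-space molecules that crossed the face during one coarse step.  The
printed form is a shape function (it integrates to sqrt(D dtau / pi), not
1) and is normalized here before sampling; sampling uses a tabulated
inverse CDF, which is statistically identical to, and far lighter than, a
pre-computed sample list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import erf, erfc

from .units import MOLECULES_PER_NM_UM3

__all__ = [
    "BoundarySpec",
    "InjectionDistanceSampler",
    "mean_injection_count_m1",
    "mean_injection_count_m2",
    "reflection_probability",
    "sample_injection_count",
    "sample_injection_distance",
]


def mean_injection_count_m1(c: float, a: float, d_ligand: float, dtau: float) -> float:
    """Mean number of molecules to inject per coarse step at a face clamped
    at concentration ``c`` (nM): 0.6022 * c * a * sqrt(D dtau / pi)."""
    if a <= 0 or d_ligand <= 0 or dtau <= 0:
        raise ValueError("a, d_ligand, dtau must be positive")
    if c < 0:
        raise ValueError("concentration must be non-negative")
    return MOLECULES_PER_NM_UM3 * c * a * math.sqrt(d_ligand * dtau / math.pi)


def mean_injection_count_m2(
    c: float, g: float, a: float, d_ligand: float, dtau: float
) -> float:
    """Mean injection count at the source face of method 2.

    0.6022 * (c a sqrt(D dtau / pi) + a g D dtau / 2); the extra term is the
    net diffusive flux a gradient g carries across the face.  With g = 0
    this reduces exactly to the method-1 expression.
    """
    if a <= 0 or d_ligand <= 0 or dtau <= 0:
        raise ValueError("a, d_ligand, dtau must be positive")
    if c < 0:
        raise ValueError("concentration must be non-negative")
    return MOLECULES_PER_NM_UM3 * (
        c * a * math.sqrt(d_ligand * dtau / math.pi)
        + 0.5 * a * g * d_ligand * dtau
    )


def reflection_probability(c_low: float, g: float, d_ligand: float, dtau: float) -> float:
    """Reflection probability of the partially absorbing face (method 2).

    p_ref = 1 - g / (c_low / sqrt(pi D dtau) + g / 2)

    This balances the absorbed flux against the diffusive flux D*g a linear
    profile carries into the face; g = 0 gives p_ref = 1 (a closed face).
    Valid only while c_low/g greatly exceeds the coarse-step diffusion
    length (enforced by config validation).
    """
    if d_ligand <= 0 or dtau <= 0:
        raise ValueError("d_ligand and dtau must be positive")
    if c_low < 0:
        raise ValueError("c_low must be non-negative")
    if g == 0.0:
        return 1.0
    p = 1.0 - g / (c_low / math.sqrt(math.pi * d_ligand * dtau) + 0.5 * g)
    if not 0.0 <= p <= 1.0:
        raise ValueError(
            f"reflection probability {p:.4g} outside [0, 1]; the method-2 "
            "validity condition is violated"
        )
    return p


def sample_injection_count(mean: float, rng: np.random.Generator) -> int:
    """Poisson draw of the number of molecules to inject this coarse step."""
    if mean < 0:
        raise ValueError("mean must be non-negative")
    if mean == 0.0:
        return 0
    return int(rng.poisson(mean))


class InjectionDistanceSampler:
    """Inverse-CDF sampler for the injection depth.

    Density f(d) proportional to erfc(d / s) with s = sqrt(4 D dtau); the
    CDF has the closed form

        F(d) = sqrt(pi) x erfc(x) + 1 - exp(-x^2),   x = d / s,

    tabulated on 4096 nodes out to x = 4 (CDF deficit ~ 1e-8) and inverted
    by linear interpolation.  Built once per (D, dtau).
    """

    N_NODES = 4096
    X_MAX = 4.0

    def __init__(self, d_ligand: float, dtau: float):
        if d_ligand <= 0 or dtau <= 0:
            raise ValueError("d_ligand and dtau must be positive")
        self.scale = math.sqrt(4.0 * d_ligand * dtau)
        x = np.linspace(0.0, self.X_MAX, self.N_NODES)
        cdf = np.sqrt(np.pi) * x * erfc(x) + 1.0 - np.exp(-(x**2))
        cdf[-1] = 1.0
        self._x = x
        self._cdf = cdf

    @property
    def mean(self) -> float:
        """Analytic first moment: s * sqrt(pi) / 4."""
        return self.scale * math.sqrt(math.pi) / 4.0

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(size)
        return self.scale * np.interp(u, self._cdf, self._x)


def sample_injection_distance(
    d_ligand: float, dtau: float, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Convenience one-shot draw; prefer a cached sampler in hot loops."""
    return InjectionDistanceSampler(d_ligand, dtau).sample(size, rng)


@dataclass
class BoundarySpec:
    """Everything the engine needs to run injection/ejection at the x faces."""

    method: str                       # "method1" | "method2" | "closed"
    area: float                       # um^2
    c_high: float                     # nM
    c_low: float                      # nM
    gradient: float                   # nM/um
    n_inj_high: float                 # mean count per coarse step
    n_inj_low: float
    p_ref: Optional[float]            # method2 only
    sampler: Optional[InjectionDistanceSampler]

    def __post_init__(self):
        if self.n_inj_high < 0 or self.n_inj_low < 0:
            raise ValueError("mean injection counts must be non-negative")
        if self.p_ref is not None and not 0.0 <= self.p_ref <= 1.0:
            raise ValueError("p_ref must lie in [0, 1]")

    @classmethod
    def from_config(cls, config, derived) -> "BoundarySpec":
        sampler = (
            None
            if config.boundary_method == "closed"
            else InjectionDistanceSampler(config.d_ligand, config.dtau)
        )
        return cls(
            method=config.boundary_method,
            area=config.face_area,
            c_high=derived.c_high,
            c_low=derived.c_low,
            gradient=config.gradient,
            n_inj_high=derived.n_inj_high,
            n_inj_low=derived.n_inj_low,
            p_ref=derived.p_ref,
            sampler=sampler,
        )
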