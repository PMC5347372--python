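"""Unit system and conversion constants.

The canonical unit system throughout the package is micrometres, seconds and
nanomolar.  All rate constants supplied in the conventional (M·s)^-1 units are
converted once, at the configuration boundary, to per-molecule volumetric
rates in um^3/s.  The single conversion constant is

    0.6022 molecules / (nM · um^3)

i.e. Avogadro's number expressed in the canonical units.
"""

from __future__ import annotations

#: molecules per (nM * um^3); 6.022e23 / L  *  1e-15 L/um^3  *  1e-9 M/nM
MOLECULES_PER_NM_UM3: float = 0.6022

#: molecules per (M * um^3)
MOLECULES_PER_M_UM3: float = MOLECULES_PER_NM_UM3 * 1e9


def molecules_from_concentration(c_nM: float, volume_um3: float) -> float:
    """Expected molecule count for concentration ``c_nM`` in ``volume_um3``.

    Parameters are in nM and um^3; the result is a real (not rounded) count.
    """
    if c_nM < 0:
        raise ValueError(f"concentration must be non-negative, got {c_nM}")
    if volume_um3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_um3}")
    return MOLECULES_PER_NM_UM3 * c_nM * volume_um3


def concentration_from_molecules(n: float, volume_um3: float) -> float:
    """Inverse of :func:`molecules_from_concentration` (returns nM)."""
    return n / (MOLECULES_PER_NM_UM3 * volume_um3)


def rate_to_volume_rate(k_on_per_M_s: float) -> float:
    """Convert an association rate in (M·s)^-1 to a per-molecule volumetric
    rate in um^3/s.

    This is the unit bridge needed wherever a macroscopic rate constant
    multiplies a number density in molecules/um^3.
    """
    if k_on_per_M_s < 0:
        raise ValueError(f"rate must be non-negative, got {k_on_per_M_s}")
    return k_on_per_M_s / MOLECULES_PER_M_UM3


def number_density(c_nM: float) -> float:
    """Concentration in nM -> number density in molecules/um^3."""
    return MOLECULES_PER_NM_UM3 * c_nM
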