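"""Closed-form passive cable quantities for a thin axon attached to a soma.

All functions work at the interface in the units conventional in cellular
neurophysiology: µm for lengths, MΩ (or GΩ where stated) for resistances,
mV for potentials.  Specific constants are given in the units they are
usually reported in (Ω·cm² for membrane resistance, Ω·cm for resistivity,
µF/cm² for capacitance); conversions happen inside each function.

The central quantities are the space constant

    λ = sqrt(Rm · d / (4 · Ri)),

the axial resistance per unit length of a cylinder

    r_a = 4 · Ri / (π · d²),

and the input resistance of an axon seen from a point at distance x from
its proximal end, under three boundary conditions at that end: sealed
(no axial current, the small-soma limit), killed (clamped to rest, the
infinite-soma limit), and a finite spherical soma in between.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PassiveMembrane",
    "CableGeometry",
    "space_constant",
    "axial_resistance_per_unit_length",
    "axial_resistance",
    "membrane_resistance_segment",
    "soma_resistance",
    "input_resistance_sealed",
    "input_resistance_killed",
    "input_resistance_finite_soma",
]

# unit conversions to the interface system (µm, MΩ)
_CM_PER_UM = 1e-4  # 1 µm in cm
_OHM_TO_MOHM = 1e-6


@dataclass(frozen=True)
class PassiveMembrane:
    """Specific passive membrane and cytoplasm constants.

    Parameters
    ----------
    Cm : specific membrane capacitance, µF/cm².
    Rm : specific membrane resistance, Ω·cm².
    Ri : intracellular (axial) resistivity, Ω·cm.
    EL : leak reversal potential, mV.
    """

    Cm: float = 0.9
    Rm: float = 15_000.0
    Ri: float = 100.0
    EL: float = -75.0

    def __post_init__(self) -> None:
        if self.Cm <= 0 or self.Rm <= 0 or self.Ri <= 0:
            raise ValueError("Cm, Rm and Ri must be positive")

    @property
    def tau_m_ms(self) -> float:
        """Membrane time constant Rm·Cm in ms."""
        return self.Rm * self.Cm * 1e-3


@dataclass(frozen=True)
class CableGeometry:
    """Axon diameter and (optionally) soma diameter, both in µm."""

    d: float = 1.0
    dS: float | None = None

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("axon diameter must be positive")
        if self.dS is not None and self.dS <= 0:
            raise ValueError("soma diameter must be positive")


def space_constant(mem: PassiveMembrane, geom: CableGeometry) -> float:
    """Space constant λ = sqrt(Rm·d/(4·Ri)) in µm."""
    lam_cm = math.sqrt(mem.Rm * geom.d * _CM_PER_UM / (4.0 * mem.Ri))
    return lam_cm / _CM_PER_UM


def axial_resistance_per_unit_length(
    mem: PassiveMembrane, geom: CableGeometry
) -> float:
    """Axial resistance per unit length r_a = 4·Ri/(π·d²), MΩ/µm."""
    ra_ohm_per_cm = 4.0 * mem.Ri / (math.pi * (geom.d * _CM_PER_UM) ** 2)
    return ra_ohm_per_cm * _CM_PER_UM * _OHM_TO_MOHM


def axial_resistance(mem: PassiveMembrane, geom: CableGeometry, x: float) -> float:
    """Axial resistance of a length x (µm) of axon: R_a = r_a·x, in MΩ."""
    if x < 0:
        raise ValueError("length must be non-negative")
    return axial_resistance_per_unit_length(mem, geom) * x


def membrane_resistance_segment(
    mem: PassiveMembrane, geom: CableGeometry, x: float
) -> float:
    """Membrane (leak) resistance of a length x of axon, Rm/(π·d·x), in GΩ.

    This is the resistance through the membrane of the cylinder of length
    x; its large value compared to the axial resistance of the same piece
    justifies neglecting the leak over the proximal axon.
    """
    if x <= 0:
        raise ValueError("length must be positive")
    r_ohm = mem.Rm / (math.pi * geom.d * _CM_PER_UM * x * _CM_PER_UM)
    return r_ohm * 1e-9


def soma_resistance(mem: PassiveMembrane, dS: float) -> float:
    """Membrane resistance of a spherical soma of diameter dS (µm), in MΩ."""
    if dS <= 0:
        raise ValueError("soma diameter must be positive")
    r_ohm = mem.Rm / (math.pi * (dS * _CM_PER_UM) ** 2)
    return r_ohm * _OHM_TO_MOHM


def _distal_resistance(
    mem: PassiveMembrane, geom: CableGeometry, x: float, axon_length: float | None
) -> float:
    """Resistance of the distal axon seen from x, MΩ.

    Semi-infinite by default (r_a·λ); with a finite total axon length the
    sealed-end correction coth((ℓ−x)/λ) is applied.
    """
    ra = axial_resistance_per_unit_length(mem, geom)
    lam = space_constant(mem, geom)
    if axon_length is None:
        return ra * lam
    if axon_length <= x:
        raise ValueError("axon length must exceed the evaluation point x")
    return ra * lam / math.tanh((axon_length - x) / lam)


def input_resistance_sealed(
    mem: PassiveMembrane,
    geom: CableGeometry,
    x: float,
    *,
    axon_length: float | None = None,
    approximate: bool = False,
) -> float:
    """Input resistance (MΩ) at distance x from a sealed proximal end.

    The proximal stub of length x with sealed end has resistance
    r_a·λ/tanh(x/λ); in parallel with the distal semi-infinite axon
    (r_a·λ) this gives exactly R(x) = r_a·λ/(1 + tanh(x/λ)).  With
    ``approximate=True`` the first-order expansion r_a·(λ − x) is
    returned instead, valid for x ≪ λ.
    """
    if x < 0:
        raise ValueError("x must be non-negative")
    ra = axial_resistance_per_unit_length(mem, geom)
    lam = space_constant(mem, geom)
    if approximate:
        return ra * (lam - x)
    r_dist = _distal_resistance(mem, geom, x, axon_length)
    if x == 0.0:
        return r_dist
    r_prox = ra * lam / math.tanh(x / lam)
    return 1.0 / (1.0 / r_prox + 1.0 / r_dist)


def input_resistance_killed(
    mem: PassiveMembrane,
    geom: CableGeometry,
    x: float,
    *,
    axon_length: float | None = None,
    approximate: bool = False,
) -> float:
    """Input resistance (MΩ) at distance x from a killed (open) end.

    The proximal stub clamped to rest at its end has resistance
    r_a·λ·tanh(x/λ), so R(x) = r_a·λ·tanh(x/λ)/(1 + tanh(x/λ)) for a
    semi-infinite distal axon.  The small-x expansion r_a·x·(1 − x/λ)
    shows that the input resistance grows nearly linearly with distance:
    the soma acts as a current sink.
    """
    if x < 0:
        raise ValueError("x must be non-negative")
    ra = axial_resistance_per_unit_length(mem, geom)
    lam = space_constant(mem, geom)
    if approximate:
        return ra * x * (1.0 - x / lam)
    if x == 0.0:
        return 0.0
    r_prox = ra * lam * math.tanh(x / lam)
    r_dist = _distal_resistance(mem, geom, x, axon_length)
    return 1.0 / (1.0 / r_prox + 1.0 / r_dist)


def input_resistance_finite_soma(
    mem: PassiveMembrane,
    geom: CableGeometry,
    x: float,
    dS: float,
    *,
    axon_length: float | None = None,
) -> float:
    """Input resistance (MΩ) at distance x with a finite spherical soma.

    The proximal path is the axial resistance r_a·x in series with the
    soma membrane resistance; the distal path is the distal axon.  This
    interpolates between the killed-end (dS → ∞) and, for a very small
    soma, approaches the resistance of a sealed proximal end over the
    proximal membrane path.
    """
    if x < 0:
        raise ValueError("x must be non-negative")
    ra = axial_resistance_per_unit_length(mem, geom)
    r_prox = ra * x + soma_resistance(mem, dS)
    r_dist = _distal_resistance(mem, geom, x, axon_length)
    return 1.0 / (1.0 / r_prox + 1.0 / r_dist)
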