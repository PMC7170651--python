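"""Analytical spike-threshold theory for the axon initial segment (AIS).

The theory treats spike initiation as a fold bifurcation of the axonal
voltage profile with the somatic potential as bifurcation parameter
("resistive coupling" regime: the soma is a current sink for the thin
axon).  Two currents are kept: the axial Ohmic current toward the soma
and an instantaneous Na⁺ current that grows exponentially with voltage
below threshold, I_Na ≈ G·exp(V/k)·(E_Na − V₁/₂), where k is the
Boltzmann slope of Nav activation.

Point AIS (all conductance at distance Δ, axial resistance Ra):

    V_ais_threshold  = V₁/₂ − k·ln(Ra·G·(E_Na − V₁/₂)/k)
    V_soma_threshold = V_ais_threshold − k

Extended AIS (length L, start Δ, uniform density g on a cylinder of
diameter d): the steady cable equation V'' ∝ −g·e^{V/k} rescales to
U'' + e^U = 0 on [0, 1] whose fold can be computed exactly.  The
somatic threshold is

    Vs = V₁/₂ + k·U0(Δ/L) − k·ln(r_a·(E_Na − V₁/₂)/k) − k·ln(π·d·g)
         − 2k·ln L

with U0(0) ≈ −0.13.  This equals the threshold of a point AIS with the
same total conductance placed at the midpoint x₁/₂ = Δ + L/2, up to a
corrective term k·F(Δ/L) ≤ 0.17k.

All logarithms are natural; lengths are µm, voltages mV, resistances MΩ
and conductances nS at the interface (SI inside the log arguments, which
are dimensionless).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .passive import CableGeometry, PassiveMembrane, space_constant

__all__ = [
    "NavTheoryParams",
    "AISGeometry",
    "RescaledBifurcation",
    "PointThreshold",
    "ExtendedThreshold",
    "NoBifurcationError",
    "solve_rescaled_bifurcation_at_soma",
    "solve_general_bifurcation",
    "corrective_term_F",
    "point_ais_threshold",
    "extended_ais_threshold",
    "extended_ais_threshold_numeric",
    "threshold_formula",
    "predict_geometry_shift",
    "threshold_shift_from_current",
    "axo_axonic_displacement_shift",
    "effective_Ra_with_conductance",
    "distal_load_threshold_shift",
    "electrical_equivalence_scaling",
    "ais_scaling_with_diameter",
]

_RESIDUAL_TOL = 1e-12


class NoBifurcationError(ValueError):
    """Raised when the axonal steady state has no fold.

    For a very proximal or weakly excitable AIS the axonal voltage
    follows the somatic voltage smoothly: there is no bifurcation and no
    'kink', so a voltage threshold is undefined.
    """


@dataclass(frozen=True)
class NavTheoryParams:
    """Nav activation parameters entering the threshold theory.

    k: Boltzmann activation slope (mV); V_half: half-activation voltage
    of the AIS Nav channels (mV); ENa: Na⁺ reversal potential (mV).
    """

    k: float = 5.0
    V_half: float = -35.0
    ENa: float = 70.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("Boltzmann slope k must be positive")
        if self.ENa <= self.V_half:
            raise ValueError("ENa must exceed V_half")

    @property
    def driving_force(self) -> float:
        """Approximated driving force E_Na − V₁/₂ (mV)."""
        return self.ENa - self.V_half


@dataclass(frozen=True)
class AISGeometry:
    """AIS placement on a cylindrical axon.

    delta: start position Δ (µm, from the soma); L: length (µm);
    d: diameter (µm); g: Nav surface density (S/m²) and/or G: total Nav
    conductance (nS).  When both g and G are given they must agree with
    G = g·π·d·L.
    """

    delta: float = 5.0
    L: float = 30.0
    d: float = 1.0
    g: float | None = 3500.0
    G: float | None = None

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("AIS start distance must be non-negative")
        if self.L <= 0 or self.d <= 0:
            raise ValueError("AIS length and diameter must be positive")
        if self.g is None and self.G is None:
            raise ValueError("one of g (S/m²) or G (nS) is required")
        if self.g is not None and self.G is not None:
            if abs(self.G - self._G_from_g()) > 1e-9 * max(abs(self.G), 1.0):
                raise ValueError("g and G are inconsistent (G must equal g·π·d·L)")

    def _G_from_g(self) -> float:
        # S/m² × µm² → nS : 1 S/m² = 1e-12 S/µm² = 1e-3 nS/µm²
        return self.g * math.pi * self.d * self.L * 1e-3

    @property
    def x_half(self) -> float:
        """Midpoint position x₁/₂ = Δ + L/2 (µm)."""
        return self.delta + self.L / 2.0

    @property
    def total_conductance_nS(self) -> float:
        return self.G if self.G is not None else self._G_from_g()

    @property
    def density_S_m2(self) -> float:
        if self.g is not None:
            return self.g
        return self.G / (math.pi * self.d * self.L * 1e-3)


@dataclass(frozen=True)
class RescaledBifurcation:
    """Fold of the rescaled cable equation U'' + e^U = 0 on [0, 1].

    z is the root of the bifurcation condition ((1+r)·z·tanh z +
    r·z²·(1 − tanh²z) = 1 with r = Δ/L); c1 = 4z² is the constant of
    the analytical solution U(y) = ln(c1/2) − 2·ln cosh(½√c1·(y − 1));
    U0 is the rescaled somatic threshold and U1 the rescaled voltage at
    the AIS end, which exceeds U0 by about 1.2 at r = 0.
    """

    ratio: float
    z: float
    c1: float = field(init=False)
    U0: float = field(init=False)
    U1: float = field(init=False)

    def __post_init__(self) -> None:
        z, r = self.z, self.ratio
        object.__setattr__(self, "c1", 4.0 * z * z)
        u1 = math.log(2.0 * z * z)  # = ln(c1/2)
        u0 = u1 - 2.0 * math.log(math.cosh(z)) - r * 2.0 * z * math.tanh(z)
        object.__setattr__(self, "U0", u0)
        object.__setattr__(self, "U1", u1)


def _bifurcation_condition(z: float, ratio: float) -> float:
    t = math.tanh(z)
    return (1.0 + ratio) * z * t + ratio * z * z * (1.0 - t * t) - 1.0


def solve_general_bifurcation(ratio: float) -> RescaledBifurcation:
    """Solve the fold condition of the rescaled threshold problem.

    ratio is Δ/L (0 = AIS abutting the soma, large = point-like AIS).
    The condition (1+r)·z·tanh z + r·z²·sech²z = 1 is monotone in z on
    (0, ∞) for every r ≥ 0, so a bracketed root is unique.
    """
    if ratio < 0:
        raise ValueError("Δ/L ratio must be non-negative")
    lo, hi = 1e-9, 10.0
    if _bifurcation_condition(hi, ratio) < 0:  # pragma: no cover
        raise RuntimeError("bifurcation bracket failure")
    z = brentq(_bifurcation_condition, lo, hi, args=(ratio,), xtol=1e-15, rtol=1e-15)
    assert abs(_bifurcation_condition(z, ratio)) < _RESIDUAL_TOL
    return RescaledBifurcation(ratio=ratio, z=z)


def solve_rescaled_bifurcation_at_soma() -> RescaledBifurcation:
    """Fold for an AIS starting at the soma (Δ = 0): z·tanh z = 1.

    Gives z ≈ 1.1997, c1 = 4z² ≈ 5.8, U0 ≈ −0.13 and U1 ≈ 1.06: at
    threshold the AIS end sits about 1.2k above the somatic potential.
    """
    return solve_general_bifurcation(0.0)


def corrective_term_F(ratio: float) -> float:
    """Corrective term F(Δ/L) = U0(Δ/L) + 1 + ln(Δ/L + 1/2).

    k·F is the threshold difference between the extended AIS and the
    equivalent point AIS (same total conductance at the midpoint).  F
    decreases monotonically from ≈0.17 at 0 toward 0 as Δ/L → ∞, which
    is why the midpoint rule is accurate to about 0.9 mV at k = 5 mV.
    """
    bif = solve_general_bifurcation(ratio)
    return bif.U0 + 1.0 + math.log(ratio + 0.5)


@dataclass(frozen=True)
class PointThreshold:
    """Thresholds of a point AIS (mV)."""

    V_soma: float
    V_ais: float
    Ra_MOhm: float
    G_nS: float


def point_ais_threshold(
    nav: NavTheoryParams,
    Ra: float,
    G: float,
    *,
    exact_driving_force: bool = False,
) -> PointThreshold:
    """Somatic and AIS-site spike threshold for a point AIS (mV).

    Ra is the axial resistance soma→AIS in MΩ and G the total available
    Nav conductance in nS.  The somatic threshold sits exactly k below
    the AIS threshold.  With ``exact_driving_force=True`` the driving
    force (E_Na − V) is kept instead of the fixed (E_Na − V₁/₂) and the
    fold is located numerically; the fold then disappears for small
    Ra·G (no-bifurcation condition) and :class:`NoBifurcationError` is
    raised.
    """
    if Ra <= 0 or G <= 0:
        raise ValueError("Ra and G must be positive")
    k = nav.k
    # Ra·G in MΩ·nS = 1e-3 (dimensionless)
    rag = Ra * G * 1e-3
    if exact_driving_force:
        return _point_threshold_exact(nav, Ra, G, rag)
    arg = rag * nav.driving_force / k
    if arg <= 1.0:
        raise NoBifurcationError(
            "Ra·G·(ENa−V_half)/k ≤ 1: the exponential-current approximation "
            "places the fold above V_half; no spike threshold is defined"
        )
    v_ais = nav.V_half - k * math.log(arg)
    return PointThreshold(V_soma=v_ais - k, V_ais=v_ais, Ra_MOhm=Ra, G_nS=G)


def _point_threshold_exact(
    nav: NavTheoryParams, Ra: float, G: float, rag: float
) -> PointThreshold:
    """Fold of Ra·G·e^{(V−V₁/₂)/k}·(E_Na − V) = V − Vs, exact driving force.

    The fold satisfies d/dV of the left side = 1, i.e.
    rag·e^{(V−V₁/₂)/k}·((E_Na − V)/k − 1) = 1, which has a solution
    below E_Na − k only if the maximum of the left side (at
    V = E_Na − 2k) reaches 1.
    """
    k = nav.k

    def slope(v: float) -> float:
        return rag * math.exp((v - nav.V_half) / k) * ((nav.ENa - v) / k - 1.0) - 1.0

    v_max = nav.ENa - 2.0 * k
    if slope(v_max) < 0:
        raise NoBifurcationError(
            "axial current is always steeper than the Na current: no fold"
        )
    v_ais = brentq(slope, -500.0, v_max, xtol=1e-12)
    v_soma = v_ais - rag * math.exp((v_ais - nav.V_half) / k) * (nav.ENa - v_ais)
    return PointThreshold(V_soma=v_soma, V_ais=v_ais, Ra_MOhm=Ra, G_nS=G)


def _ra_si(nav: NavTheoryParams, mem: PassiveMembrane, d_um: float) -> float:
    """Axial resistance per length in Ω/m for diameter d (µm)."""
    ri_ohm_m = mem.Ri * 1e-2  # Ω·cm → Ω·m
    return 4.0 * ri_ohm_m / (math.pi * (d_um * 1e-6) ** 2)


@dataclass(frozen=True)
class ExtendedThreshold:
    """Threshold of a spatially extended AIS and its midpoint-rule check."""

    V_soma: float
    V_soma_midpoint_rule: float
    correction_mV: float  # V_soma − V_soma_midpoint_rule = k·F(Δ/L)
    V_ais_end: float
    bifurcation: RescaledBifurcation


def extended_ais_threshold(
    nav: NavTheoryParams, mem: PassiveMembrane, geom: AISGeometry
) -> ExtendedThreshold:
    """Exact analytical somatic threshold for an extended AIS (mV).

    Implements Vs = V₁/₂ + k·U0(Δ/L) − k·ln(r_a·(E_Na−V₁/₂)/k)
    − k·ln(π·d·g) − 2k·ln L (all factors in SI inside the logs), along
    with the midpoint-equivalent point-AIS threshold and their
    difference k·F(Δ/L).
    """
    k = nav.k
    bif = solve_general_bifurcation(geom.delta / geom.L)
    ra = _ra_si(nav, mem, geom.d)  # Ω/m
    g = geom.density_S_m2
    L_m = geom.L * 1e-6
    if ra * g * math.pi * geom.d * 1e-6 * L_m**2 * nav.driving_force / k <= 0:
        raise NoBifurcationError("degenerate AIS parameters")
    vs = (
        nav.V_half
        + k * bif.U0
        - k * math.log(ra * nav.driving_force / k)
        - k * math.log(math.pi * geom.d * 1e-6 * g)
        - 2.0 * k * math.log(L_m)
    )
    ra_mid = ra * geom.x_half * 1e-6 * 1e-6  # MΩ at the midpoint
    vs_mid = point_ais_threshold(nav, ra_mid, geom.total_conductance_nS).V_soma
    v_end = vs + k * (bif.U1 - bif.U0)
    return ExtendedThreshold(
        V_soma=vs,
        V_soma_midpoint_rule=vs_mid,
        correction_mV=vs - vs_mid,
        V_ais_end=v_end,
        bifurcation=bif,
    )


def extended_ais_threshold_numeric(
    nav: NavTheoryParams,
    mem: PassiveMembrane,
    geom: AISGeometry,
    *,
    I_end_pA: float = 0.0,
    n_grid: int = 2001,
) -> float:
    """Somatic threshold from the steady cable equation, solved numerically.

    Integrates U'' + e^U = 0 across the AIS (finite differences on the
    rescaled interval) for a family of end values and locates the fold
    of the somatic boundary value.  Supports a current injected at the
    AIS end through the boundary condition V'(L) = r_a·I, for which no
    closed form exists; with I_end_pA = 0 this reproduces
    :func:`extended_ais_threshold` and serves as its numerical check.

    Returns the somatic threshold in mV.
    """
    k = nav.k
    ra = _ra_si(nav, mem, geom.d)  # Ω/m
    g = geom.density_S_m2
    L_m = geom.L * 1e-6
    r = geom.delta / geom.L
    # scale factor of the rescaled problem: U = (V − V1/2)/k + ln(A)
    A = ra * g * math.pi * geom.d * 1e-6 * L_m**2 * nav.driving_force / k
    # rescaled end-current boundary slope: V'(L) = ra·I → U'(1) = ra·I·L/k
    up1 = ra * (I_end_pA * 1e-12) * L_m / (k * 1e-3)

    y = np.linspace(0.0, 1.0, n_grid)
    h = y[1] - y[0]

    def u0_of_u1(u1: float) -> float:
        # integrate backward from y=1 with U(1)=u1, U'(1)=up1
        u, up = u1, up1
        # RK4 on the autonomous system dU/dy = Up, dUp/dy = −e^U, backward
        for _ in range(n_grid - 1):
            k1u, k1p = up, -math.exp(u)
            k2u, k2p = up - 0.5 * h * k1p, -math.exp(u - 0.5 * h * k1u)
            k3u, k3p = up - 0.5 * h * k2p, -math.exp(u - 0.5 * h * k2u)
            k4u, k4p = up - h * k3p, -math.exp(u - h * k3u)
            u -= h / 6.0 * (k1u + 2 * k2u + 2 * k3u + k4u)
            up -= h / 6.0 * (k1p + 2 * k2p + 2 * k3p + k4p)
        # somatic boundary: U(0) − r·U'(0) = U0
        return u - r * up

    res = minimize_scalar(
        lambda u1: -u0_of_u1(u1), bounds=(-8.0, 4.0), method="bounded",
        options={"xatol": 1e-10},
    )
    u0_star = -res.fun
    return nav.V_half + k * (u0_star - math.log(A))


def threshold_formula(
    nav: NavTheoryParams,
    geom: AISGeometry,
    reference: AISGeometry,
) -> float:
    """Geometric threshold shift ΔVs (mV) between two AIS configurations.

    ΔVs = −k·[ln(g'/g) + ln(L'/L) + ln(x'₁/₂/x₁/₂) − ln(d'/d)], the
    compact logarithmic form: density, length and midpoint position each
    lower the threshold e-fold per factor e, while a thicker AIS raises
    it (axial resistance falls as 1/d² but total conductance only grows
    as d).
    """
    for g_ in (geom, reference):
        if g_.x_half <= 0:
            raise ValueError("midpoint position must be positive")
    k = nav.k
    return -k * (
        math.log(geom.density_S_m2 / reference.density_S_m2)
        + math.log(geom.L / reference.L)
        + math.log(geom.x_half / reference.x_half)
        - math.log(geom.d / reference.d)
    )


def predict_geometry_shift(
    initial: tuple[float, float],
    final: tuple[float, float],
    k: float = 5.0,
) -> float:
    """Predicted threshold shift (mV) from (L, x₁/₂) before/after plasticity.

    ΔVs = −k·[ln(L_f/L_i) + ln(x_f/x_i)], assuming constant Nav density
    and diameter.  This is the quantity tabulated for the structural
    plasticity and development studies.
    """
    L_i, x_i = initial
    L_f, x_f = final
    if min(L_i, x_i, L_f, x_f) <= 0:
        raise ValueError("lengths and positions must be positive")
    return -k * (math.log(L_f / L_i) + math.log(x_f / x_i))


def threshold_shift_from_current(Ra: float, I: float) -> float:
    """Somatic threshold shift (mV) from a current at the AIS start.

    A current I (pA, negative = hyperpolarizing) injected at the AIS
    start shifts the somatic threshold by −Ra·I (Ra in MΩ): the AIS is
    hyperpolarized relative to the soma by Ra·I, and the axonal voltage
    profile at threshold — hence the AIS threshold — is unchanged.
    """
    return -Ra * I * 1e-6 * 1e3  # MΩ·pA = µV → mV


def axo_axonic_displacement_shift(
    dV_mV: float, end_initial_um: float, end_final_um: float
) -> float:
    """Threshold increase when a hyperpolarized AIS end moves distally.

    If standing axonal currents hyperpolarize the AIS end by dV (mV) at
    end position x_e, moving the end to x_e' scales the resistive
    hyperpolarization with the axial resistance, i.e. linearly in end
    position: the threshold increases by dV·(x_e' − x_e)/x_e.  Beyond
    the AIS end the effect of the current saturates, so end positions
    are the relevant coordinates.
    """
    if end_initial_um <= 0 or end_final_um <= 0:
        raise ValueError("end positions must be positive")
    return dV_mV * (end_final_um - end_initial_um) / end_initial_um


def effective_Ra_with_conductance(Ra: float, g_shunt: float) -> float:
    """Effective axial resistance with a conductance at the AIS (MΩ).

    A conductance g* (µS) at the AIS acts in parallel with the axial
    path: Ra_eff = 1/(1/Ra + g*).  Negligible while g* ≪ 1/Ra.
    """
    if g_shunt < 0:
        raise ValueError("shunt conductance must be non-negative")
    return 1.0 / (1.0 / Ra + g_shunt)


def distal_load_threshold_shift(
    mem: PassiveMembrane,
    d_um: float,
    Ra_end: float,
    Va: float,
    *,
    myelin_factor: float = 1.0,
) -> float:
    """Somatic threshold increase (mV) due to the distal axon load.

    The distal axon is equivalent to a conductance 1/R_distal at the AIS
    end with reversal at rest, so ΔV = (Ra_end/R_distal)·(Va − EL) with
    R_distal = r_a·λ.  Myelination multiplies Rm by ``myelin_factor``,
    hence R_distal by √myelin_factor (λ ∝ √Rm): a ×4 factor halves the
    shift.
    """
    if myelin_factor < 1.0:
        raise ValueError("myelin factor must be ≥ 1")
    geom = CableGeometry(d=d_um)
    mem_my = PassiveMembrane(
        Cm=mem.Cm, Rm=mem.Rm * myelin_factor, Ri=mem.Ri, EL=mem.EL
    )
    from .passive import axial_resistance_per_unit_length

    r_distal = axial_resistance_per_unit_length(mem_my, geom) * space_constant(
        mem_my, geom
    )
    return Ra_end / r_distal * (Va - mem.EL)


def electrical_equivalence_scaling(
    dS: float, *, anchor: tuple[float, float] = (30.0, 1.0)
) -> float:
    """Axon diameter (µm) electrically matched to a soma of diameter dS.

    Dimensional analysis of the soma–AIS system (soma area ∝ dS², axial
    conductance ∝ d²/length with length ∝ √d) gives d_axon ∝ dS^{4/3}.
    The returned law is anchored so that it passes through the supplied
    (soma, axon) diameter pair, by default (30 µm, 1 µm).
    """
    if dS <= 0:
        raise ValueError("soma diameter must be positive")
    s0, a0 = anchor
    return a0 * (dS / s0) ** (4.0 / 3.0)


def ais_scaling_with_diameter(length_um: float, d_ratio: float) -> float:
    """Companion scaling: AIS lengths/positions scale as √d.

    When the axon diameter is multiplied by d_ratio, the space constant
    grows by √d_ratio and the electrically equivalent AIS position and
    length scale by the same factor.
    """
    if d_ratio <= 0:
        raise ValueError("diameter ratio must be positive")
    return length_um * math.sqrt(d_ratio)
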