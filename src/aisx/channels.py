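"""Hodgkin–Huxley-type channel kinetics with three-parameter gates.

Each gating variable x follows dx/dt = α(V)(1−x) − β(V)x with rates

    α(V) =  (1/(2kτ*)) · (V − V₁/₂) / (1 − exp(−(V − V₁/₂)/k))
    β(V) = −(1/(2kτ*)) · (V − V₁/₂) / (1 − exp(+(V − V₁/₂)/k))

chosen so that the steady state x∞(V) is a Boltzmann function with
half-voltage V₁/₂ and slope k, and the time constant τ(V) = 1/(α+β) is
a bell curve peaking at V₁/₂ with value τ*.  For inactivation gates the
two rates are exchanged, which flips the Boltzmann.  Gates may instead
carry a fixed (voltage-independent) time constant, used by the reduced
point-Nav model.

Rates measured at a reference temperature are corrected with a Q10
factor.  :func:`standard_channel_set` builds the Nav/Kv1/Kv7 parameter
sets of the biophysical model (somatic and AIS Nav kinetics differ by a
5 mV hyperpolarizing shift of both activation and inactivation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GatingVariable",
    "ChannelSpec",
    "rate_alpha",
    "rate_beta",
    "x_inf",
    "tau_x",
    "q10_correct",
    "standard_channel_set",
    "simplified_nav",
]

# relative half-width below which the removable singularity of the rate
# expressions is evaluated by series expansion
_SING_EPS = 1e-6


@dataclass(frozen=True)
class GatingVariable:
    """One gating variable: (V₁/₂, k, τ*), gate power, activation/inactivation."""

    name: str
    V_half: float  # mV
    k_slope: float  # mV, > 0
    tau_star: float  # ms, peak (or fixed) time constant
    exponent: int = 1
    is_inactivation: bool = False
    fixed_tau: bool = False  # voltage-independent time constant

    def __post_init__(self) -> None:
        if self.k_slope <= 0:
            raise ValueError("slope factor must be positive")
        if self.tau_star <= 0:
            raise ValueError("peak time constant must be positive")
        if self.exponent < 1:
            raise ValueError("gate exponent must be ≥ 1")


@dataclass(frozen=True)
class ChannelSpec:
    """A voltage-gated conductance: gates, reversal potential, densities.

    density_map maps region names (``soma``, ``dendrite``, ``axon``,
    ``ais``) to surface conductance densities in S/m².
    """

    name: str
    gates: tuple[GatingVariable, ...]
    E_rev: float  # mV
    density_map: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.density_map.values()):
            raise ValueError("densities must be non-negative")


def _activation_alpha(gv: GatingVariable, V: np.ndarray | float) -> np.ndarray | float:
    u = (np.asarray(V, dtype=float) - gv.V_half) / gv.k_slope
    scale = 1.0 / (2.0 * gv.tau_star)
    small = np.abs(u) < _SING_EPS
    with np.errstate(over="ignore"):
        expm = np.where(small, 1.0, -np.expm1(-u))
    out = np.where(small, scale * (1.0 + u / 2.0), scale * u / expm)
    return float(out) if np.isscalar(V) else out


def rate_alpha(gv: GatingVariable, V: np.ndarray | float) -> np.ndarray | float:
    """Opening rate α(V) in 1/ms; α(V₁/₂) = 1/(2τ*)."""
    if gv.fixed_tau:
        return x_inf(gv, V) / gv.tau_star
    if gv.is_inactivation:
        return _activation_beta_raw(gv, V)
    return _activation_alpha(gv, V)


def _activation_beta_raw(gv: GatingVariable, V: np.ndarray | float):
    u = (np.asarray(V, dtype=float) - gv.V_half) / gv.k_slope
    scale = 1.0 / (2.0 * gv.tau_star)
    small = np.abs(u) < _SING_EPS
    with np.errstate(over="ignore"):
        expm = np.where(small, 1.0, np.expm1(u))
    out = np.where(small, scale * (1.0 - u / 2.0), scale * u / expm)
    return float(out) if np.isscalar(V) else out


def rate_beta(gv: GatingVariable, V: np.ndarray | float) -> np.ndarray | float:
    """Closing rate β(V) in 1/ms; for inactivation gates α and β swap."""
    if gv.fixed_tau:
        return (1.0 - x_inf(gv, V)) / gv.tau_star
    if gv.is_inactivation:
        return _activation_alpha(gv, V)
    return _activation_beta_raw(gv, V)


def x_inf(gv: GatingVariable, V: np.ndarray | float) -> np.ndarray | float:
    """Steady state x∞(V): Boltzmann, decreasing for inactivation gates."""
    u = (np.asarray(V, dtype=float) - gv.V_half) / gv.k_slope
    if gv.is_inactivation:
        u = -u
    out = 1.0 / (1.0 + np.exp(-u))
    return float(out) if np.isscalar(V) else out


def tau_x(gv: GatingVariable, V: np.ndarray | float) -> np.ndarray | float:
    """Time constant τ(V) = 1/(α+β): a bell curve peaking at V₁/₂.

    Closed form τ(V) = τ* · tanh(u/2)/(u/2) with u = (V − V₁/₂)/k.
    """
    if gv.fixed_tau:
        if np.isscalar(V):
            return gv.tau_star
        return np.full_like(np.asarray(V, dtype=float), gv.tau_star)
    u = (np.asarray(V, dtype=float) - gv.V_half) / gv.k_slope
    small = np.abs(u) < _SING_EPS
    half = np.where(small, 1.0, u / 2.0)
    out = np.where(small, gv.tau_star, gv.tau_star * np.tanh(half) / half)
    return float(out) if np.isscalar(V) else out


def q10_correct(tau_star: float, T_sim: float, T_ref: float, Q10: float = 2.8) -> float:
    """Temperature-corrected time constant: τ*/Q10^{(T_sim−T_ref)/10}."""
    if Q10 <= 0:
        raise ValueError("Q10 must be positive")
    return tau_star / Q10 ** ((T_sim - T_ref) / 10.0)


# --- standard parameter sets -------------------------------------------------

#: simulation and reference temperatures (°C) for the Nav rate correction
T_SIM, T_REF, Q10 = 33.0, 23.0, 2.8


def standard_channel_set(
    *,
    g_na_ais: float = 3500.0,
    g_k_ais: float = 1500.0,
    g_kv7_distal_ais: float = 0.0,
    kv7_kinetic: bool = False,
) -> dict[str, ChannelSpec]:
    """The biophysical model's Nav/Kv1/Kv7 channels.

    Nav: single activation gate m and inactivation gate h, k = 5 mV,
    τm* = 150 µs and τh* = 5 ms corrected by Q10 = 2.8 from 23 to 33 °C
    (to 53.6 µs and 1.79 ms); AIS kinetics hyperpolarized by 5 mV.
    Kv1: n⁸ with V₁/₂ = −70 mV, k = 20 mV, τn* = 1 ms, recorded at
    33 °C hence uncorrected.  Kv7: reversal −90 mV on the distal half of
    the AIS; by default a static (open) conductance, since threshold
    modulation depends on the standing current rather than on M-current
    kinetics; with ``kv7_kinetic=True`` a single slow gate q
    (V₁/₂ = −30 mV, k = 9 mV, τ* = 100 ms — nominal M-current values)
    is attached instead.
    """
    tau_m = q10_correct(0.150, T_SIM, T_REF, Q10)
    tau_h = q10_correct(5.0, T_SIM, T_REF, Q10)
    nav_soma = ChannelSpec(
        name="Nav_soma",
        gates=(
            GatingVariable("m", V_half=-30.0, k_slope=5.0, tau_star=tau_m),
            GatingVariable(
                "h", V_half=-60.0, k_slope=5.0, tau_star=tau_h, is_inactivation=True
            ),
        ),
        E_rev=70.0,
        density_map={"soma": 250.0, "dendrite": 50.0, "axon": 50.0},
    )
    nav_ais = ChannelSpec(
        name="Nav_AIS",
        gates=(
            GatingVariable("m", V_half=-35.0, k_slope=5.0, tau_star=tau_m),
            GatingVariable(
                "h", V_half=-65.0, k_slope=5.0, tau_star=tau_h, is_inactivation=True
            ),
        ),
        E_rev=70.0,
        density_map={"ais": g_na_ais},
    )
    kv1 = ChannelSpec(
        name="Kv1",
        gates=(
            GatingVariable("n", V_half=-70.0, k_slope=20.0, tau_star=1.0, exponent=8),
        ),
        E_rev=-90.0,
        density_map={"soma": 250.0, "dendrite": 50.0, "axon": 50.0, "ais": g_k_ais},
    )
    out = {"Nav_soma": nav_soma, "Nav_AIS": nav_ais, "Kv1": kv1}
    if g_kv7_distal_ais > 0:
        gates: tuple[GatingVariable, ...]
        if kv7_kinetic:
            gates = (GatingVariable("q", V_half=-30.0, k_slope=9.0, tau_star=100.0),)
        else:
            gates = ()  # static hyperpolarizing conductance
        out["Kv7"] = ChannelSpec(
            name="Kv7",
            gates=gates,
            E_rev=-90.0,
            density_map={"ais_distal": g_kv7_distal_ais},
        )
    return out


def simplified_nav(
    *, tau_m_ms: float = 0.0536, V_half: float = -35.0, k: float = 5.0,
    ENa: float = 70.0,
) -> ChannelSpec:
    """Point Nav channel of the reduced model: one m gate, fixed τm.

    Non-inactivating, I_Na = G·m·(E_Na − V), dm/dt = (m∞ − m)/τm with
    τm = 53.6 µs (150 µs corrected to 33 °C).  The total conductance is
    assigned where the channel is placed, not via a density map.
    """
    return ChannelSpec(
        name="Nav_point",
        gates=(
            GatingVariable(
                "m", V_half=V_half, k_slope=k, tau_star=tau_m_ms, fixed_tau=True
            ),
        ),
        E_rev=ENa,
        density_map={},
    )
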