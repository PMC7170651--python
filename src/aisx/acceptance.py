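"""Recompute the package's headline quantities from scratch.

Each entry computes one reported number by running the package: the
passive cable constants, the bifurcation constants of the extended-AIS
threshold theory, the geometric threshold-shift predictions for the
packaged plasticity studies, and the voltage-clamp threshold regression
of the reduced cable model.  Values are reported in the units and on
the scale conventional for each quantity.
"""

from __future__ import annotations

import math

from .channels import q10_correct
from .morphology import build_simplified_neuron
from .passive import (
    CableGeometry,
    PassiveMembrane,
    axial_resistance,
    membrane_resistance_segment,
    soma_resistance,
    space_constant,
)
from .protocols import log_slope, voltage_clamp_spike_threshold
from .theory import predict_geometry_shift, solve_rescaled_bifurcation_at_soma

MEM = PassiveMembrane(Cm=0.9, Rm=15_000.0, Ri=100.0, EL=-75.0)
AXON = CableGeometry(d=1.0)


def t1_space_constant() -> tuple[float, int]:
    """Axonal space constant (µm), rounded to the nearest µm."""
    return float(round(space_constant(MEM, AXON))), 1


def t2_soma_resistance() -> tuple[float, int]:
    """Membrane resistance of a 100 µm soma (MΩ), one decimal."""
    return round(soma_resistance(MEM, 100.0), 1), 1


def t3_axial_resistance() -> tuple[float, int]:
    """Axial resistance of 100 µm of 1 µm axon (MΩ), nearest MΩ."""
    return float(round(axial_resistance(MEM, AXON, 100.0))), 1


def t4_membrane_resistance_segment() -> tuple[float, int]:
    """Membrane resistance of a 100 µm axon segment (GΩ), one decimal."""
    return round(membrane_resistance_segment(MEM, AXON, 100.0), 1), 1


def t5_extended_vs_point_offset() -> tuple[float, int]:
    """Threshold offset (mV) between an AIS of length L at the soma and a
    point AIS at Δ = L with equal conductance: (1 + U0)·k at k = 5 mV."""
    bif = solve_rescaled_bifurcation_at_soma()
    return (1.0 + bif.U0) * 5.0, 1


def t6_rescaled_threshold_U0() -> tuple[float, int]:
    """Rescaled somatic threshold U0 at the bifurcation, two decimals."""
    return round(solve_rescaled_bifurcation_at_soma().U0, 2), 1


def t7_bifurcation_constant_c1() -> tuple[float, int]:
    """The constant c1 of the analytical solution, one decimal."""
    return round(solve_rescaled_bifurcation_at_soma().c1, 1), 1


def t8_shift_nucleus_magnocellularis() -> tuple[float, int]:
    """Predicted shift (mV) for chick nucleus magnocellularis plasticity."""
    return round(predict_geometry_shift((9.6, 13.3), (19.5, 18.4), k=5.0), 1), 1


def t9_shift_hippocampal_cultures() -> tuple[float, int]:
    """Predicted shift (mV) for chronically depolarized hippocampal cultures."""
    return round(predict_geometry_shift((34.8, 20.9), (33.6, 27.2), k=5.0), 1), 1


def t10_shift_midpoint_displacement() -> tuple[float, int]:
    """Threshold decrease (mV) for a midpoint displacement 25 → 30 µm."""
    return round(-predict_geometry_shift((40.0, 25.0), (40.0, 30.0), k=5.0), 1), 1


def t11_shift_elongation() -> tuple[float, int]:
    """Threshold decrease (mV) for elongation 40 → 50 µm of a proximal AIS
    (length and midpoint terms combined: 2k·ln(50/40))."""
    return round(-predict_geometry_shift((40.0, 20.0), (50.0, 25.0), k=5.0), 1), 1


def t12_simplified_position_slope() -> tuple[float, int]:
    """Log-slope (mV per e-fold) of the voltage-clamp threshold against AIS
    position in the reduced point-Nav cable model, averaged over total
    conductances 200/400/600 nS; positions 5–30 µm."""
    positions = [5.0, 10.0, 15.0, 20.0, 25.0, 30.0]
    slopes = []
    n = 0
    for G in (200.0, 400.0, 600.0):
        thr = []
        for pos in positions:
            model = build_simplified_neuron(ais_position_um=pos, G_nS=G)
            thr.append(voltage_clamp_spike_threshold(model))
            n += 1
        slopes.append(log_slope(positions, thr, parameter="position").slope_mV)
    return sum(slopes) / len(slopes), n


TARGETS = {
    "t1": t1_space_constant,
    "t2": t2_soma_resistance,
    "t3": t3_axial_resistance,
    "t4": t4_membrane_resistance_segment,
    "t5": t5_extended_vs_point_offset,
    "t6": t6_rescaled_threshold_U0,
    "t7": t7_bifurcation_constant_c1,
    "t8": t8_shift_nucleus_magnocellularis,
    "t9": t9_shift_hippocampal_cultures,
    "t10": t10_shift_midpoint_displacement,
    "t11": t11_shift_elongation,
    "t12": t12_simplified_position_slope,
}


def run_all(seed: int = 0) -> dict[str, dict[str, float]]:
    """Compute every target; the pipeline is fully deterministic, so the
    seed only pins down any future stochastic additions."""
    del seed  # no stochastic component in the current targets
    out = {}
    for key, fn in TARGETS.items():
        value, n = fn()
        out[key] = {"value": float(value), "n": int(n)}
    return out
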