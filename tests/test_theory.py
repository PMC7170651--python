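"""Spike-threshold theory: bifurcation constants, oracles, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from aisx.passive import CableGeometry, PassiveMembrane, axial_resistance_per_unit_length
from aisx.theory import (
    AISGeometry,
    NavTheoryParams,
    NoBifurcationError,
    axo_axonic_displacement_shift,
    corrective_term_F,
    distal_load_threshold_shift,
    effective_Ra_with_conductance,
    electrical_equivalence_scaling,
    extended_ais_threshold,
    extended_ais_threshold_numeric,
    point_ais_threshold,
    predict_geometry_shift,
    solve_general_bifurcation,
    solve_rescaled_bifurcation_at_soma,
    threshold_formula,
)

NAV = NavTheoryParams(k=5.0, V_half=-35.0, ENa=70.0)
MEM = PassiveMembrane()


class TestRescaledBifurcation:
    def test_constants_at_soma(self):
        b = solve_rescaled_bifurcation_at_soma()
        assert b.z == pytest.approx(1.1997, abs=1e-4)
        assert b.z * math.tanh(b.z) == pytest.approx(1.0, abs=1e-12)
        assert b.c1 == pytest.approx(5.757, abs=1e-3)
        assert b.U0 == pytest.approx(-0.13, abs=0.005)
        assert b.U1 == pytest.approx(1.057, abs=1e-3)

    def test_ais_end_sits_about_1p2k_above_soma(self):
        b = solve_rescaled_bifurcation_at_soma()
        assert b.U1 - b.U0 == pytest.approx(1.19, abs=0.01)

    def test_general_reduces_to_soma_case(self):
        a = solve_rescaled_bifurcation_at_soma()
        b = solve_general_bifurcation(0.0)
        assert b.z == a.z and b.U0 == a.U0

    def test_point_limit_F_vanishes(self):
        assert corrective_term_F(100.0) < 0.01

    def test_F_at_soma_and_monotone(self):
        assert corrective_term_F(0.0) == pytest.approx(0.177, abs=0.005)
        ratios = np.linspace(0.0, 10.0, 41)
        F = [corrective_term_F(r) for r in ratios]
        assert np.all(np.diff(F) < 0)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            solve_general_bifurcation(-0.1)


class TestPointAIS:
    def test_soma_exactly_k_below_ais(self):
        pt = point_ais_threshold(NAV, Ra=31.8, G=350.0)
        assert pt.V_ais - pt.V_soma == pytest.approx(NAV.k, abs=1e-12)

    @given(st.floats(1.2, 4.0))
    @settings(max_examples=30, deadline=None)
    def test_logarithmic_additivity_in_G(self, factor):
        a = point_ais_threshold(NAV, Ra=30.0, G=300.0).V_soma
        b = point_ais_threshold(NAV, Ra=30.0, G=300.0 * factor).V_soma
        assert a - b == pytest.approx(NAV.k * math.log(factor), rel=1e-9)

    def test_brute_force_fold_oracle(self, rng):
        """The closed form matches the fold of V − Ra·G·D·e^{(V−V₁/₂)/k}.

        The somatic threshold is the maximum over the axonal voltage V of
        Vs(V) = V − Ra·G·(E_Na − V₁/₂)·e^{(V−V₁/₂)/k}; locate it by a
        dense scan plus parabolic refinement, independently of the
        logarithmic formula.
        """
        D = NAV.ENa - NAV.V_half
        for _ in range(20):
            Ra = float(rng.uniform(5.0, 150.0))
            G = float(rng.uniform(100.0, 800.0))
            pt = point_ais_threshold(NAV, Ra=Ra, G=G)
            v = np.linspace(-90.0, -20.0, 200_001)
            vs = v - Ra * G * 1e-3 * D * np.exp((v - NAV.V_half) / NAV.k)
            i = int(np.argmax(vs))
            a, b, c = vs[i - 1], vs[i], vs[i + 1]
            vmax = b + (a - c) ** 2 / (8 * (2 * b - a - c))  # parabolic peak
            assert pt.V_soma == pytest.approx(vmax, abs=1e-4)

    def test_no_bifurcation_condition(self):
        with pytest.raises(NoBifurcationError):
            point_ais_threshold(NAV, Ra=0.01, G=1.0)
        with pytest.raises(NoBifurcationError):
            # with the exact driving force the fold only disappears for a
            # far weaker axial coupling (Ra·G·e^{(ENa−V½)/k−2} < 1)
            point_ais_threshold(NAV, Ra=1e-4, G=0.01, exact_driving_force=True)

    def test_exact_driving_force_close_to_approximate(self):
        approx = point_ais_threshold(NAV, Ra=31.8, G=350.0)
        exact = point_ais_threshold(NAV, Ra=31.8, G=350.0, exact_driving_force=True)
        # exact fold sits slightly below; gap slightly above k
        assert abs(exact.V_soma - approx.V_soma) < 1.5
        assert exact.V_ais - exact.V_soma > NAV.k


def _shooting_threshold(delta_um, L_um, g_Sm2, d_um=1.0, nav=NAV, mem=MEM):
    """Somatic threshold by dimensional shooting, independent of rescaling.

    Integrates V'' = −(4·Ri/d)·g·(E_Na − V₁/₂)/k-free exponential … more
    precisely V'' = −r_a·π·d·g·(E_Na − V₁/₂)·e^{(V−V₁/₂)/k} (SI) from the
    sealed AIS end backwards, maps through the resistive stub to the
    soma, and locates the fold by maximizing over the end voltage.
    """
    ri = mem.Ri * 1e-2  # Ω·m
    d = d_um * 1e-6
    ra = 4.0 * ri / (math.pi * d * d)  # Ω/m
    A = ra * math.pi * d * g_Sm2 * (nav.ENa - nav.V_half)  # mV/m²
    L = L_um * 1e-6
    delta = delta_um * 1e-6
    k = nav.k

    def soma_value(v_end):
        def rhs(x, y):
            return [y[1], -A * math.exp((y[0] - nav.V_half) / k)]

        sol = solve_ivp(
            rhs, (L, 0.0), [v_end, 0.0], rtol=1e-10, atol=1e-10, dense_output=False
        )
        v0, vp0 = sol.y[0][-1], sol.y[1][-1]
        return v0 - delta * vp0

    res = minimize_scalar(
        lambda v: -soma_value(v),
        bounds=(nav.V_half - 60.0, nav.V_half + 10.0),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return -res.fun


class TestExtendedAIS:
    def test_midpoint_correction_identity(self):
        """Analytic threshold minus midpoint point-AIS rule equals k·F(Δ/L)."""
        for ratio in np.linspace(0.0, 20.0, 9):
            L = 30.0
            geom = AISGeometry(delta=ratio * L, L=L, d=1.0, g=3500.0)
            ext = extended_ais_threshold(NAV, MEM, geom)
            assert ext.correction_mV == pytest.approx(
                NAV.k * corrective_term_F(ratio), abs=1e-9
            )

    def test_shooting_bvp_oracle(self, rng):
        """Closed form matches an independent shooting solution to 0.01 mV."""
        for _ in range(10):
            delta = float(rng.uniform(0.0, 40.0))
            L = float(rng.uniform(10.0, 60.0))
            g = float(rng.uniform(1000.0, 8000.0))
            geom = AISGeometry(delta=delta, L=L, d=1.0, g=g)
            ext = extended_ais_threshold(NAV, MEM, geom)
            oracle = _shooting_threshold(delta, L, g)
            assert ext.V_soma == pytest.approx(oracle, abs=0.01)

    def test_numeric_matches_analytic_without_end_current(self):
        geom = AISGeometry(delta=7.0, L=25.0, d=1.0, g=4000.0)
        num = extended_ais_threshold_numeric(NAV, MEM, geom)
        assert num == pytest.approx(extended_ais_threshold(NAV, MEM, geom).V_soma,
                                    abs=1e-6)

    def test_end_current_raises_threshold_nearly_linearly(self):
        """Hyperpolarizing current at the AIS end raises the somatic
        threshold, close to (but not exactly) the linear −Ra·I estimate."""
        geom = AISGeometry(delta=10.0, L=30.0, d=1.0, g=3500.0)
        base = extended_ais_threshold_numeric(NAV, MEM, geom)
        shifts = []
        for I in (-100.0, -200.0):
            v = extended_ais_threshold_numeric(NAV, MEM, geom, I_end_pA=I)
            shifts.append(v - base)
        ra = axial_resistance_per_unit_length(MEM, CableGeometry(d=1.0))
        lin = ra * (geom.delta + geom.L) * 100.0 * 1e-3  # MΩ·pA → mV
        assert shifts[0] > 0
        assert shifts[0] == pytest.approx(lin, rel=0.5)
        # approximate linearity in I
        assert shifts[1] == pytest.approx(2 * shifts[0], rel=0.2)

    def test_offset_to_point_ais_at_L(self):
        """Extended AIS at the soma vs point AIS at Δ = L, same G: 0.87k."""
        L = 30.0
        geom = AISGeometry(delta=0.0, L=L, d=1.0, g=3500.0)
        ext = extended_ais_threshold(NAV, MEM, geom)
        ra = axial_resistance_per_unit_length(MEM, CableGeometry(d=1.0))
        pt = point_ais_threshold(NAV, Ra=ra * L, G=geom.total_conductance_nS)
        # the extended AIS is equivalent to a point AIS at 0.42·L, hence its
        # threshold sits 0.87k above the point AIS placed at L itself
        assert ext.V_soma - pt.V_soma == pytest.approx(0.8704 * NAV.k, abs=0.01)

    def test_equivalent_point_position(self):
        """The extended AIS behaves as a point AIS at ≈0.42·L."""
        L = 30.0
        geom = AISGeometry(delta=0.0, L=L, d=1.0, g=3500.0)
        ext = extended_ais_threshold(NAV, MEM, geom)
        ra = axial_resistance_per_unit_length(MEM, CableGeometry(d=1.0))
        x_eq = math.exp(-0.8704) * L
        pt = point_ais_threshold(NAV, Ra=ra * x_eq, G=geom.total_conductance_nS)
        assert pt.V_soma == pytest.approx(ext.V_soma, abs=1e-3)
        assert x_eq / L == pytest.approx(0.419, abs=0.002)

    def test_compression_invariance_at_fixed_midpoint(self):
        """Compressing/extending about x₁/₂ at fixed G moves the threshold
        by at most ≈0.9 mV (the |k·F| bound)."""
        x_half, G = 25.0, 350.0
        thresholds = []
        for L in np.linspace(10.0, 2 * x_half, 11):
            delta = x_half - L / 2.0
            g = G / (math.pi * 1.0 * L * 1e-3)
            geom = AISGeometry(delta=delta, L=L, d=1.0, g=g)
            thresholds.append(extended_ais_threshold(NAV, MEM, geom).V_soma)
        assert max(thresholds) - min(thresholds) <= 0.9 + 1e-6

    def test_threshold_monotonicity(self):
        """Threshold decreases with g, L and x₁/₂ and increases with d."""
        base = dict(delta=10.0, L=30.0, d=1.0, g=3500.0)

        def vs(**kw):
            return extended_ais_threshold(NAV, MEM, AISGeometry(**{**base, **kw})).V_soma

        gs = [vs(g=g) for g in (2000.0, 3000.0, 4500.0, 7000.0)]
        assert np.all(np.diff(gs) < 0)
        Ls = [vs(L=L) for L in (15.0, 25.0, 35.0, 45.0)]
        assert np.all(np.diff(Ls) < 0)
        xs = [vs(delta=d0) for d0 in (2.0, 10.0, 20.0, 40.0)]
        assert np.all(np.diff(xs) < 0)
        ds = [vs(d=d0) for d0 in (0.5, 1.0, 2.0, 3.0)]
        assert np.all(np.diff(ds) > 0)


class TestGeometricFormula:
    def test_worked_examples(self):
        # midpoint displacement 25 -> 30 µm lowers the threshold by ~0.9 mV
        a = AISGeometry(delta=5.0, L=40.0, d=1.0, g=3500.0)  # x1/2 = 25
        b = AISGeometry(delta=10.0, L=40.0, d=1.0, g=3500.0)  # x1/2 = 30
        assert threshold_formula(NAV, b, a) == pytest.approx(
            -5.0 * math.log(30.0 / 25.0), rel=1e-12
        )
        # elongation 40 -> 50 with Δ = 0: combined ≈ −2.2 mV
        a = AISGeometry(delta=0.0, L=40.0, d=1.0, g=3500.0)
        b = AISGeometry(delta=0.0, L=50.0, d=1.0, g=3500.0)
        assert threshold_formula(NAV, b, a) == pytest.approx(-2.23, abs=0.01)
        # d ×3 with L ×√3 at fixed midpoint: +(k/2)·ln 3 ≈ +2.7 mV
        s3 = math.sqrt(3.0)
        a = AISGeometry(delta=40.0 - 15.0, L=30.0, d=1.0, g=3500.0)  # x1/2 = 40
        b = AISGeometry(delta=40.0 - 15.0 * s3, L=30.0 * s3, d=3.0, g=3500.0)
        assert b.x_half == pytest.approx(a.x_half)
        assert threshold_formula(NAV, b, a) == pytest.approx(
            2.5 * math.log(3.0), rel=1e-9
        )
        assert 2.5 * math.log(3.0) == pytest.approx(2.75, abs=0.01)

    @given(
        f1=st.floats(0.5, 2.0),
        f2=st.floats(0.5, 2.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_shift_additivity(self, f1, f2):
        """Log-shifts compose: shift(a→c) = shift(a→b) + shift(b→c)."""
        a = AISGeometry(delta=10.0, L=20.0, d=1.0, g=3000.0)
        b = AISGeometry(delta=10.0 * f1, L=20.0 * f1, d=1.0, g=3000.0)
        c = AISGeometry(delta=10.0 * f1 * f2, L=20.0 * f1 * f2, d=1.0, g=3000.0)
        ab = threshold_formula(NAV, b, a)
        bc = threshold_formula(NAV, c, b)
        ac = threshold_formula(NAV, c, a)
        assert ac == pytest.approx(ab + bc, abs=1e-9)


class TestPlasticityPredictions:
    @pytest.mark.parametrize(
        "initial,final,expected",
        [
            ((9.6, 13.3), (19.5, 18.4), -5.2),
            ((34.8, 20.9), (33.6, 27.2), -1.1),
            ((19.2, 10.4), (15.7, 7.85), 2.4),
            ((11.7, 21.1), (14.2, 15.5), 0.6),
            ((30.3, 24.8), (23.9, 19.9), 2.3),
            ((28.8, 24.8), (14.4, 28.3), 2.8),
            ((26.5, 26.6), (9.8, 50.1), 1.8),
        ],
    )
    def test_study_rows(self, initial, final, expected):
        assert round(predict_geometry_shift(initial, final, k=5.0), 1) == expected

    def test_identity_geometry(self):
        assert predict_geometry_shift((20.0, 15.0), (20.0, 15.0)) == 0.0


class TestCurrentsAndLoads:
    def test_zero_current_no_shift(self):
        from aisx.theory import threshold_shift_from_current

        assert threshold_shift_from_current(30.0, 0.0) == 0.0

    def test_hyperpolarizing_current_raises_threshold(self):
        from aisx.theory import threshold_shift_from_current

        assert threshold_shift_from_current(30.0, -100.0) == pytest.approx(3.0)

    def test_axo_axonic_displacement(self):
        assert axo_axonic_displacement_shift(3.0, 55.0, 65.0) == pytest.approx(
            10.0 / 55.0 * 3.0
        )

    def test_effective_Ra(self):
        assert effective_Ra_with_conductance(40.0, 0.0) == 40.0
        assert effective_Ra_with_conductance(40.0, 1.0 / 40.0) == pytest.approx(20.0)

    def test_small_shunt_negligible_on_threshold(self):
        Ra = 30.0
        base = point_ais_threshold(NAV, Ra, 350.0).V_soma
        shunted = point_ais_threshold(
            NAV, effective_Ra_with_conductance(Ra, 0.04 / Ra), 350.0
        ).V_soma
        assert abs(shunted - base) < 0.05 * NAV.k

    def test_distal_load_shift(self, mem):
        shift = distal_load_threshold_shift(mem, 1.0, Ra_end=95.0, Va=-55.0)
        assert shift == pytest.approx(2.4, abs=0.05)
        halved = distal_load_threshold_shift(
            mem, 1.0, Ra_end=95.0, Va=-55.0, myelin_factor=4.0
        )
        assert halved == pytest.approx(shift / 2.0, rel=1e-9)
        assert distal_load_threshold_shift(mem, 1.0, Ra_end=95.0, Va=mem.EL) == 0.0


class TestDimensionalScaling:
    def test_power_law_exponent(self):
        d1 = electrical_equivalence_scaling(30.0)
        d2 = electrical_equivalence_scaling(60.0)
        assert d2 / d1 == pytest.approx(2.0 ** (4.0 / 3.0), rel=1e-12)
        assert d1 == pytest.approx(1.0)

    def test_log_residuals_of_packaged_means(self):
        """Report-style check: residuals from the 4/3 law are finite and the
        law anchored at (30 µm, 1 µm) brackets the observed diameters."""
        from aisx.repro import load_diameter_data

        df = load_diameter_data()
        pred = [electrical_equivalence_scaling(ds) for ds in df.soma_diameter_um]
        resid = np.log(df.ais_diameter_um.to_numpy()) - np.log(pred)
        assert np.all(np.isfinite(resid))
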