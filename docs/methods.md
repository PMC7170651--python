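# Methods

This note documents the models, numerical methods and protocol choices
behind `aisx`, and what the synthetic test models do and do not show
about real neurons.

## The physical picture

The axon initial segment (AIS) is the proximal stretch of axon where
action potentials start, carrying a high density of Nav channels.  In
most neurons the somatodendritic compartment is electrically large
compared with the thin axon, so at the time scale of spike initiation
the soma behaves as a current sink at fixed potential (the *resistive
coupling* regime): the Na⁺ current entering the AIS flows to the soma
as an Ohmic current across the axial resistance Ra of the proximal
axon.  Two consequences drive the whole package:

1. The **somatic voltage threshold** — the largest somatic potential
   that does not trigger a spike — is a bifurcation parameter of the
   axonal subsystem.  It depends on axonal quantities only (AIS
   geometry, Nav density, standing axonal currents) and not on somatic
   leak or dendritic load, which makes it the right excitability
   measure for AIS structural plasticity.
2. Because the Na⁺ current grows ~exponentially with voltage below
   threshold (e-fold per Boltzmann slope k ≈ 5 mV), every AIS factor
   enters the threshold logarithmically:

   Vs = const − k·ln g − k·ln L − k·ln x½ + k·ln d − Ra·I

   with g the Nav surface density, L the AIS length, x½ = Δ + L/2 the
   AIS midpoint, d the axon diameter and I a standing current at the
   AIS (I < 0 raises the threshold).

## Passive cable module

Closed forms are the standard semi-infinite-cable results: space
constant λ = √(Rm·d/4Ri), axial resistance per length r_a = 4Ri/(πd²),
input resistance at distance x from a sealed end r_aλ/(1 + tanh x/λ),
from a killed end r_aλ·tanh(x/λ)/(1 + tanh x/λ), and for a finite
spherical soma the parallel combination (r_a·x + R_soma) ∥ R_distal.
The finite-soma form neglects membrane leak along the proximal stub; it
agrees with the discretized solver to <2% for x ≲ λ/5 (the AIS-relevant
regime) and degrades slowly beyond.  The killed ≤ finite-soma ≤ sealed
ordering likewise holds on the proximal axon (asserted for x ≤ λ); at
x ≫ λ a finite soma adds a conducting path that a sealed end lacks, so
the ordering genuinely reverses there.  A `coth` correction for finite
axon length is available and used when comparing against the 2-mm
simulated axon.

## Threshold theory

*Point AIS.*  Setting the exponential Na⁺ current equal to the axial
current and locating the fold gives V_ais = V½ − k·ln(Ra·G·(ENa−V½)/k)
and Vs = V_ais − k.  The driving force is approximated by (ENa − V½);
an `exact_driving_force` option locates the fold of the full equation
numerically, moving the threshold by ~1 mV and widening the soma–AIS
gap slightly above k.  When Ra·G·(ENa−V½)/k ≤ 1 the formula would place
the fold above V½, where the exponential approximation has no kink; the
package reports this as a typed `NoBifurcationError` rather than a
number.

*Extended AIS.*  The stationary cable equation V″ ∝ −g·e^{V/k} rescales
to U″ + e^U = 0 on the unit interval, with analytical solution
U(y) = ln(c₁/2) − 2·ln cosh(½√c₁(y−1)).  The sealed end fixes one
constant; the somatic boundary condition U(0) − (Δ/L)U′(0) = U0 defines
U0(c₁), and the fold is found by setting dU0/dc₁ = 0, which reduces to
(1+r)·z·tanh z + r·z²·(1−tanh²z) = 1 with r = Δ/L and z = √c₁/2.  The
root is bracketed on z ∈ (0, 10], where the left side is strictly
increasing, and solved by Brent's method to residual <1e-12.  At r = 0:
z ≈ 1.1997, c₁ = 4z² ≈ 5.76, U0 ≈ −0.1296, and the rescaled AIS-end
potential U1 = ln(c₁/2) ≈ 1.057 — the AIS end sits ≈1.2k above the
somatic threshold.  The threshold of the extended AIS equals that of a
point AIS with the same total conductance at the midpoint x½ up to
k·F(Δ/L), F(r) = U0(r) + 1 + ln(r + ½), which decreases monotonically
from ≈0.177 to 0 — hence the midpoint rule is accurate to ≲0.9 mV at
k = 5 mV.

Currents at the AIS start shift the somatic threshold by −Ra·I exactly
(the axonal profile at threshold is unchanged).  For current at the AIS
end no closed form exists; the package solves the rescaled equation
with the boundary slope U′(1) = r_a·I·L/k by backward RK4 integration
and locates the fold by bounded maximization over the end value.  The
same routine with I = 0 reproduces the closed form to ~1e-13 mV and
serves as an internal cross-check; the test suite additionally checks
the closed form against a fully dimensional shooting solution built on
`scipy.integrate.solve_ivp`.

## Channel kinetics

Gates use the three-parameter rate functions whose steady state is a
Boltzmann in (V½, k) and whose time constant is a bell peaking at V½
with value τ*: α = (u/2τ*)/(1−e^{−u}), β = (u/2τ*)/(e^{u}−1) with
u = (V−V½)/k (rates swapped for inactivation).  The removable
singularity at u = 0 is evaluated by series for |u| < 1e-6.  Nav rates
measured at 23 °C are divided by Q10^{(33−23)/10} with Q10 = 2.8
(τm* 150 → 53.6 µs, τh* 5 → 1.79 ms); Kv1 parameters were obtained at
33 °C and are not corrected.  Kv1 uses n⁸ (V½ = −70 mV, k = 20 mV,
τ* = 1 ms) so that the K⁺ current activates with a delay and barely
overlaps the Na⁺ current at initiation.

Kv7 (M-current) at the distal half of the AIS is modelled by default as
a static conductance with reversal −90 mV: the threshold effects under
study depend on the standing hyperpolarizing current, not on M-current
kinetics.  A single slow gate (V½ = −30 mV, k = 9 mV, τ* = 100 ms —
nominal M-current values, explicitly assumed rather than fitted) can be
enabled for qualitative work.

## Compartmental solver

Morphologies are trees of cylindrical sections plus a spherical soma
treated as one isopotential compartment of area π·dS²; coupling between
compartments is 1/(half-resistance + half-resistance), with the soma
contributing no half-resistance (the child's first half-compartment
carries the full coupling).  The voltage step is backward Euler: a
symmetric tree-structured linear system solved by leaf-to-root (Hines)
elimination in O(N), unconditionally stable for the passive subsystem;
gating variables are advanced by exact exponential relaxation toward
x∞(V^n) within each step, operator-split from the voltage solve.
Voltage clamp is an ideal Dirichlet constraint imposed by a diagonal
penalty (clamp error ~1e-9 mV); the electrode current is reported from
the nodal current balance.  Kernels are numba-compiled; units are
mV/ms/µS/nA/nF throughout the solver.

Default discretization: dx = 1 µm on the proximal 100 µm of axon
(including the AIS), 10 µm on the dendrite and distal axon; dt = 5 µs
for active models and 100 µs (25 µs during holding equilibration) for
passive work.  Halving dt and dx moves the measured biophysical
threshold by <0.01 mV.

The biophysical model is a 30 µm soma, 6 µm × 1 mm dendrite and
1 µm × 500 µm unmyelinated axon with the AIS at 5–35 µm (g_Na 3500,
g_Kv1 1500 S/m² at the AIS; 250/250 at the soma; 50/50 elsewhere; Nav
kinetics 5 mV hyperpolarized at the AIS).  Variants: thick axon (d = 3
µm) with the soma rescaled by the electrical-equivalence law dS ∝ d^¾
and AIS lengths scaled by √d; long axon (1 mm); myelin beyond the AIS
end (Rm ×4, Cm /4 — myelin must begin at the AIS end, otherwise the
intervening bare axon dilutes the distal-load effect); distal
bifurcation with d_parent^p = 2·d_child^p for p = 3/2 (electrically
equivalent) or 5/2; and an axon-bearing dendrite (2 µm stem splitting
after 7 µm per the 3/2 law, one branch carrying the axon — branch
lengths 300 µm, a package choice).  The reduced model is a 50 µm soma
with a passive 1 µm × 300 µm axon and a point Nav conductance
(m-gate only, fixed τm = 53.6 µs); note its rest is defined under
somatic voltage clamp — free of the clamp the standing Na⁺ current
through m∞(E_L)·G makes the resting state only marginally stable.

## Threshold protocols

*Current clamp.*  The soma is held at −75 mV by an ideal clamp until
drift <1e-6 mV/ms, the clamp current is recorded, and trials run in
current clamp with that holding current plus a 100 ms step (50 ms in
the scaled-down sweeps; the threshold is insensitive to duration).  A
spike is an AIS-end crossing of −20 mV — insensitive within [−30, 0] mV
given the >60 mV spike amplitude.  Rheobase is bisected to 0.25 pA
(configurable).

*Threshold evaluation.*  The voltage threshold is the maximal potential
in a non-spiking trial.  Near rheobase this statistic is singular: the
subthreshold maximum rises like √(rheobase − I), so "the largest
non-spiking bisection trial" sits at an amplitude that varies
erratically within the tolerance and, in the inactivating model, the
near-critical lingering lets Nav inactivation creep, amplifying the
noise.  The package therefore evaluates the threshold trial at a fixed
margin (default 1 pA, ≈0.1% of rheobase) below the resolved rheobase.
This leaves a small uniform bias (~0.3 mV below the exact fold) and
makes the estimate reproducible: tolerance 0.5 vs 0.1 pA then agree to
<0.1 mV in the biophysical model, and dt/dx refinement moves it by
<0.01 mV.  Sensitivity to the margin and tolerance are exercised in the
tests.

*Voltage clamp (reduced model).*  The somatic command climbs a
staircase (0.5 mV coarse scan, then 0.05 mV steps from the last settled
subthreshold state, 20 ms per step) until half of the point-AIS Nav
gates open; the threshold is the last subthreshold command.  20 ms per
step is long against τm = 54 µs and against the membrane time constant,
so the climb is quasi-static.

*Early-time input resistance.*  Following dual-recording practice, the
depolarization "at 300 µs" is the median over [200, 400] µs after the
pulse minus the median over the 5 ms before it, divided by the current.
The synthetic two-site fixture generates exponential charges with
distinct time constants plus seeded Gaussian noise; its ground truth
includes the exact window value of the noise-free statistic, so the
recovery tests separate estimator bias (finite τ within the window)
from noise.

*Regressions.*  Thresholds are regressed against the natural log of the
swept parameter (ordinary least squares); slopes are reported in mV per
e-fold, directly comparable to k.

## Scaled-down sweep grids

Simulation sweeps use 4–6 points per parameter centred on the standard
configurations: g ∈ [3500, 6500] S/m², x½ ∈ [20, 35] µm, L ∈ [20, 40]
µm, G ∈ [200, 600] nS, AIS positions 5–30 µm.  Configurations with a
weak, proximal AIS (total conductance ≲250 nS within ~15 µm of the
soma) are outside these grids: there the quasi-static approach to
threshold drives Nav inactivation into a runaway (the threshold rises,
which inactivates further), the AIS response becomes graded rather than
all-or-none, and a voltage threshold stops being well defined — a real
property of the model worth knowing about, not a solver artifact.

## What the synthetic models do and do not show

All quantitative checks run on the package's own idealized morphologies
with uniform channel densities, two Nav/Kv species, no stochastic
gating, cylindrical sections and an isopotential soma.  Passing them
shows the theory, solver and protocols are mutually consistent and
reproduce the reference constants under these idealizations.  They do
not show that real neurons have k = 5 mV, density-independent
inactivation, or uniform AIS composition; in real recordings the
geometric slopes are expected to differ from k in the same direction
the biophysical model already shows (steeper for g, near k for
geometry).

## Known limitations

- No tapered sections, extracellular fields, or stochastic channels;
  temperature enters only through Q10 on rates.
- The analytical theory takes the available Nav conductance as given;
  it does not model inactivation dynamics, which in the biophysical
  model steepen the threshold–conductance relation (slope ≈8 mV per
  e-fold instead of k = 5).
- The Kv7 gate parameters are nominal assumptions; only the
  static-conductance variant is quantitative.
- The finite-soma closed form and the killed/sealed bracketing are
  proximal-axon approximations (x ≲ λ).
- One ideal voltage clamp at a time; no series-resistance model.
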