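# aisx — axon initial segment geometry and neuronal excitability

`aisx` is a toolkit for the biophysics of spike initiation at the axon
initial segment (AIS): how the position, length, diameter and Nav
channel density of the AIS — and standing axonal currents such as the
Kv7 M-current — set a neuron's voltage threshold.  It is aimed at
cellular neurophysiologists and modellers studying AIS structural
plasticity.

The package contains four connected layers:

- **Passive cable theory** of the soma–AIS system: space constant
  λ = √(Rm·d/4Ri), axial resistance per length r_a = 4Ri/(πd²), and
  input resistance under sealed-end, killed-end and finite-soma
  boundary conditions — the quantities that decide whether the soma
  acts as a current sink for the axon (the *resistive coupling* regime).
- **Analytical spike-threshold theory.**  Treating spike initiation as
  a fold bifurcation of the axonal voltage profile with the somatic
  potential as control parameter gives, for a point AIS at axial
  resistance Ra with conductance G,

      Vs = V½ − k − k·ln(Ra·G·(ENa − V½)/k),

  and for a spatially extended AIS (start Δ, length L, density g,
  diameter d) the closed-form generalization via the rescaled cable
  equation U″ + e^U = 0, leading to the compact geometric law

      Vs = const − k·ln g − k·ln L − k·ln x½ + k·ln d − Ra·I,

  with x½ = Δ + L/2 the AIS midpoint and k the Nav Boltzmann slope.
  An extended AIS is equivalent to a point AIS at its midpoint up to a
  corrective term k·F(Δ/L) ≤ 0.17k ≈ 0.9 mV.
- **A branched compartmental Hodgkin–Huxley simulator** (backward-Euler
  tree solver with numba kernels, exact-exponential gating updates,
  ideal voltage clamp) with builders for the passive, reduced
  (point-Nav) and full biophysical morphologies and their variants
  (thick axon, myelin, branching, axon-bearing dendrite).
- **Measurement protocols**: rheobase bisection and somatic/AIS voltage
  threshold in current clamp, voltage-clamp threshold for the reduced
  model, early-time (300 µs) input resistance from two-site traces, and
  log-slope regressions that report threshold sensitivities in mV per
  e-fold for direct comparison with k.

`docs/methods.md` describes the models, numerics and protocol design in
detail.

## Worked example

Analytical threshold for the standard configuration — a 1 µm axon with
an AIS extending from 5 to 35 µm carrying 3500 S/m² of Nav conductance
(k = 5 mV, V½ = −35 mV, ENa = 70 mV):

```bash
$ aisx theory --delta 5 --length 30 --gdensity 3500
{
 "Vs_soma": -65.02646009116663,
 "Vs_ais": -59.135924681397626,
 "F": 0.16746212533936705,
 "z": 1.0293665030292032,
 "U0": -0.4270727665524685,
 "midpoint_rule_Vs": -65.86377071786345
}
```

`Vs_soma` is the somatic spike threshold (mV) and `Vs_ais` the voltage
at the AIS end at threshold — the AIS end sits ≈1.2k above the soma.
`midpoint_rule_Vs` is the threshold of an equivalent point AIS with the
same total conductance (330 nS) placed at the midpoint x½ = 20 µm; the
two differ by k·F(Δ/L) = 0.84 mV, with `F` the corrective term and
`z`, `U0` the constants of the underlying bifurcation problem.

The same library calls are available in Python:

```python
from aisx import (AISGeometry, NavTheoryParams, PassiveMembrane,
                  extended_ais_threshold, predict_geometry_shift)

ext = extended_ais_threshold(NavTheoryParams(), PassiveMembrane(),
                             AISGeometry(delta=5, L=30, d=1, g=3500))
ext.V_soma                      # -65.03 mV
predict_geometry_shift((9.6, 13.3), (19.5, 18.4), k=5.0)   # -5.17 mV
```

The second call predicts the threshold change when an AIS elongates
from 9.6 to 19.5 µm with its midpoint moving from 13.3 to 18.4 µm
(auditory-deprivation plasticity in chick nucleus magnocellularis):
−5.2 mV, i.e. a more excitable neuron.

Simulation-side, `aisx threshold <config.toml>` measures rheobase and
voltage threshold of a configured compartmental model, `aisx sweep`
runs threshold sweeps, and `aisx repro fig9` (etc.) regenerates the
package's reference figures and tables as CSV + PNG.

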