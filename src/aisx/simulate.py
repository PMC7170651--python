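"""Time integration of compartmental models and steady-state utilities.

:func:`integrate` advances a discretized model under a list of stimuli
(current-clamp steps and ideal voltage clamps) with the implicit
backward-Euler tree solver; :func:`steady_state_init` prepares the
standard initial condition used by the threshold protocols (relax with
the soma clamped at a holding potential, record the clamp current,
release to current clamp); :func:`passive_steady_state` solves the
stationary linear system of a passive model directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import spsolve

from . import _kernels
from .morphology import DiscretizedNeuron, IntegrationError

__all__ = [
    "Stimulus",
    "SimResult",
    "SimState",
    "integrate",
    "run_state",
    "steady_state_init",
    "passive_steady_state",
    "clamp_current",
    "IntegrationError",
]


@dataclass(frozen=True)
class Stimulus:
    """A current step or an ideal voltage clamp at one compartment.

    kind "step": constant current ``amplitude_pA`` over
    [onset_ms, onset_ms + duration_ms].  kind "clamp": Dirichlet clamp
    at ``command_mV`` over the same window (one clamp at a time).
    """

    kind: str  # "step" | "clamp"
    section: str
    x_um: float = 0.0
    amplitude_pA: float = 0.0
    command_mV: float = 0.0
    onset_ms: float = 0.0
    duration_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("step", "clamp"):
            raise ValueError("stimulus kind must be 'step' or 'clamp'")
        if self.duration_ms <= 0:
            raise ValueError("stimulus duration must be positive")


@dataclass
class SimResult:
    t_ms: np.ndarray
    V: dict[str, np.ndarray]  # probe label → mV trace
    gates: dict[str, np.ndarray] = field(default_factory=dict)  # (gate, probe) traces
    currents: dict[str, np.ndarray] = field(default_factory=dict)  # nA at probes
    stopped: bool = False
    t_stop_ms: float | None = None


@dataclass
class SimState:
    """Voltage and gating state of a discretized model."""

    V: np.ndarray
    x: np.ndarray

    def copy(self) -> "SimState":
        return SimState(self.V.copy(), self.x.copy())


def initial_state(disc: DiscretizedNeuron, V0: float | None = None) -> SimState:
    v0 = disc.model.membrane.EL if V0 is None else V0
    return SimState(np.full(disc.N, v0), disc.resting_gates(v0))


def run_state(
    disc: DiscretizedNeuron,
    state: SimState,
    t_ms: float,
    dt_ms: float,
    *,
    istim_pA: np.ndarray | None = None,
    clamp: tuple[int, float] | None = None,
    probes: dict[str, int] | None = None,
    rec_every: int = 1,
    rec_gates: bool = False,
    stop: tuple[int, int, int, float] | None = None,
) -> SimResult:
    """Advance ``state`` in place for t_ms under constant stimulation.

    ``istim_pA`` is a per-compartment constant current (pA); ``clamp``
    is (compartment, mV); ``stop`` is (mode, comp, gate, value) for
    early termination.  Probe traces are recorded every ``rec_every``
    steps.
    """
    nsteps = max(1, int(round(t_ms / dt_ms)))
    if not np.all(np.isfinite(state.V)):
        bad = int(np.argmax(~np.isfinite(state.V)))
        raise IntegrationError(
            f"non-finite voltage at compartment {bad} "
            f"({disc.comp_section[bad]}, x={disc.comp_x[bad]:.1f} µm)"
        )
    istim = np.zeros(disc.N) if istim_pA is None else istim_pA * 1e-3  # nA
    ci, cv = (-1, 0.0) if clamp is None else clamp
    probes = probes or {}
    rec_idx = np.asarray(list(probes.values()), dtype=np.int64)
    nrec_max = nsteps // rec_every + 1
    npr = max(1, len(rec_idx))
    outV = np.empty((nrec_max, npr))
    ng = len(disc.gate_names)
    outX = np.empty((nrec_max if rec_gates else 1, max(ng, 1), npr))
    smode, scomp, sgate, sval = stop or (_kernels.STOP_NONE, 0, 0, 0.0)
    done, nrec, stopped = _kernels.run_segment(
        disc.parent,
        disc.off,
        disc.offsum,
        disc.cap / dt_ms,
        disc.gl,
        disc.gl * disc.el,
        disc.erev,
        disc.gmax,
        disc.chan_of,
        disc.powr,
        disc.inact,
        disc.ftau,
        disc.vh,
        disc.kk,
        disc.taus,
        state.V,
        state.x,
        dt_ms,
        nsteps,
        istim,
        ci,
        cv,
        rec_idx if len(rec_idx) else np.zeros(1, dtype=np.int64),
        rec_every,
        outV,
        outX,
        rec_gates,
        smode,
        scomp,
        sgate,
        sval,
    )
    if not np.all(np.isfinite(state.V)):
        bad = int(np.argmax(~np.isfinite(state.V)))
        raise IntegrationError(
            f"divergence at compartment {bad} "
            f"({disc.comp_section[bad]}, x={disc.comp_x[bad]:.1f} µm)"
        )
    t = dt_ms * rec_every * np.arange(1, nrec + 1)
    V = {lbl: outV[:nrec, j].copy() for j, lbl in enumerate(probes)}
    gates = {}
    if rec_gates:
        for g, gname in enumerate(disc.gate_names):
            chan = disc.chan_names[disc.chan_of[g]]
            for j, lbl in enumerate(probes):
                gates[f"{chan}.{gname}@{lbl}"] = outX[:nrec, g, j].copy()
    return SimResult(
        t_ms=t,
        V=V,
        gates=gates,
        stopped=bool(stopped),
        t_stop_ms=done * dt_ms if stopped else None,
    )


def integrate(
    model_or_disc,
    stimuli: list[Stimulus],
    t_stop: float,
    dt: float = 0.005,
    *,
    probes: dict[str, tuple[str, float]] | None = None,
    rec_every: int = 1,
    rec_gates: bool = False,
    V0: float | None = None,
) -> SimResult:
    """Integrate a model under a stimulus protocol.

    The timeline is split at stimulus onsets/offsets into segments of
    constant drive.  ``probes`` maps labels to (section, x_um)
    locations; soma and AIS-relevant sites must be probed explicitly.
    """
    from .morphology import NeuronModel, discretize

    disc = (
        discretize(model_or_disc)
        if isinstance(model_or_disc, NeuronModel)
        else model_or_disc
    )
    for s in stimuli:
        disc.locate(s.section, s.x_um)  # validate targets early
    probes = probes or {"soma": ("soma", 0.0)}
    pidx = {lbl: disc.locate(sec, x) for lbl, (sec, x) in probes.items()}
    events = sorted(
        {0.0, t_stop}
        | {s.onset_ms for s in stimuli}
        | {s.onset_ms + s.duration_ms for s in stimuli}
    )
    events = [e for e in events if 0.0 <= e <= t_stop]
    state = initial_state(disc, V0)
    t_all: list[np.ndarray] = []
    V_all: dict[str, list[np.ndarray]] = {lbl: [] for lbl in probes}
    g_all: dict[str, list[np.ndarray]] = {}
    t0 = 0.0
    for t1 in events[1:]:
        if t1 <= t0:
            continue
        istim = np.zeros(disc.N)
        clamp = None
        for s in stimuli:
            if s.onset_ms <= t0 + dt / 2 and t0 + dt / 2 < s.onset_ms + s.duration_ms:
                idx = disc.locate(s.section, s.x_um)
                if s.kind == "step":
                    istim[idx] += s.amplitude_pA
                else:
                    clamp = (idx, s.command_mV)
        res = run_state(
            disc,
            state,
            t1 - t0,
            dt,
            istim_pA=istim,
            clamp=clamp,
            probes=pidx,
            rec_every=rec_every,
            rec_gates=rec_gates,
        )
        t_all.append(res.t_ms + t0)
        for lbl in probes:
            V_all[lbl].append(res.V[lbl])
        for key, tr in res.gates.items():
            g_all.setdefault(key, []).append(tr)
        t0 = t1
    return SimResult(
        t_ms=np.concatenate(t_all),
        V={lbl: np.concatenate(v) for lbl, v in V_all.items()},
        gates={k: np.concatenate(v) for k, v in g_all.items()},
    )


def clamp_current(
    disc: DiscretizedNeuron, state: SimState, idx: int, vc: float
) -> float:
    """Steady electrode current (pA) holding compartment ``idx`` at vc."""
    # membrane currents at the clamped node
    i_mem = disc.gl[idx] * (vc - disc.el[idx])
    nc = len(disc.chan_names)
    for c in range(nc):
        gm = disc.gmax[c, idx]
        if gm <= 0:
            continue
        go = gm
        for g in range(len(disc.gate_names)):
            if disc.chan_of[g] == c:
                go *= state.x[g, idx] ** int(disc.powr[g])
        i_mem += go * (vc - disc.erev[c])
    # axial currents toward neighbours
    i_ax = 0.0
    if disc.parent[idx] >= 0:
        i_ax += disc.off[idx] * (vc - state.V[disc.parent[idx]])
    for j in range(disc.N):
        if disc.parent[j] == idx:
            i_ax += disc.off[j] * (vc - state.V[j])
    return (i_mem + i_ax) * 1e3  # nA → pA


def steady_state_init(
    disc: DiscretizedNeuron,
    hold_V_soma: float | None = None,
    *,
    relax_ms: float = 500.0,
    dt_ms: float = 0.025,
    drift_tol: float = 1e-6,
) -> tuple[SimState, float]:
    """Equilibrate the model; returns (state, holding current in pA).

    With ``hold_V_soma`` set, the soma is clamped there while the rest
    of the tree relaxes, and the steady clamp current is returned as the
    holding current to apply after release.  Without a hold the model
    relaxes freely and the holding current is 0.  A residual drift
    larger than ``drift_tol`` mV/ms raises :class:`IntegrationError`.
    """
    state = initial_state(disc, hold_V_soma)
    clamp = None if hold_V_soma is None else (0, hold_V_soma)
    run_state(disc, state, relax_ms, dt_ms, clamp=clamp)
    v_before = state.V.copy()
    run_state(disc, state, 1.0, dt_ms, clamp=clamp)
    drift = float(np.max(np.abs(state.V - v_before))) / 1.0
    if drift > drift_tol:
        raise IntegrationError(f"state drift {drift:.2e} mV/ms after relaxation")
    ihold = 0.0
    if hold_V_soma is not None:
        ihold = clamp_current(disc, state, 0, hold_V_soma)
    return state, ihold


def passive_steady_state(
    disc: DiscretizedNeuron, istim_pA: np.ndarray
) -> np.ndarray:
    """Stationary voltage (mV) of the passive subsystem under constant drive.

    Solves (G_leak + G_axial)·(V − EL) = I directly; channels are
    ignored, so this is exact for passive models and is used as the
    steady-state oracle for input-resistance measurements.
    """
    N = disc.N
    rows, cols, vals = [], [], []
    for i in range(N):
        rows.append(i)
        cols.append(i)
        vals.append(disc.gl[i] + disc.offsum[i])
    for i in range(1, N):
        p = int(disc.parent[i])
        rows += [i, p]
        cols += [p, i]
        vals += [-disc.off[i], -disc.off[i]]
    G = csc_matrix((vals, (rows, cols)), shape=(N, N))
    rhs = istim_pA * 1e-3 + disc.gl * disc.el
    return np.asarray(spsolve(G, rhs))
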