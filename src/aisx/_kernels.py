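"""Numba kernels for the branched-cable backward-Euler integrator.

The spatial discretization is a tree of compartments ordered so that
``parent[i] < i`` (Hines ordering, soma at index 0).  Each implicit step
solves the symmetric tree-structured linear system by leaf-to-root
elimination and root-to-leaf back-substitution — O(N) per step and
unconditionally stable for the passive subsystem.  Gating variables are
advanced by exact exponential relaxation toward x∞(V) within the step,
operator-split from the voltage solve.

Units: mV, ms, µS, nA, nF (consistent: µS·mV = nA = nF·mV/ms).
"""

from __future__ import annotations

import numba as nb
import numpy as np

# Dirichlet voltage clamp is imposed by a diagonal penalty; diagonals are
# O(1) µS so this leaves ~1e-9 mV of clamp error.
_CLAMP_BIG = 1e10

STOP_NONE = 0
STOP_VOLTAGE = 1  # stop when V[stop_comp] >= stop_val
STOP_GATE = 2  # stop when x[stop_gate, stop_comp] >= stop_val


@nb.njit(cache=True, fastmath=True, error_model="numpy")
def _update_gates(V, x, dt, gmax, chan_of, powr, inact, ftau, vh, kk, taus):
    ng, N = x.shape
    for g in range(ng):
        c = chan_of[g]
        k = kk[g]
        vhg = vh[g]
        tstar = taus[g]
        for i in range(N):
            if gmax[c, i] <= 0.0:
                continue
            u = (V[i] - vhg) / k
            if inact[g]:
                xinf = 1.0 / (1.0 + np.exp(u))
            else:
                xinf = 1.0 / (1.0 + np.exp(-u))
            if ftau[g]:
                tau = tstar
            else:
                au = abs(u)
                if au < 1e-9:
                    tau = tstar
                else:
                    tau = tstar * np.tanh(0.5 * u) / (0.5 * u)
            x[g, i] = xinf + (x[g, i] - xinf) * np.exp(-dt / tau)


@nb.njit(cache=True, fastmath=True, error_model="numpy")
def _channel_sums(x, gmax, chan_of, powr, erev, gsum, rsum):
    nc, N = gmax.shape
    ng = chan_of.shape[0]
    for c in range(nc):
        ec = erev[c]
        for i in range(N):
            gm = gmax[c, i]
            if gm <= 0.0:
                continue
            go = gm
            for g in range(ng):
                if chan_of[g] == c:
                    xg = x[g, i]
                    p = powr[g]
                    acc = 1.0
                    for _ in range(p):
                        acc *= xg
                    go *= acc
            gsum[i] += go
            rsum[i] += go * ec


@nb.njit(cache=True, fastmath=True, error_model="numpy")
def run_segment(
    parent,
    off,
    offsum,
    cap_over_dt,
    gl,
    glel,
    erev,
    gmax,
    chan_of,
    powr,
    inact,
    ftau,
    vh,
    kk,
    taus,
    V,
    x,
    dt,
    nsteps,
    istim,
    clamp_idx,
    clamp_v,
    rec_idx,
    rec_every,
    outV,
    outX,
    rec_gates,
    stop_mode,
    stop_comp,
    stop_gate,
    stop_val,
):
    """Advance the model ``nsteps`` backward-Euler steps of size ``dt``.

    Records probe voltages (and optionally gate states) every
    ``rec_every`` steps into outV/outX starting at row 0.  Returns
    (steps_done, n_recorded, stopped) where stopped=1 if the stop
    condition fired.
    """
    N = V.shape[0]
    ng = x.shape[0]
    npr = rec_idx.shape[0]
    diag = np.empty(N)
    rhs = np.empty(N)
    gsum = np.empty(N)
    rsum = np.empty(N)
    nrec = 0
    stopped = 0
    for step in range(nsteps):
        _update_gates(V, x, dt, gmax, chan_of, powr, inact, ftau, vh, kk, taus)
        for i in range(N):
            gsum[i] = gl[i]
            rsum[i] = glel[i] + istim[i]
        _channel_sums(x, gmax, chan_of, powr, erev, gsum, rsum)
        for i in range(N):
            diag[i] = cap_over_dt[i] + gsum[i] + offsum[i]
            rhs[i] = cap_over_dt[i] * V[i] + rsum[i]
        if clamp_idx >= 0:
            diag[clamp_idx] += _CLAMP_BIG
            rhs[clamp_idx] += _CLAMP_BIG * clamp_v
        # Hines elimination (parent[i] < i)
        for i in range(N - 1, 0, -1):
            f = off[i] / diag[i]
            p = parent[i]
            diag[p] -= f * off[i]
            rhs[p] += f * rhs[i]
        V[0] = rhs[0] / diag[0]
        for i in range(1, N):
            V[i] = (rhs[i] + off[i] * V[parent[i]]) / diag[i]
        if (step + 1) % rec_every == 0:
            for p in range(npr):
                outV[nrec, p] = V[rec_idx[p]]
            if rec_gates:
                for g in range(ng):
                    for p in range(npr):
                        outX[nrec, g, p] = x[g, rec_idx[p]]
            nrec += 1
        if stop_mode == STOP_VOLTAGE:
            if V[stop_comp] >= stop_val:
                stopped = 1
                return step + 1, nrec, stopped
        elif stop_mode == STOP_GATE:
            if x[stop_gate, stop_comp] >= stop_val:
                stopped = 1
                return step + 1, nrec, stopped
    return nsteps, nrec, stopped
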