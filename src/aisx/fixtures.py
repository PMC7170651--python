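"""Synthetic two-site recording fixtures for the trace-analysis protocol.

Emulates a dual (somatic + axonal) current-clamp recording of a step
response: each site charges exponentially toward its Ohmic plateau with
its own time constant, plus additive Gaussian noise.  The axonal site
is fast (it charges within a few hundred µs) while the soma is slow —
the feature the early-time resistance statistic exploits.  Ground truth
is returned (and written) alongside the traces so recovery can be
tested quantitatively.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TraceFixture", "generate_trace_fixture", "write_trace_fixture"]


@dataclass(frozen=True)
class TraceFixture:
    traces: pd.DataFrame  # columns: t_ms, V_site_mV, V_soma_mV
    R_true_site_MOhm: float
    R_true_soma_MOhm: float
    tau_site_ms: float
    tau_soma_ms: float
    I_pA: float
    onset_ms: float
    noise_sd_mV: float
    seed: int

    def expected_R(self, window_ms: tuple[float, float] = (0.2, 0.4)) -> tuple[float, float]:
        """Noise-free value of the early-time statistic (site, soma), MΩ.

        The statistic reads the median depolarization over the window;
        for an exponential charge toward R·I this is
        R·(1 − e^{−t_med/τ}) with t_med the window midpoint, which is
        what a perfect recovery returns (R itself only once τ ≪ window).
        """
        t_med = 0.5 * (window_ms[0] + window_ms[1])
        out = []
        for R, tau in (
            (self.R_true_site_MOhm, self.tau_site_ms),
            (self.R_true_soma_MOhm, self.tau_soma_ms),
        ):
            out.append(R * (1.0 - float(np.exp(-t_med / tau))))
        return out[0], out[1]


def generate_trace_fixture(
    seed: int = 0,
    R_true_site: float = 140.0,
    R_true_soma: float = 45.0,
    tau_site: float = 0.1,
    tau_soma: float = 6.0,
    I: float = 50.0,
    noise_sd: float = 0.1,
    *,
    dt_ms: float = 0.025,
    pre_ms: float = 10.0,
    dur_ms: float = 20.0,
    EL_mV: float = -75.0,
) -> TraceFixture:
    """Two-site step-response traces with known resistances (MΩ) and τ (ms).

    The site trace rises as R_site·I·(1 − e^{−t/τ_site}) from onset, the
    somatic trace likewise with τ_soma; both carry i.i.d. Gaussian noise
    of ``noise_sd`` mV.  Identical parameters with different seeds give
    different noise but identical ground truth.
    """
    if min(R_true_site, R_true_soma, tau_site, tau_soma, dt_ms) <= 0:
        raise ValueError("fixture parameters must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, pre_ms + dur_ms, dt_ms)
    rel = np.clip(t - pre_ms, 0.0, None)
    on = (t >= pre_ms).astype(float)
    v_site = EL_mV + R_true_site * I * 1e-3 * on * (1.0 - np.exp(-rel / tau_site))
    v_soma = EL_mV + R_true_soma * I * 1e-3 * on * (1.0 - np.exp(-rel / tau_soma))
    v_site = v_site + rng.normal(0.0, noise_sd, t.size) if noise_sd else v_site
    v_soma = v_soma + rng.normal(0.0, noise_sd, t.size) if noise_sd else v_soma
    df = pd.DataFrame({"t_ms": t, "V_site_mV": v_site, "V_soma_mV": v_soma})
    return TraceFixture(
        traces=df,
        R_true_site_MOhm=R_true_site,
        R_true_soma_MOhm=R_true_soma,
        tau_site_ms=tau_site,
        tau_soma_ms=tau_soma,
        I_pA=I,
        onset_ms=pre_ms,
        noise_sd_mV=noise_sd,
        seed=seed,
    )


def write_trace_fixture(fix: TraceFixture, outdir: str | Path) -> tuple[Path, Path]:
    """Write traces as CSV with a JSON ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv = outdir / f"traces_seed{fix.seed}.csv"
    fix.traces.to_csv(csv, index=False)
    meta = {k: v for k, v in asdict(fix).items() if k != "traces"}
    sidecar = outdir / f"traces_seed{fix.seed}.json"
    sidecar.write_text(json.dumps(meta, indent=1))
    return csv, sidecar
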