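"""Passive membrane properties from the -5 mV membrane-test segment.

The estimators follow the standard whole-cell membrane-test analysis:

* baseline = mean over 1,800 samples (90 ms at 20 kHz) before step onset
* R_s from the instantaneous capacitive-transient peak: R_s = |dV| / |dI_peak|
* R_in from the steady-state current in a 50 ms window starting 100 ms
  after onset: R_in = |dV| / |dI_ss| - R_s (the series term is removed so
  R_in is the membrane resistance)
* tau_break-in = weighted tau of a biexponential fit of the transient
  from 95 % of its peak to 20 ms after onset
* C_p = tau_break-in / R_s

Note the known bias of this estimator family: for an ideal RC circuit
tau = C (R_s || R_in), so C_p = tau / R_s underestimates the true
capacitance by the factor R_in / (R_s + R_in).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal_core import Trace, fit_biexponential, peak_over_k, window_mean
from .synth_ephys import CellRecording, SweepRecording

__all__ = ["PassiveProperties", "TransientTooSmallError", "estimate_passive",
           "track_series_resistance"]

logger = logging.getLogger(__name__)

BASELINE_SAMPLES = 1800  # 90 ms at 20 kHz
RIN_WINDOW_START_S = 0.100  # steady-state window starts 100 ms after onset
RIN_WINDOW_LEN_S = 0.050
TAU_FIT_END_S = 0.020  # transient fit ends ~20 ms after onset


class TransientTooSmallError(ValueError):
    """Capacitive transient indistinguishable from baseline noise."""


@dataclass
class PassiveProperties:
    R_s: float  # MOhm
    R_in: float  # MOhm
    tau_break_in: float  # ms
    C_p: float  # pF
    baseline_pA: float
    measured_at: int = 0
    fit_converged: bool = True

    def __post_init__(self) -> None:
        if self.R_s <= 0 or self.R_in <= 0:
            raise ValueError("R_s and R_in must be positive")


def estimate_passive(
    sweep: SweepRecording,
    step_mV: float = -5.0,
    fit_tau: bool = True,
) -> PassiveProperties:
    """Estimate R_s, R_in, tau_break-in and C_p from one test-pulse segment.

    Parameters
    ----------
    sweep
        Recording whose ``test_pulse_onset`` marks the voltage-step onset.
    step_mV
        Amplitude of the voltage step (default -5 mV).
    fit_tau
        Skip the biexponential fit (tau and C_p set to nan) when only the
        per-sweep R_s series is needed; the fit dominates the runtime.
    """
    trace = sweep.trace
    onset = sweep.test_pulse_onset
    dt = trace.dt
    baseline_start = onset - BASELINE_SAMPLES * dt
    baseline = window_mean(trace, baseline_start, BASELINE_SAMPLES)

    polarity = "inward" if step_mV < 0 else "outward"
    # transient peak: raw extremum (k=1); the transient is far faster than
    # the 5-sample smoothing used for synaptic peaks
    peak_val, peak_time = peak_over_k(
        trace, (onset, onset + TAU_FIT_END_S), k=1, polarity=polarity
    )
    di_peak = peak_val - baseline

    i0 = trace.index_at(baseline_start)
    noise_sd = float(np.std(trace.samples[i0 : i0 + BASELINE_SAMPLES]))
    if abs(di_peak) < 5.0 * noise_sd:
        raise TransientTooSmallError(
            f"transient peak {di_peak:.2f} pA < 5 x baseline SD {noise_sd:.2f} pA"
        )

    # mV / pA = GOhm -> x1000 to MOhm
    r_s = abs(step_mV) / abs(di_peak) * 1e3

    n_ss = int(round(RIN_WINDOW_LEN_S / dt))
    i_ss = window_mean(trace, onset + RIN_WINDOW_START_S, n_ss)
    di_ss = i_ss - baseline
    if di_ss == 0:
        raise ValueError("zero steady-state current step")
    r_total = abs(step_mV) / abs(di_ss) * 1e3
    r_in = r_total - r_s
    if r_in <= 0:
        raise ValueError(f"non-positive R_in ({r_in:.1f} MOhm): degenerate step response")

    tau_w = float("nan")
    c_p = float("nan")
    converged = True
    if fit_tau:
        fit = fit_biexponential(
            trace, peak_time, start_fraction=0.95,
            t_end=onset + TAU_FIT_END_S, baseline=baseline,
        )
        converged = fit.converged
        if fit.converged:
            tau_w = fit.tau_w
            c_p = tau_w / r_s * 1e3  # ms / MOhm = nF -> pF
        else:
            logger.warning("tau_break-in fit did not converge on sweep %d",
                           sweep.sweep_index)
    return PassiveProperties(
        R_s=r_s, R_in=r_in, tau_break_in=tau_w, C_p=c_p,
        baseline_pA=baseline, measured_at=sweep.sweep_index,
        fit_converged=converged,
    )


def track_series_resistance(
    cell: CellRecording, step_mV: float = -5.0
) -> tuple[list[float], float]:
    """Per-sweep R_s series and its maximum relative change in percent.

    The change is 100 * (max - min) / first, the quantity the <30 %
    stability criterion is applied to. Sweeps whose transient fails the
    noise check are excluded from the series with a logged warning.
    """
    series: list[float] = []
    for sweep in cell.sweeps:
        try:
            props = estimate_passive(sweep, step_mV=step_mV, fit_tau=False)
        except TransientTooSmallError as exc:
            logger.warning("sweep %d excluded from R_s series: %s",
                           sweep.sweep_index, exc)
            continue
        series.append(props.R_s)
    if not series:
        raise ValueError("no sweep yielded a usable membrane test")
    change_pct = 100.0 * (max(series) - min(series)) / series[0]
    return series, change_pct
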