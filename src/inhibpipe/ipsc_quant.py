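"""Evoked-IPSC quantification on mean traces.

Amplitudes are measured as the 5-sample-centered peak minus a 64 ms
(1,280-sample) baseline ending at the first stimulus; the 20-80 % rise
time uses linearly interpolated threshold crossings on the rising phase;
the decay of the second response is the weighted tau of a biexponential
fit from 95 % of its peak to 250 ms after the stimulus; PPR = A2 / A1.
All amplitudes are reported as magnitudes (the currents are inward).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .signal_core import Trace, fit_biexponential, peak_over_k, window_mean
from .synth_ephys import CellRecording

__all__ = [
    "IPSCMeasurement",
    "IOCurve",
    "compute_mean_trace",
    "measure_ipsc",
    "percent_block",
    "build_io_curve",
    "measurements_to_frame",
]

logger = logging.getLogger(__name__)

BASELINE_SAMPLES = 1280  # 64 ms at 20 kHz
PEAK_SEARCH_START_S = 0.001  # skip the stimulus artifact
PEAK_SEARCH_END_S = 0.100  # covers slow CCK-like rise times
DECAY_FIT_END_S = 0.250  # decay fit ends 250 ms after stimulus 2
DETECTION_FLOOR_SD = 3.0


@dataclass
class IPSCMeasurement:
    """Amplitudes and kinetics of one double-pulse mean trace."""

    A1: float  # pA, magnitude
    A2: float  # pA, magnitude
    ppr: float  # A2 / A1
    rise_20_80: float  # ms
    tau_decay_w: float  # ms, weighted biexponential tau of the 2nd IPSC
    baseline_pA: float
    n_sweeps_averaged: int = 1
    responded: bool = True
    fit_converged: bool = True


@dataclass
class IOCurve:
    """Per-cell IPSC amplitude versus stimulation intensity."""

    cell_id: str
    modality: str
    intensities: list[float]
    amplitudes: list[float]
    genotype: str = "Eu"

    def __post_init__(self) -> None:
        if len(self.intensities) != len(self.amplitudes):
            raise ValueError("intensities and amplitudes must align")
        if any(b <= a for a, b in zip(self.intensities, self.intensities[1:])):
            raise ValueError("intensities must be strictly increasing")


def compute_mean_trace(
    cell: CellRecording, sweep_subset: Sequence[int] | None = None
) -> Trace:
    """Pointwise mean across sweeps (optionally a subset of sweep indices)."""
    sweeps = cell.sweeps
    if sweep_subset is not None:
        wanted = set(sweep_subset)
        sweeps = [s for s in sweeps if s.sweep_index in wanted]
    if not sweeps:
        raise ValueError("no sweeps selected")
    lengths = {s.trace.n_samples for s in sweeps}
    if len(lengths) != 1:
        raise ValueError(f"mismatched sweep lengths: {sorted(lengths)}")
    stacked = np.stack([s.trace.samples for s in sweeps])
    first = sweeps[0].trace
    return Trace(stacked.mean(axis=0), first.sampling_rate, first.t0)


def _interp_crossing(
    times: np.ndarray, magnitude: np.ndarray, i_after: int, level: float
) -> float:
    """Time at which `magnitude` crosses `level` between i_after-1 and i_after."""
    if i_after == 0:
        return float(times[0])
    m0, m1 = magnitude[i_after - 1], magnitude[i_after]
    if m1 == m0:
        return float(times[i_after])
    frac = (level - m0) / (m1 - m0)
    return float(times[i_after - 1] + frac * (times[i_after] - times[i_after - 1]))


def _rise_time_20_80(
    trace: Trace, baseline: float, a1: float, stim_time: float, peak_time: float
) -> float:
    """20-80 % rise time (ms), thresholds relative to the baseline."""
    i_stim = trace.index_at(stim_time)
    i_peak = trace.index_at(peak_time)
    seg = baseline - trace.samples[i_stim : i_peak + 1]  # magnitude of inward current
    t = trace.times()[i_stim : i_peak + 1]
    crossings = []
    for level in (0.8 * a1, 0.2 * a1):
        below = np.nonzero(seg < level)[0]
        # last sample below the level before the peak -> first crossing after it
        i_after = int(below[-1]) + 1 if below.size else 0
        if i_after > seg.size - 1:
            i_after = seg.size - 1
        crossings.append(_interp_crossing(t, seg, i_after, level))
    t80, t20 = crossings
    return (t80 - t20) * 1e3


def measure_ipsc(
    mean_trace: Trace,
    stim_times: Sequence[float],
    isi_ms: float | None = None,
    n_sweeps_averaged: int = 1,
) -> IPSCMeasurement:
    """Quantify a double-pulse mean trace.

    ``stim_times`` are the two stimulus onsets in seconds; ``isi_ms`` is
    only checked for consistency when given. Responses below 3x the
    baseline-window SD are declared no-response (PPR and kinetics nan).
    """
    if len(stim_times) != 2:
        raise ValueError("exactly two stimulus times expected")
    t1, t2 = stim_times
    if isi_ms is not None and abs((t2 - t1) * 1e3 - isi_ms) > 1e-6:
        raise ValueError("stim_times inconsistent with the stated ISI")

    dt = mean_trace.dt
    baseline_start = t1 - BASELINE_SAMPLES * dt
    baseline = window_mean(mean_trace, baseline_start, BASELINE_SAMPLES)
    i0 = mean_trace.index_at(baseline_start)
    baseline_sd = float(np.std(mean_trace.samples[i0 : i0 + BASELINE_SAMPLES]))

    peak1, peak1_time = peak_over_k(
        mean_trace, (t1 + PEAK_SEARCH_START_S, t1 + PEAK_SEARCH_END_S), k=5,
        polarity="inward",
    )
    a1 = baseline - peak1  # magnitude of the inward deflection
    if a1 < DETECTION_FLOOR_SD * baseline_sd or a1 <= 0:
        logger.info("no response: A1=%.2f pA below %.1f x SD floor", a1,
                    DETECTION_FLOOR_SD)
        return IPSCMeasurement(
            A1=max(a1, 0.0), A2=float("nan"), ppr=float("nan"),
            rise_20_80=float("nan"), tau_decay_w=float("nan"),
            baseline_pA=baseline, n_sweeps_averaged=n_sweeps_averaged,
            responded=False,
        )

    rise = _rise_time_20_80(mean_trace, baseline, a1, t1, peak1_time)

    peak2, peak2_time = peak_over_k(
        mean_trace, (t2 + PEAK_SEARCH_START_S, t2 + PEAK_SEARCH_END_S), k=5,
        polarity="inward",
    )
    a2 = baseline - peak2

    fit = fit_biexponential(
        mean_trace, peak2_time, start_fraction=0.95,
        t_end=t2 + DECAY_FIT_END_S, baseline=baseline,
    )
    if not fit.converged:
        logger.warning("decay fit of the second IPSC did not converge")
    return IPSCMeasurement(
        A1=a1, A2=a2, ppr=a2 / a1, rise_20_80=rise,
        tau_decay_w=fit.tau_w if fit.converged else float("nan"),
        baseline_pA=baseline, n_sweeps_averaged=n_sweeps_averaged,
        responded=True, fit_converged=fit.converged,
    )


def percent_block(ctrl: IPSCMeasurement, drug: IPSCMeasurement) -> float:
    """Percent reduction of A1 by a drug: 100 * (1 - A1_drug / A1_ctrl).

    Clipped to [0, 100]; a negative raw value (drug response larger than
    control) is logged before clipping. Undefined when the control shows
    no response.
    """
    if not ctrl.responded:
        raise ValueError("percent block undefined: control shows no response")
    raw = 100.0 * (1.0 - drug.A1 / ctrl.A1)
    if raw < 0:
        logger.warning("negative percent block (%.1f%%) clipped to 0", raw)
    return float(np.clip(raw, 0.0, 100.0))


def build_io_curve(cells: Sequence[CellRecording]) -> list[IOCurve]:
    """Per-cell amplitude-versus-intensity curves from repeated recordings.

    Cells are grouped by ``cell_id``; each recording contributes the A1 of
    its mean trace at its stimulation intensity. Missing intensities are
    simply absent from the curve.
    """
    by_cell: dict[str, list[CellRecording]] = {}
    for cell in cells:
        by_cell.setdefault(cell.cell_id, []).append(cell)
    curves = []
    for cell_id, recs in sorted(by_cell.items()):
        recs = sorted(recs, key=lambda c: c.intensity)
        intensities, amplitudes = [], []
        for rec in recs:
            mean = compute_mean_trace(rec)
            m = measure_ipsc(mean, rec.sweeps[0].stim_times,
                             n_sweeps_averaged=len(rec.sweeps))
            intensities.append(rec.intensity)
            amplitudes.append(m.A1 if m.responded else float("nan"))
        curves.append(
            IOCurve(cell_id=cell_id, modality=recs[0].modality,
                    intensities=intensities, amplitudes=amplitudes,
                    genotype=recs[0].genotype)
        )
    return curves


def measurements_to_frame(
    rows: Sequence[tuple[CellRecording, IPSCMeasurement]]
) -> pd.DataFrame:
    """Tidy per-cell results table (one row per cell x condition)."""
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c, _ in rows],
            "genotype": [c.genotype for c, _ in rows],
            "modality": [c.modality for c, _ in rows],
            "intensity": [c.intensity for c, _ in rows],
            "A1_pA": [m.A1 for _, m in rows],
            "A2_pA": [m.A2 for _, m in rows],
            "ppr": [m.ppr for _, m in rows],
            "rise_ms": [m.rise_20_80 for _, m in rows],
            "tau_w_ms": [m.tau_decay_w for _, m in rows],
        }
    )
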