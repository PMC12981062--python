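"""Synthetic voltage-clamp sweep generation with known ground truth.

Emulates whole-cell recordings from dentate granule cells held at -80 mV:
RC membrane-test transients to a -5 mV step, and double-pulse evoked
IPSCs (inward at -80 mV with high-chloride internals) built as
difference-of-exponentials with configurable amplitude, 20-80 % rise,
decay tau, and paired-pulse ratio, plus per-sweep Gaussian noise.

All stochastic draws come from ``numpy.random.default_rng(seed)`` so a
config is reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.signal import bessel, sosfilt

from .signal_core import Trace

__all__ = [
    "EphysGenConfig",
    "SweepRecording",
    "CellRecording",
    "solve_rise_tau",
    "generate_membrane_test",
    "generate_ipsc_sweeps",
    "generate_io_dataset",
    "save_cells",
    "load_cells",
    "cells_to_long_csv",
    "config_to_yaml",
    "config_from_yaml",
]


@dataclass
class EphysGenConfig:
    """Ground-truth parameters for one synthetic cell.

    Stimulus timing follows the sweep layout: stimulus 1 at 0.2 s, the
    second one ISI later, and the membrane-test step in the final 250 ms
    of the sweep. Electrical / PV protocols use 1.5 s sweeps (ISI 200 ms),
    the SOM protocol 2.0 s sweeps (ISI 500 ms).
    """

    sampling_rate: float = 20_000.0  # Hz
    holding: float = -80.0  # mV
    test_step: float = -5.0  # mV
    test_step_duration_ms: float = 200.0
    R_s_true: float = 10.0  # MOhm
    R_in_true: float = 340.0  # MOhm
    C_true: float = 120.0  # pF
    stim_kind: str = "electrical_iML"  # electrical_iML | opto_SOM | opto_PV
    isi_ms: float = 200.0
    stim1_time: float = 0.2  # s
    latency_ms: float = 1.0  # synaptic delay from stimulus to current onset
    A1_true: float = 372.5  # pA (magnitude of first-pulse peak)
    ppr_true: float = 0.84
    rise_20_80_true: float = 4.92  # ms
    tau_decay_true: float = 79.86  # ms
    noise_sd: float = 0.0  # pA per sweep
    baseline_current: float = 0.0  # pA DC offset of the recording
    filter_enabled: bool = False
    filter_cutoff: float = 8_000.0  # Hz, 4-pole low-pass when enabled
    n_sweeps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.R_s_true, self.R_in_true, self.C_true) <= 0:
            raise ValueError("resistances and capacitance must be positive")
        if self.n_sweeps < 1 or self.sampling_rate <= 0:
            raise ValueError("n_sweeps and sampling_rate must be positive")
        if self.ppr_true <= 0 or self.A1_true <= 0:
            raise ValueError("A1_true and ppr_true must be positive")
        if self.isi_ms <= 0 or self.rise_20_80_true <= 0 or self.tau_decay_true <= 0:
            raise ValueError("timing parameters must be positive")
        if self.rise_20_80_true >= self.isi_ms:
            raise ValueError("rise time must be shorter than the ISI")

    @property
    def sweep_duration(self) -> float:
        """Sweep length in seconds (2.0 s for the SOM protocol, else 1.5 s)."""
        return 2.0 if self.isi_ms > 300 else 1.5

    @property
    def stim_times(self) -> list[float]:
        return [self.stim1_time, self.stim1_time + self.isi_ms / 1e3]

    @property
    def test_step_onset(self) -> float:
        """Membrane-test onset: the step sits in the final 250 ms of the sweep."""
        return self.sweep_duration - 0.25

    @property
    def membrane_tau_s(self) -> float:
        """RC time constant of the voltage-clamped cell, in seconds.

        tau = C * (R_s || R_in); MOhm * pF = microseconds.
        """
        r_par = self.R_s_true * self.R_in_true / (self.R_s_true + self.R_in_true)
        return r_par * self.C_true * 1e-6


@dataclass
class SweepRecording:
    """One sweep: a current trace plus its stimulus and test-pulse timing."""

    trace: Trace
    stim_times: list[float]
    test_pulse_onset: float
    sweep_index: int = 0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.stim_times, self.stim_times[1:])):
            raise ValueError("stim_times must be strictly increasing")


@dataclass
class CellRecording:
    """Ordered sweeps from one cell plus recording metadata."""

    sweeps: list[SweepRecording]
    cell_id: str = "cell0"
    genotype: str = "Eu"  # Eu | Ts65Dn
    age_weeks: int = 8
    modality: str = "electrical_iML"
    intensity: float = 30.0  # stimulation strength (uA or mW)
    seal_GOhm: float = 2.0
    time_since_slice_h: float = 3.0
    ground_truth: EphysGenConfig | None = None

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ValueError("CellRecording requires at least one sweep")
        rates = {s.trace.sampling_rate for s in self.sweeps}
        if len(rates) != 1:
            raise ValueError("all sweeps must share one sampling rate")


# ---------------------------------------------------------------------------
# IPSC waveform kinetics
# ---------------------------------------------------------------------------

def _doe_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Peak time of exp(-t/tau_d) - exp(-t/tau_r), same units as the taus."""
    return tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)


def _doe_normalized(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials with unit (continuous-time) peak; zero for t<0."""
    tp = _doe_peak_time(tau_rise, tau_decay)
    peak = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (np.exp(-t[pos] / tau_decay) - np.exp(-t[pos] / tau_rise)) / peak
    return out


def _rise_20_80(tau_rise: float, tau_decay: float) -> float:
    """20-80 % rise time of the normalized difference-of-exponentials."""
    tp = _doe_peak_time(tau_rise, tau_decay)

    def level(t: float) -> float:
        arr = _doe_normalized(np.array([t]), tau_rise, tau_decay)
        return float(arr[0])

    t20 = brentq(lambda t: level(t) - 0.2, 1e-12, tp, xtol=1e-12, rtol=1e-14)
    t80 = brentq(lambda t: level(t) - 0.8, t20, tp, xtol=1e-12, rtol=1e-14)
    return t80 - t20


def solve_rise_tau(rise_20_80_ms: float, tau_decay_ms: float) -> float:
    """Rise time constant (ms) giving the requested 20-80 % rise.

    Solved numerically to 1e-6 relative tolerance; the 20-80 % rise of a
    difference-of-exponentials is monotone increasing in tau_rise.
    """
    hi = 0.999 * tau_decay_ms
    if _rise_20_80(hi, tau_decay_ms) < rise_20_80_ms:
        raise ValueError(
            f"rise {rise_20_80_ms} ms unreachable with decay tau {tau_decay_ms} ms"
        )
    return brentq(
        lambda tr: _rise_20_80(tr, tau_decay_ms) - rise_20_80_ms,
        1e-6 * tau_decay_ms,
        hi,
        rtol=1e-9,
    )


# ---------------------------------------------------------------------------
# Trace assembly
# ---------------------------------------------------------------------------

def _rc_step_current(t: np.ndarray, config: EphysGenConfig) -> np.ndarray:
    """Clamp current (pA) of the single-compartment circuit to the test step.

    On-transient jumps instantaneously to dV/R_s and relaxes with
    tau = C (R_s || R_in) to the steady state dV/(R_s + R_in); the
    off-transient mirrors it. mV / MOhm = nA, hence the 1e3 factor to pA.
    """
    dv = config.test_step
    i_peak = dv / config.R_s_true * 1e3
    i_ss = dv / (config.R_s_true + config.R_in_true) * 1e3
    tau = config.membrane_tau_s
    onset = config.test_step_onset
    offset_t = onset + config.test_step_duration_ms / 1e3
    out = np.zeros_like(t)
    during = (t >= onset) & (t < offset_t)
    if tau > 0:
        out[during] = i_ss + (i_peak - i_ss) * np.exp(-(t[during] - onset) / tau)
        after = t >= offset_t
        i_at_off = i_ss  # assume settled by step end
        out[after] = (i_at_off - i_peak) * np.exp(-(t[after] - offset_t) / tau)
    else:
        out[during] = i_ss
    return out


_OVERSAMPLE = 8  # acquisition-filter emulation runs at 8x the sampling rate


def _lowpass_fine(x_fine: np.ndarray, fs_fine: float, cutoff: float) -> np.ndarray:
    """Causal 4-pole Bessel low-pass applied on the oversampled grid.

    The 8 kHz cutoff sits at 0.8x Nyquist of a 20 kHz recording, where a
    bilinear digital design is badly warped; filtering at 8x the rate and
    decimating reproduces the analog anti-alias filter faithfully.
    """
    sos = bessel(4, cutoff, btype="low", fs=fs_fine, output="sos", norm="mag")
    return sosfilt(sos, x_fine)


def generate_membrane_test(config: EphysGenConfig) -> SweepRecording:
    """One 0.5 s sweep containing only the -5 mV membrane-test response.

    The step onset is at 0.15 s with the configured duration (capped to
    leave a 100 ms tail), preceded by >= 90 ms of quiet baseline.
    """
    fs = config.sampling_rate
    n = int(round(0.5 * fs))
    t = np.arange(n) / fs
    onset = 0.15
    dur_ms = min(config.test_step_duration_ms, 250.0)
    dv = config.test_step
    i_peak = dv / config.R_s_true * 1e3
    i_ss = dv / (config.R_s_true + config.R_in_true) * 1e3
    tau = config.membrane_tau_s
    offset_t = onset + dur_ms / 1e3

    def evaluate(tt: np.ndarray) -> np.ndarray:
        out = np.full(tt.size, config.baseline_current, dtype=float)
        during = (tt >= onset) & (tt < offset_t)
        after = tt >= offset_t
        if tau > 0:
            out[during] += i_ss + (i_peak - i_ss) * np.exp(-(tt[during] - onset) / tau)
            out[after] += (i_ss - i_peak) * np.exp(-(tt[after] - offset_t) / tau)
        else:
            out[during] += i_ss
        return out

    if config.filter_enabled:
        t_fine = np.arange(n * _OVERSAMPLE) / (fs * _OVERSAMPLE)
        current = _lowpass_fine(evaluate(t_fine), fs * _OVERSAMPLE,
                                config.filter_cutoff)[::_OVERSAMPLE]
    else:
        current = evaluate(t)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        current = current + rng.normal(0.0, config.noise_sd, size=n)
    return SweepRecording(
        trace=Trace(current, fs),
        stim_times=[onset],
        test_pulse_onset=onset,
        sweep_index=0,
    )


def _noiseless_ipsc_template(config: EphysGenConfig) -> np.ndarray:
    """Noise-free sweep template: IPSCs (negative) plus the test-pulse RC response.

    The first pulse is scaled so its on-grid extremum magnitude equals
    ``A1_true``; the second pulse is scaled so that the extremum of the
    *summed* trace in the second response window equals
    ``ppr_true * A1_true`` relative to the pre-stimulus baseline, i.e.
    the residual decay of the first response is compensated at
    generation time so that the planted PPR is exact on the trace.
    """
    fs = config.sampling_rate
    n = int(round(config.sweep_duration * fs))
    t = np.arange(n) / fs
    if config.rise_20_80_true < 2e3 / fs:
        raise ValueError("rise_20_80_true shorter than 2 sample periods: unrealizable")
    tau_r = solve_rise_tau(config.rise_20_80_true, config.tau_decay_true)
    lat = config.latency_ms / 1e3
    t1, t2 = config.stim_times
    w1 = _doe_normalized((t - t1 - lat) * 1e3, tau_r, config.tau_decay_true)
    w2 = _doe_normalized((t - t2 - lat) * 1e3, tau_r, config.tau_decay_true)
    c1 = config.A1_true / w1.max()
    p1 = c1 * w1
    # second-pulse scale: summed-trace extremum in the second window = ppr * A1
    win = (t >= t2) & (t <= t2 + 0.1)
    target = config.ppr_true * config.A1_true

    def excess(c2: float) -> float:
        return float(np.max(p1[win] + c2 * w2[win])) - target

    c2 = brentq(excess, 0.0, 1.5 * target, rtol=1e-12)

    def evaluate(tt: np.ndarray) -> np.ndarray:
        wf1 = _doe_normalized((tt - t1 - lat) * 1e3, tau_r, config.tau_decay_true)
        wf2 = _doe_normalized((tt - t2 - lat) * 1e3, tau_r, config.tau_decay_true)
        return (config.baseline_current - (c1 * wf1 + c2 * wf2)
                + _rc_step_current(tt, config))

    if config.filter_enabled:
        t_fine = np.arange(n * _OVERSAMPLE) / (fs * _OVERSAMPLE)
        return _lowpass_fine(evaluate(t_fine), fs * _OVERSAMPLE,
                             config.filter_cutoff)[::_OVERSAMPLE]
    return evaluate(t)


def generate_ipsc_sweeps(config: EphysGenConfig) -> CellRecording:
    """Double-pulse IPSC sweeps with per-sweep Gaussian noise.

    Ground truth is stored on the returned :class:`CellRecording`.
    """
    template = _noiseless_ipsc_template(config)
    fs = config.sampling_rate
    rng = np.random.default_rng(config.seed)
    sweeps = []
    for k in range(config.n_sweeps):
        current = template.copy()
        if config.noise_sd > 0:
            current += rng.normal(0.0, config.noise_sd, size=template.size)
        sweeps.append(
            SweepRecording(
                trace=Trace(current, fs),
                stim_times=list(config.stim_times),
                test_pulse_onset=config.test_step_onset,
                sweep_index=k,
            )
        )
    return CellRecording(
        sweeps=sweeps,
        modality=config.stim_kind,
        ground_truth=config,
    )


def generate_io_dataset(
    configs: Sequence[EphysGenConfig],
    intensities: Sequence[float],
    gain_model: Mapping[float, float] | Callable[[float], float],
    between_cell_cv: float = 0.3,
    seed: int = 0,
) -> list[CellRecording]:
    """Input-output dataset: one CellRecording per cell x intensity.

    Each cell draws a lognormal gain multiplier (coefficient of variation
    ``between_cell_cv``); its amplitude at each intensity is the
    multiplier times ``gain_model(intensity)``, which must be monotone
    non-decreasing over the supplied intensities.
    """
    if not intensities:
        raise ValueError("intensities must be non-empty")
    gain = gain_model if callable(gain_model) else (lambda i: gain_model[i])
    levels = [gain(i) for i in intensities]
    if any(b < a for a, b in zip(levels, levels[1:])):
        raise ValueError("gain_model must be monotone non-decreasing")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + between_cell_cv**2))
    out: list[CellRecording] = []
    for ci, base in enumerate(configs):
        mult = float(rng.lognormal(-0.5 * sigma**2, sigma))
        for intensity, level in zip(intensities, levels):
            cfg = dataclasses.replace(
                base,
                A1_true=max(1e-6, mult * level),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            cell = generate_ipsc_sweeps(cfg)
            cell.cell_id = f"cell{ci:03d}"
            cell.intensity = float(intensity)
            out.append(cell)
    return out


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

_CELL_ATTRS = (
    "cell_id", "genotype", "age_weeks", "modality",
    "intensity", "seal_GOhm", "time_since_slice_h",
)


def save_cells(path: str, cells: Sequence[CellRecording]) -> None:
    """Write recordings to an HDF5 container (/cells/<id>/sweeps/<k>)."""
    with h5py.File(path, "w") as f:
        root = f.create_group("cells")
        for cell in cells:
            # intensity is part of the key so repeated-measures cells coexist
            key = f"{cell.cell_id}@{cell.intensity:g}"
            g = root.create_group(key)
            for name in _CELL_ATTRS:
                g.attrs[name] = getattr(cell, name)
            if cell.ground_truth is not None:
                g.attrs["ground_truth_json"] = json.dumps(
                    dataclasses.asdict(cell.ground_truth)
                )
            sg = g.create_group("sweeps")
            for sweep in cell.sweeps:
                d = sg.create_dataset(
                    f"{sweep.sweep_index:04d}", data=sweep.trace.samples
                )
                d.attrs["sampling_rate"] = sweep.trace.sampling_rate
                d.attrs["t0"] = sweep.trace.t0
                d.attrs["stim_times"] = np.asarray(sweep.stim_times)
                d.attrs["test_pulse_onset"] = sweep.test_pulse_onset
                d.attrs["sweep_index"] = sweep.sweep_index


def load_cells(path: str) -> list[CellRecording]:
    cells: list[CellRecording] = []
    with h5py.File(path, "r") as f:
        for key in sorted(f["cells"]):
            g = f["cells"][key]
            sweeps = []
            for sk in sorted(g["sweeps"]):
                d = g["sweeps"][sk]
                sweeps.append(
                    SweepRecording(
                        trace=Trace(
                            d[()], float(d.attrs["sampling_rate"]), float(d.attrs["t0"])
                        ),
                        stim_times=list(np.atleast_1d(d.attrs["stim_times"])),
                        test_pulse_onset=float(d.attrs["test_pulse_onset"]),
                        sweep_index=int(d.attrs["sweep_index"]),
                    )
                )
            truth = None
            if "ground_truth_json" in g.attrs:
                truth = EphysGenConfig(**json.loads(g.attrs["ground_truth_json"]))
            cells.append(
                CellRecording(
                    sweeps=sweeps,
                    cell_id=str(g.attrs["cell_id"]),
                    genotype=str(g.attrs["genotype"]),
                    age_weeks=int(g.attrs["age_weeks"]),
                    modality=str(g.attrs["modality"]),
                    intensity=float(g.attrs["intensity"]),
                    seal_GOhm=float(g.attrs["seal_GOhm"]),
                    time_since_slice_h=float(g.attrs["time_since_slice_h"]),
                    ground_truth=truth,
                )
            )
    return cells


def cells_to_long_csv(path: str, cells: Sequence[CellRecording]) -> None:
    """Plain-text interoperability dump: cell_id, sweep, time_s, current_pA."""
    frames = []
    for cell in cells:
        for sweep in cell.sweeps:
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": cell.cell_id,
                        "sweep": sweep.sweep_index,
                        "time_s": sweep.trace.times(),
                        "current_pA": sweep.trace.samples,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def config_to_yaml(config: EphysGenConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def config_from_yaml(path: str) -> EphysGenConfig:
    with open(path) as fh:
        return EphysGenConfig(**yaml.safe_load(fh))
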