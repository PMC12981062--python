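"""Low-level, stimulus-agnostic trace operators.

These are the primitives shared by the passive-membrane-property and
evoked-IPSC analyses: windowed baseline means, peak-over-k-samples
amplitude extraction, and biexponential decay fitting with an
amplitude-weighted time constant.

Conventions
-----------
* Currents are in pA; inward currents are negative.
* Times are in seconds on :class:`Trace`; fitted time constants are
  reported in milliseconds, the unit in which synaptic and capacitive
  kinetics are conventionally quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import lmfit

__all__ = [
    "Trace",
    "BiexpFit",
    "TraceWindowError",
    "PeakEdgeError",
    "window_mean",
    "peak_over_k",
    "fit_biexponential",
]


class TraceWindowError(ValueError):
    """A requested analysis window does not lie fully inside the trace."""


class PeakEdgeError(ValueError):
    """The located extremum is too close to a window edge for a centered mean."""


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled current trace.

    Parameters
    ----------
    samples
        Current values in pA at uniform spacing.
    sampling_rate
        Sampling frequency in Hz (must be positive).
    t0
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("Trace requires a 1-D array of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Trace contains non-finite samples")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def dt(self) -> float:
        """Sample period in seconds."""
        return 1.0 / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total span covered by the samples, in seconds."""
        return self.n_samples * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) * self.dt

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (seconds)."""
        return int(round((t - self.t0) * self.sampling_rate))


def window_mean(trace: Trace, t_start: float, n_samples: int) -> float:
    """Mean of exactly ``n_samples`` consecutive samples starting at ``t_start``.

    Raises
    ------
    TraceWindowError
        If the window extends beyond the trace; the window is never
        silently truncated.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    i0 = trace.index_at(t_start)
    if i0 < 0 or i0 + n_samples > trace.n_samples:
        raise TraceWindowError(
            f"window [{i0}, {i0 + n_samples}) outside trace of length {trace.n_samples}"
        )
    return float(np.mean(trace.samples[i0 : i0 + n_samples]))


def peak_over_k(
    trace: Trace,
    search_window: tuple[float, float],
    k: int = 5,
    polarity: Literal["inward", "outward"] = "inward",
) -> tuple[float, float]:
    """Locate the extremum in a window and average ``k`` samples around it.

    The extremum of the stated polarity (inward = most negative) is found
    within ``search_window`` (seconds, inclusive); the returned amplitude
    is the mean of the ``k`` consecutive samples centered on it, which
    suppresses single-sample noise without the bias of a running max.
    Ties in extremum location are broken by the earliest time.

    Returns
    -------
    (peak_value, peak_time)
        Mean current over the k centered samples (pA) and the time of the
        extremum sample (seconds).

    Raises
    ------
    PeakEdgeError
        If the extremum lies within ``k // 2`` samples of a window edge,
        so a centered mean would reach outside the search window.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be a positive odd integer")
    if polarity not in ("inward", "outward"):
        raise ValueError("polarity must be 'inward' or 'outward'")
    t_lo, t_hi = search_window
    if t_hi <= t_lo:
        raise ValueError("search_window must satisfy t_lo < t_hi")
    i_lo = int(np.ceil((t_lo - trace.t0) * trace.sampling_rate - 1e-9))
    i_hi = int(np.floor((t_hi - trace.t0) * trace.sampling_rate + 1e-9))
    if i_lo < 0 or i_hi >= trace.n_samples:
        raise TraceWindowError("search window outside trace")
    if i_hi < i_lo:
        raise TraceWindowError("search window contains no samples")
    seg = trace.samples[i_lo : i_hi + 1]
    # np.argmin/argmax return the first occurrence -> earliest-time tie-break
    rel = int(np.argmin(seg)) if polarity == "inward" else int(np.argmax(seg))
    idx = i_lo + rel
    half = k // 2
    if idx - half < i_lo or idx + half > i_hi:
        raise PeakEdgeError(
            f"extremum at sample {idx} within {half} samples of window edge"
        )
    peak_value = float(np.mean(trace.samples[idx - half : idx + half + 1]))
    peak_time = trace.t0 + idx * trace.dt
    return peak_value, peak_time


@dataclass
class BiexpFit:
    """Result of a biexponential decay fit.

    ``tau_w`` is the amplitude-weighted mean time constant,
    ``(|A_fast| tau_fast + |A_slow| tau_slow) / (|A_fast| + |A_slow|)``,
    using absolute amplitudes so that inward (negative) currents weight
    correctly. Components are ordered so that ``tau_fast <= tau_slow``.
    """

    A_fast: float
    tau_fast: float
    A_slow: float
    tau_slow: float
    offset: float
    tau_w: float
    window: tuple[float, float]  # [t_start, t_end] in ms, absolute trace time
    rss: float
    converged: bool
    n_points: int = 0
    message: str = ""


def _weighted_tau(A_fast: float, tau_fast: float, A_slow: float, tau_slow: float) -> float:
    wa, wb = abs(A_fast), abs(A_slow)
    if wa + wb == 0:
        return float("nan")
    return (wa * tau_fast + wb * tau_slow) / (wa + wb)


def _biexp(t: np.ndarray, A_fast: float, tau_fast: float, A_slow: float, tau_slow: float, offset: float) -> np.ndarray:
    return A_fast * np.exp(-t / tau_fast) + A_slow * np.exp(-t / tau_slow) + offset


def fit_biexponential(
    trace: Trace,
    peak_time: float,
    start_fraction: float = 0.95,
    t_end: float | None = None,
    baseline: float | None = None,
) -> BiexpFit:
    """Least-squares biexponential fit of a decay phase.

    The fit segment starts at the first post-peak sample whose amplitude
    (relative to ``baseline``) has decayed to ``start_fraction`` of the
    peak amplitude, and ends at ``t_end`` (seconds). The start is
    sample-aligned (no sub-sample interpolation), which is within one
    sample period of the exact crossing.

    Initialization is deterministic: offset from the tail mean of the
    last 10 % of the segment, time constants at 20 % and 80 % of the
    segment length, amplitudes from a linear solve at those fixed taus.
    Time constants are bounded to [0.1 ms, 10x the segment length].

    Both amplitudes are constrained to the sign of the decay (peak minus
    baseline): a post-peak decay has same-sign components, and without
    the constraint an unconstrained biexponential admits a degenerate
    family of near-equal taus with huge opposite-sign amplitudes whose
    absolute-amplitude-weighted tau is meaningless.

    Parameters
    ----------
    baseline
        Reference level (pA) against which the peak amplitude and the
        ``start_fraction`` crossing are measured. Defaults to the mean of
        the last 10 % of the [peak, t_end] segment.
    """
    if not 0.0 < start_fraction <= 1.0:
        raise ValueError("start_fraction must be in (0, 1]")
    if t_end is None:
        t_end = trace.t0 + (trace.n_samples - 1) * trace.dt
    i_peak = trace.index_at(peak_time)
    i_end = trace.index_at(t_end)
    if i_peak < 0 or i_end >= trace.n_samples or i_end <= i_peak:
        raise TraceWindowError("decay window outside trace or empty")
    seg_all = trace.samples[i_peak : i_end + 1]
    if baseline is None:
        n_tail = max(1, seg_all.size // 10)
        baseline = float(np.mean(seg_all[-n_tail:]))
    peak_amp = seg_all[0] - baseline
    if peak_amp == 0:
        raise ValueError("zero peak amplitude relative to baseline")
    # first post-peak sample decayed to start_fraction of the peak amplitude
    rel = (seg_all - baseline) / peak_amp  # 1 at peak, -> 0 at baseline
    below = np.nonzero(rel <= start_fraction)[0]
    i0_rel = int(below[0]) if below.size else 0
    seg = seg_all[i0_rel:]
    if seg.size < 20:
        raise ValueError(
            f"decay segment has {seg.size} samples; >= 20 required for a biexponential fit"
        )
    t_ms = np.arange(seg.size) * trace.dt * 1e3
    T = t_ms[-1]
    window = (
        (trace.t0 + (i_peak + i0_rel) * trace.dt) * 1e3,
        (trace.t0 + i_end * trace.dt) * 1e3,
    )

    # Deterministic initialization. Two starts are tried and the lower-RSS
    # fit kept: (i) a log-linear monoexponential estimate of the dominant
    # tau with the fast tau a fifth of it — this anchors near-monoexponential
    # decays and avoids a degenerate valley where two almost-equal taus with
    # huge opposite-sign amplitudes cancel; (ii) taus at 20 % / 80 % of the
    # segment length. Amplitudes always come from a linear solve at the
    # fixed starting taus.
    n_tail = max(1, seg.size // 10)
    c0 = float(np.mean(seg[-n_tail:]))
    y = seg - c0
    sign = 1.0 if y[0] >= 0 else -1.0
    m = sign * y
    m0 = max(m[0], np.finfo(float).tiny)
    usable = m > 0.05 * m0
    tau_mono = 0.5 * T
    if np.count_nonzero(usable) >= 5:
        slope = np.polyfit(t_ms[usable], np.log(m[usable]), 1)[0]
        if slope < 0:
            tau_mono = float(np.clip(-1.0 / slope, 0.2, 5.0 * T))
    starts = [
        (max(0.11, tau_mono / 5.0), tau_mono),
        (0.2 * T, 0.8 * T),
    ]

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return _biexp(t_ms, p["A_fast"].value, p["tau_fast"].value,
                      p["A_slow"].value, p["tau_slow"].value, p["offset"].value) - seg

    amp_lo, amp_hi = (-np.inf, 0.0) if sign < 0 else (0.0, np.inf)

    def clip_amp(a: float) -> float:
        return float(np.clip(a, amp_lo + 1e-12, amp_hi - 1e-12))

    result = None
    for tau_f0, tau_s0 in starts:
        basis = np.column_stack(
            [np.exp(-t_ms / tau_f0), np.exp(-t_ms / tau_s0), np.ones_like(t_ms)]
        )
        coef, *_ = np.linalg.lstsq(basis, seg, rcond=None)
        params = lmfit.Parameters()
        params.add("A_fast", value=clip_amp(float(coef[0])), min=amp_lo, max=amp_hi)
        params.add("tau_fast", value=tau_f0, min=0.1, max=10.0 * T)
        params.add("A_slow", value=clip_amp(float(coef[1])), min=amp_lo, max=amp_hi)
        params.add("tau_slow", value=tau_s0, min=0.1, max=10.0 * T)
        params.add("offset", value=float(coef[2]))
        candidate = lmfit.minimize(residual, params, method="leastsq")
        if result is None or candidate.chisqr < result.chisqr:
            result = candidate
    p = result.params
    a_f, tau_f = p["A_fast"].value, p["tau_fast"].value
    a_s, tau_s = p["A_slow"].value, p["tau_slow"].value
    if tau_f > tau_s:  # canonical ordering: fast component first
        a_f, tau_f, a_s, tau_s = a_s, tau_s, a_f, tau_f
    offset = p["offset"].value
    rss = float(np.sum(np.asarray(result.residual) ** 2))
    finite = all(np.isfinite(v) for v in (a_f, tau_f, a_s, tau_s, offset))
    converged = bool(result.success) and finite
    return BiexpFit(
        A_fast=float(a_f),
        tau_fast=float(tau_f),
        A_slow=float(a_s),
        tau_slow=float(tau_s),
        offset=float(offset),
        tau_w=_weighted_tau(a_f, tau_f, a_s, tau_s),
        window=window,
        rss=rss,
        converged=converged,
        n_points=int(seg.size),
        message=str(result.message),
    )
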