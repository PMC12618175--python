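"""Respiratory surrogate signals: generation, cycle analysis, and phase sorting.

A 4DCT sorter sees breathing only through an external surrogate (here, a
laser-displacement style amplitude in millimetres sampled at a fixed rate).
This module generates idealised and irregular surrogate traces, detects
breathing cycles, summarises them (period / amplitude / irregularity), and
assigns each sample a retrospective respiratory phase in [0, 100)% under a
configurable gating-trigger rule.

Conventions
-----------
* The waveform is a cosine with its peak (end-inhale) at t = 0, so phase 0%
  coincides with end-inhale and the peak |velocity| of a sinusoid of
  zero-to-peak amplitude A and period T is 2*pi*A/T, falling in the 20-30%
  phase interval.
* Amplitudes are quoted zero-to-peak throughout (generator parameters and
  ``TraceSummary.mean_amplitude`` alike).
* Irregularity is the mean of the coefficients of variation of the per-cycle
  period and the per-cycle amplitude, expressed in percent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import truncnorm

from .errors import InsufficientCyclesError, InvalidParameterError

DEFAULT_SAMPLE_RATE_HZ = 25.0

__all__ = [
    "DEFAULT_SAMPLE_RATE_HZ",
    "RespiratoryTrace",
    "CycleFeatures",
    "TraceSummary",
    "TriggerMode",
    "GatingConfig",
    "PhaseAssignment",
    "generate_sinusoid",
    "generate_irregular",
    "detect_cycles",
    "summarize_trace",
    "assign_phases",
    "phase_from_triggers",
]


@dataclass(frozen=True)
class RespiratoryTrace:
    """Uniformly sampled surrogate displacement signal.

    Attributes
    ----------
    times : np.ndarray
        Sample times in seconds, strictly increasing and uniformly spaced.
    amplitude : np.ndarray
        Surrogate displacement in millimetres, one value per sample.
    sample_rate : float
        Sampling rate in Hz (consistent with ``times``).
    """

    times: np.ndarray
    amplitude: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        amplitude = np.asarray(self.amplitude, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "amplitude", amplitude)
        if times.ndim != 1 or times.size < 2:
            raise InvalidParameterError("trace needs at least 2 samples")
        if amplitude.shape != times.shape:
            raise InvalidParameterError("times and amplitude must have equal length")
        dt = np.diff(times)
        if np.any(dt <= 0) or np.ptp(dt) > 1e-9:
            raise InvalidParameterError("sample times must be uniform and increasing")
        if not np.all(np.isfinite(amplitude)):
            raise InvalidParameterError("amplitudes must be finite")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Span of the trace in seconds."""
        return float(self.times[-1] - self.times[0])

    def interp(self, t) -> np.ndarray:
        """Amplitude linearly interpolated at arbitrary times (edge-clamped)."""
        return np.interp(t, self.times, self.amplitude)


@dataclass(frozen=True)
class CycleFeatures:
    """Per-cycle features between consecutive end-inhale peaks."""

    peak_times: np.ndarray
    cycle_periods: np.ndarray
    cycle_amplitudes: np.ndarray  # peak-to-trough, mm

    def __post_init__(self) -> None:
        if len(self.cycle_periods) != len(self.peak_times) - 1:
            raise InvalidParameterError("need one period per inter-peak interval")
        if len(self.cycle_amplitudes) != len(self.cycle_periods):
            raise InvalidParameterError("periods and amplitudes must align")
        if np.any(np.asarray(self.cycle_periods) <= 0) or np.any(
            np.asarray(self.cycle_amplitudes) <= 0
        ):
            raise InvalidParameterError("periods and amplitudes must be positive")


@dataclass(frozen=True)
class TraceSummary:
    """Mean period, zero-to-peak amplitude and irregularity of a trace."""

    mean_period: float  # s
    mean_amplitude: float  # mm, zero-to-peak
    irregularity_pct: float


class TriggerMode(str, enum.Enum):
    """Where the gating system places the phase origin in each cycle."""

    PEAK_IN_PEAK = "peak_in_peak"
    POINT_TO_POINT = "point_to_point"


@dataclass(frozen=True)
class GatingConfig:
    """Retrospective sorting configuration.

    ``trigger_level_fraction`` is only used by the point-to-point mode: the
    trigger fires at the rising crossing of
    ``trough + fraction * (peak - trough)`` within each cycle.
    """

    trigger_mode: TriggerMode = TriggerMode.PEAK_IN_PEAK
    trigger_level_fraction: float = 0.8
    n_phase_bins: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "trigger_mode", TriggerMode(self.trigger_mode))
        if self.n_phase_bins < 2:
            raise InvalidParameterError("n_phase_bins must be >= 2")
        if not 0.0 <= self.trigger_level_fraction <= 1.0:
            raise InvalidParameterError("trigger_level_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PhaseAssignment:
    """Per-sample phase labels plus the trigger times that define them.

    Samples before the first trigger or after the last one are flagged
    unassigned (phase NaN, bin -1) rather than dropped.
    """

    phase_pct: np.ndarray
    bin_index: np.ndarray
    assigned: np.ndarray
    trigger_times: np.ndarray
    n_phase_bins: int

    def phase_at(self, t) -> tuple[np.ndarray, np.ndarray]:
        """Phase (and assignability) at arbitrary times via the triggers."""
        return phase_from_triggers(self.trigger_times, np.asarray(t, dtype=float))


def phase_from_triggers(
    trigger_times: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Linear-in-time phase in [0, 100) between consecutive triggers.

    Returns ``(phase_pct, assigned)``; times outside [first, last] trigger are
    unassigned (NaN phase).
    """
    trig = np.asarray(trigger_times, dtype=float)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    phase = np.full(t.shape, np.nan)
    assigned = (t >= trig[0]) & (t <= trig[-1])
    if trig.size >= 2 and assigned.any():
        k = np.clip(np.searchsorted(trig, t[assigned], side="right") - 1, 0, trig.size - 2)
        frac = (t[assigned] - trig[k]) / (trig[k + 1] - trig[k])
        phase[assigned] = np.minimum(frac, 1.0 - 1e-12) * 100.0
    return phase, assigned


def _uniform_times(duration_s: float, sample_rate_hz: float) -> np.ndarray:
    n = int(round(duration_s * sample_rate_hz)) + 1
    return np.arange(n) / sample_rate_hz


def generate_sinusoid(
    amplitude_mm: float,
    period_s: float,
    duration_s: float,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
) -> RespiratoryTrace:
    """Cosine surrogate ``A*cos(2*pi*t/T)`` with end-inhale peak at t = 0.

    ``amplitude_mm`` is zero-to-peak; a zero amplitude yields a constant
    (static-phantom) trace. ``duration_s`` must cover at least two periods.
    """
    if period_s <= 0 or duration_s <= 0 or sample_rate_hz <= 0:
        raise InvalidParameterError("period, duration and sample rate must be positive")
    if amplitude_mm < 0:
        raise InvalidParameterError("amplitude must be non-negative")
    if duration_s < 2 * period_s:
        raise InvalidParameterError("duration must span at least two periods")
    t = _uniform_times(duration_s, sample_rate_hz)
    a = amplitude_mm * np.cos(2 * np.pi * t / period_s)
    return RespiratoryTrace(t, a, sample_rate_hz)


def generate_irregular(
    base_amplitude_mm: float,
    base_period_s: float,
    irregularity_pct: float,
    duration_s: float,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    seed: int = 0,
) -> RespiratoryTrace:
    """Irregular breathing: concatenated half-cosine cycles with jittered
    per-cycle period and amplitude.

    Each cycle i runs peak-to-peak: the first half descends from +A_i to -A_i
    as a half cosine, the second half rises from -A_i to the next cycle's
    +A_{i+1} with a cosine easing, so the signal and its derivative are
    continuous at cycle joins. Per-cycle periods and amplitudes are drawn
    independently from normal distributions with mean equal to the base value
    and coefficient of variation ``irregularity_pct / 100``, truncated at
    +/- 3 CV so both stay positive. Reproducible under a fixed seed.
    """
    if not 0.0 <= irregularity_pct <= 50.0:
        raise InvalidParameterError("irregularity_pct must be in [0, 50]")
    if base_amplitude_mm <= 0 or base_period_s <= 0 or duration_s <= 0 or sample_rate_hz <= 0:
        raise InvalidParameterError("base amplitude/period, duration, rate must be positive")

    cv = irregularity_pct / 100.0
    rng = np.random.default_rng(seed)
    # worst case: every cycle at the lower truncation bound
    n_cycles = int(np.ceil(duration_s / (base_period_s * max(1.0 - 3 * cv, 0.05)))) + 2

    def draw(mean: float, n: int) -> np.ndarray:
        if cv == 0.0:
            return np.full(n, mean)
        return truncnorm.rvs(-3.0, 3.0, loc=mean, scale=cv * mean, size=n, random_state=rng)

    periods = draw(base_period_s, n_cycles)
    amps = draw(base_amplitude_mm, n_cycles + 1)  # one extra for the final rise target

    starts = np.concatenate([[0.0], np.cumsum(periods)])
    t = _uniform_times(duration_s, sample_rate_hz)
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, n_cycles - 1)
    s = (t - starts[idx]) / periods[idx]  # local cycle fraction in [0, 1)
    a_i = amps[idx]
    a_next = amps[idx + 1]
    first_half = s <= 0.5
    out = np.empty_like(t)
    out[first_half] = a_i[first_half] * np.cos(2 * np.pi * s[first_half])
    u = 2.0 * (s[~first_half] - 0.5)
    out[~first_half] = -a_i[~first_half] + (a_i[~first_half] + a_next[~first_half]) * (
        1.0 - np.cos(np.pi * u)
    ) / 2.0
    return RespiratoryTrace(t, out, sample_rate_hz)


def detect_cycles(trace: RespiratoryTrace) -> CycleFeatures:
    """Locate end-inhale peaks and derive per-cycle periods and amplitudes.

    Peaks are local maxima with prominence >= 10% of the trace range and
    minimum separation 0.25 x the median inter-peak interval; each cycle's
    amplitude is its starting peak value minus the trough reached before the
    next peak (peak-to-trough).
    """
    amp = trace.amplitude
    rng_amp = float(np.ptp(amp))
    if rng_amp <= 0:
        raise InsufficientCyclesError("trace is constant; no cycles to detect")
    prominence = 0.1 * rng_amp
    peaks, _ = find_peaks(amp, prominence=prominence)
    if peaks.size >= 3:
        med = float(np.median(np.diff(trace.times[peaks])))
        distance = max(1, int(0.25 * med * trace.sample_rate))
        peaks, _ = find_peaks(amp, prominence=prominence, distance=distance)
    if peaks.size < 2:
        raise InsufficientCyclesError("fewer than 2 breathing peaks found")
    peak_times = trace.times[peaks]
    periods = np.diff(peak_times)
    amplitudes = np.array(
        [
            amp[peaks[i]] - amp[peaks[i] : peaks[i + 1] + 1].min()
            for i in range(peaks.size - 1)
        ]
    )
    return CycleFeatures(peak_times, periods, amplitudes)


def summarize_trace(features: CycleFeatures) -> TraceSummary:
    """Table-style summary: mean period, mean zero-to-peak amplitude, and
    irregularity = 100 x mean(CV(periods), CV(amplitudes))."""
    periods = np.asarray(features.cycle_periods, dtype=float)
    amps = np.asarray(features.cycle_amplitudes, dtype=float)
    if periods.size < 2:
        raise InsufficientCyclesError("need at least 2 cycles to summarize")

    def cv(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.mean(x))

    return TraceSummary(
        mean_period=float(np.mean(periods)),
        mean_amplitude=float(np.mean(amps)) / 2.0,  # reported zero-to-peak
        irregularity_pct=100.0 * 0.5 * (cv(periods) + cv(amps)),
    )


def _p2p_triggers(trace: RespiratoryTrace, features: CycleFeatures, fraction: float) -> np.ndarray:
    """Rising level-crossing trigger times, one per cycle.

    The level is referenced to the cycle's trough: trough + fraction x
    (next peak - trough). Sub-sample crossing times come from linear
    interpolation between the bracketing samples.
    """
    amp = trace.amplitude
    times = trace.times
    peak_idx = np.searchsorted(times, features.peak_times)
    triggers = []
    for i in range(peak_idx.size - 1):
        lo, hi = peak_idx[i], peak_idx[i + 1]
        seg = amp[lo : hi + 1]
        tr_rel = int(np.argmin(seg))
        trough = seg[tr_rel]
        level = trough + fraction * (amp[hi] - trough)
        rise = amp[lo + tr_rel : hi + 1]
        above = np.nonzero(rise >= level)[0]
        if above.size == 0:
            continue
        j = int(above[0])
        if j == 0:
            triggers.append(times[lo + tr_rel])
            continue
        i0 = lo + tr_rel + j - 1
        f = (level - amp[i0]) / (amp[i0 + 1] - amp[i0])
        triggers.append(times[i0] + f * (times[i0 + 1] - times[i0]))
    return np.asarray(triggers)


def assign_phases(trace: RespiratoryTrace, gating: GatingConfig) -> PhaseAssignment:
    """Retrospectively label every sample with a phase and bin index.

    Peak gating puts phase 0% at each end-inhale peak; point-to-point puts it
    at the rising crossing of the configured amplitude level, which shifts all
    labels by a constant fraction of the cycle relative to peak gating.
    """
    features = detect_cycles(trace)
    if gating.trigger_mode is TriggerMode.PEAK_IN_PEAK:
        triggers = np.asarray(features.peak_times, dtype=float)
    else:
        triggers = _p2p_triggers(trace, features, gating.trigger_level_fraction)
        if triggers.size < 2:
            raise InsufficientCyclesError("fewer than 2 level-crossing triggers found")
    phase, assigned = phase_from_triggers(triggers, trace.times)
    bin_width = 100.0 / gating.n_phase_bins
    bins = np.full(trace.times.shape, -1, dtype=int)
    bins[assigned] = np.clip(
        np.floor(phase[assigned] / bin_width).astype(int), 0, gating.n_phase_bins - 1
    )
    return PhaseAssignment(phase, bins, assigned, triggers, gating.n_phase_bins)
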