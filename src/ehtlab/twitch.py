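"""Twitch detection and contractility kinetics.

Reconstructs the automated analysis stage of video-optical EHT recording:
contraction peaks are found on a lightly smoothed trace, each twitch is
measured against its local diastolic baseline, and a recording is reduced
to the per-twitch averages used for pharmacology (force, frequency,
maximal contraction/relaxation velocities = max |dF/dt| on each limb).

Times of contraction and relaxation are measured between the 10 %-of-
amplitude crossings and the peak; twitches whose rising or falling limb is
cut off by the trace boundary are dropped (only "measurable" twitches
enter the averages).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .trace import ContractionTrace

__all__ = [
    "DetectionConfig",
    "TwitchEvent",
    "RecordingSummary",
    "detect_peaks",
    "measure_twitches",
    "summarize_recording",
    "analyze_trace",
]

#: fraction of amplitude defining the foot of a twitch limb
LIMB_FRACTION = 0.10
#: percentile of the inter-beat window taken as the diastolic baseline
BASELINE_PERCENTILE = 10.0


@dataclass(frozen=True)
class DetectionConfig:
    """Peak-detection settings.

    smoothing_s : moving-average window, s (robustness to pixel/sensor noise)
    min_prominence : required peak prominence as a fraction of the smoothed
        trace's dynamic range
    min_interval_s : refractory separation between accepted peaks, s
    noise_floor_k : prominence must additionally exceed this multiple of
        the estimated smoothed-noise level, so sensor noise cannot pass as
        twitches on low-amplitude recordings
    """

    smoothing_s: float = 0.05
    min_prominence: float = 0.20
    min_interval_s: float = 0.25
    noise_floor_k: float = 6.0

    def __post_init__(self) -> None:
        if self.smoothing_s <= 0 or self.min_interval_s <= 0:
            raise ValueError("smoothing_s and min_interval_s must be positive")
        if not 0 < self.min_prominence < 1:
            raise ValueError("min_prominence must be in (0, 1)")
        if self.noise_floor_k < 0:
            raise ValueError("noise_floor_k must be >= 0")


@dataclass
class TwitchEvent:
    """One measured contraction twitch."""

    peak_time: float          # s
    peak_index: int
    amplitude: float          # trace units above local diastolic baseline
    baseline: float           # local diastolic level, trace units
    max_contraction_slope: float  # trace units / s, positive
    max_relaxation_slope: float   # trace units / s, reported positive
    contraction_time: float   # s, 10 %-crossing -> peak
    relaxation_time: float    # s, peak -> 10 %-crossing


@dataclass
class RecordingSummary:
    """Per-recording averages over all measurable twitches."""

    n_twitches: int
    mean_force: float = float("nan")
    mean_contraction_velocity: float = float("nan")
    mean_relaxation_velocity: float = float("nan")
    mean_contraction_time: float = float("nan")
    mean_relaxation_time: float = float("nan")
    frequency_hz: float = float("nan")
    frequency_bpm: float = float("nan")
    frequency_defined: bool = False
    beat_intervals: np.ndarray = field(default_factory=lambda: np.empty(0))
    well_id: str = "well"
    flags: list = field(default_factory=list)


def _smooth(values: np.ndarray, dt: float, window_s: float) -> np.ndarray:
    n = max(1, int(round(window_s / dt)))
    if n % 2 == 0:
        n += 1
    if n == 1:
        return values.astype(float)
    if n > values.size:
        raise ValueError("trace shorter than the smoothing window")
    kernel = np.full(n, 1.0 / n)
    # reflect-pad so edges stay unbiased
    pad = n // 2
    padded = np.concatenate([values[pad:0:-1], values, values[-2:-pad - 2:-1]])
    return np.convolve(padded, kernel, mode="valid")


def detect_peaks(trace: ContractionTrace,
                 cfg: DetectionConfig = DetectionConfig()) -> np.ndarray:
    """Indices of contraction peaks in ``trace``.

    Local maxima of the smoothed signal with prominence above
    ``cfg.min_prominence`` of the dynamic range — and above
    ``cfg.noise_floor_k`` times the noise level surviving the smoothing,
    estimated robustly from the raw first differences — separated by at
    least ``cfg.min_interval_s``.  A flat trace yields an empty array.
    """
    smoothed = _smooth(trace.value, trace.dt, cfg.smoothing_s)
    dyn = float(smoothed.max() - smoothed.min())
    if dyn <= 0.0 or not np.isfinite(dyn):
        return np.empty(0, dtype=int)
    # raw noise sd from the MAD of first differences (twitch slopes occupy
    # a minority of samples, so the median is dominated by noise)
    noise_raw = 1.4826 * np.median(np.abs(np.diff(trace.value))) / math.sqrt(2)
    n_window = max(1, int(round(cfg.smoothing_s / trace.dt)))
    noise_smoothed = noise_raw / math.sqrt(n_window)
    prominence = max(cfg.min_prominence * dyn,
                     cfg.noise_floor_k * noise_smoothed)
    distance = max(1, int(round(cfg.min_interval_s / trace.dt)))
    peaks, _ = find_peaks(smoothed, prominence=prominence, distance=distance)
    return peaks


def measure_twitches(trace: ContractionTrace, peaks: Sequence[int],
                     cfg: DetectionConfig = DetectionConfig()) -> list[TwitchEvent]:
    """Measure amplitude, kinetics and velocities for each detected peak.

    The diastolic baseline of a twitch is the ``BASELINE_PERCENTILE`` of the
    smoothed signal over the windows to the adjacent peaks (trace ends serve
    as window bounds for the first/last twitch).  Twitches that never fall
    to within 10 % of amplitude on one side — i.e. limbs truncated by the
    recording boundary — are dropped.
    """
    peaks = np.asarray(peaks, dtype=int)
    events: list[TwitchEvent] = []
    if peaks.size == 0:
        return events
    smoothed = _smooth(trace.value, trace.dt, cfg.smoothing_s)
    gradient = np.gradient(smoothed, trace.dt)
    n = smoothed.size

    for k, p in enumerate(peaks):
        lo = peaks[k - 1] if k > 0 else 0
        hi = peaks[k + 1] if k + 1 < peaks.size else n - 1
        pre = smoothed[lo:p + 1]
        post = smoothed[p:hi + 1]
        if pre.size < 2 or post.size < 2:
            continue
        baseline = float(np.percentile(np.concatenate([pre, post]),
                                       BASELINE_PERCENTILE))
        amplitude = float(smoothed[p] - baseline)
        if amplitude <= 0:
            continue
        foot = baseline + LIMB_FRACTION * amplitude

        below_pre = np.nonzero(pre <= foot)[0]
        below_post = np.nonzero(post <= foot)[0]
        if below_pre.size == 0 or below_post.size == 0:
            continue  # limb truncated -> not measurable
        i_start = lo + below_pre[-1]
        i_end = p + below_post[0]

        rise = gradient[i_start:p + 1]
        fall = gradient[p:i_end + 1]
        if rise.size == 0 or fall.size == 0:
            continue
        events.append(TwitchEvent(
            peak_time=float(trace.time[p]),
            peak_index=int(p),
            amplitude=amplitude,
            baseline=baseline,
            max_contraction_slope=float(rise.max()),
            max_relaxation_slope=float(-fall.min()),
            contraction_time=float(trace.time[p] - trace.time[i_start]),
            relaxation_time=float(trace.time[i_end] - trace.time[p]),
        ))
    return events


def summarize_recording(events: Sequence[TwitchEvent],
                        duration: Optional[float] = None,
                        well_id: str = "well") -> RecordingSummary:
    """Reduce one recording to per-twitch means.

    Frequency is n_intervals / sum(intervals) from successive peak times
    (undefined-flagged below two twitches, never fabricated).
    """
    events = list(events)
    summary = RecordingSummary(n_twitches=len(events), well_id=well_id)
    if not events:
        summary.flags.append("no_measurable_twitches")
        return summary
    summary.mean_force = float(np.mean([e.amplitude for e in events]))
    summary.mean_contraction_velocity = float(
        np.mean([e.max_contraction_slope for e in events]))
    summary.mean_relaxation_velocity = float(
        np.mean([e.max_relaxation_slope for e in events]))
    summary.mean_contraction_time = float(
        np.mean([e.contraction_time for e in events]))
    summary.mean_relaxation_time = float(
        np.mean([e.relaxation_time for e in events]))
    if len(events) >= 2:
        times = np.array([e.peak_time for e in events])
        intervals = np.diff(times)
        summary.beat_intervals = intervals
        summary.frequency_hz = float(intervals.size / intervals.sum())
        summary.frequency_bpm = 60.0 * summary.frequency_hz
        summary.frequency_defined = True
    else:
        summary.flags.append("frequency_undefined")
    return summary


def analyze_trace(trace: ContractionTrace,
                  cfg: DetectionConfig = DetectionConfig()) -> RecordingSummary:
    """Convenience: detect + measure + summarize a force trace."""
    peaks = detect_peaks(trace, cfg)
    events = measure_twitches(trace, peaks, cfg)
    return summarize_recording(events, duration=trace.duration,
                               well_id=trace.well_id)
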