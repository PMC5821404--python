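"""Peripheral-signal analyses: ECG R-peaks, heart rate, R-R interval
scaling, and EOG event marking.

Heart-rate variability is quantified with the same detrended fluctuation
analysis used for cortical envelopes, applied to the sequence of
inter-heartbeat (R-R) intervals with beat-count windows of 3-50 beats
(roughly 3-50 s at resting heart rates).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .lrtc import ScalingFit, dfa
from .types import RRSeries, TimeSeries

__all__ = [
    "detect_rpeaks",
    "heart_rate",
    "rr_from_peaks",
    "rr_dfa",
    "eog_events",
    "count_eog_events",
]


def detect_rpeaks(
    ecg: TimeSeries,
    window_s: float = 2.0,
    rel_threshold: float = 0.6,
    refractory_s: float = 0.25,
) -> np.ndarray:
    """R-peak times via an adaptive (rolling-maximum) threshold.

    A sample qualifies as an R-peak when it is a local maximum above
    ``rel_threshold`` times the rolling ``window_s`` maximum of the trace
    and at least ``refractory_s`` from the previous detection. Detection is
    invariant to amplitude scaling of the whole trace. A flat trace yields
    no peaks.
    """
    if ecg.rate < 100:
        raise ValueError("sampling rate too low for QRS detection (< 100 Hz)")
    x = ecg.samples
    if np.allclose(x, x[0]):
        return np.array([])
    size = max(int(round(window_s * ecg.rate)), 3)
    roll_max = ndimage.maximum_filter1d(x, size=size, mode="nearest")
    height = rel_threshold * roll_max
    # guard against near-zero thresholds in silent stretches
    floor = rel_threshold * 0.5 * x.max()
    height = np.maximum(height, floor)
    peaks, _ = sps.find_peaks(x, height=height, distance=max(int(refractory_s * ecg.rate), 1))
    return ecg.t0 + peaks / ecg.rate


def heart_rate(peak_times: np.ndarray, duration_s: float) -> float:
    """Beats per minute: total R-peak count divided by duration."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return len(peak_times) / duration_s * 60.0


def rr_from_peaks(peak_times: np.ndarray) -> RRSeries:
    """Successive R-to-R intervals from detected peak times."""
    peak_times = np.asarray(peak_times, dtype=float)
    return RRSeries(intervals=np.diff(peak_times), peak_times=peak_times)


def rr_dfa(rr: RRSeries, win_min_beats: float = 3, win_max_beats: float = 50) -> ScalingFit:
    """DFA of the R-R interval sequence with beat-count windows (3-50 beats).

    Delegates to :func:`alphacrit.lrtc.dfa` with unit rate so windows are
    counted in heartbeats.
    """
    if rr.intervals.size < 150:
        raise ValueError("need >= 150 intervals for a stable scaling estimate")
    if np.allclose(rr.intervals, rr.intervals[0]):
        raise ValueError("degenerate (constant) interval series")
    _, fit = dfa(rr.intervals, rate=1.0, win_min_s=win_min_beats, win_max_s=win_max_beats)
    return fit


def eog_events(
    eog: TimeSeries,
    band: tuple[float, float] = (1.0, 5.0),
    z_threshold: float = 4.0,
) -> np.ndarray:
    """Sample indices of EOG events (blinks/saccades).

    The trace is band-pass filtered with a third-order Butterworth (1-5 Hz,
    zero phase), z-scored, and every sample whose z-score exceeds the
    threshold is marked. Use :func:`count_eog_events` to merge contiguous
    marks into discrete events.
    """
    if eog.rate <= 10:
        raise ValueError("rate too low for the 1-5 Hz event band")
    if np.allclose(eog.samples, eog.samples[0]):
        raise ValueError("zero-variance input")
    sos = sps.butter(3, band, btype="bandpass", fs=eog.rate, output="sos")
    filt = sps.sosfiltfilt(sos, eog.samples)
    z = (filt - filt.mean()) / filt.std()
    return np.flatnonzero(z > z_threshold)


def count_eog_events(indices: np.ndarray) -> int:
    """Number of discrete events: contiguous suprathreshold runs merged."""
    indices = np.asarray(indices)
    if indices.size == 0:
        return 0
    return int(1 + np.sum(np.diff(indices) > 1))
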