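"""Detrended fluctuation analysis (DFA) and spectral scale-free measures.

DFA quantifies long-range temporal correlations (LRTC) of a time series as
the power-law growth of the root-mean-square fluctuation of its locally
detrended cumulative sum with window length N::

    <F_N>  ∝  N ** alpha

``alpha ~ 0.5`` indicates an uncorrelated process, ``0.5 < alpha < 1``
scale-free long-range correlations, ``alpha > 1`` an unbounded process.
The spectral counterpart is the power-law exponent ``beta`` of the power
spectrum, ``P(f) ∝ f**-beta``, related to DFA through ``beta = 2*alpha - 1``
for power-law decaying autocorrelations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import EnvelopeSeries, Spectrum, TimeSeries

__all__ = [
    "FluctuationFunction",
    "ScalingFit",
    "dfa_profile",
    "log_spaced_windows",
    "dfa_fluctuation",
    "fit_scaling_exponent",
    "dfa",
    "spectral_exponent",
    "alpha_from_beta",
    "envelope_spectrum_auc",
]


@dataclass
class FluctuationFunction:
    """DFA fluctuation function: mean RMS fluctuation per window length."""

    window_samples: np.ndarray
    mean_fluct: np.ndarray
    segment_counts: np.ndarray
    rate: float = 1.0

    @property
    def window_seconds(self) -> np.ndarray:
        return self.window_samples / self.rate


@dataclass
class ScalingFit:
    """Log-log regression of the fluctuation function."""

    alpha: float
    intercept: float
    r_squared: float


def dfa_profile(x) -> np.ndarray:
    """Cumulative sum of the demeaned signal, X(t) = sum_{t'<=t} (x - <x>).

    The final element is ~0 by construction (telescoping sum).
    """
    if isinstance(x, (TimeSeries, EnvelopeSeries)):
        x = x.samples
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    return np.cumsum(x - x.mean())


def log_spaced_windows(
    n_min_s: float = 3.0,
    n_max_s: float = 50.0,
    count: int = 15,
    rate: float = 1.0,
) -> np.ndarray:
    """Logarithmically spaced window lengths in samples.

    Endpoints are included, lengths are rounded to integer samples and
    duplicates (possible after rounding at low rates) removed.
    """
    if not n_min_s < n_max_s:
        raise ValueError("need n_min_s < n_max_s")
    if count < 2:
        raise ValueError("need count >= 2")
    win = np.geomspace(n_min_s * rate, n_max_s * rate, count)
    win = np.unique(np.rint(win).astype(int))
    if win[0] < 3:
        raise ValueError("smallest window below 3 samples; increase n_min_s or rate")
    return win


def _window_fluctuation(profile: np.ndarray, n: int, overlap: float) -> tuple[float, int]:
    """Mean RMS of linearly detrended segments of length ``n``.

    Segments start at floor(i * (1-overlap complement) * n) ... concretely at
    floor(i * overlap * n) for i = 0..k-1 with k = floor((T - n)/(overlap*n)),
    i.e. 50%-overlapping segments anchored at the start; a trailing remainder
    shorter than n is discarded.
    """
    t_len = profile.size
    step = overlap * n
    k = int((t_len - n) / step)
    if k < 1:
        return np.nan, 0
    starts = np.floor(np.arange(k) * step).astype(int)
    seg = profile[starts[:, None] + np.arange(n)[None, :]]
    # closed-form linear detrend on centred time axis
    t = np.arange(n, dtype=float) - (n - 1) / 2.0
    slope = (seg @ t) / (t @ t)
    resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * t
    f_seg = np.sqrt(np.mean(resid**2, axis=1))
    return float(f_seg.mean()), k


def dfa_fluctuation(
    profile: np.ndarray,
    windows: np.ndarray,
    overlap: float = 0.5,
    rate: float = 1.0,
) -> FluctuationFunction:
    """Fluctuation function <F_N> over the given window lengths (samples).

    For each window length N the cumulative profile is cut into
    k = floor[(T - N)/(overlap*N)] segments with the given overlap, each
    segment is linearly detrended by least squares, and the RMS residual is
    averaged over segments. Windows yielding k < 1 are dropped with a warning.
    """
    profile = np.asarray(profile, dtype=float)
    windows = np.asarray(windows, dtype=int)
    if windows.size == 0:
        raise ValueError("no windows given")
    out_w, out_f, out_k = [], [], []
    for n in windows:
        f_mean, k = _window_fluctuation(profile, int(n), overlap)
        if k < 1:
            import warnings

            warnings.warn(f"window of {n} samples exceeds usable length; dropped")
            continue
        out_w.append(int(n))
        out_f.append(f_mean)
        out_k.append(k)
    return FluctuationFunction(
        window_samples=np.array(out_w),
        mean_fluct=np.array(out_f),
        segment_counts=np.array(out_k),
        rate=rate,
    )


def fit_scaling_exponent(ff: FluctuationFunction) -> ScalingFit:
    """Ordinary least squares of log<F_N> on log N (all retained windows)."""
    if ff.window_samples.size < 3:
        raise ValueError("need >= 3 windows for a scaling fit")
    if np.any(ff.mean_fluct <= 0):
        raise ValueError("degenerate input: zero fluctuation in a retained window")
    log_n = np.log10(ff.window_samples.astype(float))
    log_f = np.log10(ff.mean_fluct)
    slope, intercept = np.polyfit(log_n, log_f, 1)
    pred = slope * log_n + intercept
    ss_res = float(np.sum((log_f - pred) ** 2))
    ss_tot = float(np.sum((log_f - log_f.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ScalingFit(alpha=float(slope), intercept=float(intercept), r_squared=r2)


def dfa(
    x,
    rate: float | None = None,
    win_min_s: float = 3.0,
    win_max_s: float = 50.0,
    n_windows: int = 15,
    overlap: float = 0.5,
) -> tuple[FluctuationFunction, ScalingFit]:
    """Full DFA pipeline: profile, fluctuation function, log-log fit.

    ``x`` may be a TimeSeries/EnvelopeSeries (rate taken from the object) or a
    plain array with an explicit ``rate``. Window bounds are in seconds (or in
    samples when rate=1, e.g. beat-count windows for R-R series).
    """
    if isinstance(x, (TimeSeries, EnvelopeSeries)):
        rate = x.rate
        x = x.samples
    if rate is None:
        raise ValueError("rate required for array input")
    windows = log_spaced_windows(win_min_s, win_max_s, n_windows, rate)
    if windows[-1] > len(x):
        raise ValueError("largest DFA window exceeds signal length")
    ff = dfa_fluctuation(dfa_profile(x), windows, overlap=overlap, rate=rate)
    return ff, fit_scaling_exponent(ff)


def spectral_exponent(sp: Spectrum, f_range: tuple[float, float]) -> float:
    """Power-law decay exponent beta of the spectrum over ``f_range``.

    Fits log10 P on log10 f by OLS and returns the *positive-for-decay*
    exponent, i.e. beta such that P(f) ∝ f**-beta. A flat spectrum gives
    beta ~ 0; 1/f noise gives beta ~ 1. On this convention the DFA exponent
    satisfies alpha = (beta + 1) / 2.
    """
    f_lo, f_hi = f_range
    m = (sp.frequencies >= f_lo) & (sp.frequencies <= f_hi) & (sp.frequencies > 0)
    if m.sum() < 5:
        raise ValueError("need >= 5 spectral points in range")
    p = sp.power[m]
    if np.any(p <= 0):
        raise ValueError("nonpositive power in fit range")
    slope, _ = np.polyfit(np.log10(sp.frequencies[m]), np.log10(p), 1)
    return float(-slope)


def alpha_from_beta(beta: float) -> float:
    """DFA exponent implied by the spectral decay exponent: (beta + 1) / 2."""
    return (beta + 1.0) / 2.0


def envelope_spectrum_auc(sp: Spectrum, f_range: tuple[float, float]) -> float:
    """Trapezoidal integral of spectral power over ``f_range`` (signal variance)."""
    f_lo, f_hi = f_range
    m = (sp.frequencies >= f_lo) & (sp.frequencies <= f_hi)
    if m.sum() < 2:
        raise ValueError("empty or degenerate frequency range")
    return float(np.trapezoid(sp.power[m], sp.frequencies[m]))
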