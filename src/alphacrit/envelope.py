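"""Band-pass filtering, analytic-signal envelopes and multitaper spectra.

The amplitude envelope of a band-limited signal is the magnitude of its
analytic (Hilbert) signal; its slow fluctuations are the substrate of the
long-range temporal correlation analyses in :mod:`alphacrit.lrtc`. Power
spectra are estimated with the multitaper method (discrete prolate
spheroidal / Slepian tapers), averaging over tapers and 50%-overlapping
windows: a window of T seconds with W Hz half-bandwidth smoothing admits
2*T*W - 1 orthogonal tapers (5 s and 2 Hz give 19).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import EnvelopeSeries, Spectrum, TimeSeries

__all__ = [
    "fir_order",
    "bandpass_fir",
    "hilbert_envelope",
    "multitaper_spectrum",
    "transient_samples",
    "spectral_peak",
]


def fir_order(rate: float, f_lo: float, cycles: float = 3.0) -> int:
    """Odd FIR length spanning ``cycles`` periods of the band's low edge.

    Three cycles of the low edge is a standard trade-off between transition
    width and edge loss: for an 8-12 Hz band it passes in-band tones at unit
    gain while attenuating components a band-width away by >= 20 dB.
    """
    n = int(np.ceil(cycles * rate / f_lo))
    return n + 1 if n % 2 == 0 else n


def transient_samples(rate: float, f_lo: float, cycles: float = 3.0) -> int:
    """Samples to discard at each edge after filtering (one filter length)."""
    return fir_order(rate, f_lo, cycles)


def bandpass_fir(ts: TimeSeries, f_lo: float, f_hi: float, cycles: float = 3.0) -> TimeSeries:
    """Zero-phase FIR band-pass filter (Hamming-window design).

    The linear-phase kernel is applied by centred convolution, so the output
    is delay-compensated and has the same length as the input. Edge regions
    of one filter length remain contaminated by the startup transient; see
    :func:`transient_samples`.
    """
    nyq = ts.rate / 2.0
    if not (0 < f_lo < f_hi < nyq):
        raise ValueError(f"band ({f_lo}, {f_hi}) outside (0, {nyq}) Hz")
    ntaps = fir_order(ts.rate, f_lo, cycles)
    if ntaps >= ts.n:
        raise ValueError("signal shorter than the filter kernel")
    taps = sps.firwin(ntaps, [f_lo, f_hi], pass_zero=False, fs=ts.rate)
    y = sps.fftconvolve(ts.samples, taps, mode="same")
    return TimeSeries(samples=y, rate=ts.rate, t0=ts.t0)


def hilbert_envelope(ts: TimeSeries, band: tuple[float, float] | None = None) -> EnvelopeSeries:
    """Amplitude envelope: magnitude of the analytic signal.

    The input is assumed to be band-limited already (see
    :func:`bandpass_fir`); ``band`` is carried as metadata.
    """
    if ts.n < 8:
        raise ValueError("need >= 8 samples for an analytic signal")
    env = np.abs(sps.hilbert(ts.samples))
    if band is None:
        band = (1e-9, ts.rate / 2 * (1 - 1e-12))
    return EnvelopeSeries(samples=env, rate=ts.rate, band=band, t0=ts.t0)


def multitaper_spectrum(
    ts: TimeSeries | EnvelopeSeries,
    window_s: float = 5.0,
    smoothing_hz: float = 2.0,
) -> Spectrum:
    """Multitaper power spectral density, averaged over Slepian tapers and
    50%-overlapping windows.

    ``smoothing_hz`` is the half-bandwidth W of the spectral concentration;
    the taper count is 2*window_s*W - 1. The returned one-sided density
    integrates to the signal variance (Parseval).
    """
    rate = ts.rate
    x = np.asarray(ts.samples, dtype=float)
    m = int(round(window_s * rate))
    if x.size < m:
        raise ValueError("signal shorter than one spectral window")
    nw = window_s * smoothing_hz
    k = int(round(2 * nw - 1))
    if k < 1:
        raise ValueError("smoothing too small for window (no tapers)")
    tapers = sps.windows.dpss(m, nw, Kmax=k)  # unit-energy rows
    step = max(m // 2, 1)
    starts = np.arange(0, x.size - m + 1, step)
    x = x - x.mean()
    psd = np.zeros(m // 2 + 1)
    for s in starts:
        seg = x[s : s + m]
        spec = np.fft.rfft(tapers * seg[None, :], axis=1)
        psd += np.mean(np.abs(spec) ** 2, axis=0)
    psd /= len(starts)
    # one-sided density normalisation: integral over f equals variance
    psd /= rate
    psd[1:] *= 2.0
    if m % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(m, 1.0 / rate)
    return Spectrum(
        frequencies=freqs[1:],
        power=psd[1:],
        taper_count=k,
        window_s=window_s,
        smoothing_hz=smoothing_hz,
    )


def spectral_peak(sp: Spectrum, f_range: tuple[float, float] = (2.0, 50.0)) -> float:
    """Frequency of the most prominent oscillatory peak in ``f_range``.

    Neural population spectra combine an aperiodic 1/f-like background with
    oscillatory bumps; the oscillation of interest is therefore the most
    *prominent* local maximum of log power, not the absolute maximum (which
    the background places at the lowest frequency). Falls back to the
    absolute maximum if no local peak exists in range.
    """
    m = (sp.frequencies >= f_range[0]) & (sp.frequencies <= f_range[1])
    if m.sum() < 3:
        raise ValueError("need >= 3 spectral points in range")
    f = sp.frequencies[m]
    logp = np.log10(np.maximum(sp.power[m], 1e-300))
    peaks, props = sps.find_peaks(logp, prominence=0.0)
    if peaks.size == 0:
        return float(f[np.argmax(logp)])
    return float(f[peaks[np.argmax(props["prominences"])]])
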