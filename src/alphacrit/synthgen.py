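"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its arguments including the seed
(NumPy PCG64 via ``default_rng``), and plants a known ground truth that the
matching analysis stage is expected to recover:

* colored noise with an exact power-law amplitude spectrum (spectral
  synthesis: deterministic amplitude law, independent uniform phases);
* alpha-band carriers amplitude-modulated by a scale-free envelope whose
  DFA exponent is set through beta = 2*alpha - 1;
* truncated power-law avalanche sizes (inverse-CDF sampling);
* toy sensor/filter/cross-spectral sets with planted dipole orientations;
* synthetic ECG with known R-peak times and tunable R-R scaling;
* paired per-subject voxel maps with an optional localized effect.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .types import AvalancheSizes, PairedVoxelMaps, TimeSeries

__all__ = [
    "gen_colored_noise",
    "gen_scalefree_oscillation",
    "gen_powerlaw_sizes",
    "powerlaw_cdf",
    "gen_toy_sensor_set",
    "gen_synthetic_ecg",
    "gen_paired_voxel_maps",
    "lattice_adjacency",
]

#: random generator algorithm used by every generator (recorded for
#: cross-language reproducibility)
RNG_ALGORITHM = "numpy.random.PCG64"


def gen_colored_noise(beta: float, n: int, rate: float, seed: int) -> TimeSeries:
    """Gaussian-like noise with power spectrum P(f) ∝ f**-beta.

    Spectral synthesis: the amplitude spectrum follows the deterministic law
    f**(-beta/2) while phases are independent and uniform, so the periodogram
    slope equals -beta by construction. The output is zero-mean (DC bin set
    to zero) and scaled to unit standard deviation.
    """
    if n < 64:
        raise ValueError("need n >= 64")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not -1.0 <= beta <= 2.0:
        raise ValueError("beta outside [-1, 2]")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amp[-1]  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    x /= x.std()
    return TimeSeries(samples=x, rate=rate)


def gen_scalefree_oscillation(
    alpha_target: float,
    carrier_hz: float,
    duration_s: float,
    rate: float,
    seed: int,
) -> TimeSeries:
    """Oscillation whose amplitude envelope has DFA exponent ``alpha_target``.

    A sinusoidal carrier is multiplied by a nonnegative envelope built from
    colored noise with beta = 2*alpha_target - 1. The envelope is made
    nonnegative by subtracting its minimum and adding a small offset (a
    shift leaves the autocorrelation exponent intact, unlike rectification).
    Band-passing at the carrier and applying DFA to the Hilbert envelope
    recovers ``alpha_target``.
    """
    if not 0.5 <= alpha_target < 1.0:
        raise ValueError("alpha_target outside [0.5, 1)")
    if not 0 < carrier_hz < rate / 2:
        raise ValueError("carrier outside (0, rate/2)")
    n = int(round(duration_s * rate))
    beta = 2.0 * alpha_target - 1.0
    noise = gen_colored_noise(beta, n, rate, seed).samples
    env = noise - noise.min() + 0.1
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    phase0 = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / rate
    return TimeSeries(samples=env * np.sin(2 * np.pi * carrier_hz * t + phase0), rate=rate)


def powerlaw_cdf(exponent: float, smin: int, smax: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and CDF of the truncated discrete power law p(s) ∝ s**exponent."""
    if smin < 1 or smax <= smin:
        raise ValueError("need 1 <= smin < smax")
    support = np.arange(smin, smax + 1)
    pmf = support.astype(float) ** exponent
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    return support, cdf


def gen_powerlaw_sizes(
    exponent: float, smin: int, smax: int, n: int, seed: int
) -> AvalancheSizes:
    """Inverse-CDF samples from the truncated discrete power law on [smin, smax]."""
    if n < 1:
        raise ValueError("need n >= 1")
    support, cdf = powerlaw_cdf(exponent, smin, smax)
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return AvalancheSizes(sizes=support[np.searchsorted(cdf, u, side="left")])


def gen_toy_sensor_set(
    n_sensors: int,
    n_sources: int,
    n_sessions: int,
    seed: int,
    noise_power: float = 0.01,
    source_power: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Toy spatial filters and sensor CSDs with planted dipole orientations.

    Per session an orthonormal sensor frame is drawn per source (columns of a
    QR factorisation of a random matrix, so frames of different sources are
    mutually orthogonal — this requires ``n_sensors >= 3 * n_sources``). The
    sensor cross-spectral matrix is built from each planted unit orientation
    plus isotropic noise; with vanishing noise the planted orientation is
    exactly recoverable from the session-mean source-level CSD.

    Returns
    -------
    filters : ndarray, shape (n_sessions, n_sources, n_sensors, 3)
    csds : ndarray, shape (n_sessions, n_sensors, n_sensors)
    orientations : ndarray, shape (n_sources, 3)
        Planted unit orientations (recoverable up to sign).
    """
    if n_sensors < 3 * n_sources:
        raise ValueError("need n_sensors >= 3 * n_sources (rank-deficient otherwise)")
    rng = np.random.default_rng(seed)
    orientations = rng.normal(size=(n_sources, 3))
    orientations /= np.linalg.norm(orientations, axis=1, keepdims=True)
    filters = np.empty((n_sessions, n_sources, n_sensors, 3))
    csds = np.empty((n_sessions, n_sensors, n_sensors))
    for i in range(n_sessions):
        q, _ = np.linalg.qr(rng.normal(size=(n_sensors, 3 * n_sources)))
        c = noise_power * np.eye(n_sensors)
        for r in range(n_sources):
            frame = q[:, 3 * r : 3 * r + 3]
            filters[i, r] = frame
            topo = frame @ orientations[r]
            c += source_power * np.outer(topo, topo)
        csds[i] = c
    return filters, csds, orientations


def gen_synthetic_ecg(
    duration_s: float,
    mean_bpm: float,
    rr_alpha: float,
    rate: float,
    seed: int,
    rr_cv: float = 0.05,
) -> tuple[TimeSeries, np.ndarray]:
    """Synthetic ECG trace with known R-peak times.

    QRS complexes are 10-ms triangular spikes of amplitude 10x the baseline
    noise SD — an unambiguous detection target, not a morphological model
    (no P/T waves). Successive R-R intervals fluctuate around 60/mean_bpm
    with coefficient of variation ``rr_cv`` and a DFA exponent ~ ``rr_alpha``
    imposed through colored noise with beta = 2*rr_alpha - 1.
    """
    if not 30 <= mean_bpm <= 200:
        raise ValueError("mean_bpm outside [30, 200]")
    if rate < 100:
        raise ValueError("rate too low to resolve a 10-ms QRS (< 100 Hz)")
    mean_rr = 60.0 / mean_bpm
    n_beats = int(duration_s / mean_rr * 1.3) + 16
    fluct = gen_colored_noise(2 * rr_alpha - 1, max(n_beats, 64), 1.0, seed).samples[:n_beats]
    intervals = mean_rr * (1.0 + rr_cv * fluct)
    intervals = np.clip(intervals, 0.3 * mean_rr, 3.0 * mean_rr)
    peak_times = np.cumsum(intervals) + mean_rr / 2
    peak_times = peak_times[peak_times < duration_s - 0.05]
    n = int(round(duration_s * rate))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    noise_sd = 0.01
    sig = rng.normal(scale=noise_sd, size=n)
    half = max(int(round(0.005 * rate)), 1)  # half-width of the 10-ms spike
    template = 10 * noise_sd * (1.0 - np.abs(np.arange(-half, half + 1)) / (half + 1))
    for t_peak in peak_times:
        c = int(round(t_peak * rate))
        lo, hi = c - half, c + half + 1
        if lo >= 0 and hi <= n:
            sig[lo:hi] += template
    return TimeSeries(samples=sig, rate=rate), peak_times


def lattice_adjacency(n_voxels: int) -> sparse.csr_matrix:
    """4-connectivity adjacency of ``n_voxels`` laid out row-major on a
    near-square 2-D lattice (boolean, symmetric)."""
    width = int(np.ceil(np.sqrt(n_voxels)))
    rows, cols = [], []
    for v in range(n_voxels):
        r, c = divmod(v, width)
        for dr, dc in ((0, 1), (1, 0)):
            r2, c2 = r + dr, c + dc
            w = r2 * width + c2
            if c2 < width and w < n_voxels:
                rows += [v, w]
                cols += [w, v]
    adj = sparse.csr_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n_voxels, n_voxels)
    )
    return adj


def gen_paired_voxel_maps(
    n_subjects: int,
    n_voxels: int,
    effect_size: float,
    effect_region,
    seed: int,
) -> PairedVoxelMaps:
    """Paired subject-by-voxel maps with a localized standardized effect.

    Condition A is standard normal per subject and voxel; condition B adds
    unit-variance paired noise plus ``effect_size`` (in SD units of the
    within-pair difference) on the voxels of ``effect_region``. Voxels carry
    a 4-connected lattice adjacency.
    """
    if n_subjects < 5:
        raise ValueError("need n_subjects >= 5")
    region = np.asarray(effect_region, dtype=int)
    if region.size and (region.min() < 0 or region.max() >= n_voxels):
        raise ValueError("effect_region outside voxel index range")
    rng = np.random.default_rng(seed)
    cond_a = rng.normal(size=(n_subjects, n_voxels))
    cond_b = cond_a + rng.normal(size=(n_subjects, n_voxels))
    if region.size:
        cond_b[:, region] += effect_size
    return PairedVoxelMaps(
        cond_a=cond_a,
        cond_b=cond_b,
        adjacency=lattice_adjacency(n_voxels),
        effect_region=region,
    )
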