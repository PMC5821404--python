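"""Lightweight containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSeries:
    """Uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : ndarray
        Signal values (arbitrary units).
    rate : float
        Sampling rate in Hz. Must be positive.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds (n / rate)."""
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate


@dataclass
class EnvelopeSeries:
    """Nonnegative amplitude-envelope samples of a band-limited signal."""

    samples: np.ndarray
    rate: float
    band: tuple[float, float]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples < 0):
            raise ValueError("envelope samples must be nonnegative")
        f_lo, f_hi = self.band
        if not (0 < f_lo < f_hi < self.rate / 2):
            raise ValueError(f"band {self.band} outside (0, rate/2)")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate


@dataclass
class Spectrum:
    """One-sided power spectral density estimate."""

    frequencies: np.ndarray
    power: np.ndarray
    taper_count: int = 1
    window_s: float = 0.0
    smoothing_hz: float = 0.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


@dataclass
class AvalancheSizes:
    """Positive-integer event sizes (number of activated units per avalanche)."""

    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.sizes.size and self.sizes.min() < 1:
            raise ValueError("avalanche sizes must be >= 1")

    @property
    def n(self) -> int:
        return self.sizes.size


@dataclass
class PairedVoxelMaps:
    """Per-subject voxel maps under two paired conditions plus voxel adjacency.

    ``adjacency`` is a boolean symmetric scipy sparse matrix (voxel x voxel).
    """

    cond_a: np.ndarray
    cond_b: np.ndarray
    adjacency: "object"
    effect_region: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.cond_a = np.asarray(self.cond_a, dtype=float)
        self.cond_b = np.asarray(self.cond_b, dtype=float)
        if self.cond_a.shape != self.cond_b.shape:
            raise ValueError("both conditions must share subject x voxel shape")

    @property
    def n_subjects(self) -> int:
        return self.cond_a.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.cond_a.shape[1]


@dataclass
class RRSeries:
    """Successive R-to-R intervals (s) and the R-peak times they derive from."""

    intervals: np.ndarray
    peak_times: np.ndarray

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.intervals.size != self.peak_times.size - 1:
            raise ValueError("need len(intervals) == len(peak_times) - 1")
        if self.intervals.size and self.intervals.min() <= 0:
            raise ValueError("intervals must be positive")
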