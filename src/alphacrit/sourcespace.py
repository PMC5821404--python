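"""Session-unbiased dipole orientation selection and source projection.

Given precomputed sensor-to-source spatial filters A_i(r) (sensors x 3
orientations, one per session i) and per-session sensor cross-spectral
matrices C_i(f), the session-mean source-level CSD

    C(r, f) = (1/S) * sum_i  A_i(r)^H  C_i(f)  A_i(r)

is a 3x3 Hermitian matrix whose leading eigenvector u_1(r, f) is the
dominant dipole orientation — the direction maximising projected power,
chosen once across sessions so that between-session power differences are
not confounded by orientation flips. The oriented one-dimensional filter is
B_i(r, f) = A_i(r) u_1(r, f); envelopes are |H_i(f, t) B_i| and power is
B_i^H C_i B_i.
"""

from __future__ import annotations

import numpy as np

from .types import EnvelopeSeries

__all__ = [
    "session_mean_source_csd",
    "dominant_orientation",
    "oriented_filter",
    "project_envelope",
    "source_power",
]


def session_mean_source_csd(filters: np.ndarray, csds: np.ndarray, source: int) -> np.ndarray:
    """Mean over sessions of A_i^H C_i A_i for one source (3x3 Hermitian PSD).

    ``filters`` has shape (n_sessions, n_sources, n_sensors, 3) and ``csds``
    (n_sessions, n_sensors, n_sensors). The conjugate transpose is used so
    the result is Hermitian for complex CSDs.
    """
    filters = np.asarray(filters)
    csds = np.asarray(csds)
    if filters.shape[0] < 1:
        raise ValueError("need at least one session")
    if filters.shape[2] != csds.shape[1]:
        raise ValueError("sensor dimension mismatch between filters and CSDs")
    acc = np.zeros((3, 3), dtype=complex)
    for i in range(filters.shape[0]):
        a = filters[i, source]
        acc += a.conj().T @ csds[i] @ a
    out = acc / filters.shape[0]
    if np.allclose(out.imag, 0):
        return out.real
    return out


def dominant_orientation(c3: np.ndarray) -> np.ndarray:
    """Leading eigenvector of a 3x3 Hermitian PSD matrix, unit norm.

    The eigenvector phase/sign is fixed deterministically: the global phase
    is rotated so the largest-magnitude component is real and positive. A
    near-degenerate leading eigenvalue pair (gap < 1e-12 * trace) is
    tolerated — eigh's deterministic ordering breaks the tie.
    """
    c3 = np.asarray(c3)
    if c3.shape != (3, 3):
        raise ValueError("expected a 3x3 matrix")
    vals, vecs = np.linalg.eigh(c3)
    u = vecs[:, -1]
    j = int(np.argmax(np.abs(u)))
    phase = u[j] / abs(u[j])
    u = u / phase
    if np.allclose(np.asarray(u).imag, 0):
        u = np.asarray(u).real
    return u / np.linalg.norm(u)


def oriented_filter(filters: np.ndarray, csds: np.ndarray, source: int) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased per-session sensor weights B_i = A_i u_1 for one source.

    Returns (B, u1) with B of shape (n_sessions, n_sensors).
    """
    u1 = dominant_orientation(session_mean_source_csd(filters, csds, source))
    b = np.einsum("isk,k->is", np.asarray(filters)[:, source], u1)
    return b, u1


def project_envelope(analytic: np.ndarray, b: np.ndarray, rate: float, band=(8.0, 12.0)) -> EnvelopeSeries:
    """Source-space amplitude envelope |H(f, t) . B| of a sensor-space
    analytic (complex, band-limited) signal.

    ``analytic`` has shape (n_samples, n_sensors); ``b`` is one session's
    oriented filter (n_sensors,).
    """
    analytic = np.asarray(analytic)
    if analytic.shape[0] == 0:
        raise ValueError("empty input")
    if analytic.shape[1] != np.asarray(b).size:
        raise ValueError("sensor count mismatch")
    env = np.abs(analytic @ np.asarray(b))
    return EnvelopeSeries(samples=env, rate=rate, band=band)


def source_power(b: np.ndarray, csd: np.ndarray) -> float:
    """Source-level power B^H C B (real part) for one session.

    Negative values beyond -1e-9 * trace(C) signal an invalid (non-PSD) CSD.
    """
    b = np.asarray(b)
    csd = np.asarray(csd)
    if b.size != csd.shape[0]:
        raise ValueError("dimension mismatch")
    p = float(np.real(b.conj() @ csd @ b))
    tol = 1e-9 * abs(float(np.real(np.trace(csd))))
    if p < -tol:
        raise ValueError(f"negative source power {p}: CSD is not positive semidefinite")
    return max(p, 0.0)
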