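"""Independent reference implementations used only as test oracles.

These deliberately use naive algorithms (double loops, direct formulas,
alternative quadrature) so they share no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def naive_dfa_fluctuation(profile, windows, overlap=0.5):
    """Double-loop DFA fluctuation function (np.polyfit per segment)."""
    profile = np.asarray(profile, dtype=float)
    t_len = len(profile)
    out = []
    for n in windows:
        step = overlap * n
        k = int((t_len - n) / step)
        f_vals = []
        for i in range(k):
            start = int(math.floor(i * step))
            seg = profile[start : start + n]
            x = np.arange(n, dtype=float)
            coef = np.polyfit(x, seg, 1)
            resid = seg - np.polyval(coef, x)
            f_vals.append(np.sqrt(np.mean(resid**2)))
        out.append(np.mean(f_vals))
    return np.array(out)


def periodogram_slope(x, rate, f_min=0.0):
    """Least-squares log-log slope of the raw periodogram."""
    from scipy.signal import periodogram

    f, p = periodogram(x, fs=rate)
    m = (f > f_min) & (p > 0)
    return np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)[0]


def correlation_bf_substituted(r, n):
    """Correlation JZS Bayes factor via the substitution g = x/(1-x).

    Same integrand family as the package's converter but integrated on the
    unit interval with an independent change of variables and quadrature
    grid — a numerical cross-check, not a shared code path.
    """
    from scipy.integrate import quad

    r2 = r**2

    def h(x):
        g = x / (1 - x)
        jac = 1.0 / (1 - x) ** 2
        return (
            (1 + g) ** ((n - 2) / 2)
            * (1 + (1 - r2) * g) ** (-(n - 1) / 2)
            * math.sqrt(n / 2)
            / math.gamma(0.5)
            * g**-1.5
            * math.exp(-n / (2 * g))
            * jac
        )

    val, _ = quad(h, 1e-12, 1 - 1e-12, limit=400)
    return val


def brute_force_max_projected_power(c3, n_probe=10_000, seed=0):
    """Max of u^T C u over random unit 3-vectors (sphere sampling)."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n_probe, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    vals = np.einsum("ni,ij,nj->n", u, c3, u).real
    return u, vals


def reference_network_step(conn, cfg, n_steps, uniforms):
    """Per-edge, pure-Python integrator for tiny networks (no vectorization).

    Consumes the same pre-drawn uniforms (one per unit and step, used only
    when the spiking probability is positive) as the production kernel, so
    results must be bit-identical.
    """
    n = conn.n_units
    kinds = conn.kinds
    gain = {
        (0, 0): cfg.gain_ee,
        (0, 1): cfg.gain_ei,
        (1, 0): cfg.gain_ie,
        (1, 1): cfg.gain_ii,
    }
    edges = []
    for j in range(n):
        for e in range(conn.out_indptr[j], conn.out_indptr[j + 1]):
            t = int(conn.out_targets[e])
            edges.append((j, t, conn.out_weights[e] * gain[(kinds[t], kinds[j])]))
    tau_p = [cfg.tau_p_exc_ms if k == 0 else cfg.tau_p_inh_ms for k in kinds]
    p0 = [cfg.p0_exc if k == 0 else cfg.p0_inh for k in kinds]
    p_r = [cfg.p_reset_exc if k == 0 else cfg.p_reset_inh for k in kinds]
    cur_i = [0.0] * n
    cur_p = [0.0] * n
    spiked = [0] * n
    pop = []
    counts = [0] * n
    dt = cfg.dt_ms
    decay_i = 1.0 - dt / cfg.tau_i_ms
    add_i = dt * cfg.i0 / cfg.tau_i_ms
    for t in range(n_steps):
        for j, tg, w in edges:
            if spiked[j]:
                cur_i[tg] += w
        new = [0] * n
        c = 0
        for i in range(n):
            cur_i[i] = cur_i[i] * decay_i + add_i
            cur_p[i] = (cur_p[i] + cur_i[i]) * (1.0 - dt / tau_p[i]) + dt * p0[i] / tau_p[i]
            prob = min(cur_p[i] * dt, 1.0)
            if prob > 0 and uniforms[t, i] < prob:
                new[i] = 1
                cur_p[i] = p_r[i]
                counts[i] += 1
                c += 1
        spiked = new
        pop.append(c)
    return np.array(pop), np.array(counts)
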