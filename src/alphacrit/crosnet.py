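"""Critical-oscillation recurrent E/I network with synaptic gain modulation.

A 50x50 lattice of 2,500 probabilistic integrate-and-fire units (75%
excitatory) with local connectivity inside a 7x7 neighbourhood and
exponentially distance-decaying connection probability. Unit dynamics per
1-ms step combine a synaptic input variable I and a spiking probability P:

    I_i <- I_i + sum_j N_ij W_ij S_j        (synaptic input from last step)
    tau_I dI_i/dt = I0 - I_i                (input decay, tau_I = 9 ms)
    P_i <- P_i + I_i                        (probability accumulation)
    tau_P dP_i/dt = P0 - P_i                (probability decay, 6/12 ms)
    spike_i ~ Bernoulli(clip(P_i dt, 0, 1)); on spike P_i <- P_reset

with multiplicative gain factors N_ij (unity at baseline) indexed by the
receiving/sending unit kinds. At the baseline working point (weights
W_EE = W_IE = 0.0085, W_EI = -0.569, W_II = -2; 42.5% excitatory / 75%
inhibitory connectivity) the summed-spike "local field potential" shows
alpha-band (8-12 Hz) oscillations whose amplitude envelope carries
long-range temporal correlations (DFA exponent ~ 0.85) together with
power-law avalanche statistics (kappa ~ 1). Structural and gain sweeps map
kappa, alpha and firing rate over the excitation/inhibition plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from numba import njit

from .avalanche import detect_avalanches, kappa_index
from .envelope import bandpass_fir, hilbert_envelope, transient_samples
from .lrtc import dfa
from .types import TimeSeries

__all__ = [
    "NetworkConfig",
    "Connectome",
    "SpikeRaster",
    "PhaseMap",
    "build_connectome",
    "simulate",
    "lfp_proxy",
    "lfp_alpha_exponent",
    "network_statistics",
    "sweep_structural",
    "sweep_gain",
]


@dataclass
class NetworkConfig:
    """Parameters of the lattice model (units: ms for times, 1/ms for P)."""

    n_units: int = 2500
    frac_exc: float = 0.75
    neighborhood: int = 7  # square width in lattice units
    conn_pct_exc: float = 42.5  # % of neighbourhood an excitatory unit targets
    conn_pct_inh: float = 75.0
    w_ee: float = 0.0085  # first subscript = receiving kind, second = sending
    w_ie: float = 0.0085
    w_ei: float = -0.569
    w_ii: float = -2.0
    gain_ee: float = 1.0
    gain_ie: float = 1.0
    gain_ei: float = 1.0
    gain_ii: float = 1.0
    tau_i_ms: float = 9.0
    tau_p_exc_ms: float = 6.0
    tau_p_inh_ms: float = 12.0
    p0_exc: float = 1e-6  # background spiking probability [1/ms]
    p0_inh: float = 0.0
    p_reset_exc: float = -2.0
    p_reset_inh: float = -20.0
    i0: float = 0.0
    dt_ms: float = 1.0
    decay_lambda: float = 2.0  # lattice units; connection prob ∝ exp(-d/lambda)
    toroidal: bool = False  # open boundaries by default (a patch has edges)

    def __post_init__(self) -> None:
        if min(self.tau_i_ms, self.tau_p_exc_ms, self.tau_p_inh_ms) <= 0:
            raise ValueError("time constants must be positive")
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        for pct in (self.conn_pct_exc, self.conn_pct_inh):
            if not 0 <= pct <= 100:
                raise ValueError("connection percentages must lie in [0, 100]")
        side = int(round(np.sqrt(self.n_units)))
        if side * side != self.n_units:
            raise ValueError("n_units must be a perfect square (lattice)")
        if self.neighborhood % 2 != 1:
            raise ValueError("neighbourhood width must be odd")

    @property
    def side(self) -> int:
        return int(round(np.sqrt(self.n_units)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class Connectome:
    """Directed weighted adjacency in out-edge CSR form."""

    out_indptr: np.ndarray  # int64, len n_units + 1
    out_targets: np.ndarray  # int32
    out_weights: np.ndarray  # float64, base weights (gains applied at run time)
    kinds: np.ndarray  # uint8: 0 = excitatory, 1 = inhibitory
    coords: np.ndarray  # (n_units, 2) lattice row/col
    seed: int = 0

    @property
    def n_units(self) -> int:
        return self.kinds.size

    @property
    def n_edges(self) -> int:
        return self.out_targets.size


@dataclass
class SpikeRaster:
    """Spiking output: per-step population counts, per-unit totals, and
    optionally the dense binary unit x time raster (short runs only)."""

    population_counts: np.ndarray  # int32 per time step
    unit_counts: np.ndarray  # int64 per unit
    input_sum: np.ndarray  # summed synaptic input per step (LFP alternative)
    kinds: np.ndarray
    dt_ms: float
    raster: np.ndarray | None = None  # uint8 (n_units, n_steps) if recorded

    @property
    def n_units(self) -> int:
        return self.kinds.size

    @property
    def n_steps(self) -> int:
        return self.population_counts.size

    @property
    def duration_s(self) -> float:
        return self.n_steps * self.dt_ms / 1000.0

    @property
    def mean_rate_hz(self) -> float:
        """Mean single-unit firing rate in spikes/s."""
        return float(self.unit_counts.sum()) / (self.n_units * self.duration_s)

    def events(self) -> tuple[np.ndarray, np.ndarray]:
        """(time_ms, unit_id) event list; requires a recorded dense raster."""
        if self.raster is None:
            raise ValueError("events need record_raster=True at simulation time")
        unit, step = np.nonzero(self.raster)
        order = np.argsort(step, kind="stable")
        return step[order] * self.dt_ms, unit[order]


@dataclass
class PhaseMap:
    """Per-cell mean kappa / alpha / firing rate over a 2-D parameter grid."""

    x_values: np.ndarray
    y_values: np.ndarray
    x_label: str
    y_label: str
    kappa: np.ndarray  # shape (len(y_values), len(x_values))
    alpha: np.ndarray
    rate_hz: np.ndarray
    seeds_per_cell: int = 1


def build_connectome(cfg: NetworkConfig, seed: int) -> Connectome:
    """Draw the directed lattice connectome.

    Each unit selects round(conn_pct/100 * neighbourhood size) distinct
    targets from its (open-boundary) 7x7 neighbourhood, excluding itself,
    with selection probability proportional to exp(-d / decay_lambda) in
    Euclidean lattice distance. Edge weight is W[receiving kind, sending
    kind]. E/I identities are a uniform random permutation (frac_exc
    excitatory).
    """
    rng = np.random.default_rng(seed)
    n, side, half = cfg.n_units, cfg.side, cfg.neighborhood // 2
    n_exc = int(round(cfg.frac_exc * n))
    kinds = np.ones(n, dtype=np.uint8)
    kinds[rng.permutation(n)[:n_exc]] = 0
    rows, cols = np.divmod(np.arange(n), side)
    coords = np.column_stack([rows, cols])
    w_mat = np.array([[cfg.w_ee, cfg.w_ei], [cfg.w_ie, cfg.w_ii]])
    indptr = np.zeros(n + 1, dtype=np.int64)
    targets_all: list[np.ndarray] = []
    for u in range(n):
        r, c = rows[u], cols[u]
        dr = np.arange(-half, half + 1)
        if cfg.toroidal:
            nbr_r = (r + dr) % side
            nbr_c = (c + dr) % side
            rr, cc = np.meshgrid(nbr_r, nbr_c, indexing="ij")
            d2 = (np.abs(dr)[:, None] ** 2 + np.abs(dr)[None, :] ** 2).astype(float)
        else:
            keep_r = (r + dr >= 0) & (r + dr < side)
            keep_c = (c + dr >= 0) & (c + dr < side)
            rr, cc = np.meshgrid(r + dr[keep_r], c + dr[keep_c], indexing="ij")
            d2 = (
                dr[keep_r][:, None] ** 2 + dr[keep_c][None, :] ** 2
            ).astype(float)
        nbr = (rr * side + cc).ravel()
        dist = np.sqrt(d2.ravel())
        mask = nbr != u
        nbr, dist = nbr[mask], dist[mask]
        pct = cfg.conn_pct_exc if kinds[u] == 0 else cfg.conn_pct_inh
        n_t = int(round(pct / 100.0 * nbr.size))
        if n_t > nbr.size:
            raise ValueError("connection percentage demands more targets than neighbours")
        if n_t == 0:
            targets_all.append(np.empty(0, dtype=np.int32))
            indptr[u + 1] = indptr[u]
            continue
        p = np.exp(-dist / cfg.decay_lambda)
        p /= p.sum()
        chosen = rng.choice(nbr, size=n_t, replace=False, p=p, shuffle=False)
        targets_all.append(np.sort(chosen).astype(np.int32))
        indptr[u + 1] = indptr[u] + n_t
    targets = np.concatenate(targets_all) if targets_all else np.empty(0, dtype=np.int32)
    weights = w_mat[kinds[targets], np.repeat(kinds, np.diff(indptr))]
    return Connectome(
        out_indptr=indptr,
        out_targets=targets,
        out_weights=weights,
        kinds=kinds,
        coords=coords,
        seed=seed,
    )


@njit(cache=False)
def _run_kernel(
    indptr,
    targets,
    weights,
    tau_p,
    p0,
    p_reset,
    tau_i,
    i0,
    dt,
    n_steps,
    seed,
    use_uniforms,
    uniforms,
    pop_counts,
    unit_counts,
    input_sum,
    record_raster,
    raster,
):  # pragma: no cover - exercised through simulate()
    n = tau_p.size
    cur_i = np.zeros(n)
    cur_p = np.zeros(n)
    spike_idx = np.empty(n, dtype=np.int64)
    n_spk = 0
    # decay recursions in multiplier form (Euler steps of the two ODEs)
    decay_i = 1.0 - dt / tau_i
    add_i = dt * i0 / tau_i
    decay_p = np.empty(n)
    add_p = np.empty(n)
    for i in range(n):
        decay_p[i] = 1.0 - dt / tau_p[i]
        add_p[i] = dt * p0[i] / tau_p[i]
    np.random.seed(seed)
    for t in range(n_steps):
        # (1) synaptic input from last step's spikes
        for s in range(n_spk):
            j = spike_idx[s]
            for e in range(indptr[j], indptr[j + 1]):
                cur_i[targets[e]] += weights[e]
        # (2) input decay, (3) probability accumulation, (4) probability
        # decay, (5) spike draw, (6) reset — fused per unit
        tot_i = 0.0
        n_spk = 0
        for i in range(n):
            ci = cur_i[i] * decay_i + add_i
            cur_i[i] = ci
            tot_i += ci
            cp = (cur_p[i] + ci) * decay_p[i] + add_p[i]
            prob = cp * dt
            if prob > 0.0:
                if prob > 1.0:
                    prob = 1.0
                u = uniforms[t, i] if use_uniforms else np.random.random()
                if u < prob:
                    cp = p_reset[i]
                    unit_counts[i] += 1
                    spike_idx[n_spk] = i
                    n_spk += 1
                    if record_raster:
                        raster[i, t] = 1
            cur_p[i] = cp
        input_sum[t] = tot_i
        pop_counts[t] = n_spk


def simulate(
    conn: Connectome,
    cfg: NetworkConfig,
    duration_s: float,
    seed: int,
    record_raster: bool = False,
    uniforms: np.ndarray | None = None,
) -> SpikeRaster:
    """Run the probabilistic integrate-and-fire dynamics.

    Gains are folded into the edge weights at launch (N[receiving, sending]
    kind pair). ``uniforms`` optionally supplies the per-step, per-unit
    uniform draws (shape (n_steps, n_units)) consumed in unit order for
    units with positive spiking probability — used to pin the draw sequence
    when cross-checking against a reference integrator.
    """
    if duration_s < 0.001:
        raise ValueError("duration too short")
    n_steps = int(round(duration_s * 1000.0 / cfg.dt_ms))
    n = conn.n_units
    kinds = conn.kinds
    gain = np.array([[cfg.gain_ee, cfg.gain_ei], [cfg.gain_ie, cfg.gain_ii]])
    if np.any(gain < 0):
        raise ValueError("gains must be nonnegative")
    src_kind = np.repeat(kinds, np.diff(conn.out_indptr))
    w_eff = conn.out_weights * gain[kinds[conn.out_targets], src_kind]
    tau_p = np.where(kinds == 0, cfg.tau_p_exc_ms, cfg.tau_p_inh_ms).astype(float)
    p0 = np.where(kinds == 0, cfg.p0_exc, cfg.p0_inh).astype(float)
    p_reset = np.where(kinds == 0, cfg.p_reset_exc, cfg.p_reset_inh).astype(float)
    pop_counts = np.zeros(n_steps, dtype=np.int32)
    unit_counts = np.zeros(n, dtype=np.int64)
    input_sum = np.zeros(n_steps)
    if record_raster:
        if n_steps * n > 2_00_000_000:
            raise ValueError("raster too large to record densely; use population counts")
        raster = np.zeros((n, n_steps), dtype=np.uint8)
    else:
        raster = np.zeros((1, 1), dtype=np.uint8)
    if uniforms is None:
        use_u = False
        uni = np.zeros((1, 1))
    else:
        use_u = True
        uni = np.ascontiguousarray(uniforms, dtype=np.float64)
        if uni.shape != (n_steps, n):
            raise ValueError("uniforms must have shape (n_steps, n_units)")
    _run_kernel(
        conn.out_indptr,
        conn.out_targets,
        w_eff,
        tau_p,
        p0,
        p_reset,
        cfg.tau_i_ms,
        cfg.i0,
        cfg.dt_ms,
        n_steps,
        int(seed) % 2**31,
        use_u,
        uni,
        pop_counts,
        unit_counts,
        input_sum,
        record_raster,
        raster,
    )
    if not np.all(np.isfinite(input_sum)):
        raise FloatingPointError("non-finite network state during simulation")
    return SpikeRaster(
        population_counts=pop_counts,
        unit_counts=unit_counts,
        input_sum=input_sum,
        kinds=kinds,
        dt_ms=cfg.dt_ms,
        raster=raster if record_raster else None,
    )


def lfp_proxy(raster: SpikeRaster, source: str = "spikes") -> TimeSeries:
    """Local-field-potential proxy: activity summed across all units.

    ``source='spikes'`` (default) sums the binary spike raster per step;
    ``source='input'`` sums the synaptic input variable instead.
    """
    if raster.n_steps == 0:
        raise ValueError("empty raster")
    if source == "spikes":
        x = raster.population_counts.astype(float)
    elif source == "input":
        x = raster.input_sum
    else:
        raise ValueError("source must be 'spikes' or 'input'")
    return TimeSeries(samples=x, rate=1000.0 / raster.dt_ms)


def lfp_alpha_exponent(
    lfp: TimeSeries,
    band: tuple[float, float] = (8.0, 12.0),
    win_range_s: tuple[float, float] = (5.0, 30.0),
    n_windows: int = 15,
) -> float:
    """DFA exponent of the band-limited amplitude envelope of an LFP.

    Band-pass (zero-phase FIR), Hilbert envelope, one filter length
    discarded at each edge, then DFA with log-spaced windows.
    """
    filtered = bandpass_fir(lfp, band[0], band[1])
    env = hilbert_envelope(filtered, band=band)
    cut = transient_samples(lfp.rate, band[0])
    samples = env.samples[cut:-cut]
    _, fit = dfa(samples, rate=lfp.rate, win_min_s=win_range_s[0], win_max_s=win_range_s[1], n_windows=n_windows)
    return fit.alpha


def network_statistics(
    raster: SpikeRaster,
    band: tuple[float, float] = (8.0, 12.0),
    win_range_s: tuple[float, float] = (5.0, 30.0),
    bin_ms: float = 1.0,
    threshold_percentile: float = 50.0,
) -> dict:
    """kappa, envelope DFA alpha and mean firing rate of one simulation."""
    lfp = lfp_proxy(raster)
    sizes = detect_avalanches(raster, bin_ms=bin_ms, threshold_percentile=threshold_percentile)
    kappa = np.nan
    if sizes.n >= 10 and sizes.sizes.min() < sizes.sizes.max():
        kappa = kappa_index(sizes).kappa
    alpha = np.nan
    if raster.duration_s >= 2 * win_range_s[1]:
        alpha = lfp_alpha_exponent(lfp, band=band, win_range_s=win_range_s)
    return {"kappa": kappa, "alpha": alpha, "rate_hz": raster.mean_rate_hz}


def _cell_seeds(master_seed: int, ix: int, iy: int, s: int) -> tuple[int, int]:
    ss = np.random.SeedSequence([int(master_seed), ix, iy, s])
    a, b = ss.generate_state(2)
    return int(a % 2**31), int(b % 2**31)


def _sweep(cfg_for_cell, x_values, y_values, x_label, y_label, seeds, duration_s, master_seed):
    shape = (len(y_values), len(x_values))
    kappa = np.zeros(shape)
    alpha = np.zeros(shape)
    rate = np.zeros(shape)
    for iy, yv in enumerate(y_values):
        for ix, xv in enumerate(x_values):
            cfg = cfg_for_cell(xv, yv)
            acc = {"kappa": [], "alpha": [], "rate_hz": []}
            for s in range(seeds):
                cs, ss_ = _cell_seeds(master_seed, ix, iy, s)
                conn = build_connectome(cfg, cs)
                raster = simulate(conn, cfg, duration_s, ss_)
                stats = network_statistics(raster)
                for k in acc:
                    acc[k].append(stats[k])
            kappa[iy, ix] = np.nanmean(acc["kappa"])
            alpha[iy, ix] = np.nanmean(acc["alpha"])
            rate[iy, ix] = np.nanmean(acc["rate_hz"])
    return PhaseMap(
        x_values=np.asarray(x_values, dtype=float),
        y_values=np.asarray(y_values, dtype=float),
        x_label=x_label,
        y_label=y_label,
        kappa=kappa,
        alpha=alpha,
        rate_hz=rate,
        seeds_per_cell=seeds,
    )


def sweep_structural(
    exc_range: tuple[float, float],
    inh_range: tuple[float, float],
    step_pct: float = 2.5,
    seeds: int = 10,
    duration_s: float = 1000.0,
    base_cfg: NetworkConfig | None = None,
    master_seed: int = 0,
) -> PhaseMap:
    """Mean kappa / alpha / rate over the structural connectivity plane."""
    base = base_cfg or NetworkConfig()
    xs = np.arange(exc_range[0], exc_range[1] + step_pct / 2, step_pct)
    ys = np.arange(inh_range[0], inh_range[1] + step_pct / 2, step_pct)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("empty sweep grid")
    if xs.max() > 100 or ys.max() > 100 or xs.min() < 0 or ys.min() < 0:
        raise ValueError("connectivity percentages outside [0, 100]")

    def cell(xv, yv):
        return replace(base, conn_pct_exc=float(xv), conn_pct_inh=float(yv))

    return _sweep(cell, xs, ys, "excitatory connectivity (%)", "inhibitory connectivity (%)", seeds, duration_s, master_seed)


def sweep_gain(
    mode: str = "EExIE",
    gain_grid: np.ndarray | None = None,
    seeds: int = 10,
    duration_s: float = 1000.0,
    base_cfg: NetworkConfig | None = None,
    master_seed: int = 0,
) -> PhaseMap:
    """Mean kappa / alpha / rate over synaptic gain factors.

    ``mode='EExIE'`` varies N_EE (x axis) and N_IE (y axis) independently —
    gain modulation of excitatory synapses on excitatory vs inhibitory
    targets. ``mode='(EE&IE)xEI'`` co-modulates N_EE and N_IE by the x-axis
    factor and varies N_EI on the y axis. The structural working point stays
    fixed at the baseline configuration (42.5% / 75% connectivity).
    """
    base = base_cfg or NetworkConfig()
    grid = np.arange(0.8, 1.2001, 0.05) if gain_grid is None else np.asarray(gain_grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("gains must be positive")
    if mode == "EExIE":

        def cell(xv, yv):
            return replace(base, gain_ee=float(xv), gain_ie=float(yv))

        labels = ("N_EE gain", "N_IE gain")
    elif mode == "(EE&IE)xEI":

        def cell(xv, yv):
            return replace(base, gain_ee=float(xv), gain_ie=float(xv), gain_ei=float(yv))

        labels = ("N_EE & N_IE gain", "N_EI gain")
    else:
        raise ValueError("mode must be 'EExIE' or '(EE&IE)xEI'")
    return _sweep(cell, grid, grid, labels[0], labels[1], seeds, duration_s, master_seed)
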