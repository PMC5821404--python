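"""E/I lattice model: construction, dynamics, limits and proxies."""

from dataclasses import replace

import numpy as np
import pytest

import oracles
from alphacrit import crosnet
from alphacrit.crosnet import (
    NetworkConfig,
    build_connectome,
    lfp_proxy,
    simulate,
    sweep_gain,
)
from alphacrit.types import TimeSeries


class TestConnectome:
    def test_zero_connectivity_gives_no_edges(self):
        cfg = NetworkConfig(conn_pct_exc=0.0, conn_pct_inh=0.0)
        conn = build_connectome(cfg, 0)
        assert conn.n_edges == 0

    def test_all_edges_within_neighbourhood(self, baseline_cfg):
        conn = build_connectome(baseline_cfg, 1)
        side = baseline_cfg.side
        src = np.repeat(np.arange(conn.n_units), np.diff(conn.out_indptr))
        d_row = np.abs(conn.coords[src, 0] - conn.coords[conn.out_targets, 0])
        d_col = np.abs(conn.coords[src, 1] - conn.coords[conn.out_targets, 1])
        assert np.max(np.maximum(d_row, d_col)) <= baseline_cfg.neighborhood // 2
        assert not np.any(src == conn.out_targets)

    def test_interior_out_degree_matches_percentages(self, baseline_cfg):
        conn = build_connectome(baseline_cfg, 2)
        deg = np.diff(conn.out_indptr)
        interior = np.all((conn.coords >= 3) & (conn.coords < 47), axis=1)
        exc = interior & (conn.kinds == 0)
        inh = interior & (conn.kinds == 1)
        assert np.all(deg[exc] == round(0.425 * 48))
        assert np.all(deg[inh] == round(0.75 * 48))

    def test_weights_follow_kind_pairs(self, baseline_cfg):
        conn = build_connectome(baseline_cfg, 3)
        src = np.repeat(conn.kinds, np.diff(conn.out_indptr))
        tgt = conn.kinds[conn.out_targets]
        w = conn.out_weights
        assert np.all(w[(src == 0) & (tgt == 0)] == baseline_cfg.w_ee)
        assert np.all(w[(src == 0) & (tgt == 1)] == baseline_cfg.w_ie)
        assert np.all(w[(src == 1) & (tgt == 0)] == baseline_cfg.w_ei)
        assert np.all(w[(src == 1) & (tgt == 1)] == baseline_cfg.w_ii)


class TestSimulate:
    def test_silent_network_stays_silent(self, warm_kernel):
        cfg = NetworkConfig(
            n_units=25, neighborhood=3, gain_ee=0, gain_ie=0, gain_ei=0, gain_ii=0, p0_exc=0.0
        )
        conn = build_connectome(cfg, 0)
        raster = simulate(conn, cfg, 2.0, 1)
        assert raster.population_counts.sum() == 0

    def test_uncoupled_rate_matches_renewal_closed_form(self, warm_kernel):
        import math

        p0 = 1e-3
        cfg = NetworkConfig(conn_pct_exc=0, conn_pct_inh=0, p0_exc=p0, p0_inh=p0)
        conn = build_connectome(cfg, 1)
        raster = simulate(conn, cfg, 200.0, 3)

        def renewal_rate_hz(p0, p_r, tau):
            t_rec = tau * math.log((p0 - p_r) / (p0 * 0.01))
            return 1000.0 / (t_rec + 1.0 / p0)

        k_e = raster.kinds == 0
        rate_e = raster.unit_counts[k_e].sum() / (k_e.sum() * 200.0)
        rate_i = raster.unit_counts[~k_e].sum() / ((~k_e).sum() * 200.0)
        assert rate_e == pytest.approx(renewal_rate_hz(p0, cfg.p_reset_exc, cfg.tau_p_exc_ms), rel=0.1)
        assert rate_i == pytest.approx(renewal_rate_hz(p0, cfg.p_reset_inh, cfg.tau_p_inh_ms), rel=0.1)

    def test_bit_identical_to_reference_integrator(self, small_cfg, warm_kernel):
        conn = build_connectome(small_cfg, 5)
        n_steps = 2000
        uni = np.random.default_rng(9).random((n_steps, small_cfg.n_units))
        pop_ref, cnt_ref = oracles.reference_network_step(conn, small_cfg, n_steps, uni)
        raster = simulate(conn, small_cfg, 2.0, seed=0, uniforms=uni)
        assert np.array_equal(pop_ref, raster.population_counts)
        assert np.array_equal(cnt_ref, raster.unit_counts)

    def test_deterministic_per_seed_pair(self, small_cfg, warm_kernel):
        conn = build_connectome(small_cfg, 4)
        r1 = simulate(conn, small_cfg, 3.0, 7)
        r2 = simulate(conn, small_cfg, 3.0, 7)
        r3 = simulate(conn, small_cfg, 3.0, 8)
        assert np.array_equal(r1.population_counts, r2.population_counts)
        assert not np.array_equal(r1.population_counts, r3.population_counts)

    def test_inhibitory_refractory_longer_than_excitatory(self, small_cfg, warm_kernel):
        # resets -20 (I) vs -2 (E) make early re-firing much rarer for I units
        cfg = replace(small_cfg, p0_exc=5e-2, p0_inh=5e-2, conn_pct_exc=0, conn_pct_inh=0)
        conn = build_connectome(cfg, 2)
        raster = simulate(conn, cfg, 100.0, 5, record_raster=True)
        lat = {0: [], 1: []}
        for u in range(cfg.n_units):
            times = np.flatnonzero(raster.raster[u])
            lat[int(raster.kinds[u])] += list(np.diff(times))
        assert np.median(lat[1]) > np.median(lat[0]) + 10


class TestLFP:
    def test_silent_raster_gives_zero_series(self, small_cfg, warm_kernel):
        cfg = replace(small_cfg, gain_ee=0, gain_ie=0, gain_ei=0, gain_ii=0, p0_exc=0.0, p0_inh=0.0)
        conn = build_connectome(cfg, 0)
        lfp = lfp_proxy(simulate(conn, cfg, 2.0, 1))
        assert np.all(lfp.samples == 0)

    def test_sums_spikes_across_units(self, small_cfg, warm_kernel):
        conn = build_connectome(small_cfg, 3)
        raster = simulate(conn, small_cfg, 5.0, 2, record_raster=True)
        lfp = lfp_proxy(raster)
        assert np.array_equal(lfp.samples, raster.raster.sum(axis=0))
        assert lfp.rate == 1000.0

    def test_baseline_spectrum_peaks_in_alpha_band(self, baseline_cfg, warm_kernel):
        from alphacrit.envelope import multitaper_spectrum, spectral_peak

        conn = build_connectome(baseline_cfg, 10)
        raster = simulate(conn, baseline_cfg, 120.0, 100)
        sp = multitaper_spectrum(lfp_proxy(raster))
        assert 8.0 <= spectral_peak(sp, (2.0, 50.0)) <= 12.0


class TestSweeps:
    def test_single_cell_matches_direct_call(self, warm_kernel):
        cfg = NetworkConfig()
        pm = crosnet.sweep_structural((42.5, 42.5), (75.0, 75.0), seeds=1, duration_s=80.0, master_seed=3)
        cs, ss = crosnet._cell_seeds(3, 0, 0, 0)
        conn = build_connectome(cfg, cs)
        raster = simulate(conn, cfg, 80.0, ss)
        stats = crosnet.network_statistics(raster)
        assert pm.kappa[0, 0] == pytest.approx(stats["kappa"], nan_ok=True)
        assert pm.rate_hz[0, 0] == pytest.approx(stats["rate_hz"])

    def test_identity_gains_reproduce_baseline_within_noise(self, warm_kernel):
        pm = sweep_gain(gain_grid=np.array([1.0]), seeds=2, duration_s=80.0, master_seed=1)
        cfg = NetworkConfig()
        rates = []
        for s in range(2):
            cs, ss = crosnet._cell_seeds(1, 0, 0, s)
            raster = simulate(build_connectome(cfg, cs), cfg, 80.0, ss)
            rates.append(raster.mean_rate_hz)
        assert pm.rate_hz[0, 0] == pytest.approx(np.mean(rates))

    def test_structural_corners_split_excitation_vs_inhibition_dominance(self, warm_kernel):
        """More excitatory / less inhibitory wiring gives heavier avalanche
        tails (higher kappa) and higher rates than the opposite corner."""
        pm = crosnet.sweep_structural(
            (30.0, 55.0), (60.0, 85.0), step_pct=25.0, seeds=1, duration_s=300.0, master_seed=4
        )
        exc_dominant = pm.kappa[0, 1]  # exc 55%, inh 60%
        inh_dominant = pm.kappa[1, 0]  # exc 30%, inh 85%
        assert exc_dominant > inh_dominant
        assert np.all(np.diff(pm.rate_hz, axis=1) >= 0)  # rate grows with exc

    def test_nonpositive_gain_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_gain(gain_grid=np.array([0.0, 1.0]), duration_s=10.0)


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = NetworkConfig(conn_pct_exc=40.0, gain_ee=1.1)
        path = tmp_path / "net.yaml"
        cfg.to_yaml(path)
        assert NetworkConfig.from_yaml(path) == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_units=2400)  # not a perfect square
        with pytest.raises(ValueError):
            NetworkConfig(conn_pct_exc=120.0)
        with pytest.raises(ValueError):
            NetworkConfig(tau_i_ms=-1.0)
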