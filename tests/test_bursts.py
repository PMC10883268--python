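import numpy as np
import pytest

from secgate import (BackgroundRates, BurstSearchParams, burst_metrics,
                     burst_variance_analysis, emit_photons,
                     estimate_background, refine_burst_edges, search_bursts,
                     simulate_two_state_trajectory)
from secgate.io import Burst, PhotonData
from secgate.simulate import CLOSED, OPEN

EMIS = {OPEN: (0.40, 0.60), CLOSED: (0.75, 0.60)}


def record_from_times(times_ms, streams=None):
    times_ms = np.asarray(times_ms, float)
    if streams is None:
        streams = np.zeros(times_ms.size, np.int8)
    ticks = np.round(times_ms * 1e-3 / 5e-8).astype(np.int64)
    return PhotonData(timestamps=ticks, streams=np.asarray(streams, np.int8),
                      clock_period=5e-8)


def brute_force_search(data, bg_total_khz, m, rate_factor, min_size):
    """Independent reference for the single-channel ('all') search."""
    t = data.times_s * 1e3
    n = t.size
    max_span = m / (rate_factor * bg_total_khz)
    marked = np.zeros(n, bool)
    for i in range(n - m + 1):
        if t[i + m - 1] - t[i] <= max_span:
            marked[i:i + m] = True
    bursts = []
    i = 0
    while i < n:
        if marked[i]:
            j = i
            while j < n and marked[j]:
                j += 1
            if j - i >= min_size:
                c = np.bincount(data.streams[i:j], minlength=3)
                bursts.append((i, j, int(c[0]), int(c[1]), int(c[2])))
            i = j
        else:
            i += 1
    return bursts


class TestBackground:
    def test_pure_poisson_rate(self):
        rng = np.random.default_rng(0)
        n = rng.poisson(1000 * 60)
        ticks = np.sort(rng.integers(0, int(60 / 5e-8), n))
        data = PhotonData(timestamps=ticks,
                          streams=rng.integers(0, 3, n).astype(np.int8),
                          clock_period=5e-8, acquisition_duration=60.0)
        bg = estimate_background(data)
        assert bg.total_khz == pytest.approx(1.0, abs=0.05)

    def test_empty_stream_errors_with_name(self):
        data = record_from_times(np.linspace(0, 60_000, 2000),
                                 np.zeros(2000))
        with pytest.raises(ValueError, match="DexAem"):
            estimate_background(data)

    def test_bursty_record_below_mean_rate(self, apo_data, apo_background):
        mean_khz = apo_data.n_photons / (apo_data.acquisition_duration * 1e3)
        assert apo_background.total_khz < mean_khz


class TestBurstSearch:
    def test_empty_record(self):
        data = record_from_times([])
        bg = BackgroundRates(rates_khz=np.array([0.5, 0.3, 0.2]))
        assert search_bursts(data, bg) == []

    def test_background_only_no_bursts(self):
        fp = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = rng.poisson(1.0 * 10_000)  # 1 kHz total, 10 s
            t = np.sort(rng.uniform(0, 10_000, n))
            data = record_from_times(t, rng.integers(0, 3, n))
            bg = BackgroundRates(rates_khz=np.array([0.4, 0.3, 0.3]))
            fp += bool(search_bursts(data, bg))
        assert fp < 1  # false-positive rate < 1% over 100 seeds

    def test_constructed_burst_found(self):
        rng = np.random.default_rng(1)
        bg_t = np.sort(rng.uniform(0, 10_000, 5000))  # 0.5 kHz background
        burst_t = 5000.0 + np.sort(rng.uniform(0, 4.0, 200))  # 50 kHz
        t = np.sort(np.concatenate([bg_t, burst_t]))
        data = record_from_times(t, rng.integers(0, 3, t.size))
        bg = BackgroundRates(rates_khz=np.array([0.2, 0.15, 0.15]))
        found = search_bursts(data, bg, BurstSearchParams(channels="all"))
        assert len(found) == 1
        seg = t[found[0].start:found[0].stop]
        assert np.sum((seg >= 5000.0) & (seg <= 5004.0)) >= 195
        ref = brute_force_search(data, bg.total_khz, 10, 6.0, 50)
        assert [(b.start, b.stop) for b in found] == [(r[0], r[1])
                                                      for r in ref]

    def test_matches_brute_force_on_random_records(self):
        rng = np.random.default_rng(2)
        for trial in range(50):
            n = int(rng.integers(20, 500))
            # mix of sparse background and one dense clump
            t = np.sort(np.concatenate([
                rng.uniform(0, 1000, n // 2),
                rng.uniform(0, 1000, 1) + rng.uniform(0, 2, n - n // 2)]))
            data = record_from_times(t, rng.integers(0, 3, n))
            bg = BackgroundRates(rates_khz=np.array([0.4, 0.3, 0.3]))
            params = BurstSearchParams(m=int(rng.integers(3, 12)),
                                       rate_factor=float(rng.uniform(2, 8)),
                                       min_size=int(rng.integers(1, 30)),
                                       channels="all")
            found = [(b.start, b.stop, b.n_dd, b.n_da, b.n_aa)
                     for b in search_bursts(data, bg, params)]
            ref = brute_force_search(data, bg.total_khz, params.m,
                                     params.rate_factor, params.min_size)
            assert found == ref, f"trial {trial}"

    def test_bursts_ordered_nonoverlapping(self, apo_bursts):
        starts = [b.start for b in apo_bursts]
        stops = [b.stop for b in apo_bursts]
        assert all(a < b for a, b in zip(starts, stops))
        assert all(s >= p for s, p in zip(starts[1:], stops[:-1]))

    def test_recovered_bursts_overlap_truth(self, apo_data, apo_bursts):
        truth = apo_data.ground_truth["burst_spans"]
        times = apo_data.times_s
        n_overlap = sum(
            any(times[b.start] <= hi and times[b.stop - 1] >= lo
                for lo, hi in truth)
            for b in apo_bursts)
        assert n_overlap >= 0.9 * len(apo_bursts)

    def test_and_search_suppresses_donor_only(self, apo_data,
                                              apo_background):
        found = search_bursts(apo_data, apo_background,
                              BurstSearchParams(channels="and"))
        s_vals = np.array([burst_metrics(b).s_raw for b in found])
        # donor-only molecules (S ~ 0.95) are rare in the dual-channel set
        assert np.mean(s_vals > 0.9) < 0.05

    def test_param_validation(self):
        with pytest.raises(ValueError):
            BurstSearchParams(m=1)
        with pytest.raises(ValueError):
            BurstSearchParams(rate_factor=0)
        with pytest.raises(ValueError):
            BurstSearchParams(channels="or")


class TestRefineBurstEdges:
    # background total 2.4 kHz, m = 10, F = 6 -> max window span 0.694 ms;
    # core photons at 0.025 ms spacing (40 kHz), sparse photons 1 ms apart
    BG = BackgroundRates(rates_khz=np.array([1.0, 0.6, 0.8]))
    PARAMS = BurstSearchParams(channels="all")

    @staticmethod
    def _burst_over(data, start, stop):
        c = np.bincount(data.streams[start:stop], minlength=3)
        t = data.times_s * 1e3
        return Burst(start, stop, int(c[0]), int(c[1]), int(c[2]),
                     float(t[start]), float(t[stop - 1]))

    def test_edge_background_trimmed(self):
        lead = 10.0 - np.arange(3, 0, -1) * 1.0          # 3 sparse, 1 ms apart
        core = 10.0 + np.arange(80) * 0.025
        tail = core[-1] + np.arange(1, 4) * 1.0
        t = np.concatenate([lead, core, tail])
        streams = np.arange(t.size) % 3
        data = record_from_times(t, streams)
        burst = self._burst_over(data, 0, t.size)
        out = refine_burst_edges(data, [burst], self.BG, self.PARAMS)
        assert len(out) == 1
        b = out[0]
        # two-sided rule keeps core photons with a full qualifying window on
        # both sides: indices 3 + (m-1) .. 3 + 80 - (m-1)
        assert (b.start, b.stop) == (12, 74)
        c = np.bincount(data.streams[b.start:b.stop], minlength=3)
        assert (b.n_dd, b.n_da, b.n_aa) == tuple(int(x) for x in c)
        times_ms = data.times_s * 1e3
        assert b.start_ms == pytest.approx(times_ms[b.start])
        assert b.stop_ms == pytest.approx(times_ms[b.stop - 1])

    def test_bridged_gap_splits_burst(self):
        core1 = 10.0 + np.arange(70) * 0.025
        mid = core1[-1] + np.arange(1, 4) * 1.0
        core2 = mid[-1] + 1.0 + np.arange(70) * 0.025
        t = np.concatenate([core1, mid, core2])
        data = record_from_times(t)
        burst = self._burst_over(data, 0, t.size)
        out = refine_burst_edges(data, [burst], self.BG, self.PARAMS)
        assert len(out) == 2
        for b in out:
            assert b.stop - b.start == 70 - 2 * (self.PARAMS.m - 1)
        assert out[0].stop <= 70 <= out[1].start

    def test_min_size_reapplied(self):
        core = 10.0 + np.arange(60) * 0.025   # 60 - 18 = 42 < min_size 50
        data = record_from_times(core)
        burst = self._burst_over(data, 0, core.size)
        assert refine_burst_edges(data, [burst], self.BG, self.PARAMS) == []

    def test_dense_burst_loses_only_edge_windows(self):
        core = 10.0 + np.arange(120) * 0.025
        data = record_from_times(core)
        burst = self._burst_over(data, 0, core.size)
        out = refine_burst_edges(data, [burst], self.BG, self.PARAMS)
        assert len(out) == 1
        assert (out[0].start, out[0].stop) == (9, 111)


def telegraph_bursts(tau_o, tau_c, n_bursts=60, burst_ms=50.0, seed=0,
                     rate_khz=40.0):
    """Concatenated long two-state records posing as pre-found bursts."""
    rng = np.random.default_rng(seed)
    t_parts, s_parts = [], []
    gap_ticks = int(burst_ms * 1.5e-3 / 5e-8)
    for i in range(n_bursts):
        traj = simulate_two_state_trajectory(tau_o, tau_c, burst_ms, rng=rng)
        d = emit_photons(traj, EMIS, rate_khz, rng=rng)
        t_parts.append(d.timestamps + i * gap_ticks)
        s_parts.append(d.streams)
    ts, ss = np.concatenate(t_parts), np.concatenate(s_parts)
    data = PhotonData(timestamps=ts, streams=ss, clock_period=5e-8)
    bursts, start = [], 0
    for tp in t_parts:
        stop = start + tp.size
        c = np.bincount(ss[start:stop], minlength=3)
        bursts.append(Burst(start, stop, int(c[0]), int(c[1]), int(c[2]),
                            float(ts[start]) * 5e-5,
                            float(ts[stop - 1]) * 5e-5))
        start = stop
    return data, bursts


class TestBVA:
    def test_static_mean_sd_is_shot_noise(self):
        # static E = 0.5, n = 5 -> mean window sd = sqrt(0.25/5) within 5%
        rng = np.random.default_rng(3)
        n = 40_000
        streams = np.where(rng.random(n) < 0.5, 1, 0).astype(np.int8)
        data = PhotonData(timestamps=np.arange(n, dtype=np.int64) * 500,
                          streams=streams, clock_period=5e-8)
        bursts = [Burst(i, i + 400, 200, 200, 0, 0.0, 1.0)
                  for i in range(0, n, 400)]
        res = burst_variance_analysis(bursts, data, window_n=5, rng=4)
        assert res.sd_e.mean() == pytest.approx(np.sqrt(0.25 / 5), rel=0.05)

    def test_discrimination(self):
        data_s, bursts_s = telegraph_bursts(1e9, 1e9, seed=5)
        res_s = burst_variance_analysis(bursts_s, data_s, rng=6)
        data_d, bursts_d = telegraph_bursts(1.0, 1.0, seed=7)
        res_d = burst_variance_analysis(bursts_d, data_d, rng=8)
        assert res_s.dynamic_fraction < 0.05
        assert res_d.dynamic_fraction > 0.5

    def test_monotone_in_dwell_time(self):
        # Sensitivity decays as dwells grow past the burst length (dynamics
        # leave the burst-averaging window).  Dwells faster than one BVA
        # window (~0.2 ms here) are averaged out within windows, so the
        # monotone range starts at the window timescale.
        fracs = []
        for tau in (1.0, 10.0, 100.0):
            data, bursts = telegraph_bursts(tau, tau, n_bursts=40, seed=9)
            res = burst_variance_analysis(bursts, data, rng=10)
            fracs.append(res.dynamic_fraction)
        assert all(a >= b - 0.1 for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] > fracs[-1]

    def test_sub_window_dynamics_averaged_out(self):
        # dwells much faster than one window look closer to static
        data, bursts = telegraph_bursts(0.1, 0.1, n_bursts=40, seed=9)
        fast = burst_variance_analysis(bursts, data, rng=10).dynamic_fraction
        data, bursts = telegraph_bursts(1.0, 1.0, n_bursts=40, seed=9)
        slow = burst_variance_analysis(bursts, data, rng=10).dynamic_fraction
        assert fast < slow

    def test_small_bursts_skipped(self):
        data = record_from_times(np.arange(30.0), np.zeros(30))
        bursts = [Burst(0, 6, 3, 3, 0, 0.0, 1.0)]
        res = burst_variance_analysis(bursts, data, window_n=5, rng=0)
        assert res.n_skipped == 1
        assert res.dynamic.size == 0
        assert np.isnan(res.dynamic_fraction)

    def test_shot_noise_curve(self):
        data, bursts = telegraph_bursts(1e9, 1e9, n_bursts=5, seed=11)
        res = burst_variance_analysis(bursts, data, rng=12)
        assert res.shot_noise_sd(np.array([0.5]))[0] == pytest.approx(
            np.sqrt(0.25 / 5))
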