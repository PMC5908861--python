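import numpy as np
import pytest

from neuroburst.burst import (
    Burst,
    BurstCatalog,
    DensityTrace,
    bd_spikecount_relation,
    burst_slopes,
    detect_bursts,
    msdf,
    sdf,
    window_count_histogram,
)
from conftest import make_set


def brute_force_window_counts(times, duration, window=0.1, step=0.001):
    """Independent oracle: direct count of pooled spikes in each sliding
    window [k*step, k*step + window)."""
    n = int(np.ceil(duration / step))
    times = np.asarray(times)
    return np.array(
        [np.count_nonzero((times >= k * step) & (times < k * step + window)) for k in range(n)]
    )


class TestSDF:
    def test_empty_train_is_zero(self):
        tr = sdf(np.array([]), duration=5.0)
        assert tr.values.size == 5000 and np.all(tr.values == 0)

    def test_single_spike_unit_area_gaussian(self):
        tr = sdf(np.array([2.5]), duration=5.0, sigma=0.1)
        peak = tr.values.max()
        assert abs(peak - 1 / (0.1 * np.sqrt(2 * np.pi))) < 0.01
        assert abs(tr.times[np.argmax(tr.values)] - 2.5) < 2e-3
        integral = np.trapezoid(tr.values, dx=1e-3)
        assert abs(integral - 1.0) < 1e-3

    def test_integral_counts_spikes(self, rng):
        # spikes kept >= 4 sigma away from the epoch edges
        times = np.sort(rng.uniform(1.0, 59.0, size=100))
        tr = sdf(times, duration=60.0, sigma=0.1)
        assert abs(np.trapezoid(tr.values, dx=1e-3) - 100) < 0.5

    def test_linearity(self, rng):
        a = np.sort(rng.uniform(1, 9, 40))
        b = np.sort(rng.uniform(1, 9, 25))
        both = np.sort(np.concatenate([a, b]))
        lhs = sdf(both, 10.0).values
        rhs = sdf(a, 10.0).values + sdf(b, 10.0).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestMSDF:
    def test_identical_trains_equal_single_sdf(self):
        t = np.array([1.0, 2.0, 3.0])
        sts = make_set({c: t for c in range(5)}, 5.0)
        np.testing.assert_allclose(
            msdf(sts).values, sdf(t, 5.0).values, atol=1e-9
        )

    def test_one_active_channel_of_n(self):
        t = np.array([1.0, 2.0])
        sts = make_set({0: t, 1: [], 2: [], 3: []}, 4.0)
        np.testing.assert_allclose(msdf(sts).values, sdf(t, 4.0).values / 4, atol=1e-12)

    def test_equals_mean_of_per_channel_sdfs(self, rng):
        trains = {c: np.sort(rng.uniform(0, 20, rng.integers(5, 50))) for c in range(8)}
        sts = make_set(trains, 20.0)
        mean = np.mean([sdf(trains[c], 20.0).values for c in range(8)], axis=0)
        np.testing.assert_allclose(msdf(sts).values, mean, atol=1e-12)

    def test_zero_channels_error(self):
        with pytest.raises(ValueError):
            msdf(make_set({}, 1.0))


def _event_set(n_spikes, center=10.0, spread=0.08, duration=20.0, n_channels=10):
    """n_spikes spread evenly over `spread` seconds around `center`,
    round-robin across channels."""
    t = center - spread / 2 + spread * np.arange(n_spikes) / max(n_spikes - 1, 1)
    trains = {c: [] for c in range(n_channels)}
    for i, ti in enumerate(t):
        trains[i % n_channels].append(ti)
    return make_set({c: np.sort(v) for c, v in trains.items()}, duration)


class TestDetectBursts:
    def test_empty_set_no_bursts(self):
        assert detect_bursts(make_set({}, 10.0)).n_bursts == 0

    def test_silent_set_no_bursts(self):
        assert detect_bursts(make_set({0: [], 1: []}, 10.0)).n_bursts == 0

    def test_single_event_above_threshold(self):
        cat = detect_bursts(_event_set(60))
        assert cat.n_bursts == 1
        b = cat.bursts[0]
        assert b.onset_t < b.peak_t < b.offset_t
        assert b.n_spikes == 60

    def test_single_event_below_threshold(self):
        assert detect_bursts(_event_set(30)).n_bursts == 0

    def test_window_counts_match_brute_force(self):
        sts = _event_set(60)
        hist = window_count_histogram(sts)
        brute = brute_force_window_counts(sts.pooled(), sts.duration)
        np.testing.assert_array_equal(hist.values, brute)

    def test_ibi_is_peak_to_peak(self):
        a = _event_set(80, center=10.0)
        b = _event_set(80, center=13.0)
        trains = {
            c: np.sort(np.concatenate([a.spikes[c], b.spikes[c]]))
            for c in a.channels
        }
        cat = detect_bursts(make_set(trains, 20.0))
        assert cat.n_bursts == 2
        assert abs(cat.ibis[0] - 3.0) < 0.01

    def test_threshold_monotonicity(self, burst_pause_set):
        _, sts = burst_pause_set
        n40 = detect_bursts(sts, threshold=40).n_bursts
        n50 = detect_bursts(sts, threshold=50).n_bursts
        assert n40 >= n50

    def test_generator_bookkeeping_burst_count_and_ibi(self, burst_pause_set):
        """Well-separated supra-threshold generated events are each
        detected exactly once."""
        cfg, sts = burst_pause_set
        cat = detect_bursts(sts)
        assert cat.n_bursts == cfg._realized_onsets.size


class TestBurstSlopes:
    @staticmethod
    def _envelope(rise_s, fall_s, rate=1000.0, amp=1.0, pad_s=1.0):
        up = np.linspace(0, amp, int(rise_s * rate), endpoint=False)
        dn = np.linspace(amp, 0, int(fall_s * rate))
        pad = np.zeros(int(pad_s * rate))
        vals = np.concatenate([pad, up, dn, pad])
        env = DensityTrace(values=vals, rate=rate)
        b = Burst(
            onset_t=pad_s,
            peak_t=pad_s + rise_s,
            offset_t=pad_s + rise_s + fall_s,
            peak_value=amp,
            n_spikes=0,
        )
        return env, b

    def test_piecewise_linear_slopes(self):
        env, b = self._envelope(0.2, 0.5)
        ini, fin = burst_slopes(env, b)
        assert abs(ini - 5.0) < 0.1
        assert abs(fin - 2.0) < 0.1

    def test_symmetric_triangle(self):
        env, b = self._envelope(0.3, 0.3)
        ini, fin = burst_slopes(env, b)
        # central differences on the grid leave a ~1-sample asymmetry
        assert abs(ini - fin) < 0.02 * ini

    @pytest.mark.parametrize("amp", [0.5, 3.0, 100.0])
    def test_amplitude_invariance(self, amp):
        ref = burst_slopes(*self._envelope(0.2, 0.5, amp=1.0))
        scaled = burst_slopes(*self._envelope(0.2, 0.5, amp=amp))
        np.testing.assert_allclose(scaled, ref, rtol=1e-9)

    def test_time_compression_equivariance(self):
        ini1, fin1 = burst_slopes(*self._envelope(0.2, 0.4))
        ini2, fin2 = burst_slopes(*self._envelope(0.1, 0.2))
        assert abs(ini2 / ini1 - 2.0) < 0.02
        assert abs(fin2 / fin1 - 2.0) < 0.02

    def test_degenerate_peak_at_boundary(self):
        rate = 1000.0
        vals = np.concatenate([np.zeros(100), np.linspace(0, 1, 200)])
        env = DensityTrace(values=vals, rate=rate)
        b = Burst(onset_t=0.1, peak_t=0.3, offset_t=0.299, peak_value=1.0, n_spikes=0)
        with pytest.raises(ValueError, match="degenerate"):
            burst_slopes(env, b)


def _catalog_from(bds, n_spikes):
    bursts = [
        Burst(onset_t=i * 10.0, peak_t=i * 10.0 + bd / 2, offset_t=i * 10.0 + bd,
              peak_value=1.0, n_spikes=int(ns))
        for i, (bd, ns) in enumerate(zip(bds, n_spikes))
    ]
    return BurstCatalog(bursts=bursts, duration=10.0 * len(bursts))


class TestBDSpikeCountRelation:
    def test_linear_power_law(self):
        bds = np.array([0.1, 0.2, 0.4, 0.8, 1.6])
        res = bd_spikecount_relation(_catalog_from(bds, 100 * bds))
        assert abs(res["slope"] - 1.0) < 1e-9
        assert abs(res["correlation"] - 1.0) < 1e-12

    def test_quadratic_power_law(self):
        bds = np.array([0.1, 0.2, 0.4, 0.8, 1.6])
        res = bd_spikecount_relation(_catalog_from(bds, 100 * bds**2))
        assert abs(res["slope"] - 2.0) < 1e-9

    def test_constant_bd_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bd_spikecount_relation(_catalog_from([0.3, 0.3, 0.3], [10, 20, 30]))

    def test_too_few_bursts_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            bd_spikecount_relation(_catalog_from([0.1, 0.2], [10, 20]))
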