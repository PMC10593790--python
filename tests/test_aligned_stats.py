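"""Event alignment, lagged correlation, and phase-shuffle surrogate tests."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from bgpipe import aligned_stats as al
from bgpipe.errors import InsufficientDataError, UndefinedCorrelationError
from bgpipe.events import EventSet
from bgpipe.photometry import DffTrace


def _trace(x, fs=20.0):
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size) / fs
    return DffTrace(t, np.ones_like(x), x, x, fs=fs)


class TestAlignToEvents:
    def test_raw_slice_without_baseline(self):
        x = np.arange(200.0)
        m = al.align_to_events(_trace(x), [5.0], 1.0, 1.0)
        np.testing.assert_array_equal(m.data[0], x[80:121])

    def test_constant_trace_with_baseline_is_zero(self):
        m = al.align_to_events(_trace(np.full(400, 3.0)), [10.0], 5.0, 5.0,
                               baseline_window=(-5.0, -1.0))
        np.testing.assert_allclose(m.data, 0.0, atol=1e-12)

    def test_edge_events_dropped(self):
        m = al.align_to_events(_trace(np.arange(200.0)), [0.5, 5.0, 9.9],
                               1.0, 1.0)
        assert m.data.shape[0] == 1
        assert m.n_dropped == 2

    def test_baseline_window_mean_exactly_zero(self, rng):
        x = rng.standard_normal(2000)
        m = al.align_to_events(_trace(x), [30.0, 50.0], 10.0, 10.0,
                               baseline_window=(-5.0, -1.0))
        sel = (m.rel_time_s >= -5.0) & (m.rel_time_s <= -1.0)
        np.testing.assert_allclose(m.data[:, sel].mean(axis=1), 0.0, atol=1e-12)


class TestPostEventExtremum:
    def test_single_bump_latency(self):
        fs = 20.0
        t = np.arange(300) / fs
        row = np.exp(-0.5 * ((t - 6.0) / 0.3) ** 2)  # event at 5 s, peak +1 s
        m = al.align_to_events(_trace(row, fs), [5.0], 2.0, 5.0)
        vals, lats, flagged = al.post_event_extremum(m, (0.0, 5.0), "max")
        assert lats[0] == pytest.approx(1.0, abs=0.05)
        assert not flagged[0]

    def test_min_of_mirror_equals_negated_max(self, rng):
        x = gaussian_filter1d(rng.standard_normal(400), 3)
        m = al.align_to_events(_trace(x), [10.0], 2.0, 5.0)
        m_neg = al.align_to_events(_trace(-x), [10.0], 2.0, 5.0)
        vmax, lmax, _ = al.post_event_extremum(m, mode="max")
        vmin, lmin, _ = al.post_event_extremum(m_neg, mode="min")
        assert vmin[0] == pytest.approx(-vmax[0], abs=1e-12)
        assert lmin[0] == pytest.approx(lmax[0], abs=1e-12)

    def test_monotone_row_flagged(self):
        m = al.align_to_events(_trace(np.arange(400.0)), [10.0], 2.0, 5.0)
        vals, lats, flagged = al.post_event_extremum(m, (0.0, 5.0), "max")
        assert flagged[0]
        assert lats[0] == pytest.approx(5.0, abs=0.05)


class TestAmplitudeChange:
    def test_constant_rows_zero_delta(self):
        m = al.align_to_events(_trace(np.full(600, 2.0)), [10.0], 5.0, 12.0)
        for rule in ("bout", "opto"):
            d = al.amplitude_change(m, rule, offsets_rel_s=10.0)
            np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_linear_ramp_opto_delta(self):
        fs = 20.0
        x = np.arange(600.0) / fs * 0.2  # +0.2 z/s -> +2 z over 10 s
        m = al.align_to_events(_trace(x, fs), [10.0], 5.0, 12.0)
        d = al.amplitude_change(m, "opto", offsets_rel_s=10.0)
        assert d[0] == pytest.approx(2.0, abs=1e-9)

    def test_bout_delta_matches_constructed_amplitude(self):
        fs = 20.0
        t = np.arange(1200) / fs
        # dip at the onset (20 s), peak at the offset (30 s)
        x = (-1.0 * np.exp(-0.5 * ((t - 20.0) / 0.5) ** 2)
             + 2.0 * np.exp(-0.5 * ((t - 30.0) / 0.5) ** 2))
        m = al.align_to_events(_trace(x, fs), [20.0], 10.0, 15.0)
        d = al.amplitude_change(m, "bout", offsets_rel_s=10.0, search_s=3.0)
        assert d[0] == pytest.approx(3.0, rel=0.05)


class TestDurationCoupling:
    def test_identical_durations_r_one(self):
        jumps = np.cumsum(np.concatenate([[5.0], 1.0 + 0.3 *
                                          np.random.default_rng(0).random(20)]))
        jd, td, r, p = al.transient_duration_and_event_duration(jumps, jumps)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_unrelated_transient_timing_uncorrelated(self):
        # transient jitter unrelated to (near-constant) jump durations:
        # the pooled correlation over ~1000 pairs stays near zero
        rng = np.random.default_rng(1)
        jumps = np.cumsum(1.5 + rng.uniform(-0.02, 0.02, 1001))
        peaks = jumps + rng.uniform(-0.45, 0.45, jumps.size)
        jd, td, r, p = al.transient_duration_and_event_duration(
            peaks, jumps, max_offset_s=0.5)
        assert jd.size > 900
        assert abs(r) < 0.1

    def test_correlation_rises_as_noise_falls(self):
        rng = np.random.default_rng(2)
        jumps = np.cumsum(1.2 + 0.5 * rng.random(400))
        rs = []
        for noise in (0.3, 0.1, 0.02):
            peaks = jumps + rng.normal(0.0, noise, jumps.size)
            _, _, r, _ = al.transient_duration_and_event_duration(
                np.sort(peaks), jumps)
            rs.append(r)
        assert rs[0] < rs[1] < rs[2]
        assert rs[-1] > 0.9

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            al.transient_duration_and_event_duration([1.0, 2.0], [1.0, 2.0])


class TestLaggedPearson:
    def test_identity_best_at_zero(self, rng):
        x = rng.standard_normal(500)
        lc = al.lagged_pearson(x, x, fs=10.0, max_lag_s=2.0)
        assert lc.best_r == pytest.approx(1.0, abs=1e-12)
        assert lc.best_lag_s == 0.0

    def test_known_shift_recovered(self, rng):
        x = rng.standard_normal(1000)
        k = 7
        y = np.roll(x, k)  # y[t] = x[t - k] -> x leads y by k samples
        lc = al.lagged_pearson(x, y, fs=10.0, max_lag_s=2.0)
        assert lc.best_lag_s == pytest.approx(k / 10.0)
        assert abs(lc.best_r) > 0.99

    def test_matches_bruteforce_oracle(self, rng):
        x = rng.standard_normal(400)
        y = rng.standard_normal(400)
        lc = al.lagged_pearson(x, y, fs=10.0, max_lag_s=1.5)
        for i, k in enumerate(np.arange(-15, 16)):
            if k >= 0:
                a, b = x[: 400 - k], y[k:]
            else:
                a, b = x[-k:], y[: 400 + k]
            assert lc.r_by_lag[i] == pytest.approx(np.corrcoef(a, b)[0, 1],
                                                   abs=1e-10)

    def test_antisymmetric_best_lag(self, rng):
        x = gaussian_filter1d(rng.standard_normal(600), 2)
        y = gaussian_filter1d(rng.standard_normal(600), 2) + 0.5 * np.roll(x, 3)
        ab = al.lagged_pearson(x, y, 10.0, 1.0)
        ba = al.lagged_pearson(y, x, 10.0, 1.0)
        assert ab.best_lag_s == pytest.approx(-ba.best_lag_s)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            al.lagged_pearson(np.ones(100), np.arange(100.0), 10.0, 1.0)


class TestPhaseShuffle:
    def test_amplitude_spectrum_preserved(self, rng):
        x = rng.standard_normal(257)  # odd length
        s = al.phase_shuffle(x, rng)
        np.testing.assert_allclose(np.abs(np.fft.rfft(s)),
                                   np.abs(np.fft.rfft(x)), rtol=1e-9)

    def test_even_length_and_mean_preserved(self, rng):
        x = rng.standard_normal(256)
        s = al.phase_shuffle(x, rng)
        np.testing.assert_allclose(np.abs(np.fft.rfft(s)),
                                   np.abs(np.fft.rfft(x)), rtol=1e-9)
        assert s.mean() == pytest.approx(x.mean(), abs=1e-12)

    def test_total_power_preserved(self, rng):
        x = rng.standard_normal(512)
        s = al.phase_shuffle(x, rng)
        assert np.sum(s ** 2) == pytest.approx(np.sum(x ** 2), rel=1e-9)

    def test_autocorrelation_preserved(self, rng):
        # Wiener-Khinchin: equal power spectra imply equal circular ACF
        x = gaussian_filter1d(rng.standard_normal(512), 4)
        s = al.phase_shuffle(x, rng)
        acf = lambda v: np.fft.irfft(np.abs(np.fft.rfft(v)) ** 2)
        np.testing.assert_allclose(acf(s), acf(x), atol=1e-9)


class TestShuffleCorrelationTest:
    def test_perfect_coupling_hits_ranksum_floor(self, rng):
        xs = [gaussian_filter1d(rng.standard_normal(256), 2)
              for _ in range(4)]
        st = al.shuffle_correlation_test(xs, xs, fs=50.0, n_shuffle=99,
                                         rng=rng, max_lag_s=0.2)
        assert np.all(st.real_values >= 1.0 - 1e-9)
        assert st.real_values.min() >= st.surrogate_values.max()
        # all real values above every surrogate -> the exact two-sided
        # rank-sum floor for group sizes (4, 99)
        import math
        floor = 2.0 / math.comb(103, 4)
        assert st.p_value == pytest.approx(floor, rel=1e-6)

    def test_seed_determinism(self):
        x = np.random.default_rng(3).standard_normal((4, 256))
        y = np.random.default_rng(4).standard_normal((4, 256))
        p = [al.shuffle_correlation_test(list(x), list(y), 50.0, n_shuffle=50,
                                         rng=np.random.default_rng(9),
                                         max_lag_s=0.2).p_value
             for _ in range(2)]
        assert p[0] == p[1]

    def test_surrogate_count(self, rng):
        xs = [rng.standard_normal(128)]
        st = al.shuffle_correlation_test(xs, xs, 50.0, n_shuffle=37, rng=rng,
                                         max_lag_s=0.1)
        assert st.surrogate_values.size == 37


class TestEpochCorrelation:
    def test_identical_traces_r_one_everywhere(self, rng):
        x = rng.standard_normal(3000)
        g = _trace(x)
        out = al.epoch_correlation(g, _trace(x.copy()),
                                   {"pre": (0, 50), "during": (50, 100),
                                    "post": (100, 150)})
        assert set(out) == {"pre", "during", "post"}
        for lc in out.values():
            assert lc.best_r == pytest.approx(1.0, abs=1e-12)

    def test_epoch_noise_ordering_recovered(self):
        # shared source with epoch-specific independent noise: the low-noise
        # epoch must show the higher correlation, across 20 seeds
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 4000
            shared = gaussian_filter1d(rng.standard_normal(n), 5)
            shared /= shared.std()
            noise = np.where(np.arange(n) < n // 2, 0.3, 1.5)
            x = shared + noise * rng.standard_normal(n)
            y = shared + noise * rng.standard_normal(n)
            out = al.epoch_correlation(_trace(x), _trace(y),
                                       {"low": (0, 100), "high": (100, 200)})
            wins += out["low"].best_r > out["high"].best_r
        assert wins == 20

    def test_degenerate_epoch_skipped(self, rng):
        x = rng.standard_normal(2000)
        y = x.copy()
        x[:500] = 1.0  # zero variance in the first epoch
        out = al.epoch_correlation(_trace(x), _trace(y),
                                   {"flat": (0, 25), "ok": (25, 100)})
        assert "flat" not in out and "ok" in out
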