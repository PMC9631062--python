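"""Spike detection, scoring, PSTH and cross-correlation null bands."""

import numpy as np
import pytest

from spadvi import pipeline, spikes
from spadvi.neuron import SpikeTrain


def band_trace(values, rate=1000.0):
    return pipeline.BinnedTrace(values=np.asarray(values, float),
                                effective_rate_Hz=rate, bin_factor=10)


def poisson_train(rate_hz, duration, seed, source=""):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration)
    times = np.sort(rng.uniform(0, duration, n))
    times = times[np.concatenate([[True], np.diff(times) > 0])]
    return SpikeTrain(times=times, duration_s=duration, source=source)


class TestDetect:
    def test_clean_spikes_found_at_peaks(self):
        x = np.zeros(2000)
        peaks = [300, 900, 1500]
        for p in peaks:
            x[p] = 100.0
        x += np.random.default_rng(0).normal(0, 1.0, x.size)
        params = spikes.DetectorParams(min_amplitude=1.0)
        train = spikes.detect_spikes(band_trace(x), params)
        assert len(train) == 3
        np.testing.assert_allclose(train.times, np.array(peaks) / 1000.0,
                                   atol=1.5e-3)

    def test_pure_noise_yields_no_detections(self):
        x = np.random.default_rng(1).normal(0, 1.0, 10_000)
        params = spikes.DetectorParams(sd_threshold=10.0)
        assert len(spikes.detect_spikes(band_trace(x), params)) == 0

    def test_refractory_keeps_larger_peak(self):
        x = np.zeros(1000)
        x[500] = 50.0
        x[502] = 80.0
        x += np.random.default_rng(2).normal(0, 0.5, x.size)
        train = spikes.detect_spikes(band_trace(x),
                                     spikes.DetectorParams(min_amplitude=1.0))
        assert len(train) == 1
        assert train.times[0] == pytest.approx(0.502, abs=1e-9)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            spikes.detect_spikes(band_trace(np.zeros(30)),
                                 spikes.DetectorParams(window_samples=51))


class TestScore:
    def test_confusion_counts_by_definition(self):
        truth = SpikeTrain(np.array([0.010, 0.020, 0.030]), 0.1)
        det = SpikeTrain(np.array([0.0105, 0.0202, 0.045]), 0.1)
        s = spikes.score_detection(det, truth, tolerance_ms=2.0)
        assert (s.true_positives, s.false_negatives, s.false_positives) == \
            (2, 1, 1)

    def test_identical_trains(self):
        t = SpikeTrain(np.array([0.1, 0.2]), 1.0)
        s = spikes.score_detection(t, t, 2.0)
        assert (s.true_positives, s.false_negatives, s.false_positives) == \
            (2, 0, 0)

    def test_empty_detection_all_missed(self):
        truth = SpikeTrain(np.array([0.1, 0.2, 0.3]), 1.0)
        s = spikes.score_detection(SpikeTrain(np.empty(0), 1.0), truth, 2.0)
        assert s.false_negatives == 3
        assert s.true_positives == 0

    def test_swap_symmetry(self):
        a = poisson_train(8, 5.0, 10)
        b = poisson_train(8, 5.0, 11)
        s1 = spikes.score_detection(a, b, 2.0)
        s2 = spikes.score_detection(b, a, 2.0)
        assert s1.true_positives == s2.true_positives
        assert s1.false_positives == s2.false_negatives
        assert s1.false_negatives == s2.false_positives


class TestPsth:
    def test_self_coincidence_at_zero_lag(self):
        t = poisson_train(5, 10.0, 3)
        centers, counts = spikes.psth(t, t)
        zero_bin = np.argmin(np.abs(centers - 0.001))  # [0, 2) ms
        assert counts[zero_bin] >= len(t)  # every spike coincides with itself

    def test_constructed_shift_lands_in_one_bin(self):
        ref = SpikeTrain(np.array([0.1, 0.3, 0.5]), 1.0)
        tar = SpikeTrain(ref.times + 0.004, 1.0)
        centers, counts = spikes.psth(ref, tar)
        assert counts.sum() == 3
        hit = np.flatnonzero(counts)
        assert centers[hit[0]] == pytest.approx(0.005)  # the [+4,+6) bin

    def test_independent_rate_product(self):
        ref = poisson_train(5, 50.0, 20)
        tar = poisson_train(5, 50.0, 21)
        centers, counts = spikes.psth(ref, tar, window_s=0.05, bin_s=0.002)
        expected = len(ref) * len(tar) * 0.002 / 50.0
        # each bin is ~Poisson(expected); compare the mean across 25 bins
        assert counts.mean() == pytest.approx(
            expected, abs=4 * np.sqrt(expected / counts.size))

    def test_total_count_conservation(self):
        ref = poisson_train(6, 10.0, 30)
        tar = poisson_train(6, 10.0, 31)
        centers, counts = spikes.psth(ref, tar, window_s=0.05, bin_s=0.002)
        edges_lo, edges_hi = centers[0] - 0.001, centers[-1] + 0.001
        n_pairs = sum(
            np.sum((tar.times - r >= edges_lo) & (tar.times - r < edges_hi))
            for r in ref.times)
        assert counts.sum() == n_pairs

    def test_window_not_multiple_of_bin_rejected(self):
        ref = poisson_train(5, 10.0, 1)
        with pytest.raises(ValueError):
            spikes.psth(ref, ref, window_s=0.05, bin_s=0.003)

    def test_empty_reference_rejected(self):
        ref = SpikeTrain(np.empty(0), 1.0)
        tar = poisson_train(5, 1.0, 2)
        with pytest.raises(ValueError):
            spikes.psth(ref, tar)


class TestPsthNull:
    def test_null_mean_matches_rate_product(self):
        ref = poisson_train(8, 20.0, 40)
        tar = poisson_train(8, 20.0, 41)
        band = spikes.psth_null(ref, tar, n_shuffles=200, seed=0)
        expected = len(ref) * len(tar) * 0.002 / 20.0
        assert band.null_mean.mean() == pytest.approx(expected, rel=0.1)

    def test_independent_trains_mostly_inside_band(self):
        inside = []
        for seed in range(10):
            ref = poisson_train(8, 10.0, 100 + seed)
            tar = poisson_train(8, 10.0, 200 + seed)
            band = spikes.psth_null(ref, tar, n_shuffles=100, seed=seed)
            inside.append(1 - band.outside_band().mean())
        assert np.mean(inside) >= 0.85

    def test_synchronized_trains_break_zero_lag_band(self):
        rng = np.random.default_rng(7)
        base = np.sort(rng.uniform(0, 10.0, 40))
        ref = SpikeTrain(base, 10.0)
        tar = SpikeTrain(np.sort(base + rng.normal(0, 1e-3, 40)), 10.0)
        band = spikes.psth_null(ref, tar, n_shuffles=100, seed=1)
        zero_bin = np.argmin(np.abs(band.centers - 0.001))
        near = band.observed[zero_bin] + band.observed[zero_bin - 1]
        assert near > band.p95[zero_bin] + band.p95[zero_bin - 1]

    def test_few_shuffles_warns(self):
        ref = poisson_train(5, 5.0, 50)
        with pytest.warns(UserWarning, match="shuffles"):
            spikes.psth_null(ref, ref, n_shuffles=10, seed=0)

    def test_isi_shuffle_preserves_count(self):
        ref = poisson_train(5, 10.0, 60)
        band = spikes.psth_null(ref, ref, n_shuffles=25, seed=0, scheme="isi")
        assert band.n_shuffles == 25


class TestXcorr:
    def test_autocorrelation_unity_at_zero_lag(self):
        x = np.random.default_rng(5).normal(size=500)
        lags, corr = spikes.subthreshold_xcorr(x, x)
        assert corr[lags == 0][0] == pytest.approx(1.0)

    def test_shift_peaks_at_lag(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=1000)
        y = np.roll(x, -50)  # y leads x by 50 samples
        lags, corr = spikes.subthreshold_xcorr(x, y)
        assert lags[np.argmax(corr)] == 50

    def test_independent_noise_peak_small(self):
        rng = np.random.default_rng(8)
        n = 1000
        lags, corr = spikes.subthreshold_xcorr(rng.normal(size=n),
                                               rng.normal(size=n))
        # central lags (edge lags average few samples and are noisier)
        mid = np.abs(lags) < n // 4
        assert np.abs(corr[mid]).max() < 6 / np.sqrt(n)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            spikes.subthreshold_xcorr(np.zeros(10), np.zeros(12))

    def test_epoch_averaging(self):
        rng = np.random.default_rng(9)
        pairs_a = [rng.normal(size=200) for _ in range(3)]
        pairs_b = [rng.normal(size=200) for _ in range(3)]
        lags, corr = spikes.subthreshold_xcorr(pairs_a, pairs_b)
        singles = [spikes.subthreshold_xcorr(a, b)[1]
                   for a, b in zip(pairs_a, pairs_b)]
        np.testing.assert_allclose(corr, np.mean(singles, axis=0))


class TestXcorrNull:
    def make_bank(self, n_sources=5, seed=0):
        rng = np.random.default_rng(seed)
        return {s: [rng.normal(size=300) for _ in range(2)]
                for s in range(n_sources)}

    def test_band_centered_near_zero(self):
        band = spikes.xcorr_null(self.make_bank(), n_pairs=100, seed=0)
        mid = np.abs(band.centers) < 100
        assert np.abs(band.null_mean[mid]).max() < 2 / np.sqrt(300)

    def test_common_drive_exceeds_band(self):
        rng = np.random.default_rng(1)
        common = rng.normal(size=300)
        a = common + 0.3 * rng.normal(size=300)
        b = common + 0.3 * rng.normal(size=300)
        lags, corr = spikes.subthreshold_xcorr(a, b)
        band = spikes.xcorr_null(self.make_bank(seed=2), n_pairs=100, seed=3)
        z = lags == 0
        assert corr[z][0] > band.p95[z][0]

    def test_single_source_rejected(self):
        with pytest.raises(ValueError):
            spikes.xcorr_null({0: [np.zeros(10)]}, n_pairs=10, seed=0)

    def test_default_pair_count(self):
        band = spikes.xcorr_null(self.make_bank(), seed=0)
        assert band.n_shuffles == 100
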