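import numpy as np
import pytest
from scipy.stats import spearmanr, wilcoxon

from pcaboot import (
    EpochSet,
    band_features,
    bandpass_filter,
    bartlett_psd,
    build_feature_matrix,
    make_epochs,
    time_features,
)

FS = 400.0


def _sine(freq, seconds=10.0, fs=FS, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpassFilter:
    def test_passband_tone_preserved(self):
        y = bandpass_filter(_sine(10.0), FS)
        mid = y[800:-800]  # skip edge transients
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_tone_attenuated(self):
        y = bandpass_filter(_sine(60.0), FS)
        assert np.abs(y[800:-800]).max() < 0.1

    def test_zero_signal_maps_to_zero(self):
        np.testing.assert_allclose(bandpass_filter(np.zeros(4000), FS), 0.0)

    def test_zero_phase(self):
        # forward-reverse filtering must not delay a passband tone
        x = _sine(10.0)
        y = bandpass_filter(x, FS)
        seg = slice(800, -800)
        lag = np.argmax(np.correlate(y[seg], x[seg], mode="full")) - (
            len(x[seg]) - 1
        )
        assert lag == 0

    def test_sampling_rate_too_low(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(1000), fs=70.0, hi=40.0)


class TestMakeEpochs:
    def test_one_second_epochs(self):
        x = np.random.default_rng(0).normal(size=int(150 * FS))
        es = make_epochs(x, FS)
        assert es.epochs.shape == (150, 400)

    def test_epochs_are_zero_mean(self):
        x = np.random.default_rng(1).normal(loc=5.0, size=int(10 * FS))
        es = make_epochs(x, FS)
        np.testing.assert_allclose(es.epochs.mean(axis=1), 0.0, atol=1e-9)

    def test_constant_series_gives_zero_epochs(self):
        es = make_epochs(np.full(2000, 7.7), FS)
        np.testing.assert_allclose(es.epochs, 0.0, atol=1e-12)

    def test_max_epochs_cap_keeps_first(self):
        # tone whose amplitude grows 1 -> 2 over 200 s: the cap must keep the
        # first (small-amplitude) 150 epochs, not the last ones
        t = np.arange(int(200 * FS)) / FS
        x = (1 + t / 200.0) * np.sin(2 * np.pi * 10.0 * t)
        es = make_epochs(x, FS, max_epochs=150)
        assert es.n_epochs == 150
        assert np.abs(es.epochs[-1]).max() < 1.8

    def test_too_few_epochs_flagged(self):
        x = np.random.default_rng(2).normal(size=int(100 * FS))
        es = make_epochs(x, FS, min_epochs=150)
        assert es.too_few

    def test_amplitude_threshold_rejection(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=int(20 * FS))
        x[int(5.5 * FS)] = 50.0  # one artifact spike in epoch 5
        es = make_epochs(x, FS, reject_k=10.0)
        assert es.n_rejected == 1
        assert es.n_epochs == 19


class TestBartlettPSD:
    def test_peak_at_tone_frequency(self):
        es = make_epochs(_sine(10.0, seconds=20.0), FS)
        freqs, psd = bartlett_psd(es)
        assert freqs[np.argmax(psd)] == pytest.approx(10.0)

    def test_parseval(self):
        rng = np.random.default_rng(4)
        es = make_epochs(rng.normal(size=int(30 * FS)), FS)
        freqs, psd = bartlett_psd(es)
        df = freqs[1] - freqs[0]
        assert df == pytest.approx(1.0)  # 1 Hz resolution at 1-s epochs
        total = psd.sum() * df
        ms = np.mean(es.epochs**2)
        assert total == pytest.approx(ms, rel=1e-6)

    def test_averaging_shrinks_variance(self):
        # Bartlett: across-bin scatter of a white-noise PSD shrinks with E
        rng = np.random.default_rng(5)
        x = rng.normal(size=int(200 * FS))
        few = make_epochs(x, FS, max_epochs=5)
        many = make_epochs(x, FS, max_epochs=180)
        spread = lambda es: np.std(bartlett_psd(es)[1][5:150])  # noqa: E731
        assert spread(many) < spread(few) / 2


class TestBandFeatures:
    def test_flat_psd_max_is_zero_log(self):
        freqs = np.arange(0, 201.0)
        psd = np.ones_like(freqs)
        bmax, _ = band_features(freqs, psd, (8, 13))
        assert bmax == 0.0

    def test_triangular_peak_trapezoid(self):
        freqs = np.arange(0, 201.0)
        psd = np.ones_like(freqs)
        psd[10] = 100.0
        _, bpow = band_features(freqs, psd, (8, 13), half_width=1.0)
        # trapezoid over 9,10,11 Hz: 0.5*(1+100) + 0.5*(100+1) = 101
        assert bpow == pytest.approx(np.log10(101.0))

    def test_boundary_peak_shared_by_adjacent_bands(self):
        es = make_epochs(_sine(8.0, seconds=20.0, amp=5.0), FS)
        freqs, psd = bartlett_psd(es)
        alpha_max, _ = band_features(freqs, psd, (8, 13))
        theta_max, _ = band_features(freqs, psd, (4, 8))
        assert alpha_max == theta_max

    def test_empty_band_error(self):
        with pytest.raises(ValueError):
            band_features(np.arange(10.0), np.ones(10), (20, 30))


class TestTimeFeatures:
    def test_unit_sinusoid_closed_forms(self):
        es = make_epochs(_sine(10.0, seconds=20.0), FS)
        t = time_features(es)
        assert t["rms"] == pytest.approx(1 / np.sqrt(2), abs=1e-6)
        assert t["mm"] == pytest.approx(2.0, abs=1e-6)
        assert t["skewness"] == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_epochs_zero_median_skewness(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=int(50 * FS))
        t = time_features(make_epochs(x, FS))
        assert abs(t["skewness"]) < 0.1

    def test_sd_rms_ratio_for_zero_mean_epochs(self):
        rng = np.random.default_rng(7)
        es = make_epochs(rng.normal(size=int(5 * FS)), FS)
        t = time_features(es)
        L = es.epoch_len
        # per zero-mean epoch: rms = sd * sqrt((L-1)/L) with the n-1 SD
        rms = np.sqrt(np.mean(es.epochs**2, axis=1))
        sd = es.epochs.std(axis=1, ddof=1)
        np.testing.assert_allclose(rms, sd * np.sqrt((L - 1) / L), rtol=1e-12)
        assert t["rms"] <= t["sd"]


class TestFeatureMatrix:
    def test_study_shape_and_order(self, eeg_feature_matrix):
        X = eeg_feature_matrix
        assert X.values.shape == (48, 10)
        assert X.col_names[:3] == ["alpha_power", "beta_power", "theta_power"]
        assert X.row_ids[0].endswith("_A") and X.row_ids[1].endswith("_B")

    def test_rms_sd_perfect_spearman(self, eeg_feature_matrix):
        df = eeg_feature_matrix.to_frame()
        rho = spearmanr(df["rms"], df["sd"]).statistic
        assert rho == pytest.approx(1.0)

    def test_all_feature_pairs_positively_correlated(self, eeg_feature_matrix):
        rho = spearmanr(eeg_feature_matrix.values).statistic
        off = rho[np.triu_indices(10, 1)]
        assert off.min() > 0

    def test_alpha_power_separates_conditions(self, eeg_feature_matrix):
        df = eeg_feature_matrix.to_frame()
        closed = df[df.index.str.endswith("_A")]["alpha_power"].to_numpy()
        opened = df[df.index.str.endswith("_B")]["alpha_power"].to_numpy()
        p = wilcoxon(closed, opened, alternative="greater").pvalue
        assert p < 1e-4

    def test_missing_condition_drops_subject(self):
        rng = np.random.default_rng(8)
        sets = []
        for sid in ("S1", "S2", "S3"):
            for cond in ("A", "B"):
                if sid == "S2" and cond == "B":
                    continue
                x = rng.normal(size=int(6 * FS)) + _sine(10.0, 6.0)
                sets.append(
                    make_epochs(x, FS, subject_id=sid, condition=cond)
                )
        X, excluded = build_feature_matrix(sets)
        assert excluded == ["S2"]
        assert X.values.shape[0] == 4  # S2 dropped entirely: both rows gone

    def test_inconsistent_sampling_rates_rejected(self):
        rng = np.random.default_rng(9)
        a = make_epochs(rng.normal(size=4000), 400.0, subject_id="S1", condition="A")
        b = make_epochs(rng.normal(size=4000), 200.0, subject_id="S1", condition="B")
        with pytest.raises(ValueError):
            build_feature_matrix([a, b])
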