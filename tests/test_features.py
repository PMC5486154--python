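import numpy as np
import pytest

from ctleeg import (
    BandScheme,
    Montage,
    dlat_features,
    extract_subject_features,
    gain_calibrate,
    stft_band_power,
    zscore_within_subject,
)
from ctleeg.features import BandPowerSeries, FeatureMatrix

from .conftest import make_trialset


def brute_force_band_power(x: np.ndarray, fs: float, scheme: BandScheme,
                           window: float = 1.0, overlap: float = 0.5) -> np.ndarray:
    """Independent per-frame band power: explicit windowed periodogram."""
    win = int(round(window * fs))
    step = int(round(win * (1 - overlap)))
    w = np.hamming(win)
    freqs = np.fft.rfftfreq(win, 1 / fs)
    n_frames = (len(x) - win) // step + 1
    out = np.empty((scheme.n_bands, n_frames))
    for f in range(n_frames):
        seg = x[f * step: f * step + win] * w
        psd = np.abs(np.fft.rfft(seg)) ** 2 / (fs * np.sum(w**2))
        psd[1:] *= 2
        if win % 2 == 0:
            psd[-1] /= 2
        for b, (_, low, high) in enumerate(scheme.bands):
            mask = (freqs >= max(low, 1.0)) & (freqs <= min(high, 50.0))
            out[b, f] = psd[mask].mean()
    return out


class TestStftBandPower:
    def test_frame_count_for_30s_trial(self):
        ts = make_trialset(np.random.default_rng(0).normal(size=(2, 1, 30 * 128)), fs=128)
        assert stft_band_power(ts).n_frames == 59  # starts 0.0, 0.5, ..., 29.0

    def test_all_zero_signal_gives_zero_power(self):
        ts = make_trialset(np.zeros((2, 2, 256)), fs=128)
        assert np.all(stft_band_power(ts).power == 0)

    def test_alpha_sinusoid_dominates_alpha_band_every_frame(self):
        t = np.arange(3 * 128) / 128
        ts = make_trialset(np.sin(2 * np.pi * 10 * t)[None, None, :], fs=128)
        bp = stft_band_power(ts)
        alpha = bp.scheme.names.index("alpha")
        for b in range(bp.scheme.n_bands):
            if b != alpha:
                assert np.all(bp.power[0, 0, alpha] > bp.power[0, 0, b])

    def test_matches_brute_force_periodogram_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2 * 128) + np.sin(2 * np.pi * 21 * np.arange(256) / 128)
        ts = make_trialset(x[None, None, :], fs=128)
        bp = stft_band_power(ts)
        expected = brute_force_band_power(x, 128, bp.scheme)
        np.testing.assert_allclose(bp.power[0, 0], expected, rtol=1e-6)

    def test_trial_shorter_than_window_rejected(self):
        ts = make_trialset(np.zeros((1, 1, 100)), fs=128)
        with pytest.raises(ValueError, match="shorter than"):
            stft_band_power(ts)

    def test_low_sampling_rate_rejected(self):
        ts = make_trialset(np.zeros((1, 1, 128)), fs=64)
        with pytest.raises(ValueError, match="Nyquist"):
            stft_band_power(ts)


def _series(values_per_frame, n_bands: int = 1) -> BandPowerSeries:
    """(n_frames,) values replicated into a 1-trial 1-channel series."""
    values = np.asarray(values_per_frame, dtype=float)
    power = np.tile(values, (1, 1, n_bands, 1))
    scheme = BandScheme(bands=(("alpha", 8.0, 13.0),)) if n_bands == 1 else BandScheme()
    return BandPowerSeries(
        power=power, frame_starts=np.arange(len(values)) * 0.5, window=1.0,
        fs=128.0, scheme=scheme,
    )


class TestGainCalibrate:
    def test_constant_series_becomes_one(self):
        out = gain_calibrate(_series([2.0] * 12))
        np.testing.assert_allclose(out.power, 1.0)

    def test_scale_invariance(self):
        bp = _series(np.random.default_rng(1).uniform(1, 3, 12))
        doubled = BandPowerSeries(
            power=2 * bp.power, frame_starts=bp.frame_starts, window=bp.window,
            fs=bp.fs, scheme=bp.scheme,
        )
        np.testing.assert_allclose(
            gain_calibrate(bp).power, gain_calibrate(doubled).power
        )

    def test_baseline_mean_two_frame_three_gives_ratio(self):
        vals = [2.0] * 9 + [3.0, 3.0, 3.0]  # baseline = frames starting <= 4.0 s
        out = gain_calibrate(_series(vals))
        np.testing.assert_allclose(out.power[0, 0, 0, -1], 1.5)

    def test_zero_baseline_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            gain_calibrate(_series([0.0] * 9 + [1.0] * 3))


class TestDlatFeatures:
    def test_mirrored_signals_give_zero_features(self):
        rng = np.random.default_rng(5)
        half = rng.normal(size=(3, 1, 6 * 128)) + 2.0
        signals = np.concatenate([half, half], axis=1)  # C3 == C4
        ts = make_trialset(signals, fs=128)
        montage = Montage(channel_names=("C3", "C4"))
        fm = dlat_features(gain_calibrate(stft_band_power(ts)), montage)
        np.testing.assert_allclose(fm.values, 0.0, atol=1e-12)

    def test_default_montage_yields_60_features(self, tiny_cohort):
        fm = extract_subject_features(tiny_cohort.trial_sets[0], tiny_cohort.montage)
        assert fm.n_features == 60
        assert fm.descriptors[:6] == ((0, 0), (0, 1), (0, 2), (0, 3), (0, 4), (1, 0))

    def test_left_exceeding_right_by_one_gives_feature_one(self):
        montage = Montage(channel_names=("C3", "C4"))
        power = np.ones((2, 2, 1, 12))
        power[:, 0] += 1.0  # left = right + 1 everywhere
        bp = BandPowerSeries(
            power=power, frame_starts=np.arange(12) * 0.5, window=1.0, fs=128.0,
            scheme=BandScheme(bands=(("alpha", 8.0, 13.0),)), calibrated=True,
        )
        np.testing.assert_allclose(dlat_features(bp, montage).values, 1.0)

    def test_swapping_pair_members_negates_every_feature(self, tiny_cohort):
        ts = tiny_cohort.trial_sets[0]
        m = tiny_cohort.montage
        swapped = Montage(
            channel_names=m.channel_names,
            symmetric_pairs=tuple((r, l) for l, r in m.symmetric_pairs),
        )
        bp = gain_calibrate(stft_band_power(ts))
        np.testing.assert_allclose(
            dlat_features(bp, swapped).values, -dlat_features(bp, m).values
        )

    def test_uncalibrated_input_rejected(self, tiny_cohort, montage30):
        bp = stft_band_power(tiny_cohort.trial_sets[0])
        with pytest.raises(ValueError, match="calibrated"):
            dlat_features(bp, montage30)

    def test_trial_permutation_permutes_feature_rows(self, tiny_cohort):
        ts = tiny_cohort.trial_sets[0]
        fm = extract_subject_features(ts, tiny_cohort.montage)
        perm = np.array([3, 0, 2, 1, 7, 5, 6, 4])
        ts_perm = make_trialset(ts.signals[perm], fs=ts.fs,
                                labels=ts.labels.iloc[perm].reset_index(drop=True))
        fm_perm = extract_subject_features(ts_perm, tiny_cohort.montage)
        np.testing.assert_allclose(fm_perm.values, fm.values[perm], atol=1e-10)


class TestZscore:
    def _fm(self, values):
        values = np.asarray(values, dtype=float)
        return FeatureMatrix(
            values=values, descriptors=tuple((0, i) for i in range(values.shape[1]))
        )

    def test_columns_standardized(self):
        fm = zscore_within_subject(self._fm(np.random.default_rng(2).normal(2, 3, (10, 4))))
        np.testing.assert_allclose(fm.values.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(fm.values.var(axis=0), 1, atol=1e-9)
        assert fm.zscored

    def test_two_value_column_uses_population_denominator(self):
        fm = zscore_within_subject(self._fm([[1.0], [3.0]]))
        np.testing.assert_allclose(fm.values[:, 0], [-1.0, 1.0])

    def test_idempotent(self):
        once = zscore_within_subject(self._fm(np.random.default_rng(4).normal(size=(8, 3))))
        twice = zscore_within_subject(once)
        np.testing.assert_allclose(once.values, twice.values)

    def test_constant_column_zeroed_and_flagged(self):
        fm = zscore_within_subject(self._fm([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        np.testing.assert_allclose(fm.values[:, 1], 0.0)
        assert fm.constant_columns == (1,)


def test_feature_csv_export_uses_pair_band_names(tiny_cohort, tmp_path):
    import pandas as pd

    fm = extract_subject_features(tiny_cohort.trial_sets[0], tiny_cohort.montage)
    path = tmp_path / "features.csv"
    fm.to_csv(path, subject_id="S01")
    df = pd.read_csv(path)
    assert list(df.columns[:3]) == ["subject_id", "trial_index", "Fp1Fp2_delta"]
    assert "F3F4_alpha" in df.columns
    assert len(df) == fm.n_trials
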