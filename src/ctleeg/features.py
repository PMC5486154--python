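"""Spectral asymmetry features: STFT band power, baseline gain
calibration, differential laterality (DLAT) and within-subject z-scoring.

The chain mirrors a standard affective-EEG feature pipeline: each trial is
short-time Fourier transformed with a 50%-overlapping 1-s Hamming window,
periodogram bins outside 1-50 Hz are discarded (this realizes the
band-pass), bins are grouped into the five stereotyped bands
delta(1-3), theta(4-7), alpha(8-13), beta(14-30) and gamma(31-50 Hz),
each band-power time series is divided by its own mean over the trial's
first 5 s (gain-model baseline calibration, yielding a dimensionless power
ratio), left-minus-right differences over the montage's symmetric pairs
are pooled over post-baseline frames into one scalar per trial per
(pair, band), and finally each feature column is z-scored across the
subject's trials.

Band power is the *mean* (not sum) of the periodogram bins whose center
frequency falls inclusively inside the band's printed range, which keeps
bands of different widths comparable.  With the default 1-s window the
native resolution is 1 Hz, so every printed band edge lands on a bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import TrialSet
from .montage import Montage

#: The five stereotyped EEG bands (name, low Hz, high Hz), edges inclusive.
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 3.0),
    ("theta", 4.0, 7.0),
    ("alpha", 8.0, 13.0),
    ("beta", 14.0, 30.0),
    ("gamma", 31.0, 50.0),
)

PASSBAND: tuple[float, float] = (1.0, 50.0)


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping band definitions within the 1-50 Hz passband."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        prev_high = -np.inf
        prev_low = -np.inf
        for name, low, high in self.bands:
            if low > high:
                raise ValueError(f"band {name!r} has low > high")
            if low <= prev_high or low <= prev_low:
                raise ValueError("bands must be non-overlapping and ordered by low edge")
            if low < PASSBAND[0] or high > PASSBAND[1]:
                raise ValueError(f"band {name!r} exceeds the {PASSBAND} Hz passband")
            prev_high, prev_low = high, low

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]


@dataclass
class BandPowerSeries:
    """Per-frame band power, shape (n_trials, n_channels, n_bands, n_frames)."""

    power: np.ndarray
    frame_starts: np.ndarray  # frame start times, seconds
    window: float  # window length, seconds
    fs: float
    scheme: BandScheme
    calibrated: bool = False

    @property
    def frame_step(self) -> float:
        if len(self.frame_starts) < 2:
            return self.window
        return float(self.frame_starts[1] - self.frame_starts[0])

    @property
    def n_frames(self) -> int:
        return self.power.shape[3]


@dataclass
class FeatureMatrix:
    """Per-trial feature vectors with (pair_index, band_index) descriptors."""

    values: np.ndarray  # (n_trials, n_features)
    descriptors: tuple[tuple[int, int], ...]  # pair-major, band-minor
    montage: Montage = None
    scheme: BandScheme = field(default_factory=BandScheme)
    zscored: bool = False
    constant_columns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials x features)")
        if self.values.shape[1] != len(self.descriptors):
            raise ValueError("one descriptor per feature column required")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        """Names like 'F3F4_alpha' (pair concatenated with the band name)."""
        names = []
        for pair_idx, band_idx in self.descriptors:
            if self.montage is not None:
                left, right = self.montage.symmetric_pairs[pair_idx]
            else:
                left, right = f"L{pair_idx}", f"R{pair_idx}"
            names.append(f"{left}{right}_{self.scheme.names[band_idx]}")
        return names

    def to_frame(self, subject_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "trial_index", np.arange(self.n_trials))
        if subject_id is not None:
            df.insert(0, "subject_id", subject_id)
        return df

    def to_csv(self, path, subject_id: str | None = None) -> None:
        self.to_frame(subject_id).to_csv(path, index=False)


def stft_band_power(
    trials: TrialSet,
    scheme: BandScheme | None = None,
    window: float = 1.0,
    overlap: float = 0.5,
) -> BandPowerSeries:
    """Hamming-windowed STFT band power per trial, channel, band and frame.

    Per frame and channel, band power is the mean of the one-sided
    periodogram bins whose center frequency lies inclusively within the
    band's range; bins outside 1-50 Hz are discarded.  Frame starts are
    0, step, 2*step, ... with step = window * (1 - overlap); a trial
    shorter than one window is an error.
    """
    scheme = scheme or BandScheme()
    fs = trials.fs
    if fs < 2 * PASSBAND[1]:
        raise ValueError(f"fs={fs} puts the {PASSBAND[1]} Hz band edge above Nyquist")
    win = int(round(window * fs))
    step = int(round(win * (1.0 - overlap)))
    if step < 1:
        raise ValueError("overlap too large: zero frame step")
    x = trials.signals
    n_samples = x.shape[2]
    if n_samples < win:
        raise ValueError(f"trial length {n_samples} shorter than one {win}-sample window")
    n_frames = (n_samples - win) // step + 1

    frames = np.lib.stride_tricks.sliding_window_view(x, win, axis=2)[:, :, ::step, :]
    w = np.hamming(win)
    spec = np.fft.rfft(frames * w, axis=3)
    # one-sided periodogram (power spectral density scaling); the absolute
    # scale cancels in gain calibration but is kept conventional here
    psd = (np.abs(spec) ** 2) / (fs * np.sum(w**2))
    psd[..., 1:] *= 2.0
    if win % 2 == 0:
        psd[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)

    keep = (freqs >= PASSBAND[0]) & (freqs <= PASSBAND[1])
    power = np.empty((x.shape[0], x.shape[1], scheme.n_bands, n_frames))
    for b, (name, low, high) in enumerate(scheme.bands):
        mask = keep & (freqs >= low) & (freqs <= high)
        if not mask.any():
            raise ValueError(f"band {name!r} contains no periodogram bin at fs={fs}")
        power[:, :, b, :] = psd[..., mask].mean(axis=3)
    frame_starts = np.arange(n_frames) * (step / fs)
    return BandPowerSeries(
        power=power, frame_starts=frame_starts, window=window, fs=fs, scheme=scheme
    )


def gain_calibrate(bp: BandPowerSeries, baseline: float = 5.0) -> BandPowerSeries:
    """Divide each (trial, channel, band) series by its baseline mean power.

    The baseline frames are those fully inside [0, baseline) seconds.  A
    zero baseline mean is a degenerate input and a hard error.
    """
    base_mask = bp.frame_starts + bp.window <= baseline
    if not base_mask.any():
        raise ValueError(f"no frame fully inside the first {baseline} s")
    base_mean = bp.power[..., base_mask].mean(axis=3, keepdims=True)
    if np.any(base_mean == 0):
        raise ValueError("zero baseline mean power (degenerate input)")
    return replace(bp, power=bp.power / base_mean, calibrated=True)


def dlat_features(
    bp: BandPowerSeries,
    montage: Montage,
    baseline: float = 5.0,
    include_baseline_frames: bool = False,
) -> FeatureMatrix:
    """Differential laterality: pooled left-minus-right calibrated band power.

    feature(trial, pair, band) = temporal mean over pooled frames of
    power(left) - power(right).  By default only frames starting at or
    after the baseline end are pooled (the baseline defines the calibration
    reference, not the response); descriptors are pair-major, band-minor.
    """
    if not bp.calibrated:
        raise ValueError("dlat_features expects a gain-calibrated BandPowerSeries")
    pair_idx = montage.pair_indices()
    if not pair_idx:
        raise ValueError("montage has zero symmetric pairs")
    if include_baseline_frames:
        pool = np.ones(bp.n_frames, dtype=bool)
    else:
        pool = bp.frame_starts >= baseline
        if not pool.any():
            raise ValueError("no post-baseline frame to pool")
    left = np.array([i for i, _ in pair_idx])
    right = np.array([j for _, j in pair_idx])
    diff = bp.power[:, left, :, :] - bp.power[:, right, :, :]  # (trials, pairs, bands, frames)
    pooled = diff[..., pool].mean(axis=3)
    n_pairs, n_bands = pooled.shape[1], pooled.shape[2]
    values = pooled.reshape(pooled.shape[0], n_pairs * n_bands)
    descriptors = tuple((p, b) for p in range(n_pairs) for b in range(n_bands))
    return FeatureMatrix(
        values=values, descriptors=descriptors, montage=montage, scheme=bp.scheme
    )


def zscore_within_subject(fm: FeatureMatrix) -> FeatureMatrix:
    """Standardize each feature column across the subject's trials.

    Population (n) denominator.  Constant columns are set to zero and
    flagged in ``constant_columns`` rather than erroring.  Idempotent.
    """
    if fm.n_trials < 2:
        raise ValueError("z-scoring needs at least 2 trials")
    mean = fm.values.mean(axis=0)
    std = fm.values.std(axis=0)  # population denominator
    constant = std == 0
    safe_std = np.where(constant, 1.0, std)
    values = (fm.values - mean) / safe_std
    values[:, constant] = 0.0
    return FeatureMatrix(
        values=values,
        descriptors=fm.descriptors,
        montage=fm.montage,
        scheme=fm.scheme,
        zscored=True,
        constant_columns=tuple(np.nonzero(constant)[0]),
    )


def extract_subject_features(
    trials: TrialSet,
    montage: Montage,
    scheme: BandScheme | None = None,
    window: float = 1.0,
    overlap: float = 0.5,
    baseline: float = 5.0,
    zscore: bool = True,
) -> FeatureMatrix:
    """Full per-subject chain: STFT -> calibrate -> DLAT -> z-score."""
    bp = stft_band_power(trials, scheme=scheme, window=window, overlap=overlap)
    bp = gain_calibrate(bp, baseline=baseline)
    fm = dlat_features(bp, montage, baseline=baseline)
    if zscore:
        fm = zscore_within_subject(fm)
    return fm
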