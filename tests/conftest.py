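import numpy as np
import pandas as pd
import pytest

from ctleeg import CohortSpec, Montage, TrialSet, generate_cohort


@pytest.fixture(scope="session")
def montage30() -> Montage:
    return Montage.default_30()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small raw cohort for fast end-to-end chains (4 subjects, 8 s trials)."""
    spec = CohortSpec(n_subjects=4, n_trials=8, fs=128, duration=8.0, seed=42)
    return generate_cohort(spec)


def make_feature_cohort(
    n_subjects: int = 5,
    n_trials: int = 16,
    n_features: int = 12,
    strength: float = 1.5,
    noise_subjects: tuple[int, ...] = (),
    seed: int = 0,
):
    """Feature-level cohort (skips raw EEG) with one planted informative axis.

    Subjects listed in ``noise_subjects`` get label-independent features.
    Returns (features, labels) dicts keyed by subject id.
    """
    rng = np.random.default_rng(seed)
    features, labels = {}, {}
    direction = np.zeros(n_features)
    direction[:3] = [1.0, -0.8, 0.6]
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        y = np.tile([0, 1], n_trials // 2)
        rng.shuffle(y)
        X = rng.normal(size=(n_trials, n_features))
        if s not in noise_subjects:
            X += strength * np.outer(np.where(y == 1, 1.0, -1.0), direction)
        features[sid] = X
        labels[sid] = y
    return features, labels


@pytest.fixture()
def feature_cohort():
    return make_feature_cohort()


def make_trialset(signals: np.ndarray, fs: float, labels=None) -> TrialSet:
    n = signals.shape[0]
    if labels is None:
        labels = pd.DataFrame(
            {"valence": np.tile([0, 1], (n + 1) // 2)[:n],
             "arousal": np.tile([1, 0], (n + 1) // 2)[:n]}
        )
    return TrialSet(subject_id="T01", signals=signals, fs=fs, labels=labels)
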