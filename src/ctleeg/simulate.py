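"""Synthetic multi-subject EEG cohort generator.

Generates raw cohorts with the shape of a music-listening emotion study
(by default 26 subjects x 16 trials x 30 channels x 30 s at 250 Hz,
binary balanced valence/arousal labels) and two controllable generative
knobs mirroring the hypotheses the transfer pipeline is built to test:

* **engagement** — per-subject signal-to-noise of the class-discriminative
  signal; 0 means the subject's data carry no class information at all
  (a planted "poor", non-engaged subject).
* **signature_similarity** (rho) — how much of a subject's discriminative
  asymmetry pattern is the cohort-common signature (rho = 1) versus
  idiosyncratic (rho = 0).

The class signal is built directly in the band-power domain: each channel
is 1/f pink noise plus per-band band-limited Gaussian noise whose
left/right amplitudes on the active symmetric pairs are modulated by
``+/- engagement * effect_size * pattern`` according to the trial's class
label.  The first 5 s of every trial (the calibration baseline) carry no
modulation.  Valence and arousal use disjoint active (pair, band) slots
and independently balanced labels, so both tasks are exercised by one
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import DEFAULT_BANDS
from .io import TASKS, Cohort, TrialSet
from .montage import Montage

#: Default class-discriminative slots: frontal alpha asymmetry for valence,
#: centro-parietal beta asymmetry for arousal (disjoint between tasks).
DEFAULT_ACTIVE: dict[str, tuple[tuple[tuple[str, str], str], ...]] = {
    "valence": (
        (("Fp1", "Fp2"), "alpha"),
        (("F7", "F8"), "alpha"),
        (("F3", "F4"), "alpha"),
        (("FC3", "FC4"), "alpha"),
    ),
    "arousal": (
        (("C3", "C4"), "beta"),
        (("CP3", "CP4"), "beta"),
        (("P3", "P4"), "beta"),
        (("T5", "T6"), "beta"),
    ),
}

_MAX_MODULATION = 0.95


def _per_subject(value, n: int, name: str, low: float, high: float) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
    if np.any(arr < low) or np.any(arr > high):
        raise ValueError(f"{name} must lie in [{low}, {high}]")
    return arr


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort.

    engagement and signature_similarity accept a scalar (applied to every
    subject) or one value per subject.
    """

    n_subjects: int = 26
    n_trials: int = 16
    fs: float = 250.0
    duration: float = 30.0
    montage: Montage = field(default_factory=Montage.default_30)
    engagement: float | np.ndarray = 1.0
    signature_similarity: float | np.ndarray = 0.7
    active_pairs_bands: dict = field(default_factory=lambda: dict(DEFAULT_ACTIVE))
    effect_size: float = 0.5
    amplitude_noise_sigma: float = 0.2
    baseline: float = 5.0
    amplitude_uv: float = 10.0
    pink_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_trials % 4:
            raise ValueError("n_trials must be a multiple of 4 so both tasks balance")
        if self.duration <= self.baseline:
            raise ValueError("duration must exceed the baseline")
        if self.fs < 100:
            raise ValueError("fs must be >= 100 Hz (gamma band below Nyquist)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.amplitude_noise_sigma < 0:
            raise ValueError("amplitude_noise_sigma must be >= 0")
        self.engagement = _per_subject(self.engagement, self.n_subjects, "engagement", 0, np.inf)
        self.signature_similarity = _per_subject(
            self.signature_similarity, self.n_subjects, "signature_similarity", 0, 1
        )
        band_names = {b[0] for b in DEFAULT_BANDS}
        pair_set = set(self.montage.symmetric_pairs)
        for task, slots in self.active_pairs_bands.items():
            if task not in TASKS:
                raise ValueError(f"unknown task {task!r}")
            for pair, band in slots:
                if tuple(pair) not in pair_set:
                    raise ValueError(f"active pair {pair} not a montage symmetric pair")
                if band not in band_names:
                    raise ValueError(f"unknown band {band!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def _band_range(name: str) -> tuple[float, float]:
    for bname, low, high in DEFAULT_BANDS:
        if bname == name:
            return low, high
    raise KeyError(name)


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def subject_patterns(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Per-task planted asymmetry patterns, shape (n_subjects, n_slots).

    pattern_s = unit(rho_s * common + (1 - rho_s) * idiosyncratic_s); the
    same deterministic derivation backs both generation and
    :func:`planted_truth`.
    """
    out: dict[str, np.ndarray] = {}
    for t_idx, task in enumerate(TASKS):
        slots = spec.active_pairs_bands.get(task, ())
        n_slots = len(slots)
        if n_slots == 0:
            out[task] = np.zeros((spec.n_subjects, 0))
            continue
        common = _unit(
            np.random.default_rng(np.random.SeedSequence([spec.seed, 0, t_idx]))
            .standard_normal(n_slots)
        )
        pats = np.empty((spec.n_subjects, n_slots))
        for s in range(spec.n_subjects):
            idio = _unit(
                np.random.default_rng(np.random.SeedSequence([spec.seed, 1 + s, t_idx]))
                .standard_normal(n_slots)
            )
            rho = spec.signature_similarity[s]
            pats[s] = _unit(rho * common + (1 - rho) * idio)
        out[task] = pats
    return out


def _balanced_labels(n_trials: int, rng: np.random.Generator) -> pd.DataFrame:
    combos = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])
    rep = np.repeat(combos, n_trials // 4, axis=0)
    rng.shuffle(rep, axis=0)
    return pd.DataFrame({"valence": rep[:, 0], "arousal": rep[:, 1]})


def _pink_noise(rng: np.random.Generator, shape: tuple, n: int, fs: float, exponent: float):
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    coef = rng.standard_normal((*shape, len(freqs))) + 1j * rng.standard_normal(
        (*shape, len(freqs))
    )
    x = np.fft.irfft(coef * amp, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _band_noise(rng: np.random.Generator, shape: tuple, n: int, fs: float, low: float, high: float):
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= low) & (freqs <= high)
    nb = int(mask.sum())
    coef = np.zeros((*shape, len(freqs)), dtype=complex)
    coef[..., mask] = rng.standard_normal((*shape, nb)) + 1j * rng.standard_normal((*shape, nb))
    x = np.fft.irfft(coef, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def generate_subject(spec: CohortSpec, subject_index: int,
                     patterns: dict[str, np.ndarray] | None = None) -> TrialSet:
    """Generate one subject's trial set (deterministic in spec.seed)."""
    if patterns is None:
        patterns = subject_patterns(spec)
    s = subject_index
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1 + s, 1000]))
    n, n_ch, n_tr = spec.n_samples, spec.montage.n_channels, spec.n_trials
    labels = _balanced_labels(n_tr, rng)

    # per-(trial, channel, band) modulation depth from the active slots
    band_names = [b[0] for b in DEFAULT_BANDS]
    g = np.zeros((n_tr, n_ch, len(band_names)))
    for task in TASKS:
        slots = spec.active_pairs_bands.get(task, ())
        if not len(slots):
            continue
        sign = np.where(labels[task].to_numpy() == 1, 1.0, -1.0)
        for slot_idx, (pair, band) in enumerate(slots):
            li = spec.montage.channel_index(pair[0])
            ri = spec.montage.channel_index(pair[1])
            b = band_names.index(band)
            depth = spec.engagement[s] * spec.effect_size * patterns[task][s, slot_idx]
            g[:, li, b] += sign * depth
            g[:, ri, b] -= sign * depth
    # trial-to-trial band-amplitude variability: the noise floor that makes
    # engagement act as a signal-to-noise ratio rather than a switch
    g += spec.amplitude_noise_sigma * rng.standard_normal(g.shape)
    g = np.clip(g, -_MAX_MODULATION, _MAX_MODULATION)

    time = np.arange(n) / spec.fs
    post = (time >= spec.baseline).astype(float)
    signals = _pink_noise(rng, (n_tr, n_ch), n, spec.fs, spec.pink_exponent)
    for b, name in enumerate(band_names):
        low, high = _band_range(name)
        nb = _band_noise(rng, (n_tr, n_ch), n, spec.fs, low, high)
        envelope = 1.0 + g[:, :, b, None] * post
        signals += nb * envelope
    signals *= spec.amplitude_uv
    return TrialSet(
        subject_id=f"S{subject_index + 1:02d}",
        signals=signals,
        fs=spec.fs,
        labels=labels,
        trial_duration=spec.duration,
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort; same seed gives a bit-identical cohort."""
    patterns = subject_patterns(spec)
    trial_sets = [generate_subject(spec, s, patterns) for s in range(spec.n_subjects)]
    return Cohort(trial_sets=trial_sets, montage=spec.montage)


def planted_truth(spec: CohortSpec) -> dict:
    """Ground truth the generator planted, for parameter-recovery checks.

    Returns per-subject expected transferability ('poor' for
    zero-engagement subjects, else 'good') and, per task, two matrices
    among subjects (DataFrames indexed by subject id):

    * ``pattern_correlation`` — correlation of the signed planted
      patterns (what the class-conditional DLAT expectations realize);
    * ``signature_overlap`` — correlation of the pattern *magnitudes*.
      ReliefF weights a feature by how informative it is, not by which
      hemisphere dominates, so weight-space similarity can recover the
      magnitude ordering but is blind to pattern sign.
    """
    patterns = subject_patterns(spec)
    ids = [f"S{s + 1:02d}" for s in range(spec.n_subjects)]
    transferability = {
        sid: ("poor" if spec.engagement[s] == 0 else "good") for s, sid in enumerate(ids)
    }

    def corr_matrix(pats: np.ndarray) -> pd.DataFrame:
        if pats.shape[1] == 0:
            return pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
        c = np.eye(len(ids))
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                denom = pats[i].std() * pats[j].std()
                cij = 0.0 if denom == 0 else float(np.corrcoef(pats[i], pats[j])[0, 1])
                c[i, j] = c[j, i] = cij
        return pd.DataFrame(c, index=ids, columns=ids)

    corr = {task: corr_matrix(patterns[task]) for task in TASKS}
    overlap = {task: corr_matrix(np.abs(patterns[task])) for task in TASKS}
    return {"transferability": transferability, "pattern_correlation": corr,
            "signature_overlap": overlap, "patterns": patterns}


def structured_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """An 8-subject cohort realizing the two transfer hypotheses at once.

    Subjects 1-3 form an engaged cluster sharing the cohort signature
    (engagement 1.2, rho 1); subjects 4-5 are equally engaged but fully
    idiosyncratic (rho 0); subjects 6-7 are weakly engaged (0.35) with the
    cluster signature; subject 8 is non-engaged (engagement 0, pure
    noise).  The non-engaged and weak subjects tend to gate as 'poor';
    transfer from sources similar to them (the cluster) helps them, while
    routine transfer tends to hurt the engaged subjects, most strongly the
    idiosyncratic ones.
    """
    fields = dict(
        n_subjects=8,
        engagement=np.array([1.2, 1.2, 1.2, 1.2, 1.2, 0.35, 0.35, 0.0]),
        signature_similarity=np.array([1.0, 1.0, 1.0, 0.0, 0.0, 1.0, 1.0, 1.0]),
        seed=seed,
    )
    fields.update(overrides)
    return CohortSpec(**fields)


def permute_cohort_labels(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    """Randomly permute each subject's trial labels (breaks any class signal)."""
    new_sets = []
    for ts in cohort.trial_sets:
        perm = rng.permutation(ts.n_trials)
        labels = ts.labels.iloc[perm].reset_index(drop=True)
        new_sets.append(
            TrialSet(
                subject_id=ts.subject_id,
                signals=ts.signals,
                fs=ts.fs,
                labels=labels,
                trial_duration=ts.trial_duration,
            )
        )
    return Cohort(trial_sets=new_sets, montage=cohort.montage)
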