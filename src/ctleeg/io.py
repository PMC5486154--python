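"""Cohort data model and on-disk interchange.

A :class:`TrialSet` holds one subject's labeled raw EEG trials as a
``trials x channels x samples`` array in microvolts; a :class:`Cohort` is
the multi-subject collection sharing one montage and sampling rate.

On disk a cohort is one raw-EEG file per subject (EDF, read through MNE,
or an NPZ array container as the portable escape hatch), a label CSV with
columns ``subject_id,trial_index,valence_label,arousal_label``, and a YAML
montage file.  EDF stores samples as 16-bit integers, so an EDF round trip
preserves signals only up to quantization; the NPZ container is lossless.
EDF *writing* additionally needs MNE's optional ``edfio`` export backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage, canonical_name

TASKS: tuple[str, str] = ("valence", "arousal")
_LABEL_COLUMNS = ["subject_id", "trial_index", "valence_label", "arousal_label"]


@dataclass
class TrialSet:
    """One subject's labeled raw EEG trials.

    signals : array, shape (n_trials, n_channels, n_samples), microvolts
    labels : DataFrame with one binary column per task ('valence', 'arousal')
    """

    subject_id: str
    signals: np.ndarray
    fs: float
    labels: pd.DataFrame
    trial_duration: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 3:
            raise ValueError("signals must be (n_trials, n_channels, n_samples)")
        if self.trial_duration is None:
            self.trial_duration = self.signals.shape[2] / self.fs
        if self.signals.shape[2] != round(self.fs * self.trial_duration):
            raise ValueError("n_samples must equal fs * trial_duration")
        self.labels = pd.DataFrame(self.labels).reset_index(drop=True)
        if len(self.labels) != self.signals.shape[0]:
            raise ValueError("one label row per trial required")
        for task in TASKS:
            if task not in self.labels.columns:
                raise ValueError(f"missing label column for task {task!r}")
            vals = np.asarray(self.labels[task])
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"non-binary label in task {task!r}")
        self.labels = self.labels[list(TASKS)].astype(int)

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    def task_labels(self, task: str) -> np.ndarray:
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}")
        return self.labels[task].to_numpy()


@dataclass
class Cohort:
    """Multi-subject collection of trial sets sharing montage and fs."""

    trial_sets: list[TrialSet]
    montage: Montage

    def __post_init__(self) -> None:
        ids = [ts.subject_id for ts in self.trial_sets]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")
        fss = {ts.fs for ts in self.trial_sets}
        if len(fss) > 1:
            raise ValueError("all subjects must share one sampling rate")
        for ts in self.trial_sets:
            if ts.n_channels != self.montage.n_channels:
                raise ValueError(
                    f"subject {ts.subject_id!r}: {ts.n_channels} channels, "
                    f"montage has {self.montage.n_channels}"
                )

    @property
    def subject_ids(self) -> list[str]:
        return [ts.subject_id for ts in self.trial_sets]

    @property
    def n_subjects(self) -> int:
        return len(self.trial_sets)

    @property
    def fs(self) -> float:
        return self.trial_sets[0].fs

    def subject(self, subject_id: str) -> TrialSet:
        for ts in self.trial_sets:
            if ts.subject_id == subject_id:
                return ts
        raise KeyError(subject_id)


def _labels_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for ts in cohort.trial_sets:
        for i in range(ts.n_trials):
            rows.append(
                {
                    "subject_id": ts.subject_id,
                    "trial_index": i,
                    "valence_label": int(ts.labels["valence"].iloc[i]),
                    "arousal_label": int(ts.labels["arousal"].iloc[i]),
                }
            )
    return pd.DataFrame(rows, columns=_LABEL_COLUMNS)


def write_cohort(cohort: Cohort, out_dir, format: str = "npz") -> dict[str, list[Path]]:
    """Write a cohort to ``out_dir`` as per-subject raw files + labels + montage.

    format='npz' writes the lossless array container; format='edf' exports
    through MNE and requires its optional edfio backend.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eeg_paths: list[Path] = []
    for ts in cohort.trial_sets:
        if format == "npz":
            path = out / f"{ts.subject_id}.npz"
            np.savez(
                path,
                signals=ts.signals,
                fs=np.asarray(ts.fs),
                subject_id=np.asarray(ts.subject_id),
            )
        elif format == "edf":
            path = out / f"{ts.subject_id}.edf"
            _write_edf(ts, cohort.montage, path)
        else:
            raise ValueError(f"unknown format {format!r}")
        eeg_paths.append(path)
    label_path = out / "labels.csv"
    _labels_frame(cohort).to_csv(label_path, index=False)
    montage_path = out / "montage.yaml"
    cohort.montage.to_yaml(montage_path)
    return {"eeg": eeg_paths, "labels": [label_path], "montage": [montage_path]}


def _write_edf(ts: TrialSet, montage: Montage, path: Path) -> None:
    import mne

    info = mne.create_info(list(montage.channel_names), sfreq=ts.fs, ch_types="eeg")
    data = ts.signals.transpose(1, 0, 2).reshape(ts.n_channels, -1) * 1e-6  # uV -> V
    raw = mne.io.RawArray(data, info, verbose="error")
    try:
        mne.export.export_raw(str(path), raw, fmt="edf", overwrite=True, verbose="error")
    except (ImportError, RuntimeError, ValueError) as exc:  # pragma: no cover - backend-dependent
        raise RuntimeError(
            "EDF export requires MNE's optional 'edfio' backend; "
            "use format='npz' instead"
        ) from exc


def _read_edf(path: Path, montage: Montage) -> tuple[np.ndarray, float, str]:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = [canonical_name(n) for n in raw.ch_names]
    want = [canonical_name(n) for n in montage.channel_names]
    if sorted(names) != sorted(want):
        if len(names) != len(want):
            raise ValueError(
                f"{path.name}: {len(names)} channels, montage has {len(want)}"
            )
        raise ValueError(f"{path.name}: channel names do not match montage")
    order = [names.index(w) for w in want]
    data = raw.get_data()[order] * 1e6  # V -> uV
    return data, float(raw.info["sfreq"]), path.stem


def _read_npz(path: Path) -> tuple[np.ndarray, float, str]:
    with np.load(path) as npz:
        signals = np.asarray(npz["signals"], dtype=float)
        fs = float(npz["fs"])
        subject_id = str(npz["subject_id"])
    return signals, fs, subject_id


def read_cohort(eeg_paths, label_table_path, montage_path) -> Cohort:
    """Read raw EEG files + label table + montage into a :class:`Cohort`.

    Trial order follows the label table's ``trial_index`` ordering per
    subject.  A subject file without label rows, a non-binary label, or a
    channel-count mismatch with the montage is a hard error.
    """
    montage = Montage.from_yaml(montage_path)
    table = pd.read_csv(label_table_path)
    missing_cols = set(_LABEL_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"label table missing columns: {sorted(missing_cols)}")
    for col in ("valence_label", "arousal_label"):
        if not np.isin(table[col].to_numpy(), (0, 1)).all():
            raise ValueError(f"non-binary label in column {col!r}")

    trial_sets: list[TrialSet] = []
    for path in map(Path, eeg_paths):
        if path.suffix.lower() == ".edf":
            flat_or_trials, fs, subject_id = _read_edf(path, montage)
        elif path.suffix.lower() == ".npz":
            flat_or_trials, fs, subject_id = _read_npz(path)
        else:
            raise ValueError(f"unsupported raw-EEG container: {path.suffix!r}")
        rows = table[table["subject_id"].astype(str) == subject_id]
        if rows.empty:
            raise ValueError(f"subject {subject_id!r} missing from label table")
        rows = rows.sort_values("trial_index")
        n_trials = len(rows)
        if flat_or_trials.ndim == 2:  # continuous (channels, samples): split into trials
            n_ch, total = flat_or_trials.shape
            if total % n_trials:
                raise ValueError(
                    f"subject {subject_id!r}: {total} samples not divisible by {n_trials} trials"
                )
            signals = flat_or_trials.reshape(n_ch, n_trials, total // n_trials).transpose(1, 0, 2)
        else:
            signals = flat_or_trials
            if signals.shape[0] != n_trials:
                raise ValueError(
                    f"subject {subject_id!r}: {signals.shape[0]} trials in file, "
                    f"{n_trials} in label table"
                )
        if signals.shape[1] != montage.n_channels:
            raise ValueError(
                f"subject {subject_id!r}: {signals.shape[1]} channels, "
                f"montage has {montage.n_channels}"
            )
        labels = pd.DataFrame(
            {
                "valence": rows["valence_label"].to_numpy(int),
                "arousal": rows["arousal_label"].to_numpy(int),
            }
        )
        trial_sets.append(TrialSet(subject_id=subject_id, signals=signals, fs=fs, labels=labels))
    return Cohort(trial_sets=trial_sets, montage=montage)
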