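"""Conditional transfer-learning pipeline over leave-trial-out validation.

The pipeline answers the three questions any subject-to-subject transfer
scheme must settle:

* **when to transfer** — a target subject (TS) is *poor* (transferable)
  when its default leave-trial-out (LTO) accuracy, trained solely on its
  own trials, is at or below chance (50% for two balanced classes), and
  *good* otherwise;
* **how to transfer** — source subjects (SS) are ranked by the Pearson
  correlation between ReliefF weight vectors (their emotion-relevant
  feature spaces) and the O most similar (or, for control, most
  dissimilar) are selected;
* **what to transfer** — the selected sources' labeled trials are
  concatenated with the TS's training trials (15 + O x 16 rows), the
  feature space is re-ranked and re-sized on the augmented set, and the
  classifier is re-trained.

Four scenarios are composed from these pieces: ``default`` (never
transfer), ``rTL`` (routine: always transfer), ``cTL`` (conditional:
transfer only to poor subjects) and ``oTL`` (oracle: per-subject best of
default and transferred — an upper bound, not a prospective method).

Within each LTO fold the held-out trial is disjoint from ReliefF, from
the similarity-based source selection, from feature-count optimization
and from classifier training; an optional audit records row hashes so
tests can assert this.

Everything random flows from one master seed through per-(subject, fold,
stage, repetition) ``numpy.random.SeedSequence`` derivations, so a run is
bit-reproducible and any sub-computation can be replayed in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix, extract_subject_features
from .gnb import gnb_fit, gnb_predict
from .relieff import relieff_weights
from .similarity import select_sources, similarity_profile, ts_ss_dissimilarity

logger = logging.getLogger(__name__)

SCENARIOS = ("default", "rTL", "cTL", "oTL")

# stage codes for the seed derivation (master, subject, fold, stage[, rep])
_STAGE_DEFAULT_OPT = 0
_STAGE_DEFAULT_FIT = 1
_STAGE_TL_OPT = 2
_STAGE_TL_FIT = 3


@dataclass
class PipelineConfig:
    """Tunable parameters of the transfer pipeline.

    O is the number of source subjects borrowed by the TL scenarios
    (1 <= O <= n_subjects - 1); chance_level is 1/n_classes = 0.5 for the
    binary tasks.  gate_source='outer_default' classifies transferability
    from the subject's own full-LTO default accuracy; 'nested' estimates
    the gate per fold from the 15 training trials only (strictly
    prospective, at a 15x cost).
    """

    task: str = "valence"
    O: int | None = None
    source_mode: str = "similar"
    n_balance_reps: int = 500
    n_cv_folds: int = 5
    chance_level: float = 0.5
    gate_source: str = "outer_default"
    similarity_method: str = "pearson"
    relieff_k: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("valence", "arousal"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.source_mode not in ("similar", "dissimilar"):
            raise ValueError(f"unknown source_mode {self.source_mode!r}")
        if self.gate_source not in ("outer_default", "nested"):
            raise ValueError(f"unknown gate_source {self.gate_source!r}")
        if not 0 < self.chance_level < 1:
            raise ValueError("chance_level must be in (0, 1)")
        if self.n_balance_reps < 1 or self.n_cv_folds < 2:
            raise ValueError("n_balance_reps >= 1 and n_cv_folds >= 2 required")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def classify_transferability(default_acc: float, chance: float = 0.5) -> str:
    """'poor' iff the default accuracy is at or below chance, else 'good'."""
    if not 0 <= default_acc <= 1:
        raise ValueError("accuracy must lie in [0, 1]")
    return "poor" if default_acc <= chance else "good"


def _rng(master: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master), *map(int, path)]))


def _balanced_subsample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices after subsampling the majority class to the minority size.

    Already-balanced input returns every index (identity); the result is
    sorted so row order stays stable.
    """
    classes, counts = np.unique(y, return_counts=True)
    m = counts.min()
    keep = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == cls)
        if cnt > m:
            idx = rng.choice(idx, size=m, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def _stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold (round-robin deal of shuffled class indices)."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    out = []
    all_idx = np.arange(len(y))
    for f in folds:
        te = np.sort(np.asarray(f, dtype=int))
        if te.size == 0:
            continue
        tr = np.setdiff1d(all_idx, te)
        out.append((tr, te))
    return out


def _loo_folds(n: int) -> list[tuple[np.ndarray, np.ndarray]]:
    all_idx = np.arange(n)
    return [(np.delete(all_idx, i), np.array([i])) for i in range(n)]


def _prefix_gnb_cv_accuracy(
    Xr: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Mean CV accuracy for every ranked-feature prefix d = 1..n_features.

    Exploits the additivity of the naive-Bayes log joint over features: a
    cumulative sum of per-feature log densities along the ranking yields
    the add-one-feature-in accuracies of all prefixes in one pass.  The
    result is numerically identical to fitting a separate model per d.
    Folds whose training rows contain a single class are skipped.
    """
    n, n_feat = Xr.shape
    Xr2 = Xr**2
    y1 = y == np.unique(y)[1]
    w0_rows, w1_rows, wt_rows, lp0, lp1, test_b, test_i = [], [], [], [], [], [], []
    for tr, te in folds:
        tr_lab = y1[tr]
        i0, i1 = tr[~tr_lab], tr[tr_lab]
        if len(i0) == 0 or len(i1) == 0:
            continue
        b = len(w0_rows)
        w0 = np.zeros(n)
        w0[i0] = 1.0 / len(i0)
        w1 = np.zeros(n)
        w1[i1] = 1.0 / len(i1)
        wt = np.zeros(n)
        wt[tr] = 1.0 / len(tr)
        w0_rows.append(w0)
        w1_rows.append(w1)
        wt_rows.append(wt)
        lp0.append(np.log(len(i0) / len(tr)))
        lp1.append(np.log(len(i1) / len(tr)))
        test_b.extend([b] * len(te))
        test_i.extend(te.tolist())
    if not w0_rows:
        raise ValueError("no usable CV fold (single-class training data)")
    W0, W1, Wt = np.array(w0_rows), np.array(w1_rows), np.array(wt_rows)
    mu0, mu1 = W0 @ Xr, W1 @ Xr
    v0 = np.maximum(W0 @ Xr2 - mu0**2, 0.0)
    v1 = np.maximum(W1 @ Xr2 - mu1**2, 0.0)
    mut = Wt @ Xr
    vart = np.maximum(Wt @ Xr2 - mut**2, 0.0)
    floor = np.maximum(1e-9 * vart.max(axis=1), 1e-24)
    v0 = np.maximum(v0, floor[:, None])
    v1 = np.maximum(v1, floor[:, None])
    lp0, lp1 = np.array(lp0), np.array(lp1)

    tb = np.asarray(test_b)
    ti = np.asarray(test_i)
    x = Xr[ti]
    ll0 = -0.5 * (np.log(2 * np.pi * v0[tb]) + (x - mu0[tb]) ** 2 / v0[tb])
    ll1 = -0.5 * (np.log(2 * np.pi * v1[tb]) + (x - mu1[tb]) ** 2 / v1[tb])
    cum0 = lp0[tb, None] + np.cumsum(ll0, axis=1)
    cum1 = lp1[tb, None] + np.cumsum(ll1, axis=1)
    pred1 = cum1 > cum0  # tie -> class 0
    correct = pred1 == y1[ti][:, None]
    return correct.mean(axis=0)


@dataclass
class FeatureCountResult:
    d: int
    ranking: np.ndarray
    cv_accuracy_per_d: np.ndarray
    used_loo: bool = False


def optimize_feature_count(
    X: np.ndarray,
    y: np.ndarray,
    cfg: PipelineConfig,
    ranking: np.ndarray | None = None,
    seed_path: tuple[int, ...] = (),
) -> FeatureCountResult:
    """Select the feature count maximising repeated class-balanced CV accuracy.

    The ReliefF ranking is computed on the full training set (unless
    supplied).  Each of ``cfg.n_balance_reps`` repetitions subsamples the
    majority class to the minority size, runs seeded stratified
    ``cfg.n_cv_folds``-fold CV and evaluates a GNB on every ranked prefix
    (add-one-feature-in); the selected d is the argmax of mean accuracy
    pooled over repetitions x folds, ties resolving to the smallest d.
    A minority class smaller than the fold count switches the repetitions
    to leave-one-out CV (logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if ranking is None:
        ranking = relieff_weights(X, y, k=cfg.relieff_k).ranking
    Xr = X[:, ranking]
    used_loo = False
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    for rep in range(cfg.n_balance_reps):
        rng = _rng(cfg.seed, *seed_path, rep)
        sub = _balanced_subsample(y, rng)
        ysub = y[sub]
        m = np.bincount(ysub).min() if ysub.size else 0
        if m < cfg.n_cv_folds:
            if not used_loo:
                logger.info("minority class %d < %d folds: using leave-one-out CV",
                            m, cfg.n_cv_folds)
            used_loo = True
            local = _loo_folds(len(sub))
        else:
            local = _stratified_folds(ysub, cfg.n_cv_folds, rng)
        folds.extend((sub[tr], sub[te]) for tr, te in local)
    acc = _prefix_gnb_cv_accuracy(Xr, y, folds)
    d = int(np.argmax(acc)) + 1  # argmax takes the first maximum: smallest d on ties
    return FeatureCountResult(d=d, ranking=ranking, cv_accuracy_per_d=acc, used_loo=used_loo)


def augment_training_set(
    ts_values,
    ts_labels: np.ndarray,
    sources: list[tuple[str, object, np.ndarray]],
    ts_id: str = "TS",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate the TS training trials with all trials of each source.

    ``sources`` is a list of (subject_id, values-or-FeatureMatrix, labels);
    source rows keep their own task labels.  Sources are concatenated in
    ascending subject-id order so the augmented set depends only on the
    selected *set*.  Returns (X, y, origin) with per-row subject of
    origin; a feature-descriptor mismatch is a hard error.
    """

    def unpack(v):
        if isinstance(v, FeatureMatrix):
            return v.values, v.descriptors
        return np.asarray(v, dtype=float), None

    ts_X, ts_desc = unpack(ts_values)
    blocks, labels, origin = [ts_X], [np.asarray(ts_labels)], [[ts_id] * len(ts_X)]
    for sid, v, lab in sorted(sources, key=lambda s: str(s[0])):
        X, desc = unpack(v)
        if X.shape[1] != ts_X.shape[1]:
            raise ValueError(f"source {sid!r}: feature count mismatch")
        if desc is not None and ts_desc is not None and tuple(desc) != tuple(ts_desc):
            raise ValueError(f"source {sid!r}: feature descriptor mismatch")
        blocks.append(X)
        labels.append(np.asarray(lab))
        origin.append([str(sid)] * len(X))
    return (
        np.concatenate(blocks, axis=0),
        np.concatenate(labels, axis=0).astype(int),
        np.concatenate([np.asarray(o, dtype=object) for o in origin]),
    )


def _row_hash(row: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(row, dtype=float).tobytes()).hexdigest()


def _fit_and_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    selected: np.ndarray,
    rng: np.random.Generator,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Final model: one seeded balanced subsample, GNB on the selected features."""
    sub = _balanced_subsample(y_train, rng)
    model = gnb_fit(X_train[np.ix_(sub, selected)], y_train[sub])
    post, labels = gnb_predict(model, x_test[None, selected])
    return int(labels[0]), post[0], sub


def lto_default_accuracy(
    X,
    y: np.ndarray,
    cfg: PipelineConfig,
    subject_index: int = 0,
    audit: bool = False,
) -> tuple[float, list[dict]]:
    """Default (no-transfer) leave-trial-out accuracy of one subject.

    One fold per trial; per fold, ReliefF and the feature-count
    optimization see only the remaining trials, then a GNB trained on a
    seeded balanced subsample of them classifies the held-out trial.
    Folds whose training labels are single-class are skipped with a
    warning and excluded from the accuracy denominator.
    """
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < 4 or min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("LTO needs >= 4 trials with >= 2 per class")
    records: list[dict] = []
    correct = []
    for t in range(n):
        train = np.delete(np.arange(n), t)
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            warnings.warn(f"fold {t}: single-class training labels, fold skipped")
            continue
        rw = relieff_weights(X[train], y_tr, k=cfg.relieff_k)
        opt = optimize_feature_count(
            X[train], y_tr, cfg, ranking=rw.ranking,
            seed_path=(subject_index, t, _STAGE_DEFAULT_OPT),
        )
        pred, post, sub = _fit_and_predict(
            X[train], y_tr, X[t], opt.ranking[: opt.d],
            _rng(cfg.seed, subject_index, t, _STAGE_DEFAULT_FIT),
        )
        rec = {
            "fold": t,
            "train_trials": train,
            "d": opt.d,
            "pred": pred,
            "truth": int(y[t]),
            "correct": pred == y[t],
            "posterior": post,
            "relieff_weights": rw.weights,
        }
        if audit:
            rec["test_hash"] = _row_hash(X[t])
            rec["train_hashes"] = frozenset(_row_hash(X[i]) for i in train)
        records.append(rec)
        correct.append(pred == y[t])
    if not correct:
        raise ValueError("no usable LTO fold")
    return float(np.mean(correct)), records


def _tl_fold(
    sid: str,
    subject_index: int,
    fold_rec: dict,
    X: np.ndarray,
    y: np.ndarray,
    ss_weights: dict[str, np.ndarray],
    features: dict[str, np.ndarray],
    labels: dict[str, np.ndarray],
    cfg: PipelineConfig,
    audit: bool,
) -> dict:
    """One transfer-augmented LTO fold for subject ``sid``."""
    t = fold_rec["fold"]
    train = fold_rec["train_trials"]
    profile = similarity_profile(
        sid, fold_rec["relieff_weights"], ss_weights, method=cfg.similarity_method
    )
    selected_ids = select_sources(profile, cfg.O, mode=cfg.source_mode)
    X_aug, y_aug, origin = augment_training_set(
        X[train], y[train],
        [(s, features[s], labels[s]) for s in selected_ids],
        ts_id=sid,
    )
    opt = optimize_feature_count(
        X_aug, y_aug, cfg, seed_path=(subject_index, t, _STAGE_TL_OPT)
    )
    pred, post, sub = _fit_and_predict(
        X_aug, y_aug, X[t], opt.ranking[: opt.d],
        _rng(cfg.seed, subject_index, t, _STAGE_TL_FIT),
    )
    rec = {
        "fold": t,
        "sources": selected_ids,
        "d": opt.d,
        "pred": pred,
        "truth": int(y[t]),
        "correct": pred == y[t],
        "posterior": post,
        "dissimilarity": (
            ts_ss_dissimilarity(profile, selected_ids) if len(selected_ids) >= 2 else np.nan
        ),
        "n_augmented": len(y_aug),
    }
    if audit:
        rec["test_hash"] = _row_hash(X[t])
        rec["train_hashes"] = frozenset(_row_hash(r) for r in X_aug)
    return rec


def _nested_gate_accuracy(
    X: np.ndarray, y: np.ndarray, train: np.ndarray, cfg: PipelineConfig, subject_index: int
) -> float:
    """Gate estimate from the training trials only (inner LTO on 15 trials)."""
    inner_cfg = replace(cfg)
    acc, _ = lto_default_accuracy(
        X[train], y[train], inner_cfg, subject_index=subject_index + 10_000
    )
    return acc


@dataclass
class TransferResults:
    """Per-subject and cohort-level outcome of one scenario run.

    subject_table columns: default_acc, tl_acc, scenario_acc,
    transferable, O_used, ts_ss_dissimilarity, n_folds.  ``tl_acc`` is NaN
    where the scenario never built a transferred model (default scenario,
    or good subjects under cTL).
    """

    scenario: str
    config: PipelineConfig
    subject_table: pd.DataFrame
    fold_records: dict[str, dict] = field(repr=False, default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subject_table.index)

    @property
    def accuracies(self) -> pd.Series:
        return self.subject_table["scenario_acc"]

    @property
    def improvements(self) -> pd.Series:
        return self.subject_table["scenario_acc"] - self.subject_table["default_acc"]

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1))

    @property
    def mean_improvement(self) -> float:
        return float(self.improvements.mean())

    def compare(self, other: "TransferResults") -> dict:
        """Paired two-sample t-test against another scenario's accuracies."""
        return _paired_ttest(self.accuracies, other.accuracies, self.scenario, other.scenario)

    def summary(self) -> str:
        lines = [
            f"Transfer-learning scenario results [{self.scenario}]",
            "=" * 56,
            f"task: {self.config.task}   subjects: {len(self.subject_table)}   "
            f"O: {self.config.O}   mode: {self.config.source_mode}",
            f"mean accuracy: {100 * self.mean_accuracy:.2f} +/- "
            f"{100 * self.sd_accuracy:.2f}%",
            f"mean improvement over default: {100 * self.mean_improvement:+.2f} pp",
            f"poor (transferable) subjects: "
            f"{int((self.subject_table['transferable'] == 'poor').sum())} of "
            f"{len(self.subject_table)}",
            "-" * 56,
        ]
        tbl = self.subject_table.copy()
        for col in ("default_acc", "tl_acc", "scenario_acc", "ts_ss_dissimilarity"):
            tbl[col] = tbl[col].map(lambda v: f"{v:.4f}" if pd.notna(v) else "-")
        lines.append(tbl.to_string())
        return "\n".join(lines)

    def to_csv(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subject_table.to_csv(out / f"subjects_{self.scenario}.csv")
        rows = []
        for sid, recs in self.fold_records.items():
            for kind in ("default", "tl"):
                for rec in recs.get(kind, []):
                    rows.append(
                        {
                            "subject_id": sid,
                            "kind": kind,
                            "fold": rec["fold"],
                            "d": rec["d"],
                            "pred": rec["pred"],
                            "truth": rec["truth"],
                            "correct": rec["correct"],
                        }
                    )
        pd.DataFrame(rows).to_csv(out / f"folds_{self.scenario}.csv", index=False)

    def plot_accuracies(self, ax=None):
        """Sorted per-subject accuracies, colored by transferability."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tbl = self.subject_table.sort_values("scenario_acc")
        colors = ["tab:red" if t == "poor" else "tab:blue" for t in tbl["transferable"]]
        ax.bar(range(len(tbl)), tbl["scenario_acc"], color=colors)
        ax.axhline(self.config.chance_level, color="gray", ls=":")
        ax.set_xticks(range(len(tbl)), tbl.index, rotation=90)
        ax.set_ylabel("accuracy")
        ax.set_title(f"{self.scenario} ({self.config.task})")
        return ax


ScenarioResult = TransferResults


def _check_cohort(features, labels, cfg, needs_tl):
    ids = sorted(features)
    if len(ids) < 3:
        raise ValueError("need at least 3 subjects")
    if set(labels) != set(ids):
        raise ValueError("features and labels must cover the same subjects")
    if needs_tl:
        if cfg.O is None:
            raise ValueError("transfer scenarios require cfg.O")
        if not 1 <= cfg.O <= len(ids) - 1:
            raise ValueError(f"O={cfg.O} out of range [1, {len(ids) - 1}]")
    values = {
        s: (features[s].values if isinstance(features[s], FeatureMatrix) else
            np.asarray(features[s], dtype=float))
        for s in ids
    }
    return ids, values


def _cohort_passes(
    ids: list[str],
    values: dict[str, np.ndarray],
    labels: dict[str, np.ndarray],
    cfg: PipelineConfig,
    tl_filter,
    nested_gate: bool,
    audit: bool,
) -> dict[str, dict]:
    """Default LTO pass for every subject, TL pass where ``tl_filter`` says so.

    The seed derivation never depends on the scenario, so a TL fold
    computed here is bit-identical regardless of which scenario asked for
    it — which is what lets one pass back several scenarios.
    """
    ss_weights = {}
    passes: dict[str, dict] = {}
    for i, sid in enumerate(ids):
        default_acc, def_recs = lto_default_accuracy(
            values[sid], labels[sid], cfg, subject_index=i, audit=audit
        )
        passes[sid] = {
            "default_acc": default_acc,
            "default": def_recs,
            "transferable": classify_transferability(default_acc, cfg.chance_level),
            "tl_acc": np.nan,
            "tl": None,
            "dissimilarity": np.nan,
        }
    for i, sid in enumerate(ids):
        if not tl_filter(sid, passes[sid]):
            continue
        if not ss_weights:
            ss_weights = {
                s: relieff_weights(values[s], labels[s], k=cfg.relieff_k).weights
                for s in ids
            }
        X, y = values[sid], np.asarray(labels[sid]).astype(int)
        others_w = {s: ss_weights[s] for s in ids if s != sid}
        others_f = {s: values[s] for s in ids if s != sid}
        others_l = {s: labels[s] for s in ids if s != sid}
        tl_recs = []
        for rec in passes[sid]["default"]:
            if nested_gate:
                gate = classify_transferability(
                    _nested_gate_accuracy(X, y, rec["train_trials"], cfg, i),
                    cfg.chance_level,
                )
                if gate == "good":
                    tl_recs.append({**rec, "gated": "good"})
                    continue
            tl_recs.append(
                _tl_fold(sid, i, rec, X, y, others_w, others_f, others_l, cfg, audit)
            )
        passes[sid]["tl"] = tl_recs
        passes[sid]["tl_acc"] = float(np.mean([r["correct"] for r in tl_recs]))
        dvals = np.asarray(
            [r.get("dissimilarity", np.nan) for r in tl_recs], dtype=float
        )
        passes[sid]["dissimilarity"] = (
            float(np.nanmean(dvals)) if np.isfinite(dvals).any() else np.nan
        )
    return passes


def _compose_result(
    scenario: str, ids: list[str], passes: dict[str, dict], cfg: PipelineConfig
) -> TransferResults:
    rows = []
    fold_records: dict[str, dict] = {}
    for sid in ids:
        p = passes[sid]
        default_acc, tl_acc = p["default_acc"], p["tl_acc"]
        transferable = p["transferable"]
        uses_tl = scenario in ("rTL", "oTL") or (
            scenario == "cTL"
            and (transferable == "poor" or cfg.gate_source == "nested")
        )
        uses_tl = uses_tl and p["tl"] is not None
        if scenario == "default" or not uses_tl:
            scen_acc = default_acc
        elif scenario == "oTL":
            scen_acc = max(default_acc, tl_acc)
        else:
            scen_acc = tl_acc
        rows.append(
            {
                "subject_id": sid,
                "default_acc": default_acc,
                "tl_acc": tl_acc if uses_tl else np.nan,
                "scenario_acc": scen_acc,
                "transferable": transferable,
                "O_used": cfg.O if uses_tl else 0,
                "ts_ss_dissimilarity": p["dissimilarity"] if uses_tl else np.nan,
                "n_folds": len(p["default"]),
            }
        )
        recs = {"default": p["default"]}
        if uses_tl:
            recs["tl"] = p["tl"]
        fold_records[sid] = recs
    table = pd.DataFrame(rows).set_index("subject_id")
    return TransferResults(
        scenario=scenario, config=cfg, subject_table=table, fold_records=fold_records
    )


def run_scenario(
    features: dict[str, object],
    labels: dict[str, np.ndarray],
    scenario: str,
    cfg: PipelineConfig,
    audit: bool = False,
) -> TransferResults:
    """Run one scenario with every subject in turn as the target.

    ``features`` maps subject id to a FeatureMatrix or 2-D array (shared
    descriptor order); ``labels`` maps subject id to the binary label
    vector of ``cfg.task``.  Scenario composition: default never
    transfers, rTL always, cTL only when the gate says 'poor', oTL keeps
    the per-subject best of default and transferred.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; pick one of {SCENARIOS}")
    needs_tl = scenario != "default"
    ids, values = _check_cohort(features, labels, cfg, needs_tl)
    nested = cfg.gate_source == "nested" and scenario == "cTL"

    def tl_filter(sid, p):
        if not needs_tl:
            return False
        if scenario in ("rTL", "oTL") or nested:
            return True
        return p["transferable"] == "poor"  # cTL with the outer-default gate

    passes = _cohort_passes(ids, values, labels, cfg, tl_filter, nested, audit)
    return _compose_result(scenario, ids, passes, cfg)


def run_all_scenarios(
    features: dict[str, object],
    labels: dict[str, np.ndarray],
    cfg: PipelineConfig,
    scenarios: tuple[str, ...] = SCENARIOS,
    audit: bool = False,
) -> dict[str, TransferResults]:
    """All requested scenarios from one shared default + TL pass.

    Because the seed derivation is scenario-independent, the composed
    results are bit-identical to running :func:`run_scenario` per
    scenario, at roughly half the cost.  The nested gate variant is not
    shareable and falls back to individual runs.
    """
    for sc in scenarios:
        if sc not in SCENARIOS:
            raise ValueError(f"unknown scenario {sc!r}")
    if cfg.gate_source == "nested":
        return {sc: run_scenario(features, labels, sc, cfg, audit=audit) for sc in scenarios}
    needs_tl = any(sc != "default" for sc in scenarios)
    ids, values = _check_cohort(features, labels, cfg, needs_tl)
    passes = _cohort_passes(ids, values, labels, cfg, lambda sid, p: needs_tl, False, audit)
    return {sc: _compose_result(sc, ids, passes, cfg) for sc in scenarios}


@dataclass
class SourceSweep:
    """Improvement-vs-O profiles for the similar and dissimilar modes.

    ``profiles``: long DataFrame (O, mode, group, mean_improvement,
    sd_improvement, n_subjects); ``per_subject``: per-(subject, O, mode)
    improvements; ``argmax``: per-(mode, group) best O (smallest on ties).
    """

    profiles: pd.DataFrame
    per_subject: pd.DataFrame
    argmax: pd.DataFrame
    config: PipelineConfig

    def best(self, mode: str = "similar", group: str = "all") -> tuple[int, float]:
        row = self.argmax[(self.argmax["mode"] == mode) & (self.argmax["group"] == group)]
        return int(row["O_star"].iloc[0]), float(row["max_improvement"].iloc[0])

    def plot(self, group: str = "poor", ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for mode, style in (("similar", "-"), ("dissimilar", "--")):
            sub = self.profiles[
                (self.profiles["mode"] == mode) & (self.profiles["group"] == group)
            ]
            ax.plot(sub["O"], 100 * sub["mean_improvement"], style, label=mode)
        ax.axhline(0, color="gray", lw=0.5)
        ax.set_xlabel("number of source subjects O")
        ax.set_ylabel("accuracy change vs default (pp)")
        ax.legend()
        ax.set_title(f"{group} target subjects ({self.config.task})")
        return ax


def sweep_source_count(
    features: dict[str, object],
    labels: dict[str, np.ndarray],
    cfg: PipelineConfig,
    o_range=None,
    modes: tuple[str, ...] = ("similar", "dissimilar"),
) -> SourceSweep:
    """Mean accuracy change vs default for each O and source mode.

    Subjects are grouped by transferability ({good, poor, all}); the
    default pass and the per-fold similarity profiles are computed once
    and shared across the whole grid.
    """
    ids = sorted(features)
    n = len(ids)
    if o_range is None:
        o_range = range(1, n)
    o_range = [int(o) for o in o_range]
    if any(not 1 <= o <= n - 1 for o in o_range):
        raise ValueError(f"O values must lie in [1, {n - 1}]")
    values = {
        s: (features[s].values if isinstance(features[s], FeatureMatrix) else
            np.asarray(features[s], dtype=float))
        for s in ids
    }
    ss_weights = {s: relieff_weights(values[s], labels[s], k=cfg.relieff_k).weights for s in ids}

    default_acc: dict[str, float] = {}
    def_recs: dict[str, list[dict]] = {}
    group_of: dict[str, str] = {}
    for i, sid in enumerate(ids):
        acc, recs = lto_default_accuracy(values[sid], labels[sid], cfg, subject_index=i)
        default_acc[sid] = acc
        def_recs[sid] = recs
        group_of[sid] = classify_transferability(acc, cfg.chance_level)

    rows = []
    for i, sid in enumerate(ids):
        X, y = values[sid], np.asarray(labels[sid]).astype(int)
        others_w = {s: ss_weights[s] for s in ids if s != sid}
        others_f = {s: values[s] for s in ids if s != sid}
        others_l = {s: labels[s] for s in ids if s != sid}
        for mode in modes:
            for O in o_range:
                cfg_o = replace(cfg, O=O, source_mode=mode)
                tl_recs = [
                    _tl_fold(sid, i, rec, X, y, others_w, others_f, others_l, cfg_o, False)
                    for rec in def_recs[sid]
                ]
                tl_acc = float(np.mean([r["correct"] for r in tl_recs]))
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group_of[sid],
                        "mode": mode,
                        "O": O,
                        "tl_acc": tl_acc,
                        "default_acc": default_acc[sid],
                        "improvement": tl_acc - default_acc[sid],
                    }
                )
    per_subject = pd.DataFrame(rows)

    prof_rows = []
    for mode in modes:
        for O in o_range:
            sub = per_subject[(per_subject["mode"] == mode) & (per_subject["O"] == O)]
            for group in ("good", "poor", "all"):
                grp = sub if group == "all" else sub[sub["group"] == group]
                if grp.empty:
                    continue
                prof_rows.append(
                    {
                        "O": O,
                        "mode": mode,
                        "group": group,
                        "mean_improvement": float(grp["improvement"].mean()),
                        "sd_improvement": float(grp["improvement"].std(ddof=1))
                        if len(grp) > 1 else np.nan,
                        "n_subjects": len(grp),
                    }
                )
    profiles = pd.DataFrame(prof_rows)

    argmax_rows = []
    for mode in modes:
        for group in ("good", "poor", "all"):
            sub = profiles[(profiles["mode"] == mode) & (profiles["group"] == group)]
            if sub.empty:
                continue
            sub = sub.sort_values("O")  # idxmax takes the first: smallest O on ties
            best = sub.loc[sub["mean_improvement"].idxmax()]
            argmax_rows.append(
                {
                    "mode": mode,
                    "group": group,
                    "O_star": int(best["O"]),
                    "max_improvement": float(best["mean_improvement"]),
                }
            )
    return SourceSweep(
        profiles=profiles, per_subject=per_subject,
        argmax=pd.DataFrame(argmax_rows), config=cfg,
    )


def _paired_ttest(a: pd.Series, b: pd.Series, name_a: str, name_b: str) -> dict:
    if list(a.index) != list(b.index):
        raise ValueError("mismatched subject sets")
    diff = (a - b).to_numpy(dtype=float)
    if np.allclose(diff, 0):
        return {"scenario_a": name_a, "scenario_b": name_b, "t": 0.0, "p": 1.0,
                "mean_diff": 0.0, "note": "identical"}
    if np.isclose(diff.std(ddof=1), 0):
        return {"scenario_a": name_a, "scenario_b": name_b, "t": np.nan, "p": np.nan,
                "mean_diff": float(diff.mean()), "note": "degenerate: zero variance"}
    t, p = stats.ttest_rel(a.to_numpy(dtype=float), b.to_numpy(dtype=float))
    return {"scenario_a": name_a, "scenario_b": name_b, "t": float(t), "p": float(p),
            "mean_diff": float(diff.mean()), "note": ""}


def _one_sample_ttest(x: pd.Series, name: str) -> dict:
    arr = x.to_numpy(dtype=float)
    if np.allclose(arr, 0):
        return {"scenario": name, "t": 0.0, "p": 1.0, "mean": 0.0, "note": "identical"}
    if np.isclose(arr.std(ddof=1), 0):
        return {"scenario": name, "t": np.nan, "p": np.nan, "mean": float(arr.mean()),
                "note": "degenerate: zero variance"}
    t, p = stats.ttest_1samp(arr, 0.0)
    return {"scenario": name, "t": float(t), "p": float(p), "mean": float(arr.mean()),
            "note": ""}


def compare_scenarios(results: list[TransferResults]) -> dict[str, pd.DataFrame]:
    """Paired t-tests between every scenario pair plus one-sample tests of
    each scenario's improvement over default against zero.

    Zero-variance differences are reported as degenerate with a note
    instead of erroring (and a self-comparison gives t = 0, p = 1).
    """
    ids0 = results[0].subject_ids
    for r in results[1:]:
        if r.subject_ids != ids0:
            raise ValueError("mismatched subject sets across results")
    paired = [
        _paired_ttest(a.accuracies, b.accuracies, a.scenario, b.scenario)
        for idx, a in enumerate(results)
        for b in results[idx + 1:]
    ]
    improvement = [_one_sample_ttest(r.improvements, r.scenario) for r in results]
    return {"paired": pd.DataFrame(paired), "improvement": pd.DataFrame(improvement)}


class TransferLearningExperiment:
    """Model object: a labeled multi-subject feature cohort plus a config.

    Built either from per-subject feature matrices and task labels or
    directly from a raw :class:`~ctleeg.io.Cohort` (which runs the full
    spectral chain).  ``fit(scenario)`` returns a
    :class:`TransferResults`; ``sweep_source_count`` maps the improvement
    landscape over the number of borrowed source subjects.
    """

    def __init__(self, features: dict[str, object], labels: dict[str, np.ndarray],
                 config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        if set(features) != set(labels):
            raise ValueError("features and labels must cover the same subjects")
        descs = {
            tuple(f.descriptors) for f in features.values() if isinstance(f, FeatureMatrix)
        }
        if len(descs) > 1:
            raise ValueError("all subjects must share one feature descriptor order")
        self.features = dict(features)
        self.labels = {s: np.asarray(v).astype(int) for s, v in labels.items()}

    @classmethod
    def from_cohort(cls, cohort, task: str | None = None,
                    config: PipelineConfig | None = None, **feature_kwargs):
        config = config or PipelineConfig()
        task = task or config.task
        config = replace(config, task=task)
        features = {
            ts.subject_id: extract_subject_features(ts, cohort.montage, **feature_kwargs)
            for ts in cohort.trial_sets
        }
        labels = {ts.subject_id: ts.task_labels(task) for ts in cohort.trial_sets}
        return cls(features, labels, config=config)

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.features)

    def fit(self, scenario: str = "cTL", audit: bool = False) -> TransferResults:
        return run_scenario(self.features, self.labels, scenario, self.config, audit=audit)

    def fit_all_scenarios(self, scenarios=SCENARIOS, audit: bool = False
                          ) -> dict[str, TransferResults]:
        """All scenarios from one shared pass (identical to per-scenario fits)."""
        return run_all_scenarios(self.features, self.labels, self.config,
                                 scenarios=scenarios, audit=audit)

    def sweep_source_count(self, o_range=None,
                           modes: tuple[str, ...] = ("similar", "dissimilar")) -> SourceSweep:
        return sweep_source_count(self.features, self.labels, self.config,
                                  o_range=o_range, modes=modes)

    def run_manifest(self) -> dict:
        cfg = self.config.__dict__.copy()
        blob = json.dumps(cfg, sort_keys=True, default=str)
        return {
            "config": cfg,
            "config_sha1": hashlib.sha1(blob.encode()).hexdigest(),
            "subjects": self.subject_ids,
        }
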