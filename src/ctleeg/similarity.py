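"""Inter-subject similarity from ReliefF weight spaces.

A target subject's (TS) emotion-relevant feature space is summarised by
its ReliefF weight vector; each source subject's (SS) space is summarised
the same way.  Similarity is the Pearson correlation between the raw
weight vectors (a Spearman rank option is available, since "similar
feature spaces" admits both readings), and the TS-SS dissimilarity
statistic is the population standard deviation of the absolute
correlations of the selected sources — larger means a more heterogeneous
source pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .relieff import ReliefWeights


def _as_vector(w) -> np.ndarray:
    if isinstance(w, ReliefWeights):
        return np.asarray(w.weights, dtype=float)
    return np.asarray(w, dtype=float)


@dataclass
class SimilarityProfile:
    """Per-source Pearson r of ReliefF weight vectors, with both rankings.

    ``ranking_similar`` orders sources by descending r (most similar
    first), ``ranking_dissimilar`` by ascending r; ties break by ascending
    subject id.  Sources whose weight vector has zero variance get r = 0
    and are listed in ``flagged``.
    """

    ts_id: str
    source_r: dict[str, float]
    ranking_similar: list[str]
    ranking_dissimilar: list[str]
    flagged: tuple[str, ...] = ()

    @property
    def n_sources(self) -> int:
        return len(self.source_r)


def similarity_profile(
    ts_id: str,
    w_ts,
    w_ss: dict,
    method: str = "pearson",
) -> SimilarityProfile:
    """Correlate the TS weight vector with each SS weight vector."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    v_ts = _as_vector(w_ts)
    if method == "spearman":
        v_ts = stats.rankdata(v_ts)
    flagged: list[str] = []

    def degenerate(v: np.ndarray) -> bool:
        return bool(np.ptp(v) == 0)  # exact for constant vectors, unlike std

    ts_degenerate = degenerate(v_ts)
    if ts_degenerate:
        flagged.append(str(ts_id))
    source_r: dict[str, float] = {}
    for sid, w in w_ss.items():
        v = _as_vector(w)
        if len(v) != len(v_ts):
            raise ValueError(f"weight vector length mismatch for source {sid!r}")
        if method == "spearman":
            v = stats.rankdata(v)
        if ts_degenerate or degenerate(v):
            if not ts_degenerate:
                flagged.append(str(sid))
            source_r[str(sid)] = 0.0
            continue
        source_r[str(sid)] = float(np.corrcoef(v_ts, v)[0, 1])
    ranking_similar = sorted(source_r, key=lambda s: (-source_r[s], s))
    ranking_dissimilar = sorted(source_r, key=lambda s: (source_r[s], s))
    return SimilarityProfile(
        ts_id=str(ts_id),
        source_r=source_r,
        ranking_similar=ranking_similar,
        ranking_dissimilar=ranking_dissimilar,
        flagged=tuple(flagged),
    )


def select_sources(profile: SimilarityProfile, O: int, mode: str = "similar") -> list[str]:
    """First O sources of the requested ranking."""
    n = profile.n_sources
    if not 1 <= O <= n:
        raise ValueError(f"O={O} out of range [1, {n}]")
    if mode == "similar":
        return profile.ranking_similar[:O]
    if mode == "dissimilar":
        return profile.ranking_dissimilar[:O]
    raise ValueError(f"unknown mode {mode!r}")


def ts_ss_dissimilarity(profile: SimilarityProfile, selected: list[str]) -> float:
    """Population std of |r| over the selected sources (needs >= 2)."""
    if len(selected) < 2:
        raise ValueError("dissimilarity needs at least 2 selected sources")
    r = np.array([abs(profile.source_r[str(s)]) for s in selected])
    return float(r.std())


def correlation_matrix(w_by_subject: dict, method: str = "pearson"):
    """Full subject-by-subject correlation matrix of weight vectors."""
    import pandas as pd

    ids = list(w_by_subject)
    mat = np.eye(len(ids))
    for i, a in enumerate(ids):
        prof = similarity_profile(a, w_by_subject[a], {b: w_by_subject[b] for b in ids if b != a},
                                  method=method)
        for j, b in enumerate(ids):
            if a != b:
                mat[i, j] = prof.source_r[str(b)]
    return pd.DataFrame(mat, index=ids, columns=ids)
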