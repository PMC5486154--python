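"""Two-class ReliefF feature-relevance weighting, implemented from scratch.

ReliefF rewards features whose values agree among nearest same-class
neighbours (hits) and differ among nearest other-class neighbours
(misses).  Features are max-min scaled to [0, 1] internally so the diff
contribution of every feature is commensurate and the resulting weights
lie in [-1, 1].  With ``m="all"`` (every instance sampled once, the
default) the procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class ReliefWeights:
    """Per-feature relevance weights and the induced descending ranking.

    Ranking ties are broken by ascending feature index.
    """

    weights: np.ndarray
    ranking: np.ndarray
    k_neighbors: int
    n_sampled: int

    @property
    def n_features(self) -> int:
        return len(self.weights)

    def to_frame(self, feature_names: list[str] | None = None):
        """Weights table (feature, weight, rank), rank 1 = highest weight."""
        import pandas as pd

        names = feature_names or [f"f{i}" for i in range(self.n_features)]
        rank = np.empty(self.n_features, dtype=int)
        rank[self.ranking] = np.arange(1, self.n_features + 1)
        return pd.DataFrame({"feature": names, "weight": self.weights, "rank": rank})

    def to_csv(self, path, feature_names: list[str] | None = None) -> None:
        self.to_frame(feature_names).to_csv(path, index=False)


def _rank_descending(weights: np.ndarray) -> np.ndarray:
    # sort by (-weight, feature index); lexsort's last key is primary
    return np.lexsort((np.arange(len(weights)), -weights))


def relieff_weights(
    X: np.ndarray,
    y: np.ndarray,
    k: int | None = None,
    m: int | str = "all",
    rng: np.random.Generator | None = None,
) -> ReliefWeights:
    """Standard two-class ReliefF weights under Manhattan distance.

    For each sampled instance R the k nearest hits H and k nearest misses
    M are found on max-min-scaled features; then per feature f

        W[f] <- W[f] - sum_j diff(f, R, H_j)/(m k) + sum_j diff(f, R, M_j)/(m k)

    k defaults to min(10, smallest class size - 1); an explicit k larger
    than or equal to a class size is a hard error naming that class.
    Neighbour-distance ties are broken by ascending instance index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (n_instances, n_features) with one label per row")
    if not np.isfinite(X).all():
        raise ValueError("missing or non-finite values are not supported")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("two-class ReliefF requires exactly two classes")
    min_class = counts.min()
    if k is None:
        k = int(min(10, min_class - 1))
        if k < 1:
            raise ValueError("each class needs at least 2 members for the default k")
    else:
        for cls, cnt in zip(classes, counts):
            if cnt <= k:
                raise ValueError(f"class {cls} has only {cnt} member(s), needs > k={k}")

    n, n_feat = X.shape
    mn = X.min(axis=0)
    rng_ = X.max(axis=0) - mn
    scale = np.where(rng_ == 0, 1.0, rng_)  # constant features contribute diff = 0
    Xs = (X - mn) / scale

    if m == "all":
        sampled = np.arange(n)
    else:
        gen = rng or np.random.default_rng()
        sampled = gen.choice(n, size=int(m), replace=False)

    dist = cdist(Xs, Xs, metric="cityblock")
    order = np.argsort(dist, axis=1, kind="stable")  # stable: distance ties -> ascending index

    W = np.zeros(n_feat)
    denom = len(sampled) * k
    for i in sampled:
        same = y[order[i]] == y[i]
        neighbors = order[i][order[i] != i]
        same = same[order[i] != i]
        hits = neighbors[same][:k]
        misses = neighbors[~same][:k]
        W -= np.abs(Xs[i] - Xs[hits]).sum(axis=0) / denom
        W += np.abs(Xs[i] - Xs[misses]).sum(axis=0) / denom
    return ReliefWeights(
        weights=W, ranking=_rank_descending(W), k_neighbors=k, n_sampled=len(sampled)
    )


def top_features(rw: ReliefWeights, d: int) -> np.ndarray:
    """First d entries of the descending-weight ranking."""
    if not 1 <= d <= rw.n_features:
        raise ValueError(f"d={d} out of range [1, {rw.n_features}]")
    return rw.ranking[:d].copy()
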