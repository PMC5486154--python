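"""Gaussian naive Bayes with an explicit numerical contract.

Class-conditional feature distributions are modelled as independent
Gaussians with per-class per-feature sample moments (population, i.e. n,
denominator).  Variances are floored at 1e-9 times the largest pooled
feature variance so a within-class constant feature never produces a
division error; posteriors are computed in log space and ties resolve to
class 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VAR_FLOOR_REL = 1e-9
_VAR_FLOOR_ABS = 1e-24  # keeps an all-constant input finite


@dataclass
class GNBModel:
    classes: np.ndarray  # the two class labels, ascending
    priors: np.ndarray  # per-class prior probability, sums to 1
    means: np.ndarray  # (n_classes, n_features)
    variances: np.ndarray  # (n_classes, n_features), all >= var_floor
    var_floor: float

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def gnb_fit(X: np.ndarray, y: np.ndarray) -> GNBModel:
    """Fit class priors and per-class per-feature Gaussian moments."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (n_instances, n_features) with one label per row")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    var_floor = max(VAR_FLOOR_REL * float(X.var(axis=0).max()), _VAR_FLOOR_ABS)
    priors = np.array([(y == c).mean() for c in classes])
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    variances = np.stack([X[y == c].var(axis=0) for c in classes])  # n denominator
    variances = np.maximum(variances, var_floor)
    return GNBModel(
        classes=classes, priors=priors, means=means, variances=variances, var_floor=var_floor
    )


def gnb_log_joint(model: GNBModel, X: np.ndarray) -> np.ndarray:
    """Log prior + summed log Gaussian densities, shape (n_instances, n_classes)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite input")
    # (n, 1, f) against (c, f)
    z = (X[:, None, :] - model.means) ** 2 / model.variances
    log_lik = -0.5 * (np.log(2 * np.pi * model.variances) + z).sum(axis=2)
    return np.log(model.priors) + log_lik


def gnb_predict(model: GNBModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-instance class posteriors and hard labels (tie -> first class)."""
    log_joint = gnb_log_joint(model, X)
    shifted = log_joint - log_joint.max(axis=1, keepdims=True)
    post = np.exp(shifted)
    post /= post.sum(axis=1, keepdims=True)
    # argmax returns the first maximum, so exact ties resolve to class 0
    labels = model.classes[np.argmax(log_joint, axis=1)]
    return post, labels
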