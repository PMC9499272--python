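"""Class-weight optimization (CW) for imbalanced multi-label loss.

The CW scheme assigns the i-th function class the loss weight

    W_i = phi * [log(N / n_i)]**theta

where N is the number of training instances, n_i the number of instances
carrying label i (a multi-label instance counts once for every label it
carries), phi > 0 a scale hyperparameter and theta an exponent constrained to

    1 <= theta <= (ln X - ln Y) / ln(log_Y X),   X = N/min(n), Y = N/max(n).

Rare classes therefore receive larger weights, and the majority class weight
shrinks to 0 as n_i approaches N.  The per-equation log bases differ in the
printed notation, so the Eq-5 base is configurable (default 10); the theta
bound uses natural logs throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ClassWeightParams",
    "compute_cw_weights",
    "theta_upper_bound",
    "default_theta",
    "weighted_bce_loss",
    "baseline_weights",
    "label_counts",
]

#: Probability clipping constant for the binary cross-entropy.
BCE_EPS = 1e-7


@dataclass
class ClassWeightParams:
    """The CW computation with its inputs, bound and resulting weights."""

    N: int
    counts: np.ndarray
    phi: float
    theta: float
    weights: np.ndarray
    log_base: float = 10.0

    @property
    def X(self) -> float:
        return self.N / float(np.min(self.counts))

    @property
    def Y(self) -> float:
        return self.N / float(np.max(self.counts))

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "N": int(self.N),
                    "counts": [int(c) for c in self.counts],
                    "phi": self.phi,
                    "theta": self.theta,
                    "log_base": self.log_base,
                    "weights": [float(w) for w in self.weights],
                },
                indent=1,
            )
        )


def label_counts(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-class instance counts n_i and total instance count N from an
    N x M binary label matrix."""
    labels = np.asarray(labels)
    return labels.sum(axis=0).astype(np.int64), labels.shape[0]


def compute_cw_weights(
    counts, N: int, phi: float = 1.0, theta: float = 1.0, log_base: float = 10.0
) -> np.ndarray:
    """Evaluate W_i = phi * [log_b(N / n_i)]**theta for every class.

    Strictly decreasing in n_i for any base > 1 and theta >= 1.  When the
    largest class covers every instance (n_i = N) its weight is exactly 0,
    which silences that class's loss term — a warning is emitted.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 1):
        raise ValueError("every class count n_i must be >= 1")
    if np.any(counts > N):
        raise ValueError("class count n_i cannot exceed the instance total N")
    if phi <= 0:
        raise ValueError("phi must be positive")
    if theta < 1:
        raise ValueError("theta must be >= 1")
    w = phi * (np.log(N / counts) / np.log(log_base)) ** theta
    if np.any(counts == N):
        warnings.warn(
            "majority class has n_i = N: its CW weight is 0 and its loss term "
            "is silenced; consider a weight floor",
            stacklevel=2,
        )
    return w


def theta_upper_bound(counts, N: int) -> float:
    """Upper limit of the theta constraint: (ln X - ln Y) / ln(log_Y X).

    X = N / min(n_i) and Y = N / max(n_i).  Undefined for balanced counts
    (X = Y makes the denominator ln 1 = 0).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 1):
        raise ValueError("every class count n_i must be >= 1")
    x = N / float(np.min(counts))
    y = N / float(np.max(counts))
    if x == y:
        raise ValueError("theta bound undefined for balanced counts (X = Y)")
    if y <= 1.0:
        # log base Y is degenerate when the majority class covers all instances
        raise ValueError("theta bound undefined when max(n_i) >= N (Y <= 1)")
    return (np.log(x) - np.log(y)) / np.log(np.log(x) / np.log(y))


def default_theta(counts, N: int) -> float:
    """Midpoint of the admissible interval [1, theta_upper_bound].

    Falls back to 1.0 when the bound is undefined (balanced counts) or below
    1 — the latter happens when the largest class exceeds N/e instances, which
    makes the printed constraint interval empty; theta = 1 (plain log weights)
    is the conservative choice there.
    """
    try:
        return max(1.0, (1.0 + theta_upper_bound(counts, N)) / 2.0)
    except ValueError:
        return 1.0


def weighted_bce_loss(probs: np.ndarray, targets: np.ndarray, weights) -> float:
    """Class-weighted binary cross-entropy, averaged over samples and labels.

    ``mean_{i,j} w_j * [-y_ij log p_ij - (1-y_ij) log(1-p_ij)]``; probabilities
    are clipped to [BCE_EPS, 1-BCE_EPS].  All-ones weights reduce to the
    standard BCE.
    """
    probs = np.clip(np.asarray(probs, dtype=np.float64), BCE_EPS, 1 - BCE_EPS)
    targets = np.asarray(targets, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if probs.shape != targets.shape:
        raise ValueError("probs and targets shapes disagree")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    term = -(targets * np.log(probs) + (1 - targets) * np.log(1 - probs))
    return float(np.mean(weights * term))


def baseline_weights(counts, N: int, scheme: str = "uniform") -> np.ndarray:
    """Simple reference weight schemes for comparison against CW.

    ``uniform`` gives every class weight 1 (unweighted BCE);
    ``inverse_frequency`` gives N / (M * n_i).  These are generic baselines,
    not the CW1/CW2 schemes of the prior literature.
    """
    counts = np.asarray(counts, dtype=np.float64)
    m = counts.size
    if scheme == "uniform":
        return np.ones(m)
    if scheme == "inverse_frequency":
        if np.any(counts < 1):
            raise ValueError("every class count n_i must be >= 1")
        return N / (m * counts)
    raise ValueError(
        f"unknown weight scheme {scheme!r}; options: uniform, inverse_frequency"
    )


def make_class_weight_params(
    counts, N: int, phi: float = 1.0, theta: float | None = None, log_base: float = 10.0
) -> ClassWeightParams:
    """Bundle a CW evaluation; ``theta=None`` picks the interval midpoint."""
    if theta is None:
        theta = default_theta(counts, N)
    w = compute_cw_weights(counts, N, phi=phi, theta=theta, log_base=log_base)
    return ClassWeightParams(
        N=int(N), counts=np.asarray(counts), phi=phi, theta=theta, weights=w,
        log_base=log_base,
    )
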