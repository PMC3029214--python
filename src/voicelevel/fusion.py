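"""Classifier-fusion rules: majority voting, linear combination, stacked MLP.

Six base classifiers feed the fusion layer: five per-word HMM banks (each
emitting four level log-likelihoods and a crisp level) and the word-feature
neural classifier (four soft outputs and a crisp level).  Fusion makes the
single per-child level decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neural_net import MLPModel, predict_level

__all__ = [
    "LogLikMatrix",
    "FusionDecision",
    "fuse_linear",
    "fuse_mvr",
    "fuse_stacked",
    "scale_levels",
]

N_LEVELS = 4


@dataclass(frozen=True)
class LogLikMatrix:
    """Per-classifier level log-likelihoods: entry [k, i] is classifier k's
    log-likelihood of level i+1.  Weights default to uniform (simple
    averaging — optimal for equally accurate, equally correlated bases)."""

    logliks: np.ndarray  # (N, 4)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        ll = np.atleast_2d(np.asarray(self.logliks, dtype=np.float64))
        if ll.ndim != 2 or ll.shape[1] != N_LEVELS or ll.shape[0] < 1:
            raise ValueError(f"logliks must be (N >= 1, {N_LEVELS})")
        if not np.all(np.isfinite(ll)):
            raise ValueError("log-likelihoods must be finite")
        w = self.weights
        if w is None:
            w = np.ones(ll.shape[0])
        w = np.asarray(w, dtype=np.float64)
        if w.shape != (ll.shape[0],):
            raise ValueError("one weight per classifier required")
        object.__setattr__(self, "logliks", ll)
        object.__setattr__(self, "weights", w)

    @property
    def n_classifiers(self) -> int:
        return self.logliks.shape[0]


@dataclass(frozen=True)
class FusionDecision:
    level: int
    rule: str
    evidence: np.ndarray


def fuse_linear(ll: LogLikMatrix) -> FusionDecision:
    """Weighted-sum fusion: sum each level's log-likelihoods over all
    classifiers and pick the maximizing level (ties toward the lower one)."""
    if ll.n_classifiers == 0:
        raise ValueError("no classifiers to fuse")
    sums = ll.weights @ ll.logliks
    return FusionDecision(level=int(np.argmax(sums)) + 1, rule="linear", evidence=sums)


def fuse_mvr(votes, ll: LogLikMatrix | None = None) -> FusionDecision:
    """Majority voting: the most frequent crisp label wins.

    Ties are resolved by linear-combination evidence when log-likelihoods
    are available, otherwise toward the lower level index.
    """
    votes = np.asarray(votes, dtype=int)
    if votes.size == 0:
        raise ValueError("no votes to fuse")
    if np.any((votes < 1) | (votes > N_LEVELS)):
        raise ValueError("votes must be levels 1..4")
    counts = np.bincount(votes, minlength=N_LEVELS + 1)[1:]
    top = counts.max()
    tied = np.flatnonzero(counts == top) + 1
    if tied.size == 1:
        level = int(tied[0])
    elif ll is not None:
        sums = ll.weights @ ll.logliks
        tied_scores = sums[tied - 1]
        level = int(tied[int(np.argmax(tied_scores))])
    else:
        level = int(tied[0])
    return FusionDecision(level=level, rule="mvr", evidence=counts.astype(float))


def scale_levels(levels) -> np.ndarray:
    """Map crisp levels 1..4 onto [0, 1] for the meta-network input."""
    levels = np.asarray(levels, dtype=np.float64)
    return (levels - 1.0) / (N_LEVELS - 1.0)


def fuse_stacked(base_levels, meta: MLPModel) -> FusionDecision:
    """Stacked generalization: the six base crisp decisions, scaled to
    [0, 1], feed the 6-10-4 meta-MLP; its argmax output is the decision.

    The meta-network must have been trained on data disjoint from the base
    classifiers' training split.
    """
    base_levels = np.asarray(base_levels, dtype=np.float64).ravel()
    if base_levels.size != meta.layer_sizes[0]:
        raise ValueError(
            f"expected {meta.layer_sizes[0]} base decisions, got {base_levels.size}"
        )
    if not meta.trained:
        raise ValueError("meta-classifier has not been trained")
    level, soft = predict_level(meta, scale_levels(base_levels))
    return FusionDecision(level=level, rule="stacked", evidence=soft)
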