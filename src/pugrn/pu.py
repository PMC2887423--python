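"""Positive-unlabeled classifiers for regulation prediction.

Three methods share one calibrated-SVM core:

* **PosOnly** — train a *non-traditional* classifier to separate labeled
  (s = 1) from unlabeled (s = 0) examples, estimating p(s=1|x); under
  the selected-completely-at-random assumption the true posterior is
  p(y=1|x) = p(s=1|x) / c, where c = p(s=1|y=1) is the labeling
  frequency, estimated as the mean score over held-out labeled
  positives.
* **SVMOnly** — the same non-traditional classifier with its output used
  directly as p(y=1|x), i.e. unlabeled examples treated as negatives.
  Its ranking is identical to PosOnly's (division by a positive
  constant), but its probabilities are biased low by the factor c.
* **PSEUDO-RANDOM** — an ordinary positive-vs-negative SVM whose
  negatives are the candidate set picked by the transitive-closure
  heuristic (:func:`pugrn.network.pseudo_random_negatives`).

The base classifier is a C-SVC with RBF kernel and Platt-scaled
probability outputs, delegated to libsvm via scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.svm import SVC

from .expression import PairExample
from .network import Edge

__all__ = [
    "SvmConfig",
    "CEstimate",
    "ProbabilisticClassifier",
    "train_nontraditional",
    "train_pseudo_random",
    "estimate_c",
    "posonly_predict",
    "svmonly_predict",
    "classify",
    "fit_posonly",
]

_C_FLOOR = 1e-6


@dataclass(frozen=True)
class SvmConfig:
    """C-SVC hyperparameters: soft-margin cost C and RBF width γ.

    The kernel is K(x1, x2) = exp(−γ‖x1 − x2‖²); probability outputs
    come from Platt scaling (libsvm's internal cross-validated sigmoid
    fit) unless ``probability_calibration`` is disabled.

    ``class_weight="balanced"`` scales C inversely with class frequency
    during margin optimization.  Without it, the hinge loss collapses to
    a constant decision function whenever the labeled class is nowhere a
    local majority — the typical PU regime, where labeled positives are
    a small minority and unlabeled positives overlap them exactly — and
    a constant ranker cannot be calibrated.  The Platt sigmoid itself is
    fit unweighted on held-out decision values, so the probability
    estimates remain honest estimates of p(s=1|x).
    """

    C: float = 500.0
    gamma: float = 0.05
    probability_calibration: bool = True
    class_weight: str | None = "balanced"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class CEstimate:
    """The labeling frequency c = p(s=1|y=1), clipped into (0, 1]."""

    c: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "c", float(min(1.0, max(_C_FLOOR, self.c))))


class ProbabilisticClassifier:
    """A trained SVM with calibrated probability outputs in [0, 1]."""

    def __init__(self, model: SVC) -> None:
        self._model = model

    def score(self, x: np.ndarray) -> float:
        """Probability estimate for a single feature vector."""
        return float(self.score_many(np.asarray(x, dtype=float).reshape(1, -1))[0])

    def score_many(self, X: np.ndarray) -> np.ndarray:
        """Probability estimates for a matrix of feature vectors."""
        X = np.asarray(X, dtype=float)
        pos_col = int(np.flatnonzero(self._model.classes_ == 1)[0])
        return self._model.predict_proba(X)[:, pos_col]


def _fit_svc(X: np.ndarray, labels: np.ndarray, config: SvmConfig, seed: int) -> ProbabilisticClassifier:
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both a positive and a negative class")
    model = SVC(
        C=config.C,
        gamma=config.gamma,
        kernel="rbf",
        probability=config.probability_calibration,
        class_weight=config.class_weight,
        random_state=int(seed) % 2**31,
        cache_size=500,
    )
    with warnings.catch_warnings():
        # sklearn 1.9 deprecates probability=True; libsvm's internal Platt
        # calibration is exactly the behavior wanted here.
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(X, labels)
    return ProbabilisticClassifier(model)


def _stack(examples: Sequence[PairExample]) -> np.ndarray:
    return np.vstack([ex.x for ex in examples])


def train_nontraditional(
    examples: Sequence[PairExample], config: SvmConfig, seed: int = 0
) -> ProbabilisticClassifier:
    """Train the labeled-vs-unlabeled classifier estimating p(s=1|x).

    The target is the observed label ``s``; the true class ``y`` is
    never consulted.  Requires at least one labeled and one unlabeled
    example.
    """
    s = np.array([ex.s for ex in examples], dtype=int)
    if s.sum() == 0 or s.sum() == len(s):
        raise ValueError("need at least one labeled (s=1) and one unlabeled (s=0) example")
    return _fit_svc(_stack(examples), s, config, seed)


def train_pseudo_random(
    examples: Sequence[PairExample],
    negatives: Iterable[Edge],
    config: SvmConfig,
    seed: int = 0,
) -> ProbabilisticClassifier:
    """Train positives (s=1) against heuristic-selected negative pairs.

    ``negatives`` must all be present among ``examples``; examples that
    are neither labeled positive nor selected negative are unused.
    """
    negatives = frozenset(tuple(p) for p in negatives)
    if not negatives:
        raise ValueError("negatives set is empty")
    by_pair = {ex.pair for ex in examples}
    missing = negatives - by_pair
    if missing:
        raise ValueError(f"{len(missing)} negative pairs missing from examples")
    used = [ex for ex in examples if ex.s == 1 or ex.pair in negatives]
    labels = np.array([1 if ex.s == 1 else 0 for ex in used], dtype=int)
    if labels.sum() == 0:
        raise ValueError("need at least one labeled positive example")
    return _fit_svc(_stack(used), labels, config, seed)


def estimate_c(
    classifier: ProbabilisticClassifier, validation_positives: Sequence[PairExample]
) -> CEstimate:
    """Estimate the labeling frequency c = p(s=1|y=1).

    Under selected-completely-at-random labeling, p(s=1|x) ≈ c for any
    true positive x, so c is estimated as the mean non-traditional score
    over labeled positives from a validation set drawn like the training
    set.  The estimate is clipped into (1e-6, 1].
    """
    if not validation_positives:
        raise ValueError("validation set of labeled positives is empty")
    if any(ex.s != 1 for ex in validation_positives):
        raise ValueError("all validation examples must be labeled positives (s=1)")
    scores = classifier.score_many(_stack(validation_positives))
    return CEstimate(float(scores.mean()))


def posonly_predict(
    classifier: ProbabilisticClassifier, c: CEstimate, x: np.ndarray
) -> float:
    """Corrected probability p(y=1|x) = min(1, p(s=1|x) / c)."""
    return float(min(1.0, classifier.score(x) / c.c))


def svmonly_predict(classifier: ProbabilisticClassifier, x: np.ndarray) -> float:
    """The uncorrected score, read directly as p(y=1|x)."""
    return classifier.score(x)


def classify(probability: float, threshold: float = 0.5) -> int:
    """Hard decision: 1 iff probability strictly exceeds the threshold."""
    if not 0 <= probability <= 1 + 1e-12:
        raise ValueError("probability out of range")
    return int(probability > threshold)


def fit_posonly(
    examples: Sequence[PairExample],
    config: SvmConfig,
    seed: int = 0,
    holdout_fraction: float = 0.2,
) -> tuple[ProbabilisticClassifier, CEstimate]:
    """Full PosOnly fit: holdout c-estimation, then retrain on everything.

    A seeded ``holdout_fraction`` of the examples is held out; the
    non-traditional classifier is trained on the rest and c estimated on
    the held-out labeled positives, mimicking a validation set drawn in
    the same manner as the training set.  The classifier is then
    retrained on all examples and returned with the c estimate.  If no
    labeled positive lands in the holdout, c falls back to the training
    positives (with a warning) rather than failing.
    """
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    rng = np.random.default_rng(int(seed) % 2**31)
    n = len(examples)
    n_hold = max(1, int(round(holdout_fraction * n)))
    hold_idx = set(rng.choice(n, size=n_hold, replace=False).tolist())
    held = [examples[i] for i in sorted(hold_idx)]
    rest = [examples[i] for i in range(n) if i not in hold_idx]
    held_pos = [ex for ex in held if ex.s == 1]

    try:
        partial = train_nontraditional(rest, config, seed)
    except ValueError:
        partial = None
    if partial is not None and held_pos:
        c = estimate_c(partial, held_pos)
    else:
        warnings.warn(
            "no labeled positives in the c-estimation holdout; "
            "falling back to resubstitution on training positives",
            stacklevel=2,
        )
        full = train_nontraditional(list(examples), config, seed)
        c = estimate_c(full, [ex for ex in examples if ex.s == 1])
        return full, c
    full = train_nontraditional(list(examples), config, seed)
    return full, c
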