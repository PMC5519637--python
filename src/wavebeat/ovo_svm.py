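"""One-versus-one SVM with explicit majority voting.

For n classes, n(n-1)/2 binary soft-margin RBF classifiers are trained,
one per unordered class pair, each seeing only that pair's training
samples.  A test beat is shown to every hyperplane; each contributes one
vote for the class its signed decision selects, and the beat is assigned
to the class with the most votes.  The binary solver is treated as a
black-box maximum-margin contract (scikit-learn's SVC at the given C and
gamma); the voting layer, tally bookkeeping and tie-breaking live here.

Tie-breaking is deterministic: if exactly two classes tie, the winner of
their direct pairwise hyperplane takes the beat; among three or more tied
classes, the one with the largest total signed margin over its own
hyperplanes wins; as a final fallback the earliest class in the model's
class ordering is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from .errors import PredictionError, TrainingError

_SERIAL_FORMAT = "wavebeat-ovo-v1"


@dataclass(frozen=True)
class SvmConfig:
    """Penalty weight, RBF width and the feature-scaling switch.

    ``gamma`` parameterizes the kernel K(x, y) = exp(-gamma * ||x - y||^2).
    ``standardize`` rescales every reduced-feature dimension to zero mean
    and unit variance using training statistics; a fixed gamma is only
    meaningful on such a normalized scale, but the flag can be switched
    off to feed raw projections.
    """

    C: float = 10.0
    gamma: float = 0.1
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class BinaryHyperplane:
    """One trained pairwise decision function.

    The signed score is positive for ``class_pair[1]`` and negative for
    ``class_pair[0]`` (scikit-learn's convention for a sorted class pair).
    """

    class_pair: tuple[str, str]
    svc: SVC

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(X)


@dataclass
class OvoModel:
    """All pairwise hyperplanes plus the voting rule's bookkeeping."""

    classes: tuple[str, ...]
    hyperplanes: list[BinaryHyperplane]
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    n_features: int = 0
    _pair_index: dict[tuple[str, str], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._pair_index = {
            h.class_pair: i for i, h in enumerate(self.hyperplanes)
        }

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def hyperplane_for(self, a: str, b: str) -> BinaryHyperplane:
        key = (a, b) if a < b else (b, a)
        return self.hyperplanes[self._pair_index[key]]

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise PredictionError(
                f"sample dimension {X.shape[1]} != training dimension "
                f"{self.n_features}"
            )
        if self.scaler_mean is not None:
            X = (X - self.scaler_mean) / self.scaler_scale
        return X


def train_ovo(features: np.ndarray, labels: Sequence[str],
              cfg: SvmConfig = SvmConfig(),
              classes: Sequence[str] | None = None) -> OvoModel:
    """Fit one binary RBF classifier per unordered class pair.

    Parameters
    ----------
    features : (n_samples, n_features) array of reduced feature vectors.
    labels : class label per sample.
    cfg : penalty, kernel width, scaling switch.
    classes : optional explicit class list; every listed class must have
        at least one training sample.

    Raises
    ------
    TrainingError
        For fewer than two distinct classes, or a declared class with no
        samples (the message names it).
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise TrainingError("features and labels must align row-wise")
    present = sorted(set(y.tolist()))
    if classes is None:
        class_list = present
    else:
        class_list = sorted(classes)
        missing = [c for c in class_list if c not in present]
        if missing:
            raise TrainingError(f"no training samples for class(es): {missing}")
    if len(class_list) < 2:
        raise TrainingError("need at least 2 distinct classes")

    if cfg.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0
        Xs = (X - mean) / scale
    else:
        mean = scale = None
        Xs = X

    hyperplanes: list[BinaryHyperplane] = []
    for i, a in enumerate(class_list):
        for b in class_list[i + 1:]:
            mask = (y == a) | (y == b)
            svc = SVC(kernel="rbf", C=cfg.C, gamma=cfg.gamma)
            svc.fit(Xs[mask], y[mask])
            hyperplanes.append(BinaryHyperplane(class_pair=(a, b), svc=svc))
    return OvoModel(
        classes=tuple(class_list),
        hyperplanes=hyperplanes,
        scaler_mean=mean,
        scaler_scale=scale,
        n_features=X.shape[1],
    )


def pairwise_decisions(model: OvoModel, samples: np.ndarray) -> np.ndarray:
    """Signed decision scores, shape (n_samples, n_hyperplanes)."""
    X = model._prepare(samples)
    return np.column_stack([h.decision(X) for h in model.hyperplanes])


def count_votes(model: OvoModel, sample: np.ndarray) -> dict[str, int]:
    """Vote tally over classes for one sample; totals to n(n-1)/2."""
    votes = _vote_matrix(model, np.atleast_2d(np.asarray(sample)))[0]
    return dict(zip(model.classes, votes.tolist()))


def _vote_matrix(model: OvoModel, samples: np.ndarray) -> np.ndarray:
    scores = pairwise_decisions(model, samples)
    index = {c: i for i, c in enumerate(model.classes)}
    votes = np.zeros((scores.shape[0], model.n_classes), dtype=np.int64)
    for p, h in enumerate(model.hyperplanes):
        a, b = h.class_pair
        winner_b = scores[:, p] > 0
        votes[winner_b, index[b]] += 1
        votes[~winner_b, index[a]] += 1
    return votes


def _signed_margin_for_class(model: OvoModel, scores_row: np.ndarray,
                             cls: str) -> float:
    """Sum of this class's signed margins over its n-1 hyperplanes."""
    total = 0.0
    for p, h in enumerate(model.hyperplanes):
        a, b = h.class_pair
        if cls == b:
            total += scores_row[p]
        elif cls == a:
            total -= scores_row[p]
    return total


def _resolve(model: OvoModel, votes_row: np.ndarray,
             scores_row: np.ndarray) -> str:
    top = votes_row.max()
    tied = [model.classes[i] for i in np.nonzero(votes_row == top)[0]]
    if len(tied) == 1:
        return tied[0]
    if len(tied) == 2:
        a, b = sorted(tied)
        p = model._pair_index[(a, b)]
        return b if scores_row[p] > 0 else a
    margins = [_signed_margin_for_class(model, scores_row, c) for c in tied]
    best = max(margins)
    # fallback to model class order among exactly-equal margins
    for c, m in zip(tied, margins):
        if m == best:
            return c
    return tied[0]  # unreachable


def predict(model: OvoModel, samples: np.ndarray) -> np.ndarray | str:
    """Majority-vote class per sample (deterministic, documented tie-break).

    A single vector yields a single label; a matrix yields an array of
    labels.
    """
    X = np.asarray(samples, dtype=np.float64)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    scores = pairwise_decisions(model, X2)
    index = {c: i for i, c in enumerate(model.classes)}
    votes = np.zeros((X2.shape[0], model.n_classes), dtype=np.int64)
    for p, h in enumerate(model.hyperplanes):
        a, b = h.class_pair
        winner_b = scores[:, p] > 0
        votes[winner_b, index[b]] += 1
        votes[~winner_b, index[a]] += 1
    out = np.empty(X2.shape[0], dtype=object)
    for r in range(X2.shape[0]):
        out[r] = _resolve(model, votes[r], scores[r])
    labels = out.astype(str)
    return labels[0] if single else labels


def save_model(model: OvoModel, path: str | Path) -> Path:
    """Serialize the trained model (versioned, class order explicit)."""
    path = Path(path)
    joblib.dump({
        "format": _SERIAL_FORMAT,
        "classes": list(model.classes),
        "pairs": [h.class_pair for h in model.hyperplanes],
        "svcs": [h.svc for h in model.hyperplanes],
        "scaler_mean": model.scaler_mean,
        "scaler_scale": model.scaler_scale,
        "n_features": model.n_features,
    }, path)
    return path


def load_model(path: str | Path) -> OvoModel:
    payload = joblib.load(path)
    if payload.get("format") != _SERIAL_FORMAT:
        raise TrainingError(f"{path} is not a saved one-vs-one model")
    hyperplanes = [
        BinaryHyperplane(class_pair=tuple(pair), svc=svc)
        for pair, svc in zip(payload["pairs"], payload["svcs"])
    ]
    return OvoModel(
        classes=tuple(payload["classes"]),
        hyperplanes=hyperplanes,
        scaler_mean=payload["scaler_mean"],
        scaler_scale=payload["scaler_scale"],
        n_features=payload["n_features"],
    )
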