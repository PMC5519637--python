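"""Principal-component reduction of raw wavelet feature vectors.

The model is fitted on training rows only (centering, no per-feature
variance scaling — wavelet coefficients share physical units) and every
segment is projected onto the first *k* components.  *k* is either fixed
(default 12) or chosen as the smallest count whose cumulative explained
variance ("contributory ratio") reaches a threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .errors import DataError, FitError, ProjectionError, SelectionError


@dataclass(frozen=True)
class PcaModel:
    """Fitted principal-component basis.

    Attributes
    ----------
    mean : numpy.ndarray
        Per-feature training mean (the centering vector).
    components : numpy.ndarray
        (n_components, n_features) orthonormal rows, sorted by explained
        variance descending.
    explained_ratio : numpy.ndarray
        Fraction of total training variance per component.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.components.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.components.shape[1])


def fit_pca(train_features: np.ndarray) -> PcaModel:
    """Fit the component basis on the training matrix (rows = beats).

    Raises
    ------
    FitError
        For fewer than 2 rows.
    DataError
        For non-finite entries.
    """
    X = np.asarray(train_features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise FitError(f"need at least 2 training rows, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise DataError("training features contain non-finite values")
    sk = _SkPCA(n_components=min(X.shape), svd_solver="full")
    sk.fit(X)
    return PcaModel(
        mean=sk.mean_.copy(),
        components=sk.components_.copy(),
        explained_ratio=sk.explained_variance_ratio_.copy(),
    )


def components_for_ratio(model: PcaModel, threshold: float) -> int:
    """Smallest k whose cumulative contributory ratio reaches ``threshold``.

    Raises
    ------
    SelectionError
        If the stored ratios cannot reach the threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cum = np.cumsum(model.explained_ratio)
    reached = np.nonzero(cum >= threshold - 1e-12)[0]
    if reached.size == 0:
        raise SelectionError(
            f"cumulative ratio tops out at {cum[-1]:.6f} < threshold {threshold}"
        )
    return int(reached[0]) + 1


def project(model: PcaModel, features: np.ndarray, k: int) -> np.ndarray:
    """Score the centered input against the first k components.

    Accepts a single vector or a matrix of row vectors.

    Raises
    ------
    ProjectionError
        On a feature-dimension mismatch or k beyond the stored basis.
    """
    X = np.asarray(features, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ProjectionError(
            f"feature length {X.shape[1]} != model dimension {model.n_features}"
        )
    if not 1 <= k <= model.n_components:
        raise ProjectionError(
            f"k={k} outside the stored basis (1..{model.n_components})"
        )
    scores = (X - model.mean) @ model.components[:k].T
    return scores[0] if single else scores


def reconstruct_from_scores(model: PcaModel, scores: np.ndarray) -> np.ndarray:
    """Map k-dimensional scores back to the original feature space."""
    S = np.asarray(scores, dtype=np.float64)
    single = S.ndim == 1
    if single:
        S = S[None, :]
    k = S.shape[1]
    X = S @ model.components[:k] + model.mean
    return X[0] if single else X


def save_model(model: PcaModel, path: str | Path) -> Path:
    """Persist the basis as a flat JSON text artifact."""
    path = Path(path)
    payload = {
        "format": "wavebeat-pca-v1",
        "mean": model.mean.tolist(),
        "components": model.components.tolist(),
        "explained_ratio": model.explained_ratio.tolist(),
    }
    path.write_text(json.dumps(payload))
    return path


def load_model(path: str | Path) -> PcaModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "wavebeat-pca-v1":
        raise FitError(f"{path} is not a saved component model")
    return PcaModel(
        mean=np.asarray(payload["mean"], dtype=np.float64),
        components=np.asarray(payload["components"], dtype=np.float64),
        explained_ratio=np.asarray(payload["explained_ratio"], dtype=np.float64),
    )
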