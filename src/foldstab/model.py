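"""Random-forest regression scoring function.

:class:`StabilityForest` is a scikit-learn style regressor (fit/predict,
``get_params``/``set_params``, trailing-underscore fitted attributes) around
an ensemble of 500 regression trees with 3 features considered per split —
the configuration the scoring function was designed with.  On top of the
sklearn surface it adds per-prediction feature contributions (tree-path
attribution: the change in node mean along each decision path is credited to
the split feature, so bias + contributions reproduces the prediction
exactly) and versioned persistence with self-describing metadata.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from .errors import ModelFormatError, SchemaError, ValidationError
from .features import FEATURE_NAMES

MODEL_FORMAT_VERSION = 1


@dataclass
class Prediction:
    """A single ddG prediction with its additive feature decomposition."""

    ddg_pred: float
    location: str | None = None
    bias: float = 0.0
    contributions: dict[str, float] = field(default_factory=dict)


class StabilityForest(BaseEstimator, RegressorMixin):
    """Random-forest ddG regressor.

    Parameters
    ----------
    n_trees : int
        Ensemble size (default 500).
    features_per_split : int
        Number of features sampled as split candidates at each node
        (default 3 of the 10 model features).
    min_leaf : int
        Minimum samples per leaf (default 5, the classic regression-forest
        default; the original description leaves this unspecified).
    seed : int
        Random state; the same seed reproduces the forest exactly.
    pssm_convention : str
        Recorded metadata describing how the PSSM feature was extracted,
        so persisted models are self-describing.
    """

    def __init__(
        self,
        n_trees: int = 500,
        features_per_split: int = 3,
        min_leaf: int = 5,
        seed: int = 0,
        pssm_convention: str = "diff",
    ):
        self.n_trees = n_trees
        self.features_per_split = features_per_split
        self.min_leaf = min_leaf
        self.seed = seed
        self.pssm_convention = pssm_convention

    # -- sklearn interface -------------------------------------------------

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X = self._to_matrix(X, fitting=True, feature_names=feature_names)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-dimensional")
        if len(X) != len(y):
            raise SchemaError(f"length mismatch: {len(X)} feature rows vs {len(y)} targets")
        if len(X) < 10:
            raise ValidationError("need at least 10 training samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValidationError("training data contains non-finite values")
        if not 1 <= self.features_per_split <= X.shape[1]:
            raise ValidationError("features_per_split must be in [1, n_features]")

        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=self.features_per_split,
            min_samples_leaf=self.min_leaf,
            random_state=self.seed,
            n_jobs=1,
        )
        self.forest_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        self.target_range_ = (float(y.min()), float(y.max()))
        self.fingerprint_ = hashlib.sha256(
            X.tobytes() + y.tobytes() + repr(self.get_params()).encode()
        ).hexdigest()
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict(self._to_matrix(X))

    @property
    def feature_importances_(self) -> np.ndarray:
        """Impurity-decrease importance per feature (non-negative, sums to 1)."""
        check_is_fitted(self, "forest_")
        return self.forest_.feature_importances_

    # -- attribution -------------------------------------------------------

    def feature_contributions(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Per-feature additive attribution of each prediction.

        Returns ``(bias, contributions)`` with ``contributions`` of shape
        (n_samples, n_features); ``bias + contributions.sum(axis=1)`` equals
        ``predict(X)`` up to floating-point accumulation.
        """
        check_is_fitted(self, "forest_")
        X = self._to_matrix(X)
        n, p = X.shape
        total = np.zeros((n, p))
        bias = 0.0
        for tree in self.forest_.estimators_:
            t = tree.tree_
            node_values = t.value[:, 0, 0]
            bias += node_values[0]
            paths = tree.decision_path(X).tocsr()
            for i in range(n):
                nodes = paths.indices[paths.indptr[i]:paths.indptr[i + 1]]
                for parent, child in zip(nodes[:-1], nodes[1:]):
                    total[i, t.feature[parent]] += node_values[child] - node_values[parent]
        k = len(self.forest_.estimators_)
        return bias / k, total / k

    def predict_one(self, features, location: str | None = None) -> Prediction:
        """Predict a single feature vector, returning the full decomposition."""
        row = np.asarray(
            features.to_array() if hasattr(features, "to_array") else features, dtype=float
        ).reshape(1, -1)
        bias, contrib = self.feature_contributions(row)
        ddg = float(self.predict(row)[0])
        return Prediction(
            ddg_pred=ddg,
            location=location,
            bias=float(bias),
            contributions=dict(zip(self.feature_names_, contrib[0].tolist())),
        )

    # -- helpers -----------------------------------------------------------

    def _to_matrix(self, X, fitting: bool = False, feature_names=None) -> np.ndarray:
        if hasattr(X, "columns"):  # DataFrame: enforce column identity/order
            cols = list(X.columns)
            if fitting:
                self.feature_names_ = cols if feature_names is None else list(feature_names)
            else:
                check_is_fitted(self, "forest_")
                if cols != self.feature_names_:
                    raise SchemaError(
                        f"feature names {cols} do not match the model's {self.feature_names_}"
                    )
            return np.asarray(X, dtype=float)
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr.reshape(1, -1)
        if fitting:
            self.feature_names_ = (
                list(feature_names)
                if feature_names is not None
                else (list(FEATURE_NAMES) if arr.shape[1] == len(FEATURE_NAMES)
                      else [f"f{i}" for i in range(arr.shape[1])])
            )
        elif arr.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"expected {self.n_features_in_} features, got {arr.shape[1]}"
            )
        return arr


def save_model(model: StabilityForest, path: str | Path) -> None:
    """Persist a fitted model (joblib payload + format version + metadata)."""
    check_is_fitted(model, "forest_")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": model.get_params(),
        "feature_names": model.feature_names_,
        "n_features_in": model.n_features_in_,
        "target_range": model.target_range_,
        "fingerprint": model.fingerprint_,
        "forest": model.forest_,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> StabilityForest:
    """Load a persisted model, verifying the format version."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFormatError(f"{path} is not a foldstab model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model format {payload['format_version']} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    model = StabilityForest(**payload["params"])
    model.forest_ = payload["forest"]
    model.feature_names_ = payload["feature_names"]
    model.n_features_in_ = payload["n_features_in"]
    model.target_range_ = tuple(payload["target_range"])
    model.fingerprint_ = payload["fingerprint"]
    return model


def train(X, y, **params) -> StabilityForest:
    """Thin functional wrapper: ``train(X, y, seed=1)`` == ``StabilityForest(seed=1).fit(X, y)``."""
    return StabilityForest(**params).fit(X, y)
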