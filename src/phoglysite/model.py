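"""Two-class polynomial-kernel SVM stage with a decision-score interface.

Defaults mirror the reference configuration: C-SVC with a polynomial
kernel, cost C = 1 and gamma = 1 (degree 3, coef0 = 0 exposed as knobs).
Features are z-score standardized by default, with the standardization
fit on the training partition only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC

from .io_formats import FeatureTable


@dataclass(frozen=True)
class ClassifierConfig:
    kernel: str = "poly"
    C: float = 1.0
    gamma: float = 1.0
    degree: int = 3
    coef0: float = 0.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kernel != "poly":
            raise ValueError("only the polynomial kernel is supported")
        if self.C <= 0 or self.gamma <= 0 or self.degree < 1:
            raise ValueError("C and gamma must be positive, degree >= 1")


@dataclass
class TrainedModel:
    svc: SVC
    n_features: int
    config: ClassifierConfig
    mean: np.ndarray | None  # standardization, fit on training data only
    scale: np.ndarray | None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got "
                f"{X.shape[1] if X.ndim == 2 else X.shape}"
            )
        if self.mean is None:
            return X
        return (X - self.mean) / self.scale

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def _as_xy(
    features: FeatureTable | np.ndarray, labels: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(features, FeatureTable):
        return features.X, features.labels
    if labels is None:
        raise ValueError("labels required when features is a plain array")
    return np.asarray(features, dtype=float), np.asarray(labels, dtype=int)


def train(
    features: FeatureTable | np.ndarray,
    labels: np.ndarray | None = None,
    config: ClassifierConfig | None = None,
) -> TrainedModel:
    """Fit the C-SVC.  Deterministic given identical input ordering."""
    config = config or ClassifierConfig()
    X, y = _as_xy(features, labels)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            f"training needs both classes; got only class {classes.tolist()}"
        )
    mean = scale = None
    if config.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale == 0.0, 1.0, scale)
        X = (X - mean) / scale
    svc = SVC(
        kernel="poly",
        C=config.C,
        gamma=config.gamma,
        degree=config.degree,
        coef0=config.coef0,
    )
    svc.fit(X, y)
    return TrainedModel(
        svc=svc,
        n_features=X.shape[1],
        config=config,
        mean=mean,
        scale=scale,
    )


def decision_scores(
    model: TrainedModel, features: FeatureTable | np.ndarray
) -> np.ndarray:
    """Signed distance to the separating surface; higher means more
    positive-class confidence."""
    X = features.X if isinstance(features, FeatureTable) else features
    return model.svc.decision_function(model._transform(X))


def predict(
    model: TrainedModel, features: FeatureTable | np.ndarray
) -> np.ndarray:
    """0/1 labels; 1 exactly where the decision score is >= 0."""
    return (decision_scores(model, features) >= 0.0).astype(int)
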