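"""Scikit-learn-style front end for the evolutionary graph-broad classifier.

``SaEGBLSClassifier`` bundles per-feature z-scoring (statistics from the
training data only), neighbour-graph construction, the self-adaptive DE
optimization of the node parameters, and thresholded prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import bls
from .errors import ValidationError
from .graphs import NeighborGraphSpec
from .sae import SaEConfig, SaEResult, run_sae


@dataclass
class Standardizer:
    """Per-feature z-scoring with a guarded divide.

    Zero-variance features get scale 1, so a constant feature standardizes
    to all zeros instead of NaN.
    """

    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValidationError("standardizer has not been fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


@dataclass
class SaEGBLSClassifier:
    """Binary (or multiclass) classifier trained by self-adaptive DE.

    Parameters mirror the three configuration blocks: the broad-learning
    architecture, the neighbour-graph regularizer, and the DE run. ``seed``
    overrides ``sae.seed`` when given, so cross-validation can reseed each
    fold without rebuilding configs.
    """

    architecture: bls.BLSArchitecture = field(default_factory=bls.BLSArchitecture)
    graph: NeighborGraphSpec = field(default_factory=NeighborGraphSpec)
    sae: SaEConfig = field(default_factory=SaEConfig)
    threshold: float = 0.5
    standardize: bool = True
    seed: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SaEGBLSClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int).ravel()
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValidationError("training labels must contain at least two classes")
        self.scaler_ = Standardizer().fit(X) if self.standardize else None
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else X
        cfg = self.sae if self.seed is None else replace(self.sae, seed=self.seed)
        result: SaEResult = run_sae(cfg, Xs, y, self.architecture, self.graph)
        self.result_ = result
        self.model_ = result.model
        self.trace_ = result.trace
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else np.asarray(X)
        scores, _ = bls.predict(self.model_, Xs, threshold=self.threshold)
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else np.asarray(X)
        _, idx = bls.predict(self.model_, Xs, threshold=self.threshold)
        return self.classes_[idx]
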