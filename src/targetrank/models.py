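"""Classifier construction and training with a uniform train/predict contract.

The primary classifier is a small dense network (see :mod:`targetrank.nn`);
random forest, gradient boosting and SVM baselines expose the same
``fit`` / ``predict_scores`` surface so the evaluation protocols are
classifier-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FeatureBlock
from .nn import DenseNetwork

VALID_KINDS = ("dnn", "random_forest", "gradient_boosting", "svm")


@dataclass
class ClassifierConfig:
    """Hyperparameters of the classifier.

    Defaults follow the selected grid point for the dense network: two tanh
    hidden layers of 64 and 32 units, Nadam at learning rate 0.01, batch
    size 16, 30 epochs, binary cross-entropy with L2 on the hidden layers'
    weights and biases.  ``epochs=100`` is the full-data retraining setting
    used before ranking unlabeled genes.
    """

    kind: str = "dnn"
    hidden_sizes: tuple[int, ...] = (64, 32)
    activation: str = "tanh"
    learning_rate: float = 0.01
    batch_size: int = 16
    epochs: int = 30
    l2: float = 1e-3
    init_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(
                f"unknown classifier kind {self.kind!r}; valid kinds: {VALID_KINDS}"
            )
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs and batch_size must be >= 1, learning_rate > 0")

    def with_seed(self, seed: int) -> "ClassifierConfig":
        return ClassifierConfig(**{**asdict(self), "seed": int(seed)})


class SklearnStyleModel:
    """Adapter giving library classifiers the dense-network contract."""

    def __init__(self, estimator, input_dim: int):
        self.estimator = estimator
        self.input_dim = int(input_dim)

    def fit(self, X, y):
        self.estimator.fit(np.asarray(X), np.asarray(y).ravel().astype(int))
        return self

    def predict_scores(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(
                f"model expects {self.input_dim}-dimensional input, got shape {X.shape}"
            )
        return self.estimator.predict_proba(X)[:, 1]


Model = Union[DenseNetwork, SklearnStyleModel]


def build_classifier(config: ClassifierConfig, input_dim: int) -> Model:
    """Instantiate an untrained classifier of the configured kind."""
    if input_dim < 1:
        raise ValueError("input_dim must be positive")
    if config.kind == "dnn":
        return DenseNetwork(
            input_dim=input_dim,
            hidden_sizes=config.hidden_sizes,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            epochs=config.epochs,
            l2=config.l2,
            init_scale=config.init_scale,
            seed=config.seed,
        )
    if config.kind == "random_forest":
        return SklearnStyleModel(
            RandomForestClassifier(random_state=config.seed), input_dim
        )
    if config.kind == "gradient_boosting":
        return SklearnStyleModel(
            XGBClassifier(random_state=config.seed, eval_metric="logloss"),
            input_dim,
        )
    if config.kind == "svm":
        return SklearnStyleModel(
            SVC(probability=True, random_state=config.seed), input_dim
        )
    raise ValueError(f"unknown classifier kind {config.kind!r}")


@dataclass
class TrainedModel:
    """A fitted classifier with its provenance manifest."""

    model: Model
    config: ClassifierConfig
    feature_dimension: int
    n_samples: int
    class_counts: tuple[int, int]  # (negatives, positives)

    def predict_scores(self, features: Union[FeatureBlock, np.ndarray]) -> np.ndarray:
        X = features.matrix if isinstance(features, FeatureBlock) else np.asarray(features)
        if X.shape[1] != self.feature_dimension:
            raise ValueError(
                f"feature dimension mismatch: model trained on "
                f"{self.feature_dimension}, input has {X.shape[1]}"
            )
        return self.model.predict_scores(X)

    def save(self, directory: Path | str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if not isinstance(self.model, DenseNetwork):
            raise NotImplementedError("persistence is implemented for the dnn kind")
        self.model.save(directory / "network")
        manifest = {
            "config": asdict(self.config),
            "feature_dimension": self.feature_dimension,
            "n_samples": self.n_samples,
            "class_counts": list(self.class_counts),
        }
        (directory / "model.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: Path | str) -> "TrainedModel":
        directory = Path(directory)
        manifest = json.loads((directory / "model.json").read_text())
        cfg = manifest["config"]
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        return cls(
            model=DenseNetwork.load(directory / "network"),
            config=ClassifierConfig(**cfg),
            feature_dimension=manifest["feature_dimension"],
            n_samples=manifest["n_samples"],
            class_counts=tuple(manifest["class_counts"]),
        )


def train(
    features: Union[FeatureBlock, np.ndarray],
    labels,
    config: Optional[ClassifierConfig] = None,
) -> TrainedModel:
    """Fit a classifier on a labeled feature matrix.

    Raises on single-class label vectors (a degenerate training set) and on
    a row-count mismatch.  Deterministic given ``config.seed``.
    """
    config = config or ClassifierConfig()
    X = features.matrix if isinstance(features, FeatureBlock) else np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).ravel().astype(int)
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"{X.shape[0]} feature rows but {y.shape[0]} labels"
        )
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("degenerate training set: only one class present")
    model = build_classifier(config, X.shape[1])
    model.fit(X, y)
    count_map = dict(zip(classes.tolist(), counts.tolist()))
    return TrainedModel(
        model=model,
        config=config,
        feature_dimension=X.shape[1],
        n_samples=X.shape[0],
        class_counts=(count_map.get(0, 0), count_map.get(1, 0)),
    )


def predict_scores(model: TrainedModel, features: Union[FeatureBlock, np.ndarray]) -> np.ndarray:
    """Prediction probabilities in [0, 1], one per feature row."""
    return model.predict_scores(features)
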