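"""Supervised decoy selection: lRMSD regression on learned features.

Featurizations are judged by how well simple supervised models predict a
decoy's lRMSD from the (withheld) native structure.  Two predictors are
compared: ordinary least-squares linear regression (closed form) and a
single-layer perceptron with sigmoid output trained by full-batch gradient
descent on squared error.  lRMSDs are scaled into [0, 1] by the maximum
training-set lRMSD so the sigmoid's range covers the targets; test labels
exceeding the training maximum clip to 1 (with a logged count).

Regimes mirror a multi-target benchmark: one model per difficulty category
(easy/medium/hard), trained on roughly 2/3 of that category's targets and
tested on the held-out rest, plus a combined regime pooling all categories.
Features for each target come from a featurizer trained per target under
the same protocol as the model search; per-target latent orientations are
not aligned across targets (the literal reading of per-dataset training),
which is a documented limitation of the cross-target setting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, InvalidSpecError, ShapeError

logger = logging.getLogger(__name__)

__all__ = [
    "LabelScaler",
    "RegressionModel",
    "RegimeSpec",
    "scale_labels",
    "fit_predictor",
    "evaluate_predictor",
    "run_regime",
]

PREDICTOR_KINDS = ("linear", "perceptron_sigmoid")


@dataclass
class LabelScaler:
    """Scale lRMSDs (Å) into [0, 1] by the training-set maximum."""

    train_max: float

    def __post_init__(self) -> None:
        if self.train_max <= 0:
            raise InvalidSpecError("train_max must be positive")

    def transform(self, labels: np.ndarray, clip: bool = True) -> np.ndarray:
        scaled = np.asarray(labels, dtype=float) / self.train_max
        n_over = int((scaled > 1.0).sum())
        if n_over and clip:
            logger.warning(
                "%d labels exceed the training maximum %.3g A; clipped to 1",
                n_over,
                self.train_max,
            )
            scaled = np.clip(scaled, 0.0, 1.0)
        return scaled

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        return np.asarray(scaled, dtype=float) * self.train_max


def scale_labels(labels: np.ndarray, train_max: float) -> tuple[np.ndarray, LabelScaler]:
    """Scaled labels plus the scaler recorded for inversion."""
    scaler = LabelScaler(train_max)
    return scaler.transform(labels), scaler


@dataclass
class RegressionModel:
    """A fitted predictor: (k+1)-weight vector including the intercept.

    Features are standardized internally by the training mean and standard
    deviation (stored on the model), so gradient training is insensitive to
    the arbitrary scale of a featurization; the weights act on standardized
    features.
    """

    kind: str
    weights: np.ndarray
    feature_mean: np.ndarray = None
    feature_scale: np.ndarray = None
    metadata: dict = field(default_factory=dict)

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] + 1 != self.weights.shape[0]:
            raise ShapeError(
                f"features have {X.shape[1]} columns; model expects "
                f"{self.weights.shape[0] - 1}"
            )
        if self.feature_mean is not None:
            X = (X - self.feature_mean) / self.feature_scale
        z = X @ self.weights[1:] + self.weights[0]
        return expit(z) if self.kind == "perceptron_sigmoid" else z


def fit_predictor(
    features: np.ndarray,
    labels: np.ndarray,
    kind: str = "linear",
    epochs: int = 5000,
    learning_rate: float = 0.1,
    seed: int = 0,
) -> RegressionModel:
    """Fit a linear or sigmoid-perceptron lRMSD predictor.

    Linear: closed-form least squares (minimum-norm solution with a warning
    when the design is rank deficient).  Perceptron: affine map + sigmoid,
    full-batch gradient descent on mean squared error for a fixed epoch
    budget under ``seed``.  Labels are expected already scaled to [0, 1]
    for the perceptron.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float)
    m, k = X.shape
    if y.shape != (m,):
        raise ShapeError(f"labels shape {y.shape} does not match {m} feature rows")
    if m <= k:
        raise InvalidSpecError(f"need more samples ({m}) than features ({k})")
    if kind not in PREDICTOR_KINDS:
        raise InvalidSpecError(f"kind must be one of {PREDICTOR_KINDS}")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    Xs = (X - mean) / scale
    design = np.column_stack([np.ones(m), Xs])
    if kind == "linear":
        w, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            warnings.warn(
                "rank-deficient design; returning the minimum-norm solution",
                stacklevel=2,
            )
        return RegressionModel(kind=kind, weights=w, feature_mean=mean, feature_scale=scale)

    rng = np.random.default_rng(seed)
    w = rng.normal(scale=0.01, size=k + 1)
    for _ in range(epochs):
        z = design @ w
        p = expit(z)
        grad = design.T @ ((p - y) * p * (1.0 - p)) * (2.0 / m)
        w -= learning_rate * grad
    return RegressionModel(
        kind=kind,
        weights=w,
        feature_mean=mean,
        feature_scale=scale,
        metadata={"epochs": epochs, "learning_rate": learning_rate, "seed": seed},
    )


def evaluate_predictor(
    model: RegressionModel, features: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """MSE (scaled units²) and explained variance of a predictor.

    ``explained_variance = 1 - Var(residual) / Var(label)``; with zero label
    variance it is undefined and reported as NaN with a warning.
    """
    y = np.asarray(labels, dtype=float)
    pred = model.predict(features)
    if pred.shape != y.shape:
        raise ShapeError("prediction and label shapes differ")
    mse = float(((pred - y) ** 2).mean())
    label_var = float(y.var())
    if label_var == 0.0:
        warnings.warn("zero label variance; explained variance undefined", stacklevel=2)
        return mse, float("nan")
    ev = 1.0 - float((y - pred).var()) / label_var
    return mse, ev


@dataclass
class RegimeSpec:
    """One train/test regime over featurized targets.

    ``grouping`` names the difficulty category (or 'combined');
    ``train_targets`` and ``test_targets`` are disjoint, nonempty target-id
    lists; ``feature_method`` and ``feature_dim`` record provenance of the
    features being evaluated.
    """

    grouping: str
    train_targets: tuple[str, ...]
    test_targets: tuple[str, ...]
    feature_method: str = "pca"
    feature_dim: int = 2

    def __post_init__(self) -> None:
        if self.grouping not in ("easy", "medium", "hard", "combined"):
            raise InvalidSpecError(f"unknown grouping {self.grouping!r}")
        if not self.train_targets or not self.test_targets:
            raise ConfigurationError("train and test target lists must be nonempty")
        overlap = set(self.train_targets) & set(self.test_targets)
        if overlap:
            raise ConfigurationError(
                f"train/test target lists overlap: {sorted(overlap)}"
            )


def run_regime(
    regime: RegimeSpec,
    featurized: dict[str, tuple[np.ndarray, np.ndarray]],
    seed: int = 0,
) -> pd.DataFrame:
    """Fit and evaluate both predictor kinds under one regime.

    ``featurized`` maps target id to ``(features, lrmsd_labels_in_A)``;
    features of training targets are concatenated, labels scaled by the
    training maximum, both predictors fit, and both evaluated on the pooled
    held-out targets.  Returns one row per predictor kind with MSE and
    explained variance on the scaled labels.
    """
    for tid in (*regime.train_targets, *regime.test_targets):
        if tid not in featurized:
            raise ConfigurationError(f"no features available for target {tid!r}")
        X, y = featurized[tid]
        if np.atleast_2d(X).shape[1] != regime.feature_dim:
            raise ConfigurationError(
                f"target {tid!r} features have dim "
                f"{np.atleast_2d(X).shape[1]}, regime expects {regime.feature_dim}"
            )

    def pool(targets):
        Xs, ys = zip(*(featurized[t] for t in targets))
        return np.vstack(Xs), np.concatenate(ys)

    X_train, y_train = pool(regime.train_targets)
    X_test, y_test = pool(regime.test_targets)
    y_train_scaled, scaler = scale_labels(y_train, float(y_train.max()))
    y_test_scaled = scaler.transform(y_test)

    rows = []
    for kind in PREDICTOR_KINDS:
        model = fit_predictor(X_train, y_train_scaled, kind=kind, seed=seed)
        mse, ev = evaluate_predictor(model, X_test, y_test_scaled)
        rows.append(
            dict(
                grouping=regime.grouping,
                feature_method=regime.feature_method,
                feature_dim=regime.feature_dim,
                predictor=kind,
                mse=mse,
                explained_variance=ev,
                n_train=len(y_train),
                n_test=len(y_test),
            )
        )
    return pd.DataFrame(rows)
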