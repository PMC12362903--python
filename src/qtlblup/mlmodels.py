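"""Random-forest and support-vector-regression baselines.

Both models treat phenotypes as the target and raw 0/1/2 dosages as features
(no standardisation), and are evaluated exactly like GBLUP: their test-set
predictions stand in for GEBV.  Hyperparameters follow the study settings
(RF: 1,500 trees, 2,500 candidate features per split; SVR: radial-basis
kernel with C = 1); everything unlisted stays at scikit-learn defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR

__all__ = ["MLConfig", "MLFit", "fit_predict_rf", "fit_predict_svr"]


@dataclass(frozen=True)
class MLConfig:
    """Hyperparameters for the machine-learning baselines."""

    model: str  # "rf" or "svr"
    n_estimators: int = 1500
    max_features: int = 2500
    C: float = 1.0
    kernel: str = "rbf"
    gamma: str | float = "scale"
    seed: int = 0

    @classmethod
    def default_rf(cls, seed: int = 0) -> "MLConfig":
        return cls(model="rf", n_estimators=1500, max_features=2500, seed=seed)

    @classmethod
    def default_svr(cls) -> "MLConfig":
        return cls(model="svr", kernel="rbf", C=1.0)

    def with_seed(self, seed: int) -> "MLConfig":
        return replace(self, seed=seed)


@dataclass
class MLFit:
    """A trained estimator with predictions aligned to animal order."""

    model: str
    estimator: object
    train_pred: np.ndarray
    test_pred: np.ndarray

    @property
    def feature_importances(self) -> np.ndarray:
        return self.estimator.feature_importances_


def _check(X_train, y, X_test):
    X_train = np.asarray(X_train, dtype=np.float64)
    X_test = np.asarray(X_test, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train and test feature columns must match")
    if X_train.shape[0] != len(y):
        raise ValueError("y must have one entry per training animal")
    return X_train, y, X_test


def fit_predict_rf(X_train, y, X_test, cfg: MLConfig) -> MLFit:
    """Random forest regression; rejects max_features above the feature count."""
    X_train, y, X_test = _check(X_train, y, X_test)
    if cfg.max_features > X_train.shape[1]:
        raise ValueError(
            f"max_features={cfg.max_features} exceeds the {X_train.shape[1]} "
            "available features"
        )
    est = RandomForestRegressor(
        n_estimators=cfg.n_estimators,
        max_features=cfg.max_features,
        random_state=cfg.seed,
        n_jobs=1,
    )
    est.fit(X_train, y)
    return MLFit("RF", est, est.predict(X_train), est.predict(X_test))


def fit_predict_svr(X_train, y, X_test, cfg: MLConfig) -> MLFit:
    """Epsilon-insensitive SVR with a radial-basis (or configured) kernel."""
    X_train, y, X_test = _check(X_train, y, X_test)
    est = SVR(kernel=cfg.kernel, C=cfg.C, gamma=cfg.gamma)
    est.fit(X_train, y)
    return MLFit("SVR", est, est.predict(X_train), est.predict(X_test))
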