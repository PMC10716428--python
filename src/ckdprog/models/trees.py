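"""Snapshot baselines: random forest and gradient-boosted trees.

Both are trained on each patient's latest feature vector (time feature
included) rather than the full sequence.  Random forest merges the training
and validation folds (no tuning is needed); the boosted model uses the
validation fold for early stopping of boosting rounds.
"""

from __future__ import annotations

import numpy as np
from lightgbm import LGBMClassifier, early_stopping
from sklearn.ensemble import RandomForestClassifier


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")


class RandomForestModel:
    """Random forest on the latest feature vector."""

    kind = "random_forest"

    def __init__(self, n_estimators: int = 300, seed: int = 0):
        self.model = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForestModel":
        y = np.asarray(y, dtype=int)
        _check_two_classes(y)
        self.model.fit(np.asarray(X, dtype=float), y)
        return self

    def score(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X, dtype=float))[:, 1]


class GBDTModel:
    """LightGBM classifier with validation-fold early stopping."""

    kind = "gbdt"

    def __init__(self, n_estimators: int = 500, learning_rate: float = 0.05,
                 early_stopping_rounds: int = 20, seed: int = 0):
        self.early_stopping_rounds = early_stopping_rounds
        self.model = LGBMClassifier(
            n_estimators=n_estimators,
            learning_rate=learning_rate,
            random_state=seed,
            n_jobs=1,
            deterministic=True,
            force_row_wise=True,
            verbosity=-1,
        )

    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray, y_val: np.ndarray) -> "GBDTModel":
        y = np.asarray(y, dtype=int)
        _check_two_classes(y)
        self.model.fit(
            np.asarray(X, dtype=float), y,
            eval_set=[(np.asarray(X_val, dtype=float), np.asarray(y_val, dtype=int))],
            callbacks=[early_stopping(self.early_stopping_rounds, verbose=False)],
        )
        return self

    def score(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X, dtype=float))[:, 1]
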