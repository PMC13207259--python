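"""Pluggable gradient-boosted learner behind a minimal contract.

The feature-selection pipeline only needs three capabilities — fit,
probability prediction, and per-feature importances — so the learner is a
pluggable component.  The default is a LightGBM gradient-boosted tree
ensemble configured for single-thread determinism; any object satisfying
:class:`LearnerContract` (including cheap stubs in tests) slots in.
"""

from __future__ import annotations

import warnings
from typing import Protocol, runtime_checkable

import numpy as np
from lightgbm import LGBMClassifier


@runtime_checkable
class LearnerContract(Protocol):
    def fit(self, features: np.ndarray, labels: np.ndarray) -> "LearnerContract": ...

    def predict_probability(self, features: np.ndarray) -> np.ndarray: ...

    def feature_importance(self) -> np.ndarray: ...


class BoostedTreesLearner:
    """Gradient-boosted decision trees (LightGBM backend).

    Hyperparameters mirror the tuning axes of the selection grid: learning
    rate, tree depth, number of boosting rounds, and L2 regularization.
    Deterministic under a fixed seed (single-threaded, deterministic mode).
    """

    def __init__(
        self,
        learning_rate: float = 0.1,
        max_depth: int = 4,
        n_estimators: int = 100,
        reg_lambda: float = 1.0,
        seed: int = 0,
    ):
        self.params = dict(
            learning_rate=learning_rate,
            max_depth=max_depth,
            n_estimators=n_estimators,
            reg_lambda=reg_lambda,
        )
        self.seed = seed
        self._model: LGBMClassifier | None = None

    def _make(self) -> LGBMClassifier:
        return LGBMClassifier(
            **self.params,
            num_leaves=2 ** min(self.params["max_depth"], 6),
            random_state=self.seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbosity=-1,
            min_child_samples=10,
        )

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "BoostedTreesLearner":
        self._model = self._make()
        self._model.fit(np.asarray(features, dtype=np.float32),
                        np.asarray(labels, dtype=int))
        return self

    def predict_probability(self, features: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("learner is not fitted")
        with warnings.catch_warnings():
            # the backend invents feature names for plain arrays at fit time
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names"
            )
            return self._model.predict_proba(
                np.asarray(features, dtype=np.float32)
            )[:, 1]

    def feature_importance(self) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("learner is not fitted")
        return self._model.booster_.feature_importance(
            importance_type="gain"
        ).astype(float)


def boosted_trees_factory(params: dict | None = None):
    """Factory of seeded learners for one hyperparameter configuration."""
    params = dict(params or {})

    def make(seed: int) -> BoostedTreesLearner:
        return BoostedTreesLearner(seed=seed, **params)

    return make
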