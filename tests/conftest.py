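import numpy as np
import pandas as pd
import pytest

from tedclaims.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort, small enough for fast module tests."""
    return generate_cohort(CohortConfig(n_patients=3000, seed=11))


class StubLearner:
    """Cheap deterministic learner for pipeline-logic tests.

    Scores are a correlation-weighted vote over features; importance is the
    absolute point-biserial correlation of each feature with the labels.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed
        self.w = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        xc = X - X.mean(axis=0)
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum()) + 1e-12
        self.w = (xc * yc[:, None]).sum(axis=0) / denom
        return self

    def predict_probability(self, X):
        score = np.asarray(X, dtype=float) @ self.w
        lo, hi = score.min(), score.max()
        if hi - lo < 1e-12:
            return np.full(len(score), 0.5)
        return (score - lo) / (hi - lo)

    def feature_importance(self):
        return np.abs(self.w)


@pytest.fixture
def stub_factory():
    def factory_for_config(params=None):
        def make(seed):
            return StubLearner(seed)

        return make

    return factory_for_config


def planted_signal_matrix(
    n: int, seed: int, n_informative: int = 2, n_noise: int = 48,
    rate_pos: float = 0.6, rate_neg: float = 0.1,
):
    """Binary features with a known informative subset.

    Informative features occur at ``rate_pos`` in cases vs ``rate_neg`` in
    controls; noise features are class-independent.
    """
    rng = np.random.default_rng(seed)
    y = rng.random(n) < 0.5
    cols = {}
    for i in range(n_informative):
        cols[f"ICD-10-CM:SIG{i}"] = np.where(
            y, rng.random(n) < rate_pos, rng.random(n) < rate_neg
        )
    for i in range(n_noise):
        cols[f"CPT:NOISE{i:03d}"] = rng.random(n) < 0.2
    X = pd.DataFrame(cols, index=[f"P{i:05d}" for i in range(n)]).astype(np.int8)
    X.index.name = "patient_id"
    return X, pd.Series(y, index=X.index)
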