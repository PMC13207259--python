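"""Machine-learning feature pipeline: binary code indicators over a baseline
window, prevalence screening, expert-list merge, utilization-code exclusion,
recursive feature elimination (RFE) under stratified cross-validation across
a hyperparameter grid, consensus feature ranking, and a simplified
small-tree model over the consensus codes.

Leakage hygiene: screening statistics, RFE, consensus and fitting see only
training rows; the evaluation entry point refuses overlapping train/test
patient sets.  The whole pipeline is bit-reproducible under one base seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .codes import DIAGNOSIS_PROCEDURE_SYSTEMS, normalize_code
from .errors import ConfigurationError, InputError, LeakageError
from .learners import LearnerContract, boosted_trees_factory
from .metrics import ThresholdGrid, auc as auc_of, threshold_sweep

#: Default tuning grid: 3 values on each of 4 axes -> 81 configurations.
DEFAULT_GRID = {
    "learning_rate": [0.03, 0.1, 0.3],
    "max_depth": [2, 4, 6],
    "n_estimators": [50, 100, 200],
    "reg_lambda": [0.0, 1.0, 10.0],
}


@dataclass
class MLConfig:
    baseline_days: int = 730
    screen_threshold: float = 0.001       # 0.1% in BOTH classes
    excluded_icd_chapters: frozenset[str] = frozenset({"X", "Y", "Z"})
    n_folds: int = 5
    grid: dict[str, list] = field(default_factory=lambda: dict(DEFAULT_GRID))
    rfe_drop_fraction: float = 0.2
    rfe_min_improvement: float = 1e-4
    rfe_patience: int = 2                 # consecutive non-improving iterations
    rfe_feature_cap: int = 201
    consensus_k: int = 29
    simplified_trees: int = 10
    thresholds: ThresholdGrid = field(default_factory=ThresholdGrid)
    seed: int = 0

    def __post_init__(self):
        if self.consensus_k > self.rfe_feature_cap:
            raise ConfigurationError("consensus_k must be <= rfe_feature_cap")
        if not 0.0 < self.rfe_drop_fraction < 1.0:
            raise ConfigurationError("rfe_drop_fraction must lie in (0, 1)")

    @property
    def grid_configurations(self) -> list[dict]:
        keys = sorted(self.grid)
        return [
            dict(zip(keys, values))
            for values in itertools.product(*(self.grid[k] for k in keys))
        ]


@dataclass
class FeatureSelectionTrace:
    """Record of one RFE run: per-iteration feature sets and CV AUCs."""

    config: dict
    seed: int
    iterations: list[dict] = field(default_factory=list)  # iteration, features, cv_auc
    selected: list[str] = field(default_factory=list)
    selected_auc: float = float("nan")
    final_importance: dict[str, float] = field(default_factory=dict)


def build_feature_matrix(
    claims: pd.DataFrame,
    patients: pd.DataFrame,
    baseline_days: int = 730,
) -> pd.DataFrame:
    """Binary patient x code indicator matrix over the baseline window.

    An entry is 1 iff the patient has >= 1 claim with the code in
    [index - baseline_days, index] (index day included).  Diagnosis and
    procedure systems only; drug (NDC) codes are not features.  Columns are
    ``system:normalized_code`` keys, deduplicated after normalization.
    """
    pidx = patients.set_index("patient_id")["index_day"]
    sub = claims.loc[claims["system"].isin(DIAGNOSIS_PROCEDURE_SYSTEMS)].copy()
    sub = sub.loc[sub["patient_id"].isin(pidx.index)]
    idx = sub["patient_id"].map(pidx)
    delta = sub["service_day"] - idx
    sub = sub.loc[(delta >= -baseline_days) & (delta <= 0)]
    keys = [
        f"{s}:{normalize_code(c, s)}"
        for c, s in zip(sub["code"], sub["system"])
    ]
    sub = sub.assign(key=keys)
    mat = (
        pd.crosstab(sub["patient_id"], sub["key"]) > 0
    ).astype(np.int8)
    mat = mat.reindex(index=patients["patient_id"], fill_value=0)
    mat.index.name = "patient_id"
    return mat.sort_index(axis=1)


def prevalence_screen(
    matrix: pd.DataFrame, labels: pd.Series | np.ndarray, threshold: float = 0.001
) -> list[str]:
    """Columns whose prevalence is >= threshold in BOTH classes."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise InputError("prevalence screening needs both classes present")
    mean_pos = matrix.loc[y].mean(axis=0)
    mean_neg = matrix.loc[~y].mean(axis=0)
    keep = (mean_pos >= threshold) & (mean_neg >= threshold)
    return matrix.columns[keep].tolist()


def merge_expert_list(
    retained: list[str], expert: list[str]
) -> tuple[list[str], dict[str, int]]:
    """Union of data-driven and expert-curated code columns.

    Returns the merged (sorted) column list and the bookkeeping counts:
    data-driven, expert-only, overlap, final.
    """
    r, e = set(retained), set(expert)
    merged = sorted(r | e)
    counts = {
        "data_driven": len(r),
        "expert": len(e),
        "overlap": len(r & e),
        "expert_only": len(e - r),
        "final": len(merged),
    }
    return merged, counts


def exclude_utilization_codes(
    columns: list[str], chapters: frozenset[str] | set[str] = frozenset({"X", "Y", "Z"})
) -> list[str]:
    """Drop ICD-10 columns in the configured letter chapters.

    X/Y (external causes) and Z (factors influencing health status) codes
    reflect utilization or external events rather than disease; procedure
    and ICD-9 columns pass through untouched.
    """
    out = []
    for col in columns:
        system, code = col.split(":", 1)
        if system == "ICD-10-CM" and code[:1].upper() in chapters:
            continue
        out.append(col)
    return out


def _cv_auc(
    X: np.ndarray, y: np.ndarray, factory, n_folds: int, seed: int
) -> float:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise InputError("degenerate fold: a class is missing")
        learner = factory(seed + k)
        learner.fit(X[tr], y[tr])
        aucs.append(auc_of(learner.predict_probability(X[te]), y[te]))
    return float(np.mean(aucs))


def rfe_select(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    factory,
    config: MLConfig,
    seed: int | None = None,
    learner_config: dict | None = None,
) -> FeatureSelectionTrace:
    """Recursive feature elimination with cross-validated AUC.

    Each iteration measures the current feature set's stratified-CV AUC,
    refits on all rows for importances, and drops the lowest-importance
    ``rfe_drop_fraction`` of features (at least one).  Elimination stops
    after ``rfe_patience`` consecutive iterations without an AUC gain above
    ``rfe_min_improvement`` (or when < 2 features remain); the selected set
    is the argmax-AUC iterate, hard-capped at ``rfe_feature_cap`` features
    by final importance.
    """
    if matrix.shape[1] < 2:
        raise InputError("need at least 2 features for elimination")
    seed = config.seed if seed is None else seed
    y = np.asarray(labels, dtype=int)
    features = list(matrix.columns)
    trace = FeatureSelectionTrace(config=dict(learner_config or {}), seed=seed)

    best_auc, stall = -np.inf, 0
    importance_by_feature: dict[str, float] = {}
    iteration = 0
    while True:
        X = matrix[features].to_numpy(dtype=np.float32)
        cv = _cv_auc(X, y, factory, config.n_folds, seed)
        full = factory(seed).fit(X, y)
        imp = np.asarray(full.feature_importance(), dtype=float)
        importance_by_feature = dict(zip(features, imp))
        trace.iterations.append(
            {"iteration": iteration, "features": tuple(features), "cv_auc": cv}
        )
        if cv > best_auc + config.rfe_min_improvement:
            best_auc, stall = cv, 0
        else:
            stall += 1
        if stall >= config.rfe_patience or len(features) < 2:
            break
        n_drop = max(1, int(config.rfe_drop_fraction * len(features)))
        n_drop = min(n_drop, len(features) - 1)
        # deterministic tie-break: importance, then reverse-lexicographic key
        order = sorted(features, key=lambda f: (importance_by_feature[f], f))
        drop = set(order[:n_drop])
        features = [f for f in features if f not in drop]
        iteration += 1

    best = max(trace.iterations, key=lambda rec: rec["cv_auc"])
    selected = list(best["features"])
    if len(selected) > config.rfe_feature_cap:
        # hard cap: keep the top features by their importance at that iterate
        X = matrix[selected].to_numpy(dtype=np.float32)
        imp = np.asarray(factory(seed).fit(X, y).feature_importance(), dtype=float)
        ranked = sorted(
            zip(selected, imp), key=lambda t: (-t[1], t[0])
        )[: config.rfe_feature_cap]
        selected = [f for f, _ in ranked]
    trace.selected = selected
    trace.selected_auc = float(best["cv_auc"])
    trace.final_importance = importance_by_feature
    return trace


def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic per-configuration seed below 2**31."""
    return int((base_seed * 1_000_003 + 7919 * (index + 1)) % (2**31 - 1))


def run_grid(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    factory_for_config=boosted_trees_factory,
    config: MLConfig | None = None,
) -> list[FeatureSelectionTrace]:
    """One RFE trace per hyperparameter configuration (81 by default)."""
    config = config or MLConfig()
    traces = []
    for i, params in enumerate(config.grid_configurations):
        factory = factory_for_config(params)
        traces.append(
            rfe_select(
                matrix, labels, factory, config,
                seed=derive_seed(config.seed, i), learner_config=params,
            )
        )
    return traces


def consensus_features(
    traces: list[FeatureSelectionTrace], k: int
) -> pd.DataFrame:
    """Codes ranked by cross-run consensus.

    Ranking key: selection frequency across traces, then mean importance
    among traces that selected the code, then the code key itself as a
    deterministic final tie-break.  Returns the top k rows (all, with a
    warning, when the pool is smaller).
    """
    if not traces:
        raise InputError("need at least one trace")
    freq: dict[str, int] = {}
    imp: dict[str, list[float]] = {}
    for tr in traces:
        sel = set(tr.selected)
        for f in sel:
            freq[f] = freq.get(f, 0) + 1
            imp.setdefault(f, []).append(tr.final_importance.get(f, 0.0))
    rows = [
        {
            "feature": f,
            "selection_count": c,
            "selection_frequency": c / len(traces),
            "mean_importance": float(np.mean(imp[f])),
        }
        for f, c in freq.items()
    ]
    ranked = pd.DataFrame(rows).sort_values(
        ["selection_count", "mean_importance", "feature"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    if k > len(ranked):
        warnings.warn(
            f"requested k={k} consensus codes but only {len(ranked)} candidates"
        )
    return ranked.head(k)


def train_simplified(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    consensus: list[str],
    trees: int = 10,
    factory_for_config=boosted_trees_factory,
    learner_params: dict | None = None,
    seed: int = 0,
):
    """Small interpretable model over the consensus codes only.

    Boosting rounds equal ``trees``; returns (fitted learner, column list).
    Predictions depend only on the consensus columns.
    """
    if not consensus:
        raise InputError("consensus code list is empty")
    params = dict(learner_params or {})
    params["n_estimators"] = trees
    learner = factory_for_config(params)(seed)
    X = matrix[list(consensus)].to_numpy(dtype=np.float32)
    learner.fit(X, np.asarray(labels, dtype=int))
    return learner, list(consensus)


def evaluate_model(
    model: LearnerContract,
    feature_columns: list[str],
    test_matrix: pd.DataFrame,
    test_labels: pd.Series | np.ndarray,
    thresholds: ThresholdGrid = ThresholdGrid(),
    prevalence: float | None = None,
    train_ids: set[str] | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Threshold-sweep report plus AUC on held-out patients.

    Raises :class:`LeakageError` when the test matrix contains any training
    patient id.
    """
    if train_ids is not None:
        overlap = set(test_matrix.index) & set(train_ids)
        if overlap:
            raise LeakageError(
                f"{len(overlap)} patient(s) appear in both train and test sets"
            )
    X = test_matrix[list(feature_columns)].to_numpy(dtype=np.float32)
    probs = model.predict_probability(X)
    report = threshold_sweep(probs, test_labels, thresholds, prevalence=prevalence)
    return report, auc_of(probs, test_labels)
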