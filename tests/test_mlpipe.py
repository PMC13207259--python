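"""Feature pipeline: matrix construction, screening, expert merge,
utilization exclusion, RFE, grid, consensus ranking, simplified model, and
leakage guards."""

import numpy as np
import pandas as pd
import pytest

from tedclaims.errors import ConfigurationError, InputError, LeakageError
from tedclaims.learners import BoostedTreesLearner, boosted_trees_factory
from tedclaims.metrics import ThresholdGrid
from tedclaims.mlpipe import (
    MLConfig,
    build_feature_matrix,
    consensus_features,
    derive_seed,
    evaluate_model,
    exclude_utilization_codes,
    merge_expert_list,
    prevalence_screen,
    rfe_select,
    run_grid,
    train_simplified,
)

from conftest import planted_signal_matrix

FAST_CFG = dict(
    grid={"learning_rate": [0.1], "max_depth": [3],
          "n_estimators": [30], "reg_lambda": [1.0]},
    consensus_k=10,
    rfe_feature_cap=50,
)
FAST_PARAMS = {"learning_rate": 0.1, "max_depth": 3, "n_estimators": 30,
               "reg_lambda": 1.0}


class TestFeatureMatrix:
    def test_outside_baseline_window_is_zero(self):
        patients = pd.DataFrame({"patient_id": ["A"], "index_day": [1000]})
        claims = pd.DataFrame(
            {"patient_id": ["A"], "service_day": [200],
             "code": ["E05.00"], "system": ["ICD-10-CM"]}
        )
        mat = build_feature_matrix(claims, patients, baseline_days=730)
        assert mat.shape[1] == 0 or mat.loc["A"].sum() == 0

    def test_binary_not_count(self):
        patients = pd.DataFrame({"patient_id": ["A"], "index_day": [1000]})
        claims = pd.DataFrame(
            {"patient_id": ["A"] * 3, "service_day": [900, 950, 1000],
             "code": ["E05.00"] * 3, "system": ["ICD-10-CM"] * 3}
        )
        mat = build_feature_matrix(claims, patients, 730)
        assert mat.loc["A", "ICD-10-CM:E0500"] == 1

    def test_ndc_excluded(self):
        patients = pd.DataFrame({"patient_id": ["A"], "index_day": [1000]})
        claims = pd.DataFrame(
            {"patient_id": ["A"] * 2, "service_day": [950, 960],
             "code": ["12345678901", "99214"], "system": ["NDC", "CPT"]}
        )
        mat = build_feature_matrix(claims, patients, 730)
        assert list(mat.columns) == ["CPT:99214"]

    def test_matches_per_patient_scan(self, small_cohort):
        patients = small_cohort.patients.head(50)
        claims = small_cohort.claims[
            small_cohort.claims["patient_id"].isin(patients["patient_id"])
        ]
        mat = build_feature_matrix(claims, patients, 730)
        from tedclaims.codes import DIAGNOSIS_PROCEDURE_SYSTEMS, normalize_code

        for row in patients.itertuples(index=False):
            pc = claims[claims["patient_id"] == row.patient_id]
            keys = {
                f"{s}:{normalize_code(c, s)}"
                for _, (d, c, s) in pc[["service_day", "code", "system"]].iterrows()
                if row.index_day - 730 <= d <= row.index_day
                and s in DIAGNOSIS_PROCEDURE_SYSTEMS
            }
            got = set(mat.columns[mat.loc[row.patient_id] == 1])
            assert got == keys


class TestScreenAndMerge:
    def test_requires_threshold_in_both_classes(self):
        y = np.array([True] * 1000 + [False] * 2000)
        X = pd.DataFrame(
            {
                "a": np.r_[np.ones(2), np.zeros(998), np.ones(1), np.zeros(1999)],
                "b": np.r_[np.ones(500), np.zeros(500), np.ones(1000),
                           np.zeros(1000)],
            }
        )
        # a: 0.2% of cases but 0.05% of controls -> dropped; b: common -> kept
        assert prevalence_screen(X, y, 0.001) == ["b"]

    def test_zero_threshold_keeps_everything(self):
        y = np.array([True, False, True, False])
        X = pd.DataFrame({"a": [0, 0, 0, 0], "b": [1, 0, 0, 0]})
        assert prevalence_screen(X, y, 0.0) == ["a", "b"]

    def test_merge_counts_mirror_set_arithmetic(self):
        data_driven = [f"ICD-10-CM:D{i:04d}" for i in range(4233)]
        overlap = data_driven[:43]
        expert = overlap + [f"ICD-10-CM:E{i:04d}" for i in range(125)]
        merged, counts = merge_expert_list(data_driven, expert)
        assert counts["data_driven"] == 4233
        assert counts["expert"] == 168
        assert counts["overlap"] == 43
        assert counts["final"] == len(merged) == 4358

    def test_merge_empty_expert_is_identity(self):
        merged, counts = merge_expert_list(["a", "b"], [])
        assert merged == ["a", "b"] and counts["final"] == 2

    def test_utilization_chapters_excluded(self):
        cols = ["ICD-10-CM:Z79899", "ICD-10-CM:E0500", "CPT:99214",
                "ICD-10-CM:X580", "ICD-9:V700"]
        kept = exclude_utilization_codes(cols)
        assert kept == ["ICD-10-CM:E0500", "CPT:99214", "ICD-9:V700"]


class TestRfe:
    def test_planted_signal_recovered(self):
        X, y = planted_signal_matrix(2000, seed=101)
        cfg = MLConfig(**FAST_CFG, seed=1)
        trace = rfe_select(X, y, boosted_trees_factory(FAST_PARAMS), cfg, seed=1)
        assert {"ICD-10-CM:SIG0", "ICD-10-CM:SIG1"} <= set(trace.selected)

    def test_feature_counts_strictly_decrease(self):
        X, y = planted_signal_matrix(800, seed=102, n_noise=18)
        cfg = MLConfig(**FAST_CFG, seed=2)
        trace = rfe_select(X, y, boosted_trees_factory(FAST_PARAMS), cfg, seed=2)
        sizes = [len(rec["features"]) for rec in trace.iterations]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        best = max(rec["cv_auc"] for rec in trace.iterations)
        assert trace.selected_auc == best

    def test_single_informative_feature_survives(self, stub_factory):
        rng = np.random.default_rng(5)
        y = rng.random(400) < 0.5
        X = pd.DataFrame(
            {"CPT:SIG": y.astype(int),
             **{f"CPT:N{i}": (rng.random(400) < 0.3).astype(int)
                for i in range(9)}}
        )
        cfg = MLConfig(**FAST_CFG, seed=3)
        trace = rfe_select(X, y, stub_factory(None), cfg, seed=3,
                           learner_config={})
        assert "CPT:SIG" in trace.iterations[-1]["features"]

    def test_too_few_features_rejected(self, stub_factory):
        X = pd.DataFrame({"a": [1, 0, 1, 0]})
        with pytest.raises(InputError):
            rfe_select(X, np.array([1, 0, 1, 0]), stub_factory(None),
                       MLConfig(**FAST_CFG))


class TestGridAndConsensus:
    def test_default_grid_has_81_configurations(self):
        assert len(MLConfig().grid_configurations) == 81

    def test_run_grid_produces_trace_per_configuration(self, stub_factory):
        X, y = planted_signal_matrix(300, seed=7, n_noise=8)
        cfg = MLConfig(seed=4, consensus_k=5, rfe_feature_cap=10)
        traces = run_grid(X, y, stub_factory, cfg)
        assert len(traces) == 81
        assert len({t.seed for t in traces}) == 81

    def test_rerun_is_deterministic(self):
        X, y = planted_signal_matrix(600, seed=8, n_noise=18)
        cfg = MLConfig(**FAST_CFG, seed=5)
        t1 = run_grid(X, y, boosted_trees_factory, cfg)
        t2 = run_grid(X, y, boosted_trees_factory, cfg)
        assert [t.selected for t in t1] == [t.selected for t in t2]
        assert [t.selected_auc for t in t1] == [t.selected_auc for t in t2]

    def test_consensus_ranks_frequency_first(self):
        from tedclaims.mlpipe import FeatureSelectionTrace

        def trace(sel, imp):
            return FeatureSelectionTrace(
                config={}, seed=0, selected=sel,
                final_importance={f: imp for f in sel},
            )

        traces = [trace(["a", "b"], 1.0)] * 4 + [trace(["b"], 99.0)]
        ranked = consensus_features(traces, 2)
        assert ranked["feature"].tolist() == ["b", "a"]

    def test_tie_broken_deterministically_by_code(self):
        from tedclaims.mlpipe import FeatureSelectionTrace

        tr = FeatureSelectionTrace(
            config={}, seed=0, selected=["z", "a"],
            final_importance={"z": 1.0, "a": 1.0},
        )
        ranked = consensus_features([tr], 1)
        assert ranked["feature"].tolist() == ["a"]

    def test_k_larger_than_pool_warns(self):
        from tedclaims.mlpipe import FeatureSelectionTrace

        tr = FeatureSelectionTrace(config={}, seed=0, selected=["a"],
                                   final_importance={"a": 1.0})
        with pytest.warns(UserWarning):
            ranked = consensus_features([tr], 5)
        assert len(ranked) == 1

    def test_consensus_k_capped_by_feature_cap(self):
        with pytest.raises(ConfigurationError):
            MLConfig(consensus_k=300, rfe_feature_cap=201)

    def test_derived_seeds_stay_below_two_to_31(self):
        for i in range(100):
            assert 0 <= derive_seed(2**20, i) < 2**31


class TestSimplifiedModel:
    def test_prediction_ignores_non_consensus_columns(self):
        X, y = planted_signal_matrix(800, seed=9, n_noise=8)
        model, cols = train_simplified(
            X, y, ["ICD-10-CM:SIG0", "ICD-10-CM:SIG1"], trees=10, seed=0
        )
        X2 = X.copy()
        for c in X2.columns:
            if c not in cols:
                X2[c] = 1 - X2[c]
        p1 = model.predict_probability(X[cols].to_numpy(np.float32))
        p2 = model.predict_probability(X2[cols].to_numpy(np.float32))
        assert np.allclose(p1, p2)

    def test_single_tree_yields_valid_probabilities(self):
        X, y = planted_signal_matrix(300, seed=10, n_noise=3)
        model, cols = train_simplified(X, y, list(X.columns), trees=1, seed=0)
        p = model.predict_probability(X[cols].to_numpy(np.float32))
        assert ((0 <= p) & (p <= 1)).all()

    def test_simplified_close_to_full_when_signal_is_contained(self):
        """When only the consensus features carry signal, the 10-tree model
        matches a larger model's held-out AUC within 0.05."""
        from tedclaims.metrics import auc

        X, y = planted_signal_matrix(2000, seed=11)
        tr = X.index[:1000]
        te = X.index[1000:]
        full = BoostedTreesLearner(n_estimators=100, seed=0).fit(
            X.loc[tr].to_numpy(np.float32), y.loc[tr].to_numpy()
        )
        simple, cols = train_simplified(
            X.loc[tr], y.loc[tr], ["ICD-10-CM:SIG0", "ICD-10-CM:SIG1"],
            trees=10, seed=0,
        )
        auc_full = auc(
            full.predict_probability(X.loc[te].to_numpy(np.float32)), y.loc[te]
        )
        auc_simple = auc(
            simple.predict_probability(X.loc[te, cols].to_numpy(np.float32)),
            y.loc[te],
        )
        assert abs(auc_full - auc_simple) < 0.05

    def test_empty_consensus_rejected(self):
        X, y = planted_signal_matrix(100, seed=12, n_noise=3)
        with pytest.raises(InputError):
            train_simplified(X, y, [], trees=5)


class TestEvaluateModel:
    def test_overlapping_ids_raise_leakage_error(self):
        X, y = planted_signal_matrix(200, seed=13, n_noise=3)
        model, cols = train_simplified(X, y, list(X.columns)[:2], trees=5)
        with pytest.raises(LeakageError):
            evaluate_model(model, cols, X, y, train_ids=set(X.index[:5]))

    def test_report_has_row_per_threshold_and_auc(self):
        X, y = planted_signal_matrix(600, seed=14)
        tr, te = X.index[:300], X.index[300:]
        model, cols = train_simplified(
            X.loc[tr], y.loc[tr], ["ICD-10-CM:SIG0", "ICD-10-CM:SIG1"], trees=10
        )
        report, model_auc = evaluate_model(
            model, cols, X.loc[te], y.loc[te],
            ThresholdGrid((0.3, 0.5, 0.7)), train_ids=set(tr),
        )
        assert len(report) == 3
        assert 0.5 < model_auc <= 1.0
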