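"""Generator behaviour: determinism, parameter recovery, window nesting,
reference-standard feasibility, proxy index dates."""

import numpy as np
import pandas as pd
import pytest

from tedclaims.errors import ConfigurationError, InfeasibleReferenceError
from tedclaims.profiles import CodeProfile, default_profiles
from tedclaims.synth import (
    CohortConfig,
    assign_proxy_index_dates,
    assign_reference_labels,
    generate_cohort,
    solve_reference_fp_rate,
)


def test_fixed_seed_gives_bit_identical_output():
    cfg = CohortConfig(n_patients=500, seed=42)
    a, b = generate_cohort(cfg), generate_cohort(cfg)
    pd.testing.assert_frame_equal(a.patients, b.patients)
    pd.testing.assert_frame_equal(a.claims, b.claims)
    pd.testing.assert_frame_equal(a.enrollment, b.enrollment)


def test_different_seeds_differ():
    a = generate_cohort(CohortConfig(n_patients=500, seed=1))
    b = generate_cohort(CohortConfig(n_patients=500, seed=2))
    assert not a.patients["true_ted"].equals(b.patients["true_ted"])


def test_prevalence_within_binomial_ci():
    cfg = CohortConfig(n_patients=10_000, ted_prevalence=0.72, seed=1)
    cohort = generate_cohort(cfg)
    phat = cohort.patients["true_ted"].mean()
    se = np.sqrt(0.72 * 0.28 / 10_000)
    assert abs(phat - 0.72) < 1.96 * se * 1.5  # 95% CI with head-room


@pytest.mark.parametrize("prevalence", [0.0, 1.0, -0.1, 1.5])
def test_degenerate_prevalence_rejected(prevalence):
    with pytest.raises(ConfigurationError):
        CohortConfig(n_patients=100, ted_prevalence=prevalence)


def test_empty_index_date_range_rejected():
    with pytest.raises(ConfigurationError):
        CohortConfig(n_patients=10, index_date_range=("2020-01-01", "2019-01-01"))


def test_claims_lie_inside_enrollment_spans():
    cohort = generate_cohort(CohortConfig(n_patients=1000, seed=3,
                                          enrollment_gap_prob=0.3))
    m = cohort.claims.merge(cohort.enrollment, on="patient_id")
    assert ((m["service_day"] >= m["start_day"])
            & (m["service_day"] <= m["end_day"])).all()


def test_window_nesting_of_generated_claims():
    """Codes seen within +/-90 days of index are seen within +/-180 and
    +/-365 days — automatic from banded offset sampling."""
    cohort = generate_cohort(CohortConfig(n_patients=2000, seed=5))
    ted = cohort.patients[cohort.patients["true_ted"]]
    m = cohort.claims.merge(ted[["patient_id", "index_day"]], on="patient_id")
    m["absdelta"] = (m["service_day"] - m["index_day"]).abs()
    for w_small, w_big in [(90, 180), (180, 365)]:
        small = set(map(tuple, m.loc[m.absdelta <= w_small,
                                     ["patient_id", "code"]].values))
        big = set(map(tuple, m.loc[m.absdelta <= w_big,
                                   ["patient_id", "code"]].values))
        assert small <= big


class TestReferenceStandard:
    def test_perfect_reference_is_identity(self):
        cohort = generate_cohort(CohortConfig(n_patients=500, seed=9))
        p = assign_reference_labels(cohort.patients, 1.0, 1.0, seed=0)
        assert (p["reference_label"] == p["true_ted"]).all()

    def test_precision_recall_recovered(self):
        cohort = generate_cohort(CohortConfig(n_patients=20_000, seed=13,
                                              n_noise_codes=0))
        p = cohort.patients
        tp = (p.true_ted & p.reference_label).sum()
        fp = (~p.true_ted & p.reference_label).sum()
        fn = (p.true_ted & ~p.reference_label).sum()
        precision, recall = tp / (tp + fp), tp / (tp + fn)
        se_r = np.sqrt(0.91 * 0.09 / p.true_ted.sum())
        assert abs(recall - 0.91) < 3 * se_r
        se_p = np.sqrt(0.90 * 0.10 / (tp + fp))
        assert abs(precision - 0.90) < 3 * se_p

    def test_infeasible_precision_reports_implied_rate(self):
        # low precision at high prevalence needs fp probability above 1
        with pytest.raises(InfeasibleReferenceError) as err:
            solve_reference_fp_rate(precision=0.05, recall=0.99, prevalence=0.9)
        assert err.value.implied_fp_rate > 1.0

    def test_reference_specificity_implied_by_fp_rate(self):
        # a reference false-positive RATE of 23.1% corresponds to reference
        # specificity 1 - 0.231 = 0.769
        q = solve_reference_fp_rate(0.90, 0.91, 0.72)
        assert 0.0 < q < 1.0
        assert 1 - 0.231 == pytest.approx(0.769)


class TestProxyIndexDates:
    def test_degenerate_zero_interval_anchors_at_first_record(self):
        cohort = generate_cohort(CohortConfig(n_patients=300, seed=21))
        patients, _ = assign_proxy_index_dates(
            cohort.patients, cohort.claims, [0], seed=1
        )
        non_ted = patients[~patients["true_ted"] & patients["has_claims"]]
        first = cohort.claims.groupby("patient_id")["service_day"].min()
        assert (
            non_ted["index_day"].to_numpy()
            == first.loc[non_ted["patient_id"]].to_numpy()
        ).all()

    def test_patients_without_claims_flagged(self):
        cohort = generate_cohort(CohortConfig(n_patients=200, seed=22))
        # forge a claimless control
        patients = cohort.patients.copy()
        patients.loc[~patients.true_ted, "true_ted"] = False
        target = patients.index[~patients["true_ted"]][0]
        pid = patients.loc[target, "patient_id"]
        claims = cohort.claims[cohort.claims["patient_id"] != pid]
        out, flagged = assign_proxy_index_dates(patients, claims, [10], seed=0)
        assert pid in flagged
        assert not out.loc[out["patient_id"] == pid, "has_claims"].iloc[0]

    def test_clip_binds_only_at_record_boundaries(self):
        """With a constant interval, every proxy gap equals the interval
        except where the record range is shorter."""
        cohort = generate_cohort(CohortConfig(n_patients=500, seed=24))
        patients, _ = assign_proxy_index_dates(
            cohort.patients, cohort.claims, [7], seed=2
        )
        span = cohort.claims.groupby("patient_id")["service_day"].agg(
            lambda s: s.max() - s.min()
        )
        nt = patients[~patients["true_ted"] & patients["has_claims"]]
        gaps = (nt["index_day"] - nt["first_claim_day"]).astype(int)
        want = np.minimum(7, span.loc[nt["patient_id"]].to_numpy())
        assert (gaps.to_numpy() == want).all()

    def test_resampled_gaps_match_source_distribution(self):
        """Among patients whose record range cannot trigger clipping, proxy
        gaps are an exact resample of the source distribution (KS-close)."""
        from scipy.stats import ks_2samp

        cohort = generate_cohort(CohortConfig(n_patients=8000, seed=23))
        p = cohort.patients
        ted = p.true_ted & p.has_claims
        source = (
            p.loc[ted, "index_day"] - p.loc[ted, "first_claim_day"]
        ).astype(int).to_numpy()
        patients, _ = assign_proxy_index_dates(
            cohort.patients, cohort.claims, source, seed=3
        )
        span = cohort.claims.groupby("patient_id")["service_day"].agg(
            lambda s: s.max() - s.min()
        )
        nt = patients[~patients["true_ted"] & patients["has_claims"]].copy()
        nt["span"] = span.loc[nt["patient_id"]].to_numpy()
        free = nt[nt["span"] >= source.max()]  # clipping cannot bind above
        proxy_gaps = (free["index_day"] - free["first_claim_day"]).astype(int)
        stat = ks_2samp(np.maximum(source, 0), proxy_gaps).statistic
        assert len(free) > 200
        assert stat < 0.08


def test_flat_profile_yields_chance_level_auc():
    """With identical occurrence in both classes there is no signal: a
    score built from any code indicator has AUC ~ 0.5."""
    from tedclaims.mlpipe import build_feature_matrix
    from tedclaims.metrics import auc

    flat = [
        CodeProfile(
            code=f"F{i:02d}", system="CPT", description="flat",
            prob_ted_window=(0.1, 0.15, 0.2),
            prob_nonted_window=(0.1, 0.15, 0.2),
        )
        for i in range(10)
    ]
    cohort = generate_cohort(
        CohortConfig(n_patients=4000, seed=31, n_noise_codes=0), profiles=flat
    )
    X = build_feature_matrix(cohort.claims, cohort.patients, 730)
    score = X.sum(axis=1).to_numpy(float)
    truth = cohort.patients.set_index("patient_id").loc[X.index, "true_ted"]
    assert abs(auc(score, truth) - 0.5) < 0.05


def test_default_profile_window_probabilities_are_nested():
    for prof in default_profiles():
        assert prof.prob_ted_window[0] <= prof.prob_ted_window[1] <= prof.prob_ted_window[2]
        assert prof.prob_nonted_window[0] <= prof.prob_nonted_window[1] <= prof.prob_nonted_window[2]
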