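"""Cohort construction: inclusion criteria, splitting, sample size, and
coding-pattern characterization around the index date.

Inclusion mirrors a standard claims-validation design: adults (>=18 at
index) with at least 12 months (365 days) of continuous enrollment before
the index date and an evaluated reference standard.  The lookback window
excludes the index day itself ("prior to the index date"); coding-pattern
windows include it ("before, on, or after").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError
from .synth import Cohort


@dataclass(frozen=True)
class InclusionCriteria:
    min_age_years: int = 18
    lookback_days: int = 365
    max_gap_days: int = 0
    require_reference_evaluated: bool = True

    def __post_init__(self):
        if self.lookback_days < 1:
            raise ConfigurationError("lookback_days must be >= 1")
        if self.max_gap_days < 0:
            raise ConfigurationError("max_gap_days must be >= 0")


@dataclass(frozen=True)
class SampleSizeParams:
    expected_sensitivity: float
    margin_of_error: float
    confidence_level: float = 0.95

    def __post_init__(self):
        if not 0.0 < self.expected_sensitivity < 1.0:
            raise ConfigurationError(
                "expected_sensitivity must lie strictly inside (0, 1)"
            )
        if not 0.0 < self.margin_of_error < 1.0:
            raise ConfigurationError("margin_of_error must lie in (0, 1)")
        if not 0.0 < self.confidence_level < 1.0:
            raise ConfigurationError("confidence_level must lie in (0, 1)")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.5
    seed: int = 0
    stratify_by_reference: bool = False

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")


def continuous_enrollment_ok(
    spans: list[tuple[int, int]],
    index_day: int,
    lookback_days: int = 365,
    max_gap_days: int = 0,
) -> bool:
    """Is every day in [index - lookback, index - 1] covered by the spans,
    allowing uncovered runs of at most ``max_gap_days``?

    Spans are closed integer-day intervals, sorted and pairwise disjoint.
    """
    for (a, b) in spans:
        if b < a:
            raise InputError(f"span ({a}, {b}) has end before start")
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 <= b1:
            raise InputError("spans must be sorted and non-overlapping")

    win_lo, win_hi = index_day - lookback_days, index_day - 1
    cursor = win_lo  # first day not yet known to be covered
    for a, b in spans:
        if b < win_lo or a > win_hi:
            continue
        a, b = max(a, win_lo), min(b, win_hi)
        if a - cursor > max_gap_days:
            return False
        cursor = max(cursor, b + 1)
        if cursor > win_hi:
            return True
    return win_hi + 1 - cursor <= max_gap_days


def _spans_by_patient(enrollment: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for pid, grp in enrollment.sort_values(["patient_id", "start_day"]).groupby(
        "patient_id", sort=False
    ):
        out[pid] = list(zip(grp["start_day"].tolist(), grp["end_day"].tolist()))
    return out


def apply_inclusion(
    cohort: Cohort, criteria: InclusionCriteria = InclusionCriteria()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply inclusion criteria; return (included patients, exclusion log).

    Each excluded patient carries exactly one reason — the first failing
    criterion in the fixed order age -> enrollment -> reference_evaluated —
    so the attrition log is deterministic.  Idempotent.
    """
    patients = cohort.patients
    spans = _spans_by_patient(cohort.enrollment)

    reasons: list[tuple[str, str]] = []
    keep_mask = np.ones(len(patients), dtype=bool)
    for pos, row in enumerate(patients.itertuples(index=False)):
        if row.age_at_index < criteria.min_age_years:
            reasons.append((row.patient_id, "age"))
            keep_mask[pos] = False
            continue
        ok = continuous_enrollment_ok(
            spans.get(row.patient_id, []),
            int(row.index_day),
            criteria.lookback_days,
            criteria.max_gap_days,
        )
        if not ok:
            reasons.append((row.patient_id, "enrollment"))
            keep_mask[pos] = False
            continue
        if criteria.require_reference_evaluated and not row.reference_evaluated:
            reasons.append((row.patient_id, "reference_not_evaluated"))
            keep_mask[pos] = False

    log = pd.DataFrame(reasons, columns=["patient_id", "reason"])
    return patients.loc[keep_mask].reset_index(drop=True), log


def min_positive_sample_size(params: SampleSizeParams) -> int:
    """Smallest n with z * sqrt(p(1-p)/n) <= E, i.e. ceil(z^2 p(1-p) / E^2).

    With p=0.70, 95% confidence and E=0.025 this gives n=1291 — the minimum
    number of reference-positive patients needed to estimate sensitivity to
    the stated margin.
    """
    z = stats.norm.ppf(0.5 + params.confidence_level / 2.0)
    p, e = params.expected_sensitivity, params.margin_of_error
    return int(math.ceil(z * z * p * (1.0 - p) / (e * e)))


def split_cohort(
    patients: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[list[str], list[str]]:
    """Random train/test split of patient ids; disjoint and exhaustive,
    sizes within one patient of the requested fraction, seed-reproducible.
    Optionally stratified on the reference label."""
    if len(patients) < 2:
        raise InputError("need at least 2 patients to split")
    rng = np.random.default_rng(spec.seed)
    ids = patients["patient_id"].to_numpy()

    def _split(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        perm = rng.permutation(len(arr))
        n_train = int(round(spec.train_fraction * len(arr)))
        return arr[perm[:n_train]], arr[perm[n_train:]]

    if spec.stratify_by_reference:
        ref = patients["reference_label"].to_numpy(dtype=bool)
        tr_pos, te_pos = _split(ids[ref])
        tr_neg, te_neg = _split(ids[~ref])
        train = np.concatenate([tr_pos, tr_neg])
        test = np.concatenate([te_pos, te_neg])
    else:
        train, test = _split(ids)
    return sorted(train.tolist()), sorted(test.tolist())


def characterize_coding_patterns(
    claims: pd.DataFrame,
    patients: pd.DataFrame,
    window_days_list: tuple[int, ...] = (90, 180, 365),
) -> pd.DataFrame:
    """Per-code patient counts within +/-w days of the index date.

    A claim on the index day itself counts in every window.  Returns one row
    per (code, window): columns code, system, window, n, pct — sorted by
    descending frequency within each window.  Patient counts are
    nondecreasing in window size by construction.
    """
    n_patients = len(patients)
    merged = claims.merge(
        patients[["patient_id", "index_day"]], on="patient_id", how="inner"
    )
    merged["absdelta"] = (merged["service_day"] - merged["index_day"]).abs()
    rows = []
    for w in window_days_list:
        sub = merged.loc[merged["absdelta"] <= w]
        counts = (
            sub.groupby(["code", "system"])["patient_id"].nunique().reset_index()
        )
        counts.columns = ["code", "system", "n"]
        counts["window"] = w
        rows.append(counts)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["code", "system", "n", "window"]
    )
    out["pct"] = 100.0 * out["n"] / max(n_patients, 1)
    return (
        out.sort_values(["window", "n", "code"], ascending=[True, False, True])
        .reset_index(drop=True)[["code", "system", "window", "n", "pct"]]
    )
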