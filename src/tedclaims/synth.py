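"""Synthetic linked claims/registry cohort generator.

Emulates the statistical structure of a linked ophthalmology-registry /
claims validation cohort for thyroid eye disease (TED):

* a case-enriched cohort (default 72% TED prevalence) with demographics
  matching the validation population (age ~ N(60.4, 14.5), 76% female);
* an imperfect reference standard emulating an NLP note classifier with
  configurable precision (default 0.90) and recall (default 0.91) against
  the simulation ground truth;
* per-code claim frequencies concentrated in nested windows around an index
  date, driven by :mod:`tedclaims.profiles`;
* continuous-enrollment spans that always contain every generated claim
  (a claims database can only observe covered periods), with a configurable
  fraction of patients whose lookback coverage is deliberately too short;
* proxy index dates for non-TED patients resampled from the TED patients'
  empirical (index - first record) gap distribution.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config, so a fixed seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dates import to_day
from .errors import ConfigurationError, InfeasibleReferenceError
from .profiles import CodeProfile, default_profiles, noise_profiles

PATIENT_COLUMNS = [
    "patient_id", "age_at_index", "sex", "true_ted", "reference_label",
    "index_day", "has_claims", "reference_evaluated",
]
CLAIM_COLUMNS = ["patient_id", "service_day", "code", "system"]
ENROLLMENT_COLUMNS = ["patient_id", "start_day", "end_day"]


@dataclass(frozen=True)
class Cohort:
    """A generated (or loaded) linked dataset: three tidy tables."""

    patients: pd.DataFrame
    claims: pd.DataFrame
    enrollment: pd.DataFrame


@dataclass
class CohortConfig:
    n_patients: int = 10_000
    ted_prevalence: float = 0.72
    reference_precision: float = 0.90
    reference_recall: float = 0.91
    index_date_range: tuple[str, str] = ("2017-01-01", "2023-12-31")
    enrollment_mean_span_days: float = 1095.0
    enrollment_gap_prob: float = 0.08
    age_mean: float = 60.4
    age_sd: float = 14.5
    female_fraction: float = 0.76
    #: None -> resample proxy intervals from the TED patients' empirical gaps.
    proxy_interval_distribution: np.ndarray | list[int] | None = None
    n_noise_codes: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0.0 < self.ted_prevalence < 1.0:
            raise ConfigurationError(
                "ted_prevalence must lie in the open interval (0, 1)"
            )
        for name in ("reference_precision", "reference_recall"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1]")
        for name in ("enrollment_gap_prob", "female_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.enrollment_mean_span_days <= 0:
            raise ConfigurationError("enrollment_mean_span_days must be positive")
        start, end = (to_day(d) for d in self.index_date_range)
        if end < start:
            raise ConfigurationError("index_date_range is empty")


def solve_reference_fp_rate(
    precision: float, recall: float, prevalence: float
) -> float:
    """False-positive probability q = P(ref=1 | true=0) that makes the
    reference standard hit the requested precision in expectation.

    From precision = r*pi / (r*pi + q*(1-pi)):
        q = r*pi*(1-precision) / (precision*(1-pi)).
    Raises :class:`InfeasibleReferenceError` when q falls outside [0, 1].
    """
    q = recall * prevalence * (1.0 - precision) / (precision * (1.0 - prevalence))
    if not 0.0 <= q <= 1.0:
        raise InfeasibleReferenceError(q)
    return q


def assign_reference_labels(
    patients: pd.DataFrame,
    precision: float,
    recall: float,
    seed: int,
    prevalence: float | None = None,
) -> pd.DataFrame:
    """Simulate the imperfect reference standard from the ground truth.

    True cases are labelled positive with probability ``recall``; controls
    are labelled positive with the false-positive probability solved
    analytically so that expected precision equals ``precision`` at the
    (by default empirical) prevalence.
    """
    rng = np.random.default_rng(seed)
    truth = patients["true_ted"].to_numpy(dtype=bool)
    if prevalence is None:
        prevalence = float(truth.mean())
    if not 0.0 < prevalence < 1.0:
        raise ConfigurationError(
            "reference labelling needs both classes present (prevalence in (0,1))"
        )
    q = solve_reference_fp_rate(precision, recall, prevalence)
    u = rng.random(len(truth))
    ref = np.where(truth, u < recall, u < q)
    out = patients.copy()
    out["reference_label"] = ref
    return out


def sample_index_gaps(patients: pd.DataFrame) -> np.ndarray:
    """Empirical (index - first claim) gaps among TED patients with claims."""
    m = patients["true_ted"] & patients["has_claims"]
    gaps = (
        patients.loc[m, "index_day"] - patients.loc[m, "first_claim_day"]
    ).to_numpy(dtype="int64")
    return gaps


def assign_proxy_index_dates(
    patients: pd.DataFrame,
    claims: pd.DataFrame,
    interval_distribution: np.ndarray | list[int] | None,
    seed: int,
) -> tuple[pd.DataFrame, list[str]]:
    """Re-anchor non-TED patients' index dates to a proxy.

    Each non-TED patient's index becomes first-record date plus a gap sampled
    from ``interval_distribution`` (by default the TED patients' empirical
    gaps), clipped into the patient's observed record range.  Patients with
    no claims cannot receive a proxy; they are flagged (``has_claims=False``)
    and returned for downstream exclusion.
    """
    if interval_distribution is None:
        interval_distribution = sample_index_gaps(patients)
    intervals = np.asarray(interval_distribution, dtype="int64")
    if intervals.size == 0:
        raise ConfigurationError("proxy interval distribution is empty")

    rng = np.random.default_rng(seed)
    out = patients.copy()
    bounds = claims.groupby("patient_id")["service_day"].agg(["min", "max"])

    nonted = out.index[~out["true_ted"].to_numpy(dtype=bool)]
    flagged: list[str] = []
    ids = out.loc[nonted, "patient_id"]
    have = ids.isin(bounds.index).to_numpy()
    flagged = ids[~have].tolist()
    target = nonted[have]
    if len(target):
        first = bounds.loc[out.loc[target, "patient_id"], "min"].to_numpy("int64")
        last = bounds.loc[out.loc[target, "patient_id"], "max"].to_numpy("int64")
        gaps = rng.choice(intervals, size=len(target), replace=True)
        out.loc[target, "index_day"] = np.clip(first + gaps, first, last)
        out.loc[target, "first_claim_day"] = first
    out.loc[out["patient_id"].isin(flagged), "has_claims"] = False
    return out, flagged


def fully_observed_mask(
    patients: pd.DataFrame,
    enrollment: pd.DataFrame,
    window_days: int = 365,
) -> np.ndarray:
    """Patients whose enrollment covers [index - window, index + window].

    Claims are only generated (and only observable) inside enrollment spans,
    so configured window frequencies are recoverable exactly among these
    fully observed patients; truncated patients under-express them.
    """
    spans = enrollment.groupby("patient_id").agg(
        start=("start_day", "min"), end=("end_day", "max")
    )
    start = patients["patient_id"].map(spans["start"])
    end = patients["patient_id"].map(spans["end"])
    idx = patients["index_day"]
    ok = (start <= idx - window_days) & (end >= idx + window_days)
    return ok.fillna(False).to_numpy(dtype=bool)


def _sample_offsets(band: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Day offsets from index for claims in nested bands 1..3.

    Band 1: |offset| <= 90; band 2: 91..180; band 3: 181..365.  Sampling per
    band (rather than per window) is what makes the configured window
    probabilities exactly recoverable and window nesting automatic.
    """
    n = len(band)
    off = np.zeros(n, dtype="int64")
    b1 = band == 1
    off[b1] = rng.integers(-90, 91, size=int(b1.sum()))
    for b, lo, hi in ((2, 91, 180), (3, 181, 365)):
        m = band == b
        k = int(m.sum())
        mag = rng.integers(lo, hi + 1, size=k)
        sign = rng.integers(0, 2, size=k) * 2 - 1
        off[m] = mag * sign
    return off


def _claims_for_profile(
    profile: CodeProfile,
    truth: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(patient row indices, day offsets) for one code across the cohort."""
    n = len(truth)
    p = np.where(
        truth[:, None],
        np.asarray(profile.prob_ted_window),
        np.asarray(profile.prob_nonted_window),
    )  # n x 3 cumulative band probabilities
    u = rng.random(n)
    band = np.select([u < p[:, 0], u < p[:, 1], u < p[:, 2]], [1, 2, 3], default=0)
    hit = band > 0
    idx = np.flatnonzero(hit)
    counts = 1 + rng.poisson(profile.mean_repeats, size=len(idx))
    rows = np.repeat(idx, counts)
    bands = np.repeat(band[idx], counts)
    offsets = _sample_offsets(bands, rng)
    return rows, offsets


def generate_cohort(
    config: CohortConfig,
    profiles: list[CodeProfile] | None = None,
) -> Cohort:
    """Generate a full synthetic linked cohort.

    Returns patients, claims and enrollment tables.  The fraction of true
    TED patients is binomial around ``config.ted_prevalence``; per-code claim
    frequencies follow the profiles conditioned on class and window band;
    every claim lies inside an enrollment span.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    if profiles is None:
        profiles = default_profiles()
    if config.n_noise_codes:
        profiles = profiles + noise_profiles(config.n_noise_codes, rng)

    truth = rng.random(n) < config.ted_prevalence
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 1.0, 100.0)
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    lo, hi = (to_day(d) for d in config.index_date_range)
    index_day = rng.integers(lo, hi + 1, size=n)
    patient_id = np.array([f"P{i:06d}" for i in range(n)])

    rows_all, offs_all, codes_all, systems_all = [], [], [], []
    for profile in profiles:
        rows, offs = _claims_for_profile(profile, truth, rng)
        rows_all.append(rows)
        offs_all.append(offs)
        codes_all.append(np.full(len(rows), profile.code, dtype=object))
        systems_all.append(np.full(len(rows), profile.system, dtype=object))
    rows = np.concatenate(rows_all)
    offs = np.concatenate(offs_all)
    claims = pd.DataFrame(
        {
            "patient_id": patient_id[rows],
            "service_day": index_day[rows] + offs,
            "code": np.concatenate(codes_all),
            "system": np.concatenate(systems_all),
        }
    )

    # Enrollment: cover the index lookback and every claim, then knock a
    # configurable fraction of patients down to an insufficient lookback.
    pre = 365.0 + rng.exponential(config.enrollment_mean_span_days / 2.0, size=n)
    post = 30.0 + rng.exponential(config.enrollment_mean_span_days / 2.0, size=n)
    min_off = np.zeros(n, dtype="int64")
    max_off = np.zeros(n, dtype="int64")
    if len(rows):
        g = pd.DataFrame({"row": rows, "off": offs}).groupby("row")["off"]
        mn, mx = g.min(), g.max()
        min_off[mn.index.to_numpy()] = mn.to_numpy()
        max_off[mx.index.to_numpy()] = mx.to_numpy()
    start = index_day - np.maximum(pre.astype("int64"), -min_off)
    end = index_day + np.maximum(post.astype("int64"), max_off)

    gap = rng.random(n) < config.enrollment_gap_prob
    short_start = index_day - rng.integers(30, 330, size=n)
    start = np.where(gap, np.maximum(start, short_start), start)
    if gap.any():  # enforce the generator guarantee: claims live inside spans
        keep = claims["service_day"].to_numpy() >= start[rows]
        claims = claims.loc[keep].reset_index(drop=True)

    claims = claims.sort_values(
        ["patient_id", "service_day", "system", "code"], kind="stable"
    ).reset_index(drop=True)
    enrollment = pd.DataFrame(
        {"patient_id": patient_id, "start_day": start, "end_day": end}
    )

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "age_at_index": np.round(age, 1),
            "sex": sex,
            "true_ted": truth,
            "reference_label": False,
            "index_day": index_day,
            "has_claims": False,
            "reference_evaluated": True,
        }
    )
    bounds = claims.groupby("patient_id")["service_day"].min()
    patients["has_claims"] = patients["patient_id"].isin(bounds.index)
    patients["first_claim_day"] = (
        patients["patient_id"].map(bounds).astype("Int64")
    )

    patients = assign_reference_labels(
        patients,
        config.reference_precision,
        config.reference_recall,
        seed=int(rng.integers(0, 2**31)),
    )
    patients, _ = assign_proxy_index_dates(
        patients,
        claims,
        config.proxy_interval_distribution,
        seed=int(rng.integers(0, 2**31)),
    )
    return Cohort(patients=patients, claims=claims, enrollment=enrollment)
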