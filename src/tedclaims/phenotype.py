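"""Rule-based claims phenotyping algorithms for TED.

Six declarative algorithms over diagnosis claims:

1. any TED-related eye sign/symptom, no hyperthyroidism requirement;
2. hyperthyroidism + a core eye-sign set, co-occurring within 12 months;
3. algorithm 2's set plus ocular pain and keratoconjunctivitis;
4. algorithm 2's set plus the full broader symptom list;
5. hyperthyroidism + a narrow set (exophthalmos, lid retraction,
   periorbital edema, eyelid erythema) within 12 months;
6. algorithm 2 without the 12-month timing restriction.

"Within 12 months" means an absolute day gap of at most 365, either
temporal order, boundary inclusive; same-day claims qualify.  By default
algorithms see each patient's entire claims history (algorithm 6 needs
unbounded lookback); an index-anchored observation window is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codes import CodeSet, default_codelists, normalize_code
from .errors import ConfigurationError
from .synth import Cohort

# Symptom concept lists per algorithm (names into the code-list file).
CORE_SIGNS = [
    "exophthalmos", "diplopia", "lid_retraction", "strabismus",
    "orbital_inflammation",
]
EXPANDED_SIGNS = CORE_SIGNS + ["ocular_pain", "keratoconjunctivitis"]
BROAD_SIGNS = EXPANDED_SIGNS + [
    "eye_edema", "visual_disturbance", "scotoma", "vision_deficiency",
    "corneal_ulcer", "optic_neuropathy",
]
NARROW_SIGNS = [
    "exophthalmos", "lid_retraction", "periorbital_edema", "eyelid_erythema",
]


@dataclass(frozen=True)
class AlgorithmSpec:
    id: int
    symptom_sets: tuple[str, ...]
    require_hyperthyroidism: bool
    window_days: int | None  # None -> no co-occurrence timing restriction

    def __post_init__(self):
        if self.window_days is not None and self.window_days <= 0:
            raise ConfigurationError("window_days must be positive when present")


def default_algorithms() -> list[AlgorithmSpec]:
    return [
        AlgorithmSpec(1, tuple(BROAD_SIGNS), False, None),
        AlgorithmSpec(2, tuple(CORE_SIGNS), True, 365),
        AlgorithmSpec(3, tuple(EXPANDED_SIGNS), True, 365),
        AlgorithmSpec(4, tuple(BROAD_SIGNS), True, 365),
        AlgorithmSpec(5, tuple(NARROW_SIGNS), True, 365),
        AlgorithmSpec(6, tuple(CORE_SIGNS), True, None),
    ]


def matching_claim_dates(claims: pd.DataFrame, codeset: CodeSet) -> np.ndarray:
    """Sorted service days of one patient's claims matching the code set;
    duplicates preserved."""
    if not len(claims):
        return np.array([], dtype="int64")
    normalized = [
        normalize_code(c, s) for c, s in zip(claims["code"], claims["system"])
    ]
    hit = np.fromiter(
        (codeset.matches(s, c) for s, c in zip(claims["system"], normalized)),
        dtype=bool,
        count=len(claims),
    )
    return np.sort(claims.loc[hit, "service_day"].to_numpy(dtype="int64"))


def co_occurrence_within(
    dates_a: np.ndarray, dates_b: np.ndarray, window_days: int
) -> bool:
    """True iff some a in A and b in B satisfy |a - b| <= window_days.

    Sorted-merge sweep, O(len A + len B); empty input is False.
    """
    if window_days < 0:
        raise ConfigurationError("window_days must be >= 0")
    a = np.sort(np.asarray(dates_a, dtype="int64"))
    b = np.sort(np.asarray(dates_b, dtype="int64"))
    if not len(a) or not len(b):
        return False
    i = j = 0
    while i < len(a) and j < len(b):
        d = a[i] - b[j]
        if abs(d) <= window_days:
            return True
        if d > 0:
            j += 1
        else:
            i += 1
    return False


def _union_dates(
    claims: pd.DataFrame, names: tuple[str, ...], codesets: dict[str, CodeSet]
) -> np.ndarray:
    dates = []
    for name in names:
        if name not in codesets:
            raise ConfigurationError(f"unknown code set name: {name!r}")
        dates.append(matching_claim_dates(claims, codesets[name]))
    return np.sort(np.concatenate(dates)) if dates else np.array([], dtype="int64")


def classify_patient(
    spec: AlgorithmSpec,
    claims: pd.DataFrame,
    codesets: dict[str, CodeSet] | None = None,
) -> bool:
    """Apply one algorithm to one patient's claims."""
    if codesets is None:
        codesets = default_codelists()
    symptom_dates = _union_dates(claims, spec.symptom_sets, codesets)
    if not spec.require_hyperthyroidism:
        return bool(len(symptom_dates))
    if "hyperthyroidism" not in codesets:
        raise ConfigurationError("unknown code set name: 'hyperthyroidism'")
    hyper_dates = matching_claim_dates(claims, codesets["hyperthyroidism"])
    if not len(hyper_dates) or not len(symptom_dates):
        return False
    if spec.window_days is None:
        return True
    return co_occurrence_within(hyper_dates, symptom_dates, spec.window_days)


def _membership_mask(
    systems: pd.Series, normalized: pd.Series, codeset: CodeSet
) -> np.ndarray:
    mask = np.zeros(len(systems), dtype=bool)
    for sys_name in set(systems.unique()):
        sys_rows = (systems == sys_name).to_numpy()
        codes = normalized[sys_rows]
        exact = {c for s, c in codeset.exact if s == sys_name}
        hit = codes.isin(exact).to_numpy()
        for s, prefix in codeset.prefixes:
            if s == sys_name:
                hit |= codes.str.startswith(prefix).to_numpy()
        mask[sys_rows] = hit
    return mask


def run_algorithms(
    cohort: Cohort,
    specs: list[AlgorithmSpec] | None = None,
    codesets: dict[str, CodeSet] | None = None,
    observation_window_days: int | None = None,
) -> pd.DataFrame:
    """Apply all algorithms to every patient; returns the prediction matrix
    (rows: patient_id, columns ``alg<k>``, boolean verdicts).

    ``observation_window_days`` optionally restricts evaluation to claims
    within that many days of each patient's index date; the default is the
    entire available history.  Deterministic and invariant to claim order.
    """
    if specs is None:
        specs = default_algorithms()
    if codesets is None:
        codesets = default_codelists()
    for spec in specs:
        missing = [n for n in spec.symptom_sets if n not in codesets]
        if spec.require_hyperthyroidism and "hyperthyroidism" not in codesets:
            missing.append("hyperthyroidism")
        if missing:
            raise ConfigurationError(f"unknown code set name(s): {missing}")

    patients, claims = cohort.patients, cohort.claims
    if observation_window_days is not None and len(claims):
        merged = claims.merge(
            patients[["patient_id", "index_day"]], on="patient_id", how="inner"
        )
        keep = (
            (merged["service_day"] - merged["index_day"]).abs()
            <= observation_window_days
        )
        claims = merged.loc[keep.to_numpy(), ["patient_id", "service_day",
                                              "code", "system"]]

    normalized = pd.Series(
        [normalize_code(c, s) for c, s in zip(claims["code"], claims["system"])],
        index=claims.index,
        dtype="object",
    )
    set_masks = {
        name: _membership_mask(claims["system"], normalized, cs)
        for name, cs in codesets.items()
    }

    def dates_by_patient(mask: np.ndarray) -> dict[str, np.ndarray]:
        sub = claims.loc[mask, ["patient_id", "service_day"]]
        return {
            pid: np.sort(g.to_numpy(dtype="int64"))
            for pid, g in sub.groupby("patient_id")["service_day"]
        }

    hyper_by_patient = dates_by_patient(set_masks.get("hyperthyroidism",
                                                      np.zeros(len(claims), bool)))

    out = pd.DataFrame(index=pd.Index(patients["patient_id"], name="patient_id"))
    for spec in specs:
        symptom_mask = np.zeros(len(claims), dtype=bool)
        for name in spec.symptom_sets:
            symptom_mask |= set_masks[name]
        symp_by_patient = dates_by_patient(symptom_mask)

        if not spec.require_hyperthyroidism:
            positive = set(symp_by_patient)
        elif spec.window_days is None:
            positive = set(symp_by_patient) & set(hyper_by_patient)
        else:
            positive = {
                pid
                for pid in set(symp_by_patient) & set(hyper_by_patient)
                if co_occurrence_within(
                    hyper_by_patient[pid], symp_by_patient[pid], spec.window_days
                )
            }
        out[f"alg{spec.id}"] = out.index.isin(positive)
    return out
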