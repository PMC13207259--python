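"""Published operating points of the TED claims-validation study.

The original linked registry/claims dataset is proprietary, but the study's
reported per-algorithm and per-threshold operating points (sensitivity,
specificity, and the metrics derived from them) are internally consistent
given the reported cohort composition.  This module exposes those reported
rows as data so the metric machinery can be checked against them: derived
metrics (PLR, NLR, PPV, NPV, F1) recomputed from each row's sensitivity and
specificity plus the cohort prevalence must land within print rounding of
the reported values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .metrics import predictive_values_at_prevalence

#: Reported validation-cohort composition (reference-positive / -negative).
COHORT_TED = 66_396
COHORT_NONTED = 25_754
COHORT_TOTAL = COHORT_TED + COHORT_NONTED
COHORT_PREVALENCE = COHORT_TED / COHORT_TOTAL


def load_reported_operating_points() -> pd.DataFrame:
    """The reported metric rows, one per algorithm / model threshold."""
    with resources.as_file(
        resources.files("tedclaims.data") / "reported_operating_points.csv"
    ) as p:
        return pd.read_csv(p, dtype={"label": str})


def derive_from_operating_point(
    sensitivity: float, specificity: float, prevalence: float = COHORT_PREVALENCE
) -> dict[str, float]:
    """Recompute the full derived-metric set from one operating point.

    Returns PLR, NLR, and prevalence-transported PPV, NPV and F1 on natural
    scales (fractions for proportions, raw ratios).
    """
    ppv, npv = predictive_values_at_prevalence(sensitivity, specificity, prevalence)
    return {
        "plr": sensitivity / (1.0 - specificity),
        "nlr": (1.0 - sensitivity) / specificity,
        "ppv": ppv,
        "npv": npv,
        "f1": 2.0 * ppv * sensitivity / (ppv + sensitivity),
    }
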