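"""Diagnostic-performance metrics with confidence intervals.

Computes the standard 2x2 metric set — sensitivity, specificity, PPV, NPV,
positive/negative likelihood ratios and F1 — plus AUC and a probability
threshold sweep.  Predictive values can be transported to an arbitrary
prevalence via Bayes' rule, which is how a validation cohort's PPV/NPV map
onto populations with different disease frequency.

Confidence-interval conventions (stated in output metadata): Wilson score
for proportions, the log method for likelihood ratios, a normal
approximation for AUC.  Undefined metrics (zero denominators) surface as
``None`` with the offending cell named in ``notes`` — never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .errors import InputError

CI_METHODS = {
    "proportions": "wilson",
    "likelihood_ratios": "log",
    "auc": "normal-approximation",
}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InputError("confusion counts must be non-negative")
        if self.total == 0:
            raise InputError("confusion counts sum to zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class DiagnosticMetrics:
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    plr: float | None  # may be +inf when specificity == 1 and sensitivity > 0
    nlr: float | None
    f1: float | None
    prevalence: float | None
    auc: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)


def confusion(predicted, reference) -> ConfusionCounts:
    """2x2 counts of a boolean prediction against the reference standard."""
    pred = np.asarray(predicted, dtype=bool)
    ref = np.asarray(reference, dtype=bool)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise InputError("predicted and reference must be equal-length vectors")
    if len(pred) == 0:
        raise InputError("empty vectors")
    return ConfusionCounts(
        tp=int(np.sum(pred & ref)),
        fp=int(np.sum(pred & ~ref)),
        fn=int(np.sum(~pred & ref)),
        tn=int(np.sum(~pred & ~ref)),
    )


def proportion_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion; subset of [0, 1]."""
    if not 0 <= successes <= n or n < 1:
        raise InputError("need 0 <= successes <= n, n >= 1")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def lr_ci(
    cm: ConfusionCounts, level: float = 0.95
) -> dict[str, tuple[float, float] | None]:
    """Log-method confidence intervals for the likelihood ratios.

    SE(ln PLR) = sqrt((1-sens)/(sens*n1) + spec/((1-spec)*n0)) and the NLR
    analogue; returns None for a ratio whose cells are degenerate.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    n1, n0 = cm.tp + cm.fn, cm.fp + cm.tn
    out: dict[str, tuple[float, float] | None] = {"plr": None, "nlr": None}
    if n1 and n0:
        sens, spec = cm.tp / n1, cm.tn / n0
        if 0 < sens and 0 < spec < 1:
            plr = sens / (1 - spec)
            se = np.sqrt((1 - sens) / (sens * n1) + spec / ((1 - spec) * n0))
            out["plr"] = (plr * np.exp(-z * se), plr * np.exp(z * se))
        if sens < 1 and spec > 0:
            nlr = (1 - sens) / spec
            se = np.sqrt(sens / ((1 - sens) * n1) + (1 - spec) / (spec * n0))
            out["nlr"] = (nlr * np.exp(-z * se), nlr * np.exp(z * se))
    return out


def predictive_values_at_prevalence(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float | None, float | None]:
    """Transport PPV/NPV to a target prevalence via Bayes' rule.

    ppv = sens*pi / (sens*pi + (1-spec)(1-pi));
    npv = spec*(1-pi) / ((1-sens)*pi + spec*(1-pi)).
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise InputError("sensitivity/specificity must lie in [0, 1]")
    if not 0.0 < prevalence < 1.0:
        raise InputError("prevalence must lie in (0, 1)")
    pi = prevalence
    pos = sensitivity * pi + (1.0 - specificity) * (1.0 - pi)
    neg = (1.0 - sensitivity) * pi + specificity * (1.0 - pi)
    ppv = sensitivity * pi / pos if pos > 0 else None
    npv = specificity * (1.0 - pi) / neg if neg > 0 else None
    return ppv, npv


def metrics_from_counts(
    cm: ConfusionCounts,
    ci_level: float = 0.95,
    prevalence: float | None = None,
) -> DiagnosticMetrics:
    """All 2x2 metrics from confusion counts.

    When ``prevalence`` is given, PPV/NPV are transported to it; otherwise
    they come from the raw 2x2 table (equivalently, transport at the
    empirical prevalence).
    """
    n1, n0 = cm.tp + cm.fn, cm.fp + cm.tn
    npred1, npred0 = cm.tp + cm.fp, cm.fn + cm.tn
    notes: dict[str, str] = {}
    ci: dict[str, tuple[float, float]] = {}

    def prop(num: int, den: int, name: str, zero_cell: str) -> float | None:
        if den == 0:
            notes[name] = f"undefined: {zero_cell} is empty"
            return None
        ci[name] = proportion_ci(num, den, ci_level)
        return num / den

    sens = prop(cm.tp, n1, "sensitivity", "reference-positive column")
    spec = prop(cm.tn, n0, "specificity", "reference-negative column")

    emp_prev = n1 / cm.total
    pi = prevalence if prevalence is not None else emp_prev
    if sens is not None and spec is not None and 0.0 < pi < 1.0:
        ppv, npv = predictive_values_at_prevalence(sens, spec, pi)
        if ppv is None:
            notes["ppv"] = "undefined: no predicted positives at this prevalence"
        if npv is None:
            notes["npv"] = "undefined: no predicted negatives at this prevalence"
    else:
        ppv = prop(cm.tp, npred1, "ppv", "predicted-positive row")
        npv = prop(cm.tn, npred0, "npv", "predicted-negative row")
    if prevalence is None:
        # raw-table CIs for predictive values
        if npred1:
            ci["ppv"] = proportion_ci(cm.tp, npred1, ci_level)
        if npred0:
            ci["npv"] = proportion_ci(cm.tn, npred0, ci_level)

    plr = nlr = None
    if sens is not None and spec is not None:
        if spec < 1.0:
            plr = sens / (1.0 - spec)
        elif sens > 0:
            plr = float("inf")
            notes["plr"] = "+inf: fp cell is zero"
        else:
            notes["plr"] = "undefined: fp and tp cells are zero"
        if spec > 0.0:
            nlr = (1.0 - sens) / spec
        else:
            notes["nlr"] = "undefined: tn cell is zero"
    lrci = lr_ci(cm, ci_level)
    for k in ("plr", "nlr"):
        if lrci[k] is not None:
            ci[k] = lrci[k]

    f1 = None
    if 2 * cm.tp + cm.fp + cm.fn > 0:
        f1 = 2 * cm.tp / (2 * cm.tp + cm.fp + cm.fn)
    else:
        notes["f1"] = "undefined: no positives predicted or present"
    if prevalence is not None and sens is not None and ppv is not None:
        # prevalence-transported F1 (harmonic mean of transported PPV and sens)
        f1 = (
            2 * ppv * sens / (ppv + sens) if (ppv + sens) > 0 else None
        )

    return DiagnosticMetrics(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        plr=plr, nlr=nlr, f1=f1, prevalence=pi, ci=ci, notes=notes,
    )


def auc(scores, reference) -> float | None:
    """Area under the ROC curve = normalized Mann-Whitney U, ties half."""
    ref = np.asarray(reference, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(ref):
        raise InputError("scores and reference must be equal length")
    if ref.all() or not ref.any():
        return None
    return float(roc_auc_score(ref, s))


@dataclass(frozen=True)
class ThresholdGrid:
    thresholds: tuple[float, ...] = (0.60, 0.65, 0.70, 0.75, 0.80, 0.85)

    def __post_init__(self):
        t = self.thresholds
        if any(not 0.0 < x < 1.0 for x in t) or any(
            a >= b for a, b in zip(t, t[1:])
        ):
            raise InputError("thresholds must be strictly increasing in (0, 1)")


def threshold_sweep(
    probabilities,
    reference,
    grid: ThresholdGrid = ThresholdGrid(),
    prevalence: float | None = None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Metric row per probability threshold (positive iff prob >= threshold).

    Sensitivity is nonincreasing and specificity nondecreasing in the
    threshold.  PPV/NPV/F1 are transported to ``prevalence`` when given.
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.min() < 0.0 or probs.max() > 1.0:
        raise InputError("probabilities must lie in [0, 1]")
    rows = []
    for t in grid.thresholds:
        cm = confusion(probs >= t, reference)
        m = metrics_from_counts(cm, ci_level=ci_level, prevalence=prevalence)
        rows.append(
            {
                "threshold": t,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "ppv": m.ppv,
                "npv": m.npv,
                "plr": m.plr,
                "nlr": m.nlr,
                "f1": m.f1,
            }
        )
    return pd.DataFrame(rows)


# Report rounding conventions: percentages to 1 dp, ratios to 2 dp.
def pct1(x: float | None) -> float | None:
    return None if x is None else round(100.0 * x, 1)


def ratio2(x: float | None) -> float | None:
    return None if x is None else round(x, 2)
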