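#!/usr/bin/env python
"""Run the six rule-based TED algorithms and score them against the
reference standard.

Confirms the monotone nesting of the positive sets (alg2 <= alg3 <= alg4 <=
alg1 and alg2 <= alg6) and writes a per-algorithm metric table (sensitivity,
specificity, PPV, NPV, PLR, NLR, F1 with 95% CIs) under results/.
"""

from pathlib import Path

import pandas as pd

from tedclaims.io import read_dataset
from tedclaims.metrics import confusion, metrics_from_counts, pct1, ratio2
from tedclaims.phenotype import run_algorithms
from tedclaims.synth import Cohort

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main() -> None:
    cohort = read_dataset(DATA)
    included = pd.read_csv(DATA / "included_patients.csv")
    analytic = Cohort(
        patients=included,
        claims=cohort.claims[
            cohort.claims["patient_id"].isin(included["patient_id"])
        ].reset_index(drop=True),
        enrollment=cohort.enrollment,
    )

    preds = run_algorithms(analytic)
    pos = {c: set(preds.index[preds[c]]) for c in preds.columns}
    nested = (pos["alg2"] <= pos["alg3"] <= pos["alg4"] <= pos["alg1"]
              and pos["alg2"] <= pos["alg6"])
    print(f"algorithm nesting holds: {nested}")

    ref = included.set_index("patient_id")["reference_label"].reindex(preds.index)
    rows = []
    for col in preds.columns:
        m = metrics_from_counts(confusion(preds[col], ref))
        rows.append(
            {
                "algorithm": col,
                "n_positive": int(preds[col].sum()),
                "sensitivity_pct": pct1(m.sensitivity),
                "sensitivity_ci": tuple(pct1(x) for x in m.ci["sensitivity"]),
                "specificity_pct": pct1(m.specificity),
                "specificity_ci": tuple(pct1(x) for x in m.ci["specificity"]),
                "ppv_pct": pct1(m.ppv),
                "npv_pct": pct1(m.npv),
                "plr": ratio2(m.plr),
                "nlr": ratio2(m.nlr),
                "f1": ratio2(m.f1),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "rule_algorithm_metrics.csv", index=False)
    print(table.drop(columns=["sensitivity_ci", "specificity_ci"])
               .to_string(index=False))


if __name__ == "__main__":
    main()
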