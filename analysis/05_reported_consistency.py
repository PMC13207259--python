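#!/usr/bin/env python
"""Internal-consistency check of the published validation tables.

The original linked dataset is proprietary, but every derived metric in the
published per-algorithm and per-threshold tables (PLR, NLR, PPV, NPV, F1)
is determined by that row's sensitivity and specificity plus the cohort
composition (66,396 TED / 25,754 non-TED).  This driver recomputes each
derived value with the package's metric machinery and reports how many land
within one unit in the last printed digit.  Writes the side-by-side table
under results/.
"""

from pathlib import Path

import pandas as pd

from tedclaims.reported import (
    COHORT_PREVALENCE,
    derive_from_operating_point,
    load_reported_operating_points,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = load_reported_operating_points()
    rows, ok, checks = [], 0, 0
    for row in table.itertuples(index=False):
        d = derive_from_operating_point(
            row.sensitivity_pct / 100.0, row.specificity_pct / 100.0
        )
        rec = {"model": row.model, "label": row.label,
               "sensitivity_pct": row.sensitivity_pct,
               "specificity_pct": row.specificity_pct}
        for metric, printed, dp, scale in [
            ("plr", row.plr, 2, 1),
            ("nlr", row.nlr, 2, 1),
            ("ppv", row.ppv_pct, 1, 100),
            ("npv", row.npv_pct, 1, 100),
            ("f1", row.f1, 2, 1),
        ]:
            got = round(scale * d[metric], dp)
            rec[f"{metric}_reported"] = printed
            rec[f"{metric}_recomputed"] = got
            checks += 1
            ok += abs(got - printed) <= 10.0 ** (-dp) + 1e-9
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "reported_consistency.csv", index=False)
    print(f"cohort prevalence used: {COHORT_PREVALENCE:.5f} (66,396 / 92,150)")
    print(f"{ok}/{checks} derived values agree within one unit in the last "
          f"printed digit")
    print(out[["model", "label", "plr_reported", "plr_recomputed",
               "ppv_reported", "ppv_recomputed",
               "f1_reported", "f1_recomputed"]].to_string(index=False))


if __name__ == "__main__":
    main()
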