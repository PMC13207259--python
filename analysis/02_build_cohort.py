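#!/usr/bin/env python
"""Apply the study inclusion criteria and characterize coding patterns.

Inclusion: adults (>=18 at index) with 365 days of continuous pre-index
enrollment and an evaluated reference label.  Also reports the minimum
number of reference-positive test patients needed to estimate a 70%
sensitivity to a 2.5% margin at 95% confidence, and a 50/50 split of the
analytic cohort.  Writes the attrition flow and the per-code window
frequency table under results/.
"""

from pathlib import Path

import pandas as pd

from tedclaims.cohort import (
    InclusionCriteria,
    SampleSizeParams,
    SplitSpec,
    apply_inclusion,
    characterize_coding_patterns,
    min_positive_sample_size,
    split_cohort,
)
from tedclaims.io import read_dataset

SEED = 20_260_915
ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main() -> None:
    cohort = read_dataset(DATA)
    included, log = apply_inclusion(cohort, InclusionCriteria())

    counts = log["reason"].value_counts()
    flow = pd.DataFrame(
        {
            "step": ["generated", "excluded_age", "excluded_enrollment",
                     "excluded_reference_not_evaluated", "included"],
            "n": [
                len(cohort.patients),
                int(counts.get("age", 0)),
                int(counts.get("enrollment", 0)),
                int(counts.get("reference_not_evaluated", 0)),
                len(included),
            ],
        }
    )
    flow.to_csv(ROOT / "cohort_flow.csv", index=False)
    included.to_csv(DATA / "included_patients.csv", index=False)
    print(flow.to_string(index=False))

    n_min = min_positive_sample_size(
        SampleSizeParams(expected_sensitivity=0.70, margin_of_error=0.025)
    )
    train, test = split_cohort(
        included, SplitSpec(train_fraction=0.5, seed=SEED,
                            stratify_by_reference=True)
    )
    ref = included.set_index("patient_id")["reference_label"]
    n_pos_test = int(ref.loc[test].sum())
    print(f"\nminimum reference-positive test sample: {n_min}")
    print(f"50/50 split: {len(train)} train / {len(test)} test; "
          f"{n_pos_test} reference-positive in test "
          f"({'meets' if n_pos_test >= n_min else 'below'} the minimum)")

    ted = included[included["reference_label"]].reset_index(drop=True)
    table = characterize_coding_patterns(cohort.claims, ted)
    table.to_csv(ROOT / "coding_patterns.csv", index=False)
    top = table[table["window"] == 90].head(5)
    print("\ntop codes within +/-90 days of index (reference-positive patients):")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
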