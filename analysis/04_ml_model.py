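#!/usr/bin/env python
"""Train and evaluate the machine-learning TED classifier.

Builds binary code indicators over the 2-year baseline window on the
training half only, screens at 0.1% prevalence in both classes, drops
ICD-10 X/Y/Z utilization chapters, runs RFE-consensus feature selection
over a compact hyperparameter grid, fits the simplified small-tree model on
the consensus codes, and sweeps classification thresholds on the held-out
test half.  Writes the consensus feature list and the threshold report
under results/.  (The full 81-configuration grid is available via
MLConfig's default grid; this driver uses a compact grid at analysis
scale.)
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tedclaims.cohort import SplitSpec, split_cohort
from tedclaims.io import read_dataset
from tedclaims.learners import boosted_trees_factory
from tedclaims.metrics import pct1, ratio2
from tedclaims.mlpipe import (
    MLConfig,
    build_feature_matrix,
    consensus_features,
    evaluate_model,
    exclude_utilization_codes,
    prevalence_screen,
    run_grid,
    train_simplified,
)

SEED = 20_260_915
ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"

GRID = {
    "learning_rate": [0.1, 0.3],
    "max_depth": [3],
    "n_estimators": [40],
    "reg_lambda": [1.0],
}


def main() -> None:
    cohort = read_dataset(DATA)
    included = pd.read_csv(DATA / "included_patients.csv")
    claims = cohort.claims[
        cohort.claims["patient_id"].isin(included["patient_id"])
    ]

    cfg = MLConfig(grid=dict(GRID), seed=SEED)
    train_ids, test_ids = split_cohort(
        included, SplitSpec(0.5, seed=SEED, stratify_by_reference=True)
    )
    matrix = build_feature_matrix(claims, included, cfg.baseline_days)
    labels = included.set_index("patient_id")["reference_label"]
    Xtr, ytr = matrix.loc[train_ids], labels.loc[train_ids]
    Xte, yte = matrix.loc[test_ids], labels.loc[test_ids]

    retained = prevalence_screen(Xtr, ytr, cfg.screen_threshold)
    kept = exclude_utilization_codes(retained, cfg.excluded_icd_chapters)
    print(f"features: {matrix.shape[1]} built, {len(retained)} past the "
          f"0.1% screen, {len(kept)} after X/Y/Z exclusion")

    traces = run_grid(Xtr[kept], ytr, boosted_trees_factory, cfg)
    consensus = consensus_features(traces, cfg.consensus_k)
    consensus.to_csv(ROOT / "consensus_features.csv", index=False)
    print(f"consensus codes selected: {len(consensus)} "
          f"(top 5: {', '.join(consensus['feature'].head(5))})")

    model, cols = train_simplified(
        Xtr, ytr, consensus["feature"].tolist(),
        trees=cfg.simplified_trees, seed=SEED,
    )
    report, model_auc = evaluate_model(
        model, cols, Xte, yte, cfg.thresholds, train_ids=set(train_ids)
    )
    out = report.copy()
    for c in ("sensitivity", "specificity", "ppv", "npv"):
        out[c + "_pct"] = out[c].map(pct1)
        out = out.drop(columns=[c])
    for c in ("plr", "nlr", "f1"):
        out[c] = out[c].map(ratio2)
    out["auc"] = ratio2(model_auc)
    out.to_csv(ROOT / "ml_thresholds.csv", index=False)
    print(f"\nsimplified {cfg.simplified_trees}-tree model, held-out AUC "
          f"{model_auc:.3f}; threshold sweep:")
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
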