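"""End-to-end reproducible pipeline: simulate -> build cohort -> rule
phenotyping -> ML feature pipeline -> evaluation reports, with a run
manifest (config snapshot, seed fan-out, file digests) sufficient to re-run
identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import InclusionCriteria, SplitSpec, apply_inclusion, split_cohort
from .errors import StageError, TedClaimsError
from .io import load_config_file, write_dataset
from .learners import boosted_trees_factory
from .metrics import ThresholdGrid, confusion, metrics_from_counts, pct1, ratio2
from .mlpipe import (
    MLConfig,
    build_feature_matrix,
    consensus_features,
    evaluate_model,
    exclude_utilization_codes,
    prevalence_screen,
    run_grid,
    train_simplified,
)
from .phenotype import default_algorithms, run_algorithms
from .synth import Cohort, CohortConfig, generate_cohort

REPORT_FILES = [
    "cohort_flow.csv",
    "rule_metrics.csv",
    "ml_thresholds.csv",
    "consensus_features.csv",
]

#: Demo-scale ML grid used by the default pipeline config (2 x 1 x 1 x 1);
#: the full 81-configuration grid is available by overriding ``ml.grid``.
SMALL_GRID = {
    "learning_rate": [0.1, 0.3],
    "max_depth": [3],
    "n_estimators": [40],
    "reg_lambda": [1.0],
}


def stage_seed(base_seed: int, stage: str) -> int:
    """Fan one top-level seed out to a stable per-stage seed (< 2**31)."""
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the full pipeline from a config mapping (or YAML/JSON path).

    Recognized keys: ``n_patients``, ``seed``, ``cohort`` (CohortConfig
    overrides), ``ml`` (MLConfig overrides), ``train_fraction``.  Writes the
    dataset, report CSVs and ``manifest.json`` under ``out_dir``.
    """
    if not isinstance(config, dict):
        config = load_config_file(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    started = time.strftime("%Y-%m-%dT%H:%M:%S")

    def stage(name: str, fn):
        try:
            return fn()
        except TedClaimsError:
            raise
        except Exception as exc:  # noqa: BLE001 - halt with stage name and cause
            raise StageError(name, exc) from exc

    # --- simulate ---------------------------------------------------------
    def _simulate() -> Cohort:
        cc = dict(config.get("cohort", {}))
        cc.setdefault("n_patients", int(config.get("n_patients", 5000)))
        cc.setdefault("seed", stage_seed(seed, "simulate"))
        return generate_cohort(CohortConfig(**cc))

    cohort = stage("synthetic_linked_data", _simulate)
    written = stage(
        "synthetic_linked_data", lambda: write_dataset(cohort, out / "data")
    )

    # --- build cohort -----------------------------------------------------
    def _build():
        included, log = apply_inclusion(cohort, InclusionCriteria())
        flow = pd.DataFrame(
            {
                "step": ["generated", *[f"excluded_{r}" for r in
                                        ("age", "enrollment",
                                         "reference_not_evaluated")],
                         "included"],
                "n": [
                    len(cohort.patients),
                    int((log["reason"] == "age").sum()),
                    int((log["reason"] == "enrollment").sum()),
                    int((log["reason"] == "reference_not_evaluated").sum()),
                    len(included),
                ],
            }
        )
        flow.to_csv(out / "cohort_flow.csv", index=False)
        return included

    included = stage("cohort_builder", _build)
    analytic = Cohort(
        patients=included,
        claims=cohort.claims.loc[
            cohort.claims["patient_id"].isin(included["patient_id"])
        ].reset_index(drop=True),
        enrollment=cohort.enrollment,
    )

    # --- rule phenotyping -------------------------------------------------
    def _phenotype():
        preds = run_algorithms(analytic)
        ref = analytic.patients.set_index("patient_id")["reference_label"]
        ref = ref.reindex(preds.index)
        rows = []
        for col in preds.columns:
            m = metrics_from_counts(confusion(preds[col], ref))
            rows.append(
                {
                    "algorithm": col,
                    "sensitivity_pct": pct1(m.sensitivity),
                    "specificity_pct": pct1(m.specificity),
                    "ppv_pct": pct1(m.ppv),
                    "npv_pct": pct1(m.npv),
                    "plr": ratio2(m.plr),
                    "nlr": ratio2(m.nlr),
                    "f1": ratio2(m.f1),
                }
            )
        pd.DataFrame(rows).to_csv(out / "rule_metrics.csv", index=False)
        return preds

    stage("rule_phenotyping", _phenotype)

    # --- ML train + evaluate ---------------------------------------------
    def _ml():
        ml_overrides = dict(config.get("ml", {}))
        ml_overrides.setdefault("grid", dict(SMALL_GRID))
        ml_overrides.setdefault("seed", stage_seed(seed, "ml"))
        mlc = MLConfig(**ml_overrides)

        train_ids, test_ids = split_cohort(
            analytic.patients,
            SplitSpec(
                train_fraction=float(config.get("train_fraction", 0.5)),
                seed=stage_seed(seed, "split"),
                stratify_by_reference=True,
            ),
        )
        matrix = build_feature_matrix(
            analytic.claims, analytic.patients, mlc.baseline_days
        )
        labels = analytic.patients.set_index("patient_id")["reference_label"]
        Xtr, ytr = matrix.loc[train_ids], labels.loc[train_ids]
        Xte, yte = matrix.loc[test_ids], labels.loc[test_ids]

        retained = prevalence_screen(Xtr, ytr, mlc.screen_threshold)
        retained = exclude_utilization_codes(retained, mlc.excluded_icd_chapters)
        traces = run_grid(Xtr[retained], ytr, boosted_trees_factory, mlc)
        consensus = consensus_features(traces, mlc.consensus_k)
        consensus.to_csv(out / "consensus_features.csv", index=False)

        model, cols = train_simplified(
            Xtr, ytr, consensus["feature"].tolist(),
            trees=mlc.simplified_trees, seed=stage_seed(seed, "simplified"),
        )
        report, model_auc = evaluate_model(
            model, cols, Xte, yte, mlc.thresholds,
            train_ids=set(train_ids),
        )
        report = report.assign(model="simplified", auc=model_auc)
        for c in ("sensitivity", "specificity", "ppv", "npv"):
            report[c + "_pct"] = report[c].map(pct1)
            report = report.drop(columns=[c])
        for c in ("plr", "nlr", "f1", "auc"):
            report[c] = report[c].map(ratio2)
        report.to_csv(out / "ml_thresholds.csv", index=False)

    stage("ml_feature_pipeline", _ml)

    # --- manifest ---------------------------------------------------------
    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "stage_seeds": {
            s: stage_seed(seed, s)
            for s in ("simulate", "split", "ml", "simplified")
        },
        "config": {k: v for k, v in config.items()},
        "started": started,
        "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def render_reports(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run directory."""
    run_dir = Path(run_dir)
    missing = [f for f in REPORT_FILES if not (run_dir / f).exists()]
    if missing:
        raise TedClaimsError(
            f"incomplete run at {run_dir}: missing artifacts {missing}"
        )
    lines = [f"run summary: {run_dir}"]
    rule = pd.read_csv(run_dir / "rule_metrics.csv")
    lines.append("\nrule-based algorithms (vs reference standard):")
    for row in rule.itertuples(index=False):
        lines.append(
            f"  {row.algorithm}: sens {row.sensitivity_pct}% | "
            f"spec {row.specificity_pct}% | ppv {row.ppv_pct}% | "
            f"plr {row.plr} | nlr {row.nlr} | f1 {row.f1}"
        )
    ml = pd.read_csv(run_dir / "ml_thresholds.csv")
    lines.append("\nsimplified model threshold sweep (held-out test set):")
    for row in ml.itertuples(index=False):
        lines.append(
            f"  p>={row.threshold}: sens {row.sensitivity_pct}% | "
            f"spec {row.specificity_pct}% | ppv {row.ppv_pct}% | f1 {row.f1}"
        )
    if "auc" in ml.columns and len(ml):
        lines.append(f"  test AUC: {ml['auc'].iloc[0]}")
    return "\n".join(lines)
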