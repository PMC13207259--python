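"""Dataset serialization.

A cohort round-trips through three tables (patients, claims, enrollment) in
either delimited text (CSV) or columnar (Parquet) form.  Integer day offsets
become ISO calendar dates on disk and are converted back on read, so
``read_dataset(write_dataset(x)) == x``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from ._dates import dates_to_days, days_to_dates
from .codes import CODE_SYSTEMS
from .errors import ParseError
from .synth import CLAIM_COLUMNS, ENROLLMENT_COLUMNS, PATIENT_COLUMNS, Cohort

_DAY_COLUMNS = {
    "patients": ["index_day", "first_claim_day"],
    "claims": ["service_day"],
    "enrollment": ["start_day", "end_day"],
}


def _externalize(name: str, df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in _DAY_COLUMNS[name]:
        if col in out.columns:
            date_col = col.replace("_day", "_date")
            vals = out[col]
            mask = vals.notna()
            rendered = pd.Series(pd.NA, index=out.index, dtype="object")
            if mask.any():
                rendered[mask] = days_to_dates(vals[mask].astype("int64"))
            out[date_col] = rendered
            out = out.drop(columns=[col])
    return out


def _internalize(name: str, df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in _DAY_COLUMNS[name]:
        date_col = col.replace("_day", "_date")
        if date_col in out.columns:
            vals = out[date_col]
            mask = vals.notna()
            days = pd.Series(pd.NA, index=out.index, dtype="Int64")
            if mask.any():
                days[mask] = dates_to_days(vals[mask]).to_numpy()
            # first_claim_day is nullable by contract (claimless patients)
            nullable = col == "first_claim_day"
            out[col] = days if nullable else days.astype("int64")
            out = out.drop(columns=[date_col])
    return out


def write_dataset(cohort: Cohort, path: str | Path, format: str = "csv") -> list[Path]:
    """Write the three cohort tables under ``path``; returns files written."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (
        ("patients", cohort.patients),
        ("claims", cohort.claims),
        ("enrollment", cohort.enrollment),
    ):
        ext = _externalize(name, df)
        f = path / f"{name}.{'parquet' if format == 'parquet' else 'csv'}"
        if format == "parquet":
            ext.to_parquet(f, index=False)
        else:
            ext.to_csv(f, index=False)
        written.append(f)
    return written


def _validate_claims(claims: pd.DataFrame) -> None:
    bad = ~claims["system"].isin(CODE_SYSTEMS)
    if bad.any():
        row = int(bad.idxmax())
        raise ParseError(
            f"unknown code system {claims.loc[row, 'system']!r}", row=row
        )


def read_dataset(path: str | Path) -> Cohort:
    """Read a dataset written by :func:`write_dataset` (CSV or Parquet)."""
    path = Path(path)
    frames = {}
    for name in ("patients", "claims", "enrollment"):
        csv, pq = path / f"{name}.csv", path / f"{name}.parquet"
        if pq.exists():
            df = pd.read_parquet(pq)
        elif csv.exists():
            df = pd.read_csv(csv)
        else:
            raise ParseError(f"missing table {name!r} under {path}")
        frames[name] = _internalize(name, df)

    patients, claims, enrollment = (
        frames["patients"], frames["claims"], frames["enrollment"]
    )
    if len(claims):
        _validate_claims(claims)
        claims["code"] = claims["code"].astype(str)
    else:
        claims = pd.DataFrame(columns=CLAIM_COLUMNS)
    for col in ("true_ted", "reference_label", "has_claims", "reference_evaluated"):
        if col in patients.columns:
            patients[col] = patients[col].astype(bool)
    return Cohort(
        patients=patients[
            [c for c in PATIENT_COLUMNS + ["first_claim_day"] if c in patients]
        ],
        claims=claims[CLAIM_COLUMNS] if len(claims) else claims,
        enrollment=enrollment[ENROLLMENT_COLUMNS],
    )


def load_config_file(path: str | Path) -> dict:
    """Read a YAML (or JSON; YAML is a superset) config mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"config file {path}: expected a mapping")
    return cfg
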