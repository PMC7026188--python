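"""Readers and writers for the CSV/JSON artefacts the pipeline exchanges.

Measurement extracts are comma-separated UTF-8 with a required header and
ISO-8601 date-times.  Row-level problems (unparseable timestamps or values,
non-positive creatinine, age outside the eligibility window) never abort a
run and are never silently dropped: offending rows go to a rejects table
with a reason, so input rows = processed + rejected always holds.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .ealert import MEASUREMENT_COLUMNS
from .errors import SchemaError
from .reference import ELIGIBLE_AGE_MAX_DAYS, ELIGIBLE_AGE_MIN_DAYS

AUDIT_REQUIRED_COLUMNS = ["patient_id", "recognised"]

_VALID_SEXES = {"any", "male", "female", "m", "f", ""}
_SEX_MAP = {"m": "male", "f": "female", "": "any"}


def prepare_measurements(
    raw: pd.DataFrame,
    *,
    age_min_days: float = ELIGIBLE_AGE_MIN_DAYS,
    age_max_days: float = ELIGIBLE_AGE_MAX_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate a raw measurement table into (clean, rejects).

    ``clean`` has typed columns in canonical order; ``rejects`` carries the
    original row values plus ``row_number`` (1-based, excluding the header)
    and ``reason``.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"measurement table is missing columns {missing}; expected {MEASUREMENT_COLUMNS}"
        )
    df = raw.loc[:, MEASUREMENT_COLUMNS].reset_index(drop=True)

    measured_at = pd.to_datetime(df["measured_at"], errors="coerce", format="ISO8601")
    value = pd.to_numeric(df["creatinine_umol_l"], errors="coerce")
    age = pd.to_numeric(df["age_days"], errors="coerce")
    sex_raw = df["sex"].astype(str).str.strip().str.lower()

    reason = pd.Series([""] * len(df), dtype=object)
    def flag(mask, msg):
        sel = mask & (reason == "")
        reason[sel] = msg

    flag(df["patient_id"].astype(str).str.strip() == "", "missing patient_id")
    flag(measured_at.isna(), "unparseable measured_at (expected ISO-8601)")
    flag(value.isna(), "unparseable creatinine_umol_l")
    flag(value.notna() & (value <= 0), "non-positive creatinine_umol_l")
    flag(age.isna(), "unparseable age_days")
    flag(age.notna() & ~((age >= age_min_days) & (age < age_max_days)),
         f"age outside eligibility window [{age_min_days},{age_max_days}) days")
    flag(~sex_raw.isin(_VALID_SEXES), "unknown sex (expected any/male/female)")

    bad = reason != ""
    rejects = df.loc[bad].copy()
    rejects.insert(0, "row_number", rejects.index + 1)
    rejects["reason"] = reason[bad]
    rejects = rejects.reset_index(drop=True)

    clean = pd.DataFrame(
        {
            "patient_id": df.loc[~bad, "patient_id"].astype(str),
            "measured_at": measured_at[~bad],
            "creatinine_umol_l": value[~bad].astype(float),
            "age_days": age[~bad].astype(float),
            "sex": sex_raw[~bad].map(lambda s: _SEX_MAP.get(s, s)),
            "centre": df.loc[~bad, "centre"].astype(str),
        }
    ).reset_index(drop=True)
    return clean, rejects


def read_measurements(
    path: str | Path,
    *,
    age_min_days: float = ELIGIBLE_AGE_MIN_DAYS,
    age_max_days: float = ELIGIBLE_AGE_MAX_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    return prepare_measurements(raw, age_min_days=age_min_days, age_max_days=age_max_days)


def read_audit(path: str | Path) -> pd.DataFrame:
    audit = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in AUDIT_REQUIRED_COLUMNS if c not in audit.columns]
    if missing:
        raise SchemaError(
            f"audit table is missing columns {missing}; expected at least {AUDIT_REQUIRED_COLUMNS}"
        )
    return audit


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, *, config: dict,
                   inputs: Optional[dict[str, str]] = None) -> None:
    """Run manifest: the configuration, package version and input checksums.

    Contains no timestamps, so re-running on identical inputs reproduces it
    byte for byte.
    """
    from . import __version__

    manifest = {
        "package": "akialert",
        "version": __version__,
        "config": config,
        "input_sha256": {
            name: sha256_file(p) for name, p in (inputs or {}).items() if p is not None
        },
    }
    write_json(manifest, path)
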