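"""Reading and writing discharge-record tables and run artifacts.

Discharge records travel as CSV/TSV with one row per hospitalization and a
fixed header; comorbidity codes are a single semicolon-joined field.  Flags
are serialized as 0/1.  Malformed rows are not fatal: they are collected
into a rejects table with a reason code, and accepted + rejected always
equals the input row count.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .risk_model import FHJ_LEVELS, MDC10_LABELS, PS_LEVELS
from .synthetic_data import RECORD_COLUMNS

__all__ = ["read_discharges", "write_discharges", "write_json", "config_hash"]

_FLAG_COLUMNS = ("emergency", "ambulance", "exam_hospitalization", "planned_short", "died")


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def write_discharges(records: pd.DataFrame, path, sidecar: Optional[dict] = None) -> None:
    """Write records as delimited text (flags as 0/1, codes ';'-joined).

    ``sidecar``, when given, is written as ``<path>.json`` alongside —
    conventionally the generator config and true parameters, for parameter
    recovery tests.
    """
    out = records.loc[:, list(RECORD_COLUMNS)].copy()
    for col in _FLAG_COLUMNS:
        out[col] = out[col].astype(bool).astype(int)
    out["comorbidity_codes"] = out["comorbidity_codes"].fillna("")
    out.to_csv(path, sep=_sep_for(path), index=False)
    if sidecar is not None:
        write_json(sidecar, str(path) + ".json")


def read_discharges(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a discharge table; returns ``(accepted, rejects)``.

    Rejected rows keep their original content plus a ``reject_reason``
    column (the first failing check: ``unknown_mdc``, ``bad_age_band``,
    ``bad_sex``, ``bad_ps_grade``, ``bad_fhj_class``, ``bad_flag``).
    """
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        dtype={"hospital_id": str, "comorbidity_codes": str},
        keep_default_na=False,
        na_values=[],
    )
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    if len(df) == 0:
        return df.loc[:, list(RECORD_COLUMNS)], df.assign(reject_reason=pd.Series(dtype=str))

    reason = pd.Series("", index=df.index, dtype=object)

    def mark(mask, code):
        reason[(reason == "") & mask] = code

    age = pd.to_numeric(df["age_band"], errors="coerce")
    mark(~df["mdc10"].isin(MDC10_LABELS), "unknown_mdc")
    mark(age.isna() | (age < 0) | (age > 5) | (age != age.round()), "bad_age_band")
    mark(~df["sex"].isin(["male", "female"]), "bad_sex")
    mark(~df["ps_grade"].isin(PS_LEVELS), "bad_ps_grade")
    mark(~df["fhj_class"].isin(FHJ_LEVELS), "bad_fhj_class")
    for col in _FLAG_COLUMNS:
        v = pd.to_numeric(df[col], errors="coerce")
        mark(~v.isin([0, 1]), "bad_flag")

    bad = reason != ""
    rejects = df[bad].copy()
    rejects["reject_reason"] = reason[bad]
    accepted = df[~bad].copy()
    accepted["age_band"] = age[~bad].astype(int)
    for col in _FLAG_COLUMNS:
        accepted[col] = pd.to_numeric(accepted[col]).astype(bool)
    accepted["comorbidity_codes"] = accepted["comorbidity_codes"].fillna("")
    return accepted.reset_index(drop=True)[list(RECORD_COLUMNS)], rejects


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if hasattr(obj, "item"):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_hash(payload: dict) -> str:
    """Stable sha256 of a JSON-serializable configuration mapping."""
    blob = json.dumps(payload, sort_keys=True, default=_jsonify).encode()
    return hashlib.sha256(blob).hexdigest()
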