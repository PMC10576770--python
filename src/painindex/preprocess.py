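"""Reading/writing the cohort tables and the per-minute noise filter.

All tables are plain CSV with a mandatory header, integer minutes since
ICU admission (minute 0 = admission), and missing values as empty fields.
The noise filter is row-atomic: a record in which any present vital
violates any plausibility rule is excluded whole, and every exclusion is
logged with the rule it violated.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .config import VITALS, NoiseRuleSet

VITALS_COLUMNS = ["patient_id", "t_min", "hr", "sbp", "mbp", "dbp",
                  "rr", "spo2"]
ASSESSMENT_COLUMNS = ["patient_id", "t_min", "cpot", "rass", "cam_icu"]
EVENT_COLUMNS = ["patient_id", "t_min", "drug", "dose_ug"]
DEMOGRAPHIC_COLUMNS = ["patient_id", "age", "sex"]


def _read_table(path, columns) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise ValueError(
            f"{path}: bad header {list(df.columns)}, expected {columns}")
    return df


def _numeric(df: pd.DataFrame, col: str, path, required: bool = False,
             integer: bool = False) -> pd.Series:
    """Coerce a string column to numbers, citing the offending CSV row."""
    raw = df[col].str.strip()
    out = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
    bad = out.isna() & (raw != "")
    if bad.any():
        row = int(bad.idxmax()) + 2  # header is line 1
        raise ValueError(
            f"{path}: non-numeric value {raw[bad.idxmax()]!r} in column "
            f"'{col}' at line {row}")
    if required and out.isna().any():
        row = int(out.isna().idxmax()) + 2
        raise ValueError(f"{path}: missing value in required column "
                         f"'{col}' at line {row}")
    if integer:
        frac = out.dropna() % 1
        if (frac != 0).any():
            row = int(frac[frac != 0].index[0]) + 2
            raise ValueError(f"{path}: non-integer value in column "
                             f"'{col}' at line {row}")
    return out


def _check_unique_minutes(df: pd.DataFrame, path) -> None:
    dup = df.duplicated(subset=["patient_id", "t_min"])
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise ValueError(
            f"{path}: duplicate (patient_id, t_min) record at line {row}")


def read_vitals(path) -> pd.DataFrame:
    """Read vitals.csv into a typed frame sorted by (patient, minute)."""
    df = _read_table(path, VITALS_COLUMNS)
    out = pd.DataFrame({"patient_id": df["patient_id"]})
    out["t_min"] = _numeric(df, "t_min", path, required=True, integer=True)
    if (out["t_min"] < 0).any():
        row = int((out["t_min"] < 0).idxmax()) + 2
        raise ValueError(f"{path}: negative t_min at line {row}")
    out["t_min"] = out["t_min"].astype(np.int64)
    for v in VITALS:
        out[v] = _numeric(df, v, path)
    _check_unique_minutes(out, path)
    return (out.sort_values(["patient_id", "t_min"], kind="stable")
            .reset_index(drop=True))


def read_assessments(path) -> pd.DataFrame:
    df = _read_table(path, ASSESSMENT_COLUMNS)
    out = pd.DataFrame({"patient_id": df["patient_id"]})
    out["t_min"] = _numeric(df, "t_min", path, required=True,
                            integer=True).astype(np.int64)
    out["cpot"] = _numeric(df, "cpot", path, integer=True)
    out["rass"] = _numeric(df, "rass", path, integer=True)
    cpot = out["cpot"].dropna()
    if ((cpot < 0) | (cpot > 8)).any():
        raise ValueError(f"{path}: cpot outside [0, 8]")
    rass = out["rass"].dropna()
    if ((rass < -5) | (rass > 4)).any():
        raise ValueError(f"{path}: rass outside [-5, 4]")
    cam = df["cam_icu"].str.strip().replace("", np.nan)
    bad = cam.dropna()[~cam.dropna().isin(["positive", "negative"])]
    if len(bad):
        raise ValueError(
            f"{path}: cam_icu must be positive/negative/empty, got "
            f"{bad.iloc[0]!r} at line {int(bad.index[0]) + 2}")
    out["cam_icu"] = cam
    return (out.sort_values(["patient_id", "t_min"], kind="stable")
            .reset_index(drop=True))


def read_events(path) -> pd.DataFrame:
    df = _read_table(path, EVENT_COLUMNS)
    out = pd.DataFrame({"patient_id": df["patient_id"]})
    out["t_min"] = _numeric(df, "t_min", path, required=True,
                            integer=True).astype(np.int64)
    out["drug"] = df["drug"].str.strip()
    out["dose_ug"] = _numeric(df, "dose_ug", path)
    return (out.sort_values(["patient_id", "t_min"], kind="stable")
            .reset_index(drop=True))


def read_demographics(path) -> pd.DataFrame:
    df = _read_table(path, DEMOGRAPHIC_COLUMNS)
    out = pd.DataFrame({"patient_id": df["patient_id"]})
    out["age"] = _numeric(df, "age", path, required=True,
                          integer=True).astype(np.int64)
    sex = df["sex"].str.strip()
    bad = sex[~sex.isin(["male", "female"])]
    if len(bad):
        raise ValueError(f"{path}: sex must be male/female, got "
                         f"{bad.iloc[0]!r} at line {int(bad.index[0]) + 2}")
    out["sex"] = sex
    return out


def _write(df: pd.DataFrame, columns, path) -> None:
    df.to_csv(path, index=False, columns=columns, na_rep="")


def write_vitals(df, path):
    _write(df, VITALS_COLUMNS, path)


def write_assessments(df, path):
    _write(df, ASSESSMENT_COLUMNS, path)


def write_events(df, path):
    _write(df, EVENT_COLUMNS, path)


def write_demographics(df, path):
    _write(df, DEMOGRAPHIC_COLUMNS, path)


# ---------------------------------------------------------------------------
# noise filter


def apply_noise_filter(vitals: pd.DataFrame,
                       rules: NoiseRuleSet | None = None) -> tuple:
    """Row-atomic plausibility filtering of a vitals frame.

    Returns ``(kept, exclusion_log)`` where the log has one row per
    (patient, minute, violated rule); a minute violating several rules
    appears once per rule.  Missing fields never trigger exclusion.
    """
    rules = rules or NoiseRuleSet()
    violations = []
    any_bad = np.zeros(len(vitals), dtype=bool)
    for v in VITALS:
        lo, hi = rules.ranges[v]
        col = vitals[v]
        bad = col.notna() & ((col < lo) | (col > hi))
        any_bad |= bad.to_numpy()
        if bad.any():
            violations.append(pd.DataFrame({
                "patient_id": vitals.loc[bad, "patient_id"],
                "t_min": vitals.loc[bad, "t_min"],
                "rule": f"{v}_range"}))
    if rules.enforce_pressure_order:
        p = vitals[["sbp", "mbp", "dbp"]]
        present = p.notna().all(axis=1)
        bad = present & ~((vitals["dbp"] <= vitals["mbp"])
                          & (vitals["mbp"] <= vitals["sbp"]))
        any_bad |= bad.to_numpy()
        if bad.any():
            violations.append(pd.DataFrame({
                "patient_id": vitals.loc[bad, "patient_id"],
                "t_min": vitals.loc[bad, "t_min"],
                "rule": "pressure_order"}))
    log_cols = ["patient_id", "t_min", "rule"]
    if violations:
        log = (pd.concat(violations)[log_cols]
               .sort_values(["patient_id", "t_min", "rule"], kind="stable")
               .reset_index(drop=True))
    else:
        log = pd.DataFrame(columns=log_cols)
    kept = vitals.loc[~any_bad].reset_index(drop=True)
    return kept, log
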