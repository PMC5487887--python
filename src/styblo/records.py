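"""Survey unit-record I/O, eligibility filtering and the case definition.

Unit records are plain CSV with a fixed header.  Reading is strict about
the schema but tolerant of malformed rows: every bad value becomes a
row-level error record (row number, column, offending value) and the rest
of the file loads; a missing mandatory column is a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hazard import age_group_label

#: CSV schema: column -> (dtype kind, mandatory)
SCHEMA: dict[str, tuple[str, bool]] = {
    "survey_year": ("int", True),
    "sex": ("sex", True),
    "age": ("int", True),
    "region": ("str", True),
    "fasting_confirmed": ("bool", True),
    "fpg": ("float", False),
    "on_medication": ("bool", True),
    "pregnant": ("bool", True),
    "weight": ("float", False),
    "height": ("float", False),
}

FPG_THRESHOLD = 7.0  # mmol/L

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


class SchemaError(ValueError):
    """A mandatory column is absent or the header does not match."""


@dataclass
class SurveyRecordSet:
    """Typed unit records plus the row-level parse/eligibility bookkeeping."""

    records: pd.DataFrame
    errors: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "column", "value", "reason"])
    )
    removed: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


def _parse_column(raw: pd.Series, kind: str):
    """Return (parsed series, boolean bad-mask). NaN allowed for optionals."""
    if kind in ("int", "float"):
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if kind == "int":
            frac = parsed.dropna() % 1
            if (frac != 0).any():
                bad |= parsed.notna() & (parsed % 1 != 0)
        return parsed, bad
    if kind == "bool":
        s = raw.astype(str).str.strip().str.lower()
        parsed = pd.Series(pd.NA, index=raw.index, dtype="boolean")
        parsed[s.isin(_TRUE)] = True
        parsed[s.isin(_FALSE)] = False
        bad = ~s.isin(_TRUE | _FALSE)
        return parsed, bad
    if kind == "sex":
        s = raw.astype(str).str.strip().str.lower()
        s = s.replace({"m": "male", "f": "female", "men": "male", "women": "female"})
        bad = ~s.isin(["male", "female"])
        return s, bad
    return raw.astype(str), pd.Series(False, index=raw.index)


def read_survey_records(path) -> SurveyRecordSet:
    """Read a unit-record CSV, reporting (not dropping) malformed rows.

    Raises :class:`SchemaError` naming any missing mandatory column.
    Rows with an unparseable value in any column are excluded from
    ``records`` and enumerated in ``errors``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace("", np.nan)
    missing = [c for c, (_, mand) in SCHEMA.items() if mand and c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    errors = []
    parsed = {}
    bad_any = pd.Series(False, index=raw.index)
    for col, (kind, mand) in SCHEMA.items():
        if col not in raw.columns:
            parsed[col] = pd.Series(np.nan, index=raw.index)
            continue
        vals, bad = _parse_column(raw[col], kind)
        if mand:
            bad = bad | vals.isna()
        parsed[col] = vals
        for i in raw.index[bad]:
            errors.append(
                {"row": int(i) + 2, "column": col, "value": raw[col].get(i),
                 "reason": f"unparseable {kind}"}
            )
        bad_any |= bad

    df = pd.DataFrame(parsed)[list(SCHEMA)]
    df = df[~bad_any].reset_index(drop=True)
    for col in ("survey_year", "age"):
        df[col] = df[col].astype(int)
    for col in ("fasting_confirmed", "on_medication", "pregnant"):
        df[col] = df[col].astype(bool)
    err_df = pd.DataFrame(errors, columns=["row", "column", "value", "reason"])
    return SurveyRecordSet(records=df, errors=err_df)


def write_survey_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(SCHEMA))


def read_census_table(path) -> pd.DataFrame:
    census = pd.read_csv(path)
    required = {"region", "sex", "age_group", "count"}
    missing = required - set(census.columns)
    if missing:
        raise SchemaError(f"census table missing column(s): {', '.join(sorted(missing))}")
    if (census["count"] < 0).any():
        raise ValueError("census counts must be non-negative")
    return census


def classify_t2dm(record, threshold: float = FPG_THRESHOLD):
    """Case definition: FPG >= threshold (mmol/L) and/or on diabetes medication.

    Accepts a mapping-like single record or a DataFrame (vectorized).  A
    record whose fasting status is unconfirmed is ineligible and must be
    removed by :func:`filter_eligible` before classification; for eligible
    records with missing FPG and no medication flag the status is unknown
    (returned as NA) — such records never enter prevalence denominators.
    """
    if isinstance(record, pd.DataFrame):
        return case_status(record, threshold)
    if not record["fasting_confirmed"]:
        raise ValueError("fasting status not confirmed: record is ineligible")
    fpg = record.get("fpg")
    on_med = bool(record.get("on_medication", False))
    if fpg is None or (isinstance(fpg, float) and np.isnan(fpg)):
        if on_med:
            return True
        raise ValueError("status indeterminable: no FPG and not on medication")
    return bool(fpg >= threshold or on_med)


def case_status(df: pd.DataFrame, threshold: float = FPG_THRESHOLD) -> pd.Series:
    """Vectorized case definition -> boolean with NA for unknown status."""
    fpg_case = df["fpg"] >= threshold  # NaN -> False
    status = pd.Series(
        (fpg_case | df["on_medication"]).to_numpy(), index=df.index, dtype="boolean"
    )
    unknown = df["fpg"].isna() & ~df["on_medication"]
    status[unknown] = pd.NA
    return status


def filter_eligible(record_set) -> SurveyRecordSet:
    """Retain non-pregnant 25-64 year olds with confirmed fasting status.

    Removal counts per rule are reported, applied in a fixed order so the
    same record is counted once.  Idempotent.
    """
    if isinstance(record_set, pd.DataFrame):
        record_set = SurveyRecordSet(records=record_set)
    df = record_set.records
    removed = dict(record_set.removed)
    keep = pd.Series(True, index=df.index)

    rule_age = (df["age"] < 25) | (df["age"] > 64)
    removed["age_outside_25_64"] = removed.get("age_outside_25_64", 0) + int(rule_age.sum())
    keep &= ~rule_age

    rule_preg = df["pregnant"] & keep
    removed["pregnant"] = removed.get("pregnant", 0) + int(rule_preg.sum())
    keep &= ~rule_preg

    rule_fast = (~df["fasting_confirmed"]) & keep
    removed["fasting_unconfirmed"] = removed.get("fasting_unconfirmed", 0) + int(rule_fast.sum())
    keep &= ~rule_fast

    out = df[keep].reset_index(drop=True)
    return SurveyRecordSet(records=out, errors=record_set.errors, removed=removed)


def with_age_groups(df: pd.DataFrame) -> pd.DataFrame:
    """Attach the 5-year age-group label column (records must be eligible)."""
    out = df.copy()
    out["age_group"] = age_group_label(out["age"].to_numpy())
    return out
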