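"""Rule-based record cleansing with a complete rejection log.

Each record is either kept or rejected with at least one reason code;
kept + rejected always equals the input count. Missing values are not
incoherencies — range rules only fire on present values — but a column
that is missing everywhere (the diabetes marker) can be dropped outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["CleansingRules", "CleansingReport", "cleanse", "validate_record",
           "DEFAULT_RANGES"]

# Wide physiological windows: keep all plausible mass, reject gross extremes.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "age": (18, 100),
    "systolic_bp": (60, 250),
    "diastolic_bp": (30, 150),
    "cholesterol": (80, 500),
    "fast_glucose": (40, 500),
    "smoke_years": (0, 80),
    "cigarettes_per_day": (0, 80),
    "bmi": (10, 70),
}

SYSTOLIC_ABOVE_DIASTOLIC = "systolic_not_above_diastolic"
SUPERSEDED = "superseded_record"


@dataclass(frozen=True)
class CleansingRules:
    """Configuration of the cleansing stage.

    ``ranges`` maps attribute name to a closed [lo, hi] interval. When
    ``dedupe_key`` names a column, only the latest record (by
    ``date_column``) per key survives; earlier ones are rejected as
    superseded.
    """

    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES))
    require_systolic_above_diastolic: bool = True
    drop_all_missing_columns: bool = True
    dedupe_key: str | None = None
    date_column: str = "record_date"

    def __post_init__(self) -> None:
        for attr, (lo, hi) in self.ranges.items():
            if lo >= hi:
                raise ValueError(f"empty range for {attr!r}: ({lo}, {hi})")

    def check_schema(self, columns) -> None:
        cols = set(columns)
        unknown = [a for a in self.ranges if a not in cols]
        if self.require_systolic_above_diastolic:
            unknown += [a for a in ("systolic_bp", "diastolic_bp") if a not in cols]
        if unknown:
            raise KeyError(f"rules reference unknown attributes: {sorted(set(unknown))}")


@dataclass
class CleansingReport:
    input_count: int
    kept_count: int
    rejections: pd.DataFrame  # original row index + semicolon-joined reasons
    dropped_columns: list[str]

    @property
    def rejected_count(self) -> int:
        return len(self.rejections)


def validate_record(record: Mapping, rules: CleansingRules | None = None) -> list[str]:
    """Violation codes for one record; empty list means the record is clean."""
    rules = rules or CleansingRules()
    codes: list[str] = []
    for attr, (lo, hi) in rules.ranges.items():
        value = record.get(attr)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        if not lo <= float(value) <= hi:
            codes.append(f"{attr}_out_of_range")
    if rules.require_systolic_above_diastolic:
        sbp, dbp = record.get("systolic_bp"), record.get("diastolic_bp")
        if sbp is not None and dbp is not None and not (
                pd.isna(sbp) or pd.isna(dbp)) and not float(sbp) > float(dbp):
            codes.append(SYSTOLIC_ABOVE_DIASTOLIC)
    return codes


def cleanse(records: pd.DataFrame,
            rules: CleansingRules | None = None,
            ) -> tuple[pd.DataFrame, CleansingReport]:
    """Filter a raw table; returns (kept records, report).

    Deterministic and idempotent: cleansing already-clean data keeps every
    row and drops nothing further.
    """
    rules = rules or CleansingRules()
    rules.check_schema(records.columns)
    n = len(records)
    if n == 0:
        report = CleansingReport(0, 0, pd.DataFrame(columns=["row", "reasons"]),
                                 [])
        return records.copy(), report

    reasons = [[] for _ in range(n)]

    if rules.dedupe_key and rules.dedupe_key in records.columns:
        tmp = pd.DataFrame({
            "key": records[rules.dedupe_key].to_numpy(),
            "date": pd.to_datetime(records[rules.date_column]).to_numpy(),
            "pos": np.arange(n),
        })
        keep_pos = set(tmp.sort_values(["date", "pos"]).groupby("key")["pos"].last())
        for i in range(n):
            if i not in keep_pos:
                reasons[i].append(SUPERSEDED)

    for attr, (lo, hi) in rules.ranges.items():
        col = pd.to_numeric(records[attr], errors="coerce")
        bad = col.notna() & ~col.between(lo, hi)
        for i in np.flatnonzero(bad.to_numpy()):
            reasons[i].append(f"{attr}_out_of_range")

    if rules.require_systolic_above_diastolic:
        sbp = pd.to_numeric(records["systolic_bp"], errors="coerce")
        dbp = pd.to_numeric(records["diastolic_bp"], errors="coerce")
        bad = sbp.notna() & dbp.notna() & ~(sbp > dbp)
        for i in np.flatnonzero(bad.to_numpy()):
            reasons[i].append(SYSTOLIC_ABOVE_DIASTOLIC)

    keep_mask = np.array([not r for r in reasons])
    kept = records.loc[keep_mask].copy()

    dropped: list[str] = []
    if rules.drop_all_missing_columns:
        for col in list(kept.columns):
            if col == "class":
                continue
            if records[col].isna().all():
                dropped.append(col)
        kept = kept.drop(columns=dropped)

    rej_rows = np.flatnonzero(~keep_mask)
    rejections = pd.DataFrame({
        "row": records.index[rej_rows],
        "reasons": [";".join(reasons[i]) for i in rej_rows],
    })
    report = CleansingReport(n, len(kept), rejections, dropped)
    return kept, report
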