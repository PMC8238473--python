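"""CSV-backed star schema with SCD-type-4 user history and incremental ETL.

Layout of a warehouse directory::

    dim_calendar.csv   one row per date in the loaded range
    dim_district.csv   static geography lookup
    dim_user.csv       current user attributes (+ active flag)
    dim_user_hst.csv   full change history: validity intervals per user
    fact.csv           one row per (user, day) measurement with its index
    watermark.json     last-loaded timestamp per source

Change capture is snapshot diffing: applying a user snapshot closes the
open history interval when a tracked attribute (district, education, salary
band) changed and opens a new one, keeping per-user intervals disjoint and
contiguous with exactly one open interval. Fact loading is incremental —
only measurements dated after the stored watermark enter the fact table,
and the watermark only ever moves forward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cardiowell.index_engine import IndexCurve, index_of
from cardiowell.modeling import TrainedClassifier

__all__ = [
    "Warehouse", "EtlSources", "EtlReport", "ChangeReport",
    "derive_fact_fields", "band_salary", "exercise_from_calories",
    "age_in_full_years", "DEFAULT_EXERCISE_THRESHOLDS", "SALARY_BANDS",
]

SCHEMAS: dict[str, list[str]] = {
    "dim_calendar": ["date", "year", "month", "day", "weekday"],
    "dim_district": ["code", "name", "province", "region", "coastal"],
    "dim_user": ["id_user", "district", "education", "salary", "gender", "active"],
    "dim_user_hst": ["id_user", "district", "education", "salary",
                     "valid_from", "valid_to"],
    "fact": ["id_user", "index_date", "bmi", "fam_history", "diabetes",
             "hypertension", "pain_effort", "hypothyroidism",
             "total_cholesterol", "fast_glucose", "age", "smoke_amount",
             "physical_exercise", "systolic_bp", "diastolic_bp", "index_value"],
}

TRACKED_ATTRS = ("district", "education", "salary")

# kcal/day -> activity level (configurable)
DEFAULT_EXERCISE_THRESHOLDS = (100, 300, 600)

# fixed salary bands for the Int -> Varchar dimension attribute
SALARY_BANDS = ((1000, "<1000"), (2000, "1000-1999"), (3000, "2000-2999"),
                (5000, "3000-4999"))


def band_salary(salary: float) -> str:
    for upper, label in SALARY_BANDS:
        if salary < upper:
            return label
    return ">=5000"


def exercise_from_calories(calories: float,
                           thresholds: Sequence[int] = DEFAULT_EXERCISE_THRESHOLDS,
                           ) -> str:
    none_lt, low_lt, moderate_lt = thresholds
    if calories < none_lt:
        return "None"
    if calories < low_lt:
        return "Low"
    if calories < moderate_lt:
        return "Moderate"
    return "High"


def age_in_full_years(born: date, at: date) -> int:
    """Completed years between two dates (birthday not yet reached counts less)."""
    if born >= at:
        raise ValueError("date of birth must precede the reference date")
    years = at.year - born.year
    if (at.month, at.day) < (born.month, born.day):
        years -= 1
    return years


def derive_fact_fields(snapshot: Mapping, measurement: Mapping,
                       exercise_thresholds: Sequence[int] = DEFAULT_EXERCISE_THRESHOLDS,
                       ) -> dict:
    """Source-to-target transformations for one fact row.

    bmi = weight[kg] / (height[m])^2; age in completed years between date of
    birth and the clinical-analysis date; smoke_amount = 365 x cigarettes/day
    x smoking years / 1000 (thousands of cigarettes); exercise level from
    daily calories.
    """
    height_cm = float(snapshot["height"])
    if height_cm <= 0:
        raise ValueError("height must be positive")
    born = _as_date(snapshot["date_of_birth"])
    analysis = _as_date(snapshot["clinical_analysis_date"])
    return {
        "bmi": float(snapshot["weight"]) / (height_cm / 100.0) ** 2,
        "age": age_in_full_years(born, analysis),
        "smoke_amount": 365.0 * float(snapshot["cigarettes_per_day"])
        * float(snapshot["smoke_years"]) / 1000.0,
        "physical_exercise": exercise_from_calories(
            float(measurement["calories"]), exercise_thresholds),
    }


def _as_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


@dataclass
class ChangeReport:
    action: str  # insert | update | noop | remove
    changed: dict = field(default_factory=dict)  # attr -> (old, new)


@dataclass
class EtlReport:
    calendar_rows: int = 0
    district_rows: int = 0
    users_inserted: int = 0
    users_updated: int = 0
    facts_loaded: int = 0
    quarantined: list = field(default_factory=list)
    watermark_before: str | None = None
    watermark_after: str | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "calendar_rows", "district_rows", "users_inserted",
            "users_updated", "facts_loaded", "quarantined",
            "watermark_before", "watermark_after")}


@dataclass
class EtlSources:
    users: pd.DataFrame
    measurements: pd.DataFrame
    districts: pd.DataFrame


class Warehouse:
    """Handle on one warehouse directory; every operation persists to CSV."""

    def __init__(self, path):
        self.path = Path(path)
        if not (self.path / "fact.csv").exists():
            raise FileNotFoundError(
                f"{self.path} is not an initialized warehouse (run init first)")

    # -- lifecycle ---------------------------------------------------------

    @classmethod
    def init(cls, path, overwrite: bool = False) -> "Warehouse":
        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)
        existing = [t for t in SCHEMAS if (root / f"{t}.csv").exists()]
        if existing and not overwrite:
            raise FileExistsError(
                f"warehouse already initialized at {root}; pass overwrite=True")
        for table, columns in SCHEMAS.items():
            pd.DataFrame(columns=columns).to_csv(root / f"{table}.csv", index=False)
        (root / "watermark.json").write_text("{}\n")
        return cls(root)

    def read(self, table: str) -> pd.DataFrame:
        frame = pd.read_csv(self.path / f"{table}.csv", dtype=str,
                            keep_default_na=False, na_values=[""])
        return frame

    def write(self, table: str, frame: pd.DataFrame) -> None:
        frame.to_csv(self.path / f"{table}.csv", index=False,
                     columns=SCHEMAS[table])

    def status(self) -> dict:
        info = {t: len(self.read(t)) for t in SCHEMAS}
        info["watermark"] = self.watermark()
        return info

    # -- watermark ---------------------------------------------------------

    def watermark(self, source: str = "measurements") -> str | None:
        data = json.loads((self.path / "watermark.json").read_text() or "{}")
        return data.get(source)

    def _advance_watermark(self, value: str, source: str = "measurements") -> None:
        wm_path = self.path / "watermark.json"
        data = json.loads(wm_path.read_text() or "{}")
        prev = data.get(source)
        if prev is None or value > prev:  # never moves backwards
            data[source] = value
            wm_path.write_text(json.dumps(data, sort_keys=True) + "\n")

    # -- static dimensions -------------------------------------------------

    def load_static_dimensions(self, calendar_range: tuple[date, date],
                               districts: pd.DataFrame) -> dict:
        """Full load, once: repeat calls are no-ops reporting zero rows."""
        counts = {"dim_calendar": 0, "dim_district": 0}
        cal = self.read("dim_calendar")
        if cal.empty:
            start, end = calendar_range
            if end < start:
                raise ValueError("calendar range end precedes start")
            days = (end - start).days + 1
            rows = []
            for i in range(days):
                d = start + timedelta(days=i)
                rows.append({"date": d.isoformat(), "year": d.year,
                             "month": d.month, "day": d.day,
                             "weekday": d.strftime("%A")})
            self.write("dim_calendar", pd.DataFrame(rows))
            counts["dim_calendar"] = days
        dist = self.read("dim_district")
        if dist.empty:
            required = set(SCHEMAS["dim_district"])
            if not required <= set(districts.columns):
                raise ValueError(
                    f"district rows lack columns {required - set(districts.columns)}")
            if districts["code"].duplicated().any():
                raise ValueError("district codes must be unique")
            self.write("dim_district", districts.copy())
            counts["dim_district"] = len(districts)
        return counts

    # -- SCD type 4 user dimension ----------------------------------------

    def apply_user_snapshot(self, snapshot: Mapping, at) -> ChangeReport:
        """Diff one user snapshot against the current dimension row."""
        at_iso = _as_date(at).isoformat()
        uid = str(snapshot["id_user"])
        incoming = {
            "district": str(snapshot["district"]),
            "education": str(snapshot.get("education_level",
                                          snapshot.get("education", ""))),
            "salary": band_salary(float(snapshot["salary"])),
        }
        dim = self.read("dim_user")
        hst = self.read("dim_user_hst")
        mask = dim["id_user"] == uid

        if not mask.any():
            row = {"id_user": uid, **incoming,
                   "gender": str(snapshot.get("gender", "")), "active": "1"}
            dim = pd.concat([dim, pd.DataFrame([row])], ignore_index=True)
            hst = pd.concat([hst, pd.DataFrame([{
                "id_user": uid, **incoming,
                "valid_from": at_iso, "valid_to": np.nan}])], ignore_index=True)
            self.write("dim_user", dim)
            self.write("dim_user_hst", hst)
            return ChangeReport("insert", {k: (None, v) for k, v in incoming.items()})

        current = dim.loc[mask].iloc[0]
        open_mask = (hst["id_user"] == uid) & hst["valid_to"].isna()
        latest_from = hst.loc[open_mask, "valid_from"].iloc[0]
        if at_iso < latest_from:
            raise ValueError(
                f"snapshot at {at_iso} predates open interval from {latest_from}")

        changed = {a: (current[a], incoming[a]) for a in TRACKED_ATTRS
                   if current[a] != incoming[a]}
        if not changed and current["active"] == "1":
            return ChangeReport("noop")

        hst.loc[open_mask, "valid_to"] = at_iso
        hst = pd.concat([hst, pd.DataFrame([{
            "id_user": uid, **incoming,
            "valid_from": at_iso, "valid_to": np.nan}])], ignore_index=True)
        for attr, (_, new) in changed.items():
            dim.loc[mask, attr] = new
        dim.loc[mask, "active"] = "1"
        self.write("dim_user", dim)
        self.write("dim_user_hst", hst)
        return ChangeReport("update", changed)

    def remove_user(self, id_user, at) -> ChangeReport:
        """Tombstone: close the open interval, mark the current row inactive."""
        at_iso = _as_date(at).isoformat()
        uid = str(id_user)
        dim = self.read("dim_user")
        hst = self.read("dim_user_hst")
        mask = dim["id_user"] == uid
        if not mask.any():
            raise KeyError(f"unknown user {uid}")
        open_mask = (hst["id_user"] == uid) & hst["valid_to"].isna()
        hst.loc[open_mask, "valid_to"] = at_iso
        dim.loc[mask, "active"] = "0"
        self.write("dim_user", dim)
        self.write("dim_user_hst", hst)
        return ChangeReport("remove")

    # -- ETL ---------------------------------------------------------------

    def run_etl(self, sources: EtlSources, model: TrainedClassifier,
                curve: IndexCurve,
                exercise_thresholds: Sequence[int] = DEFAULT_EXERCISE_THRESHOLDS,
                ) -> EtlReport:
        """One incremental pass: static dims (if empty) -> users -> facts.

        Only measurements dated strictly after the watermark are loaded;
        measurements for unknown users are quarantined (logged, never fatal)
        and do not advance the watermark past valid data.
        """
        report = EtlReport(watermark_before=self.watermark())
        users = sources.users.copy()
        meas = sources.measurements.copy()

        # 1. static dimensions, full load once
        meas_dates = pd.to_datetime(meas["index_date"])
        lo = date(meas_dates.min().year, 1, 1)
        hi = date(meas_dates.max().year, 12, 31)
        counts = self.load_static_dimensions((lo, hi), sources.districts)
        report.calendar_rows = counts["dim_calendar"]
        report.district_rows = counts["dim_district"]

        # 2. user dimension, snapshots in timestamp order
        users["_at"] = pd.to_datetime(users["clinical_analysis_date"])
        users = users.sort_values(["_at", "id_user"], kind="stable")
        for _, snap in users.iterrows():
            try:
                change = self.apply_user_snapshot(snap.to_dict(),
                                                  snap["clinical_analysis_date"])
            except ValueError:
                continue  # stale snapshot: the warehouse already holds newer state
            if change.action == "insert":
                report.users_inserted += 1
            elif change.action == "update":
                report.users_updated += 1

        # 3. facts newer than the watermark
        wm = self.watermark()
        new = meas if wm is None else meas[meas["index_date"] > wm]
        known = set(users["id_user"].astype(str))
        unknown_mask = ~new["id_user"].astype(str).isin(known)
        report.quarantined = new.loc[unknown_mask].to_dict("records")
        new = new.loc[~unknown_mask]

        fact = self.read("fact")
        existing_keys = set(zip(fact["id_user"], fact["index_date"]))
        if not new.empty:
            new_rows = self._build_facts(new, users, model, curve,
                                         exercise_thresholds)
            new_rows = [r for r in new_rows
                        if (str(r["id_user"]), r["index_date"]) not in existing_keys]
            if new_rows:
                fact = pd.concat([fact, pd.DataFrame(new_rows).astype(str)],
                                 ignore_index=True)
                self.write("fact", fact)
            report.facts_loaded = len(new_rows)
            self._advance_watermark(str(new["index_date"].max()))
        report.watermark_after = self.watermark()
        return report

    def _build_facts(self, measurements: pd.DataFrame, users: pd.DataFrame,
                     model: TrainedClassifier, curve: IndexCurve,
                     exercise_thresholds: Sequence[int]) -> list[dict]:
        # latest snapshot per user dated at or before the measurement;
        # a user whose first snapshot is later falls back to that first one
        snaps: dict[str, list[dict]] = {}
        for _, row in users.iterrows():
            snaps.setdefault(str(row["id_user"]), []).append(row.to_dict())
        for lst in snaps.values():
            lst.sort(key=lambda r: str(r["clinical_analysis_date"]))

        rows, model_input = [], []
        for _, m in measurements.iterrows():
            uid = str(m["id_user"])
            candidates = [s for s in snaps[uid]
                          if str(s["clinical_analysis_date"]) <= str(m["index_date"])]
            snap = candidates[-1] if candidates else snaps[uid][0]
            derived = derive_fact_fields(snap, m, exercise_thresholds)
            cigs = float(snap["cigarettes_per_day"])
            model_input.append({
                "age": derived["age"],
                "systolic_bp": float(m["systolic_bp"]),
                "diastolic_bp": float(m["diastolic_bp"]),
                "cholesterol": float(snap["total_cholesterol"]),
                "fast_glucose": float(snap["fast_glucose"]),
                "smoke_years": float(snap["smoke_years"]),
                "cigarettes_per_day": cigs,
                "bmi": derived["bmi"],
                "family_history": snap["family_history"],
                "pain_after_effort": snap["pain_after_effort"],
                "physical_exercise": derived["physical_exercise"],
                "smoking": "Yes" if cigs > 0 else "No",
                "hypertension": snap["hypertension"],
                "hypothyroid": snap["hypothyroidism"],
                "gender": snap["gender"],
            })
            rows.append({
                "id_user": uid, "index_date": str(m["index_date"]),
                "bmi": round(derived["bmi"], 4),
                "fam_history": snap["family_history"],
                "diabetes": snap["diabetes"],
                "hypertension": snap["hypertension"],
                "pain_effort": snap["pain_after_effort"],
                "hypothyroidism": snap["hypothyroidism"],
                "total_cholesterol": snap["total_cholesterol"],
                "fast_glucose": snap["fast_glucose"],
                "age": derived["age"],
                "smoke_amount": round(derived["smoke_amount"], 4),
                "physical_exercise": derived["physical_exercise"],
                "systolic_bp": m["systolic_bp"],
                "diastolic_bp": m["diastolic_bp"],
            })
        probs = model.predict_disease_proba(pd.DataFrame(model_input))
        indexes = index_of(curve, probs)
        for row, value in zip(rows, np.atleast_1d(indexes)):
            row["index_value"] = round(float(value), 6)
        return rows
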