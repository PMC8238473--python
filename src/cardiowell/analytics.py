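"""Trend and population analytics over the warehouse.

The individual ("weighted") index at a query date is the value of the
ordinary-least-squares regression line fitted to all of the user's stored
index values up to and including that date, with time measured in days
since the user's first observation. Regressing damps outliers so the value
shown already reflects the whole history. Global indexes are plain
unweighted means of stored fact index values, optionally sliced by gender,
geography or calendar attributes.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cardiowell.index_engine import INDEX_MAX, INDEX_MIN, colour_of
from cardiowell.warehouse import TRACKED_ATTRS, Warehouse

__all__ = ["TrendPoint", "weighted_index", "global_index", "breakdown",
           "history_report", "export_report", "enriched_facts", "SLICE_DIMENSIONS"]

SLICE_DIMENSIONS = ("gender", "region", "district", "weekday", "year", "month", "day")


@dataclass(frozen=True)
class TrendPoint:
    date: date
    index_value: float


def _as_date(value) -> date:
    return value if isinstance(value, date) else date.fromisoformat(str(value))


def weighted_index(history: Sequence, query_date) -> float:
    """OLS line through the supplied history, evaluated at ``query_date``.

    Accepts TrendPoints or (date, value) pairs; dates must be unique. A
    single point returns its own value; the regression value is clamped to
    the index scale [-5, 5]. Monitoring callers must pass only points known
    at the query date (see :func:`user_trend`) — the regression itself uses
    every point it is given.
    """
    pts = [(p.date, p.index_value) if isinstance(p, TrendPoint) else
           (_as_date(p[0]), float(p[1])) for p in history]
    if not pts:
        raise ValueError("empty history")
    q = _as_date(query_date)
    pts = sorted(pts)
    if q < pts[0][0]:
        raise ValueError("query date precedes the earliest observation")
    if len(pts) != len({d for d, _ in pts}):
        raise ValueError("duplicate dates in history")
    d0 = pts[0][0]
    t = np.array([(d - d0).days for d, _ in pts], dtype=float)
    v = np.array([val for _, val in pts], dtype=float)
    if len(pts) == 1 or np.ptp(t) == 0:
        return float(np.clip(v.mean(), INDEX_MIN, INDEX_MAX))
    tm, vm = t.mean(), v.mean()
    slope = float(np.sum((t - tm) * (v - vm)) / np.sum((t - tm) ** 2))
    intercept = vm - slope * tm
    predicted = intercept + slope * (q - d0).days
    return float(np.clip(predicted, INDEX_MIN, INDEX_MAX))


def enriched_facts(wh: Warehouse) -> pd.DataFrame:
    """Fact table joined with the slicing attributes of its dimensions."""
    fact = wh.read("fact")
    if fact.empty:
        return fact.assign(**{d: pd.Series(dtype=str) for d in SLICE_DIMENSIONS})
    fact = fact.copy()
    fact["index_value"] = fact["index_value"].astype(float)
    users = wh.read("dim_user")[["id_user", "gender", "district"]]
    fact = fact.drop(columns=["district"], errors="ignore").merge(
        users, on="id_user", how="left")
    districts = wh.read("dim_district")[["code", "region"]].rename(
        columns={"code": "district"})
    fact = fact.merge(districts, on="district", how="left")
    dates = pd.to_datetime(fact["index_date"])
    fact["weekday"] = dates.dt.day_name()
    fact["year"] = dates.dt.year.astype(str)
    fact["month"] = dates.dt.month.astype(str)
    fact["day"] = dates.dt.day.astype(str)
    return fact


def global_index(wh: Warehouse, dimension: str | None = None,
                 value: str | None = None) -> float | None:
    """Unweighted mean index over a slice; ``None`` when the slice is empty."""
    if dimension is not None and dimension not in SLICE_DIMENSIONS:
        raise KeyError(f"unknown slicing dimension {dimension!r}")
    facts = enriched_facts(wh)
    if dimension is not None and value is not None:
        facts = facts[facts[dimension].astype(str) == str(value)]
    if facts.empty:
        return None
    return float(facts["index_value"].mean())


def breakdown(wh: Warehouse, dimension: str) -> pd.DataFrame:
    """Per-category global index, colour and count for one dimension.

    The count-weighted mean of the categories reconstructs the unsliced
    global index (conservation).
    """
    if dimension not in SLICE_DIMENSIONS:
        raise KeyError(f"unknown slicing dimension {dimension!r}")
    facts = enriched_facts(wh)
    if facts.empty:
        return pd.DataFrame(columns=[dimension, "global_index", "colour", "count"])
    grouped = facts.groupby(dimension, dropna=False)["index_value"]
    out = grouped.agg(global_index="mean", count="count").reset_index()
    out["colour"] = [colour_of(v) for v in out["global_index"]]
    out["count"] = out["count"].astype(int)
    return out[[dimension, "global_index", "colour", "count"]]


def history_report(wh: Warehouse, user_id) -> pd.DataFrame:
    """Chronological education/residence/salary changes for one user."""
    uid = str(user_id)
    dim = wh.read("dim_user")
    if not (dim["id_user"] == uid).any():
        raise KeyError(f"unknown user {uid}")
    hst = wh.read("dim_user_hst")
    hst = hst[hst["id_user"] == uid].sort_values("valid_from", kind="stable")
    rows = []
    prev = None
    for _, interval in hst.iterrows():
        if prev is not None:
            for attr in TRACKED_ATTRS:
                if interval[attr] != prev[attr]:
                    rows.append({"date": interval["valid_from"],
                                 "attribute": attr,
                                 "old": prev[attr], "new": interval[attr]})
        prev = interval
    return pd.DataFrame(rows, columns=["date", "attribute", "old", "new"])


def user_trend(wh: Warehouse, user_id) -> pd.DataFrame:
    fact = wh.read("fact")
    mine = fact[fact["id_user"] == str(user_id)].copy()
    mine["index_value"] = mine["index_value"].astype(float)
    mine = mine.sort_values("index_date", kind="stable")
    points = [(row["index_date"], row["index_value"]) for _, row in mine.iterrows()]
    mine["colour"] = [colour_of(v) for v in mine["index_value"]]
    # running value: the regression at each date sees only points up to it
    mine["weighted_index"] = [weighted_index(points[:i + 1], d)
                              for i, d in enumerate(mine["index_date"])]
    return mine[["id_user", "index_date", "index_value", "colour", "weighted_index"]]


def export_report(wh: Warehouse, out_dir,
                  breakdown_dimensions: Iterable[str] = ("gender", "region",
                                                         "weekday", "month"),
                  ) -> dict[str, Path]:
    """File-based stand-in for the three dashboard pages.

    Writes ``trend.csv`` (per-user series with running weighted index),
    ``global.csv`` (overall index plus per-dimension breakdowns) and
    ``history.csv`` (tracked attribute changes for every user). An empty
    warehouse still yields valid files with headers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fact = wh.read("fact")

    trends = [user_trend(wh, uid) for uid in sorted(fact["id_user"].unique())]
    trend = (pd.concat(trends, ignore_index=True) if trends else
             pd.DataFrame(columns=["id_user", "index_date", "index_value",
                                   "colour", "weighted_index"]))
    trend_path = out / "trend.csv"
    trend.to_csv(trend_path, index=False)

    rows = []
    overall = global_index(wh)
    rows.append({"dimension": "overall", "category": "all",
                 "global_index": overall,
                 "colour": colour_of(overall) if overall is not None else "",
                 "count": len(fact)})
    for dim_name in breakdown_dimensions:
        bd = breakdown(wh, dim_name)
        for _, r in bd.iterrows():
            rows.append({"dimension": dim_name, "category": r[dim_name],
                         "global_index": r["global_index"],
                         "colour": r["colour"], "count": r["count"]})
    global_path = out / "global.csv"
    pd.DataFrame(rows, columns=["dimension", "category", "global_index",
                                "colour", "count"]).to_csv(global_path, index=False)

    dim = wh.read("dim_user")
    histories = []
    for uid in dim["id_user"]:
        h = history_report(wh, uid)
        if not h.empty:
            h.insert(0, "id_user", uid)
            histories.append(h)
    history = (pd.concat(histories, ignore_index=True) if histories else
               pd.DataFrame(columns=["id_user", "date", "attribute", "old", "new"]))
    history_path = out / "history.csv"
    history.to_csv(history_path, index=False)

    return {"trend": trend_path, "global": global_path, "history": history_path}
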