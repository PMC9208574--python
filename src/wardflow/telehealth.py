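"""Unit-level telehealth call-log filtering and summaries.

Call logs carry only the host unit, start/end times and the participant
count — calls cannot be linked to individual nurses or patients, so all
summaries are at unit/arm level by construction.  The inclusion rule keeps
calls lasting between 30 seconds and 2 hours (inclusive at both ends) with
2 or more participants; shorter calls are auto-answer artifacts and longer
ones are sessions left open.  Utilization is expressed as calls per
patient-day, with patient-days counted from the midnight census.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .census import _check_census
from .errors import SchemaError
from .outcomes import assign_stage

CALL_COLUMNS = ["unit_id", "t_start", "t_end", "n_participants"]

SUMMARY_COLUMNS = [
    "arm",
    "stage",
    "n_calls",
    "mean_min",
    "sd_min",
    "cumulative_hours",
    "patient_days",
    "calls_per_patient_day",
]


def _check_calls(calls: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise SchemaError(f"call table missing columns: {missing}")
    c = calls.copy()
    for col in ("t_start", "t_end"):
        if not pd.api.types.is_datetime64_any_dtype(c[col]):
            c[col] = pd.to_datetime(c[col], errors="coerce")
    bad = c["t_start"].isna() | c["t_end"].isna() | (c["t_end"] < c["t_start"])
    if bad.any():
        raise SchemaError(
            f"{int(bad.sum())} call row(s) malformed (NaT or negative duration): "
            f"{c.index[bad].tolist()[:20]}",
            rows=c.index[bad].tolist(),
        )
    return c


def filter_calls(
    calls: pd.DataFrame,
    min_duration_s: float = 30.0,
    max_duration_s: float = 7200.0,
    min_participants: int = 2,
) -> pd.DataFrame:
    """Keep calls with min_duration_s <= duration <= max_duration_s and
    at least ``min_participants`` participants (bounds inclusive)."""
    c = _check_calls(calls)
    dur = (c["t_end"] - c["t_start"]).dt.total_seconds()
    keep = (
        (dur >= min_duration_s)
        & (dur <= max_duration_s)
        & (c["n_participants"] >= min_participants)
    )
    return c.loc[keep].reset_index(drop=True)


def summarize_calls(
    calls: pd.DataFrame,
    census: pd.DataFrame | None = None,
    stages=None,
    arm_of: dict | None = None,
) -> pd.DataFrame:
    """Summarize filtered calls per arm and stage.

    Returns call counts, mean (SD) duration in minutes, cumulative hours,
    patient-days from the midnight census, and calls per patient-day.  A
    call belongs to the stage containing its start time.  Without census /
    stage / arm context (all three optional), a single overall row is
    returned with the rate fields NaN.
    """
    c = _check_calls(calls)
    c["duration_min"] = (c["t_end"] - c["t_start"]).dt.total_seconds() / 60.0

    if census is None or stages is None or arm_of is None:
        return pd.DataFrame(
            [
                {
                    "arm": "all",
                    "stage": "all",
                    "n_calls": len(c),
                    "mean_min": c["duration_min"].mean() if len(c) else 0.0,
                    "sd_min": c["duration_min"].std() if len(c) > 1 else np.nan,
                    "cumulative_hours": c["duration_min"].sum() / 60.0,
                    "patient_days": np.nan,
                    "calls_per_patient_day": np.nan,
                }
            ],
            columns=SUMMARY_COLUMNS,
        )

    cen = _check_census(census)
    cen["arm"] = cen["unit_id"].map(arm_of)
    cen["stage"] = assign_stage(cen["census_date"], stages).to_numpy()
    pdays = (
        cen[cen["stage"].notna()]
        .groupby(["arm", "stage"], sort=False)["occupied"]
        .sum()
        .rename("patient_days")
    )

    c["arm"] = c["unit_id"].map(arm_of)
    c["stage"] = assign_stage(c["t_start"].dt.date, stages).to_numpy()
    c = c[c["stage"].notna() & c["arm"].notna()]
    grp = c.groupby(["arm", "stage"], sort=False)["duration_min"].agg(
        n_calls="size", mean_min="mean", sd_min="std", cumulative_min="sum"
    )

    out = pdays.reset_index().merge(grp.reset_index(), on=["arm", "stage"], how="outer")
    out["n_calls"] = out["n_calls"].fillna(0).astype(int)
    out["mean_min"] = out["mean_min"].where(out["n_calls"] > 0, 0.0)
    out["cumulative_hours"] = out["cumulative_min"].fillna(0.0) / 60.0
    out["calls_per_patient_day"] = np.where(
        out["patient_days"] > 0, out["n_calls"] / out["patient_days"], np.nan
    )
    return out[SUMMARY_COLUMNS].reset_index(drop=True)


class TelehealthCallFilter(BaseEstimator, TransformerMixin):
    """Transformer applying the call inclusion rule.

    Parameters mirror :func:`filter_calls`: duration bounds in seconds
    (inclusive) and the minimum participant count.
    """

    def __init__(
        self,
        min_duration_s: float = 30.0,
        max_duration_s: float = 7200.0,
        min_participants: int = 2,
    ):
        self.min_duration_s = min_duration_s
        self.max_duration_s = max_duration_s
        self.min_participants = min_participants

    def fit(self, X=None, y=None):
        if self.min_duration_s < 0 or self.max_duration_s < self.min_duration_s:
            raise ValueError("require 0 <= min_duration_s <= max_duration_s")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return filter_calls(
            X,
            min_duration_s=self.min_duration_s,
            max_duration_s=self.max_duration_s,
            min_participants=self.min_participants,
        )
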