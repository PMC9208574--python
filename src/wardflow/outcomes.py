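"""Per-shift workflow outcomes and stage-level summaries.

Three outcomes are computed for every unit-day-shift cell:

1. ``encounters_per_patient`` — number of direct nurse-patient encounters
   divided by the number of occupied beds at the governing midnight census;
2. ``median_encounter_min`` — the median encounter duration (minutes) over
   the shift's encounters;
3. ``median_total_min_per_patient`` — the median, over occupied rooms, of
   the total time (minutes) nurses spent in that room during the shift
   (patients with no encounters contribute 0).

Encounters flagged at link time (unoccupied room, missing census record)
are excluded from all three outcomes; denominators follow the census.
Stage summaries report the mean and SD of the daily values within each
(arm, stage, shift); for the duration outcomes this is a mean of daily
medians.  The comparison arm pools its units' unit-day records rather than
averaging unit means.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .census import AM, PM, FLAG_OK, _check_census
from .errors import SchemaError, ConfigError

logger = logging.getLogger(__name__)

#: The three outcome column names, in the order they are reported.
OUTCOMES = (
    "encounters_per_patient",
    "median_encounter_min",
    "median_total_min_per_patient",
)

DAILY_COLUMNS = [
    "unit_id",
    "arm",
    "shift_date",
    "shift",
    "n_patients",
    "n_encounters",
    *OUTCOMES,
]


def _shift_grid(census: pd.DataFrame, pm_census: str) -> pd.DataFrame:
    """Enumerate the unit-day-shift cells governed by the census.

    Every census date D yields the AM shift of D and one PM shift: the PM
    shift of D-1 when the night shift is governed by the midnight inside it
    (``pm_census="next"``), or of D otherwise.
    """
    occ = (
        census.groupby(["unit_id", "census_date"], sort=True)["occupied"]
        .sum()
        .rename("n_patients")
        .reset_index()
    )
    am = occ.assign(shift=AM, shift_date=occ["census_date"])
    pm_offset = dt.timedelta(days=1) if pm_census == "next" else dt.timedelta(0)
    pm = occ.assign(
        shift=PM, shift_date=occ["census_date"].map(lambda d: d - pm_offset)
    )
    grid = pd.concat([am, pm], ignore_index=True)
    return grid[["unit_id", "shift_date", "shift", "n_patients"]]


def daily_outcomes(
    linked: pd.DataFrame,
    census: pd.DataFrame,
    arm_of: dict,
    pm_census: str = "next",
) -> pd.DataFrame:
    """Compute the three workflow outcomes for every unit-day-shift cell.

    Parameters
    ----------
    linked : output of :func:`wardflow.census.link` (flags resolved).
    census : midnight census table; defines the cell grid and denominators.
    arm_of : mapping unit_id -> {"covid", "comparison"}.
    pm_census : which midnight governs the night shift (must match the
        convention used at link time).

    Cells with zero occupied beds have all per-patient fields NaN
    (undefined); cells with zero encounters have ``encounters_per_patient``
    0, duration-median NaN and total-time-median 0.
    """
    cen = _check_census(census)
    unknown = set(cen["unit_id"]) - set(arm_of)
    if unknown:
        raise ConfigError(f"arm_of missing unit(s): {sorted(unknown)}")

    grid = _shift_grid(cen, pm_census)
    inc = linked[linked["flag"] == FLAG_OK].copy() if len(linked) else linked

    cell = ["unit_id", "shift_date", "shift"]
    if len(inc):
        counts = inc.groupby(cell, sort=False).agg(
            n_encounters=("duration_s", "size"),
            _median_s=("duration_s", "median"),
        )
        out = grid.merge(counts.reset_index(), on=cell, how="left")
    else:
        out = grid.assign(n_encounters=np.nan, _median_s=np.nan)
    out["n_encounters"] = out["n_encounters"].fillna(0).astype(int)
    has_patients = out["n_patients"] > 0
    out["encounters_per_patient"] = np.where(
        has_patients, out["n_encounters"] / out["n_patients"].where(has_patients), np.nan
    )
    out["median_encounter_min"] = out["_median_s"] / 60.0

    # Median over occupied rooms of per-room total time, zero-filled for
    # rooms the nurses never entered.
    occ_rooms = cen[cen["occupied"]].copy()
    offset = dt.timedelta(days=1) if pm_census == "next" else dt.timedelta(0)
    am_rooms = occ_rooms.assign(shift=AM, shift_date=occ_rooms["census_date"])
    pm_rooms = occ_rooms.assign(
        shift=PM, shift_date=occ_rooms["census_date"].map(lambda d: d - offset)
    )
    room_grid = pd.concat([am_rooms, pm_rooms], ignore_index=True)[
        ["unit_id", "room_id", "shift_date", "shift"]
    ]
    if len(inc):
        room_tot = (
            inc.groupby(cell + ["room_id"], sort=False)["duration_s"]
            .sum()
            .reset_index()
        )
        room_grid = room_grid.merge(room_tot, on=cell + ["room_id"], how="left")
    else:
        room_grid = room_grid.assign(duration_s=np.nan)
    room_grid["duration_s"] = room_grid["duration_s"].fillna(0.0)
    tot_median = (
        room_grid.groupby(cell, sort=False)["duration_s"].median().rename("_tot_s")
    )
    out = out.merge(tot_median.reset_index(), on=cell, how="left")
    out["median_total_min_per_patient"] = np.where(
        has_patients, out["_tot_s"] / 60.0, np.nan
    )

    out["arm"] = out["unit_id"].map(arm_of)
    out = out.drop(columns=["_median_s", "_tot_s"])
    return (
        out[DAILY_COLUMNS]
        .sort_values(["unit_id", "shift_date", "shift"], kind="mergesort")
        .reset_index(drop=True)
    )


def assign_stage(dates, stages) -> pd.Series:
    """Map calendar dates to stage names; dates outside all windows get NaN."""
    dates = pd.Series(pd.to_datetime(pd.Series(list(dates))).dt.date)
    out = pd.Series([None] * len(dates), dtype=object)
    for st in stages:
        mask = (dates >= st.start_date) & (dates <= st.end_date)
        out[mask.to_numpy()] = st.name
    return out


def stage_summary(daily: pd.DataFrame, stages) -> pd.DataFrame:
    """Aggregate daily outcomes to stage means and SDs per arm and shift.

    Returns a tidy frame with one row per (outcome, arm, stage, shift):
    ``mean`` and ``sd`` over the unit-day values (the comparison arm pools
    its units' days) and ``n_days``, the number of non-missing unit-day
    values.  Raises :class:`SchemaError` if a stage covers zero days of
    data; unit-days outside every stage window are dropped with a log line.
    """
    d = daily.copy()
    d["stage"] = assign_stage(d["shift_date"], stages).to_numpy()
    dropped = d["stage"].isna()
    if dropped.any():
        logger.info("dropping %d unit-day row(s) outside all stages", int(dropped.sum()))
        d = d[~dropped]
    present = set(d["stage"])
    for st in stages:
        if st.name not in present:
            raise SchemaError(f"stage {st.name!r} covers zero days of data")

    long = d.melt(
        id_vars=["arm", "stage", "shift"],
        value_vars=list(OUTCOMES),
        var_name="outcome",
        value_name="value",
    ).dropna(subset=["value"])
    summ = (
        long.groupby(["outcome", "arm", "stage", "shift"], sort=False)["value"]
        .agg(mean="mean", sd="std", n_days="size")
        .reset_index()
    )
    summ["n_days"] = summ["n_days"].astype(int)
    order = {st.name: i for i, st in enumerate(stages)}
    summ = summ.sort_values(
        ["outcome", "stage", "arm", "shift"],
        key=lambda s: s.map(order) if s.name == "stage" else s,
        kind="mergesort",
    )
    return summ.reset_index(drop=True)


def daily_with_stage(daily: pd.DataFrame, stages) -> pd.DataFrame:
    """Return daily outcomes with a ``stage`` column, dropping out-of-stage days."""
    d = daily.copy()
    d["stage"] = assign_stage(d["shift_date"], stages).to_numpy()
    return d[d["stage"].notna()].reset_index(drop=True)


class ShiftOutcomeAggregator(BaseEstimator, TransformerMixin):
    """Transformer from linked encounters to daily unit-shift outcomes.

    Parameters
    ----------
    arm_of : mapping unit_id -> arm label ("covid" / "comparison").
    pm_census : {"next", "same"}; must match the linkage convention.

    ``fit(census)`` stores the census that defines cells and denominators;
    ``transform(linked)`` returns one row per unit-day-shift.
    """

    def __init__(self, arm_of=None, pm_census: str = "next"):
        self.arm_of = arm_of
        self.pm_census = pm_census

    def fit(self, X: pd.DataFrame, y=None):
        self.census_ = _check_census(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "census_"):
            raise RuntimeError("fit on the census table before transforming")
        return daily_outcomes(
            X, self.census_, arm_of=dict(self.arm_of), pm_census=self.pm_census
        )


def plot_daily_series(daily: pd.DataFrame, outcome: str, path) -> None:
    """Write a daily time-series figure (one panel per shift, line per arm)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
    for ax, shift in zip(axes, (AM, PM)):
        sub = daily[daily["shift"] == shift]
        for arm, g in sub.groupby("arm"):
            series = g.groupby("shift_date")[outcome].mean()
            ax.plot(series.index, series.values, label=arm)
        ax.set_title(f"{outcome} — {shift} shift")
        ax.legend()
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
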