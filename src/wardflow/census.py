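"""Linking encounters to the midnight census and to unit-day-shift cells.

The hospital day is split into two 12-hour nursing shifts: the morning (AM)
shift covers 07:00:00-18:59:59 of its calendar date and the night (PM) shift
covers 19:00:00 of its date through 06:59:59 of the next day.  An encounter
belongs wholly to the shift containing its start time.

Patient presence and COVID-19 status come from a midnight census snapshot,
one row per (room, date).  The AM shift of date D is governed by the
midnight entering D (census date D); by default the PM shift starting on D
is governed by the midnight that falls inside it (census date D+1), the
snapshot contemporaneous with most of the shift.  Set ``pm_census="same"``
for the alternative convention.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import SchemaError

AM, PM = "AM", "PM"
AM_START_HOUR = 7
PM_START_HOUR = 19

CENSUS_COLUMNS = ["unit_id", "room_id", "census_date", "occupied", "covid_status"]
LINKED_EXTRA_COLUMNS = ["shift_date", "shift", "occupied", "covid_status", "flag"]

#: flag values on a linked encounter: kept rows are "", rows excluded from
#: per-patient denominators carry a reason.
FLAG_OK = ""
FLAG_UNOCCUPIED = "unoccupied"
FLAG_NO_CENSUS = "no_census"


def assign_shift(t):
    """Map a timestamp to its (shift_date, shift) pair.

    07:00-18:59 -> (date, AM); 19:00-23:59 -> (date, PM);
    00:00-06:59 -> (date - 1 day, PM), i.e. the night shift that started
    the previous evening.  Total function; accepts a scalar timestamp or a
    datetime Series (vectorized).
    """
    if isinstance(t, pd.Series):
        hours = t.dt.hour
        date = t.dt.normalize()
        shift = np.where((hours >= AM_START_HOUR) & (hours < PM_START_HOUR), AM, PM)
        shift_date = date.where(hours >= AM_START_HOUR, date - pd.Timedelta(days=1))
        return shift_date.dt.date, pd.Series(shift, index=t.index)
    ts = pd.Timestamp(t)
    if AM_START_HOUR <= ts.hour < PM_START_HOUR:
        return ts.date(), AM
    if ts.hour >= PM_START_HOUR:
        return ts.date(), PM
    return (ts - pd.Timedelta(days=1)).date(), PM


def governing_census(shift_date, shift: str, pm_census: str = "next"):
    """Return the census date whose midnight snapshot governs a shift.

    AM shift of date D -> D (the midnight entering D).  PM shift starting on
    D -> D+1 under the default ``pm_census="next"`` (the only midnight
    inside the 19:00-06:59 window), or D under ``pm_census="same"``.
    """
    if pm_census not in ("next", "same"):
        raise ValueError("pm_census must be 'next' or 'same'")
    if shift == AM or pm_census == "same":
        return shift_date
    if shift == PM:
        return shift_date + dt.timedelta(days=1)
    raise ValueError(f"unknown shift {shift!r}")


def _check_census(census: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CENSUS_COLUMNS if c not in census.columns]
    if missing:
        raise SchemaError(f"census table missing columns: {missing}")
    cen = census.copy()
    if not pd.api.types.is_object_dtype(cen["census_date"]):
        cen["census_date"] = pd.to_datetime(cen["census_date"]).dt.date
    else:
        cen["census_date"] = pd.to_datetime(cen["census_date"]).dt.date
    dup = cen.duplicated(["unit_id", "room_id", "census_date"])
    if dup.any():
        raise SchemaError(
            f"census has {int(dup.sum())} duplicate (room, date) record(s)"
        )
    return cen


def link(
    encounters: pd.DataFrame,
    census: pd.DataFrame,
    pm_census: str = "next",
) -> pd.DataFrame:
    """Attach shift keys and census occupancy/COVID status to encounters.

    Every encounter receives exactly one (shift_date, shift) from its start
    time and the occupancy/COVID status of its room's governing midnight
    census.  Rows are never dropped: encounters in unoccupied rooms are
    flagged "unoccupied" and encounters whose governing census record is
    missing are flagged "no_census"; both are excluded from per-patient
    outcome denominators downstream.

    Raises :class:`SchemaError` if a room appears in the encounters but in
    no census record at all (schema mismatch between the two extracts).
    """
    cen = _check_census(census)
    enc = encounters.copy()
    if enc.empty:
        out = enc.reindex(columns=list(encounters.columns) + LINKED_EXTRA_COLUMNS)
        return out

    known_rooms = set(zip(cen["unit_id"], cen["room_id"]))
    enc_rooms = set(zip(enc["unit_id"], enc["room_id"]))
    orphans = sorted(enc_rooms - known_rooms)
    if orphans:
        raise SchemaError(
            f"{len(orphans)} room(s) present in encounters but absent from the "
            f"census for all dates: {orphans[:10]}"
        )

    t = pd.to_datetime(enc["t_start"])
    shift_date, shift = assign_shift(t)
    enc["shift_date"] = shift_date
    enc["shift"] = shift.to_numpy()
    offset = (
        pd.Timedelta(days=1)
        if pm_census == "next"
        else pd.Timedelta(0)
    )
    if pm_census not in ("next", "same"):
        raise ValueError("pm_census must be 'next' or 'same'")
    gov = pd.to_datetime(enc["shift_date"])
    gov = gov.where(enc["shift"] == AM, gov + offset)
    enc["_gov_date"] = gov.dt.date

    merged = enc.merge(
        cen[CENSUS_COLUMNS].rename(columns={"census_date": "_gov_date"}),
        on=["unit_id", "room_id", "_gov_date"],
        how="left",
    )
    no_census = merged["occupied"].isna()
    merged["flag"] = FLAG_OK
    merged.loc[merged["occupied"] == False, "flag"] = FLAG_UNOCCUPIED  # noqa: E712
    merged.loc[no_census, "flag"] = FLAG_NO_CENSUS
    merged["occupied"] = merged["occupied"].eq(True).to_numpy()
    merged["covid_status"] = merged["covid_status"].fillna("unknown")
    return merged.drop(columns=["_gov_date"])


class CensusLinker(BaseEstimator, TransformerMixin):
    """Transformer attaching shift keys and midnight-census context.

    Parameters
    ----------
    pm_census : {"next", "same"}, default "next"
        Which midnight snapshot governs the night shift starting on date D:
        the midnight inside the shift (D+1, default) or the one entering D.

    Call ``fit(census)`` with the census table, then ``transform`` the
    encounter table.
    """

    def __init__(self, pm_census: str = "next"):
        self.pm_census = pm_census

    def fit(self, X: pd.DataFrame, y=None):
        self.census_ = _check_census(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "census_"):
            raise RuntimeError("CensusLinker must be fit on a census table first")
        return link(X, self.census_, pm_census=self.pm_census)
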