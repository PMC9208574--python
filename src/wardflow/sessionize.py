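"""Sessionization of raw RTLS badge events into direct nurse-patient encounters.

A real-time locating system (RTLS) records an event whenever a badge is in
line of sight of a room sensor.  A brief interruption of that line of sight
(a nurse turning away from the sensor) fragments one bedside visit into
several short, consecutive events.  This module reconstructs unique direct
nurse-patient encounters from the raw event stream:

1. events no longer than ``min_event_s`` seconds are discarded (the
   hardware-level floor below which a sighting is noise), as are events from
   roles outside the included set;
2. successive events of the same nurse in the same room separated by a gap
   strictly shorter than ``merge_gap_s`` seconds are collapsed into a single
   encounter, transitively;
3. an encounter's duration runs from the first to the last timestamp of its
   constituent events, gaps included.

The gap between two successive events is measured end-to-start, i.e.
``next.t_start - latest t_end seen so far`` within the stream, which is what
a line-of-sight interruption produces.  The defaults (5 s floor, 30 s gap,
roles "nurse" and "float nurse") are the conventional settings for inpatient
nurse-movement analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import SchemaError

logger = logging.getLogger(__name__)

#: Column order of a raw RTLS event table.
EVENT_COLUMNS = ["nurse_id", "role", "unit_id", "room_id", "t_start", "t_end"]

#: Column order of an encounter table.
ENCOUNTER_COLUMNS = [
    "nurse_id",
    "unit_id",
    "room_id",
    "t_start",
    "t_end",
    "duration_s",
    "n_fragments",
]

DEFAULT_ROLES = frozenset({"nurse", "float nurse"})


@dataclass(frozen=True)
class SessionizeParams:
    """Parameters of the event filter and the collapse rule.

    min_event_s : events must be strictly longer than this to be kept.
    merge_gap_s : successive events merge iff the gap is strictly below this.
    included_roles : RTLS role strings admitted to the analysis.
    """

    min_event_s: float = 5.0
    merge_gap_s: float = 30.0
    included_roles: frozenset = field(default_factory=lambda: DEFAULT_ROLES)

    def __post_init__(self):
        if self.min_event_s < 0:
            raise ValueError("min_event_s must be >= 0")
        if self.merge_gap_s <= 0:
            raise ValueError("merge_gap_s must be > 0")


def _as_params(params, **overrides) -> SessionizeParams:
    if params is None:
        params = SessionizeParams(**overrides)
    elif overrides:
        raise TypeError("pass either params or keyword overrides, not both")
    return params


def _check_event_frame(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"event table missing columns: {missing}")
    ev = events.copy()
    for col in ("t_start", "t_end"):
        if not pd.api.types.is_datetime64_any_dtype(ev[col]):
            ev[col] = pd.to_datetime(ev[col], errors="coerce")
    return ev


def filter_events(
    events: pd.DataFrame,
    params: SessionizeParams | None = None,
    *,
    on_error: str = "strict",
    **overrides,
) -> pd.DataFrame:
    """Apply the event-duration floor and the role filter.

    Keeps events with ``t_end - t_start`` strictly greater than
    ``min_event_s`` whose role is in ``included_roles``; returns them sorted
    by (nurse_id, unit_id, room_id, t_start).  Input order is irrelevant.

    Malformed rows (unparseable timestamp, ``t_end < t_start``) raise
    :class:`SchemaError` naming the row indices when ``on_error="strict"``,
    or are dropped with a log line when ``on_error="skip"``.
    """
    if on_error not in ("strict", "skip"):
        raise ValueError("on_error must be 'strict' or 'skip'")
    p = _as_params(params, **overrides)
    ev = _check_event_frame(events)

    bad = ev["t_start"].isna() | ev["t_end"].isna() | (ev["t_end"] < ev["t_start"])
    if bad.any():
        rows = ev.index[bad].tolist()
        if on_error == "strict":
            raise SchemaError(
                f"{len(rows)} malformed event row(s) (NaT or t_end < t_start): "
                f"{rows[:20]}",
                rows=rows,
            )
        logger.warning("dropping %d malformed event row(s)", len(rows))
        ev = ev[~bad]

    dur = (ev["t_end"] - ev["t_start"]).dt.total_seconds()
    keep = (dur > p.min_event_s) & ev["role"].isin(p.included_roles)
    out = ev.loc[keep, EVENT_COLUMNS]
    return out.sort_values(
        ["nurse_id", "unit_id", "room_id", "t_start", "t_end"], kind="mergesort"
    ).reset_index(drop=True)


def _warn_cross_room_overlaps(ev: pd.DataFrame) -> None:
    # A badge sighted in two rooms at once is an RTLS artifact; keep both
    # streams but make the anomaly visible.
    if len(ev) < 2:
        return
    by_nurse = ev.sort_values(["nurse_id", "t_start"], kind="mergesort")
    grp = by_nurse.groupby("nurse_id", sort=False)
    prev_end = grp["t_end"].apply(lambda s: s.cummax().shift()).reset_index(drop=True)
    prev_room = grp["room_id"].shift().reset_index(drop=True)
    t_start = by_nurse["t_start"].reset_index(drop=True)
    room = by_nurse["room_id"].reset_index(drop=True)
    n = int(((t_start < prev_end) & (room != prev_room) & prev_room.notna()).sum())
    if n:
        logger.warning(
            "%d event(s) overlap a prior event of the same nurse in a "
            "different room; kept in both rooms' streams",
            n,
        )


def collapse_encounters(
    events: pd.DataFrame,
    params: SessionizeParams | None = None,
    **overrides,
) -> pd.DataFrame:
    """Collapse filtered events into unique direct nurse-patient encounters.

    Within each (nurse_id, unit_id, room_id) stream, successive events merge
    iff the gap ``next.t_start - (latest t_end so far)`` is strictly less
    than ``merge_gap_s``; merging is transitive.  Every input event belongs
    to exactly one encounter; an encounter's duration is last ``t_end``
    minus first ``t_start``, intra-encounter gaps included.
    """
    p = _as_params(params, **overrides)
    ev = _check_event_frame(events)
    if ev.empty:
        return pd.DataFrame(columns=ENCOUNTER_COLUMNS)

    ev = ev.sort_values(
        ["nurse_id", "unit_id", "room_id", "t_start", "t_end"], kind="mergesort"
    ).reset_index(drop=True)
    _warn_cross_room_overlaps(ev)

    keys = ["nurse_id", "unit_id", "room_id"]
    grp = ev.groupby(keys, sort=False)
    run_end = grp["t_end"].cummax()
    prev_end = run_end.groupby([ev[k] for k in keys], sort=False).shift()
    gap_s = (ev["t_start"] - prev_end).dt.total_seconds()
    # Strict <: a gap of exactly merge_gap_s starts a new encounter.
    new_encounter = gap_s.isna() | (gap_s >= p.merge_gap_s)
    enc_id = new_encounter.cumsum()

    enc = (
        ev.assign(_eid=enc_id)
        .groupby("_eid", sort=True)
        .agg(
            nurse_id=("nurse_id", "first"),
            unit_id=("unit_id", "first"),
            room_id=("room_id", "first"),
            t_start=("t_start", "min"),
            t_end=("t_end", "max"),
            n_fragments=("t_start", "size"),
        )
        .reset_index(drop=True)
    )
    enc["duration_s"] = (enc["t_end"] - enc["t_start"]).dt.total_seconds()
    return enc[ENCOUNTER_COLUMNS]


def encounters_to_events(encounters: pd.DataFrame) -> pd.DataFrame:
    """Re-express encounters as single raw events (one per encounter).

    Used by the idempotence property: collapsing the result reproduces the
    encounters (with ``n_fragments`` reset to 1).
    """
    ev = encounters[["nurse_id", "unit_id", "room_id", "t_start", "t_end"]].copy()
    ev.insert(1, "role", "nurse")
    return ev[EVENT_COLUMNS]


def encounter_table(encounters: pd.DataFrame, path) -> None:
    """Write encounters to the delimited encounter format (lossless)."""
    from .io import write_encounters

    write_encounters(encounters, path)


class EncounterSessionizer(BaseEstimator, TransformerMixin):
    """Transformer from raw RTLS events to direct nurse-patient encounters.

    Parameters
    ----------
    min_event_s : float, default 5.0
        Events must be strictly longer than this many seconds to be kept.
    merge_gap_s : float, default 30.0
        Successive same-nurse same-room events merge iff separated by a gap
        strictly shorter than this many seconds.
    included_roles : iterable of str, default ("nurse", "float nurse")
        RTLS role labels admitted to the analysis.
    on_error : {"strict", "skip"}, default "strict"
        Whether malformed rows abort the transform or are dropped with a log
        line.

    Examples
    --------
    >>> enc = EncounterSessionizer().fit_transform(events)   # doctest: +SKIP
    """

    def __init__(
        self,
        min_event_s: float = 5.0,
        merge_gap_s: float = 30.0,
        included_roles=("nurse", "float nurse"),
        on_error: str = "strict",
    ):
        self.min_event_s = min_event_s
        self.merge_gap_s = merge_gap_s
        self.included_roles = included_roles
        self.on_error = on_error

    def _params(self) -> SessionizeParams:
        return SessionizeParams(
            min_event_s=self.min_event_s,
            merge_gap_s=self.merge_gap_s,
            included_roles=frozenset(self.included_roles),
        )

    def fit(self, X=None, y=None):
        self.params_ = self._params()  # validates invariants
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        params = getattr(self, "params_", None) or self._params()
        filtered = filter_events(X, params, on_error=self.on_error)
        self.n_events_in_ = len(X)
        self.n_events_kept_ = len(filtered)
        return collapse_encounters(filtered, params)
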