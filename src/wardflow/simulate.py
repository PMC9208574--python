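"""Synthetic ward simulator: RTLS events, midnight census, telehealth logs.

Generates raw data with the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any hospital extract:

* a configurable number of identical single-room units (default: one
  COVID-19 unit and three comparison units of 22 beds each);
* per-patient per-shift *true visit* counts drawn from a negative binomial
  (daily encounter counts are overdispersed relative to Poisson), with
  arm- x stage- x shift-specific means;
* right-skewed lognormal visit durations (arm x stage specific);
* line-of-sight dropouts that fragment a visit into successive events with
  inter-fragment gaps below a configurable cap (default 25 s, under the
  30 s collapse rule, so ground truth stays recoverable), plus spurious
  sub-5-second events that the hardware-level floor removes;
* a midnight census per room and date with a COVID-19 status, and
  unit-level telehealth call logs with lognormal call durations.

Distinct true visits to the same room within a shift are spaced at least
``inter_visit_gap_s`` apart (default 120 s), so two different bedside
visits are never close enough to be merged by the 30 s rule; together with
fragments kept strictly longer than the 5 s floor, this makes the
generator's internal visit ledger exactly recoverable by sessionization.
Identical config + seed give byte-identical outputs.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError

SHIFTS = ("AM", "PM")
ARMS = ("covid", "comparison")
STAGE_NAMES = (
    "prepandemic",
    "rollout",
    "nonsurge1",
    "surge1",
    "nonsurge2",
    "surge2",
)
SHIFT_SECONDS = 12 * 3600
_MIN_FRAGMENT_S = 7  # every emitted fragment survives the 5 s floor


@dataclass(frozen=True)
class StageWindow:
    """A named calendar window of the observation period."""

    name: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self):
        object.__setattr__(self, "start_date", _as_date(self.start_date))
        object.__setattr__(self, "end_date", _as_date(self.end_date))
        if self.start_date > self.end_date:
            raise ConfigError(f"stage {self.name!r}: start_date after end_date")
        if self.name not in STAGE_NAMES:
            raise ConfigError(
                f"stage name {self.name!r} not one of {STAGE_NAMES}"
            )

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


def _as_date(d) -> dt.date:
    if isinstance(d, dt.date) and not isinstance(d, dt.datetime):
        return d
    return pd.Timestamp(d).date()


@dataclass(frozen=True)
class DropoutModel:
    """Per-visit line-of-sight interruption model.

    prob : probability a visit is fragmented (one interruption).
    gap_min_s / gap_cap_s : bounds of the uniform gap length, seconds; the
        cap defaults below the 30 s merge rule so fragmentation is
        reversible by sessionization.
    """

    prob: float = 0.35
    gap_min_s: int = 3
    gap_cap_s: int = 25

    def __post_init__(self):
        if not 0 <= self.prob <= 1:
            raise ConfigError("dropout.prob must be in [0, 1]")
        if not 0 < self.gap_min_s <= self.gap_cap_s:
            raise ConfigError("dropout gap bounds must satisfy 0 < min <= cap")


class SimulationResult(NamedTuple):
    """Raw tables plus the generator's ground-truth visit ledger."""

    events: pd.DataFrame
    census: pd.DataFrame
    calls: pd.DataFrame
    visits: pd.DataFrame


@dataclass(frozen=True)
class WardConfig:
    """Full parameterization of the simulated ward.

    units : mapping unit_id -> arm ("covid" or "comparison").
    stages : ordered, non-overlapping stage windows; "prepandemic" must be
        present and earliest.
    encounter_rate : arm -> stage -> shift -> (mean, dispersion); the mean
        is true visits per occupied bed per shift, the dispersion is the
        negative-binomial size parameter k (variance = m + m^2/k).
    visit_duration : arm -> stage -> (median_min, sigma) of the lognormal
        visit duration.
    nurse_to_patient_ratio : stage -> patients per nurse (3 or 4).
    ping_interval_s : (lo, hi) bounds of the badge ping cadence, seconds.
    dropout : see :class:`DropoutModel`.
    spurious_event_rate : expected sub-5-second noise events per unit-shift.
    occupancy : probability a bed holds a patient at midnight.
    covid_positive_fraction : arm -> stage -> fraction of occupied beds
        with a positive COVID-19 status.
    telehealth : arm -> stage -> (calls_per_patient_day, median_min, sigma).
    inter_visit_gap_s : minimum spacing between distinct true visits to the
        same room within a shift, seconds (> merge gap keeps them distinct).
    visit_timing : "uniform" or "clustered" start times within the shift.
    seed : integer RNG seed.
    """

    units: Mapping[str, str]
    stages: tuple
    encounter_rate: Mapping
    visit_duration: Mapping
    nurse_to_patient_ratio: Mapping[str, int]
    beds_per_unit: int = 22
    ping_interval_s: tuple = (1.0, 3.0)
    dropout: DropoutModel = field(default_factory=DropoutModel)
    spurious_event_rate: float = 2.0
    occupancy: float = 0.9
    covid_positive_fraction: Mapping = None
    telehealth: Mapping = None
    inter_visit_gap_s: int = 120
    visit_timing: str = "uniform"
    seed: int = 0

    def validate(self) -> "WardConfig":
        if self.beds_per_unit < 1:
            raise ConfigError("beds_per_unit must be >= 1")
        if not self.units:
            raise ConfigError("units must be non-empty")
        for u, arm in self.units.items():
            if arm not in ARMS:
                raise ConfigError(f"units[{u!r}]: arm must be one of {ARMS}")
        if not (0 < self.ping_interval_s[0] <= self.ping_interval_s[1]):
            raise ConfigError("ping_interval_s must satisfy 0 < lo <= hi")
        if not 0 <= self.occupancy <= 1:
            raise ConfigError("occupancy must be in [0, 1]")
        if self.spurious_event_rate < 0:
            raise ConfigError("spurious_event_rate must be >= 0")
        if self.inter_visit_gap_s < 0:
            raise ConfigError("inter_visit_gap_s must be >= 0")
        if self.visit_timing not in ("uniform", "clustered"):
            raise ConfigError("visit_timing must be 'uniform' or 'clustered'")
        stages = sorted(self.stages, key=lambda s: s.start_date)
        names = [s.name for s in stages]
        if len(set(names)) != len(names):
            raise ConfigError("stages: names must be unique")
        if "prepandemic" not in names or names[0] != "prepandemic":
            raise ConfigError("stages: 'prepandemic' must be present and earliest")
        for a, b in zip(stages, stages[1:]):
            if b.start_date <= a.end_date:
                raise ConfigError(f"stages: {a.name!r} and {b.name!r} overlap")
        for st in stages:
            for arm in set(self.units.values()):
                for shift in SHIFTS:
                    mean, k = self.encounter_rate[arm][st.name][shift]
                    if mean < 0 or k <= 0:
                        raise ConfigError(
                            f"encounter_rate[{arm}][{st.name}][{shift}]: "
                            "mean must be >= 0 and dispersion > 0"
                        )
                med, sig = self.visit_duration[arm][st.name]
                if med <= 0 or sig < 0:
                    raise ConfigError(
                        f"visit_duration[{arm}][{st.name}]: median_min > 0, sigma >= 0"
                    )
                frac = (self.covid_positive_fraction or {}).get(arm, {}).get(st.name, 0.0)
                if not 0 <= frac <= 1:
                    raise ConfigError(
                        f"covid_positive_fraction[{arm}][{st.name}] must be in [0, 1]"
                    )
                cpd = (self.telehealth or {}).get(arm, {}).get(st.name, (0.0, 1.0, 0.0))
                if cpd[0] < 0:
                    raise ConfigError(
                        f"telehealth[{arm}][{st.name}]: calls_per_patient_day >= 0"
                    )
            ratio = self.nurse_to_patient_ratio.get(st.name)
            if ratio is None or ratio < 1:
                raise ConfigError(
                    f"nurse_to_patient_ratio[{st.name}] must be an integer >= 1"
                )
        return self

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "units": dict(self.units),
            "stages": [
                {
                    "name": s.name,
                    "start_date": s.start_date.isoformat(),
                    "end_date": s.end_date.isoformat(),
                }
                for s in self.stages
            ],
            "encounter_rate": {
                a: {s: {sh: list(v) for sh, v in d.items()} for s, d in m.items()}
                for a, m in self.encounter_rate.items()
            },
            "visit_duration": {
                a: {s: list(v) for s, v in m.items()}
                for a, m in self.visit_duration.items()
            },
            "nurse_to_patient_ratio": dict(self.nurse_to_patient_ratio),
            "beds_per_unit": self.beds_per_unit,
            "ping_interval_s": list(self.ping_interval_s),
            "dropout": {
                "prob": self.dropout.prob,
                "gap_min_s": self.dropout.gap_min_s,
                "gap_cap_s": self.dropout.gap_cap_s,
            },
            "spurious_event_rate": self.spurious_event_rate,
            "occupancy": self.occupancy,
            "covid_positive_fraction": {
                a: dict(m) for a, m in (self.covid_positive_fraction or {}).items()
            },
            "telehealth": {
                a: {s: list(v) for s, v in m.items()}
                for a, m in (self.telehealth or {}).items()
            },
            "inter_visit_gap_s": self.inter_visit_gap_s,
            "visit_timing": self.visit_timing,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WardConfig":
        return cls(
            units=dict(d["units"]),
            stages=tuple(
                StageWindow(s["name"], s["start_date"], s["end_date"])
                for s in d["stages"]
            ),
            encounter_rate={
                a: {s: {sh: tuple(v) for sh, v in sd.items()} for s, sd in m.items()}
                for a, m in d["encounter_rate"].items()
            },
            visit_duration={
                a: {s: tuple(v) for s, v in m.items()}
                for a, m in d["visit_duration"].items()
            },
            nurse_to_patient_ratio=dict(d["nurse_to_patient_ratio"]),
            beds_per_unit=int(d.get("beds_per_unit", 22)),
            ping_interval_s=tuple(d.get("ping_interval_s", (1.0, 3.0))),
            dropout=DropoutModel(**d.get("dropout", {})),
            spurious_event_rate=float(d.get("spurious_event_rate", 2.0)),
            occupancy=float(d.get("occupancy", 0.9)),
            covid_positive_fraction={
                a: dict(m) for a, m in d.get("covid_positive_fraction", {}).items()
            },
            telehealth={
                a: {s: tuple(v) for s, v in m.items()}
                for a, m in d.get("telehealth", {}).items()
            },
            inter_visit_gap_s=int(d.get("inter_visit_gap_s", 120)),
            visit_timing=d.get("visit_timing", "uniform"),
            seed=int(d.get("seed", 0)),
        )


# -- defaults: a four-unit ward with paper-scale magnitudes -----------------

_DEFAULT_STAGES = (
    StageWindow("prepandemic", dt.date(2020, 1, 1), dt.date(2020, 3, 15)),
    StageWindow("rollout", dt.date(2020, 3, 16), dt.date(2020, 4, 30)),
    StageWindow("nonsurge1", dt.date(2020, 5, 1), dt.date(2020, 6, 15)),
    StageWindow("surge1", dt.date(2020, 6, 16), dt.date(2020, 8, 15)),
    StageWindow("nonsurge2", dt.date(2020, 8, 16), dt.date(2020, 11, 15)),
    StageWindow("surge2", dt.date(2020, 11, 16), dt.date(2020, 12, 27)),
)

# Visits per occupied bed per shift: (mean, NB dispersion k).
_RATES = {
    "covid": {
        "prepandemic": {"AM": (22.4, 35.0), "PM": (17.8, 35.0)},
        "rollout": {"AM": (8.9, 12.0), "PM": (6.8, 12.0)},
        "nonsurge1": {"AM": (10.5, 12.0), "PM": (8.6, 12.0)},
        "surge1": {"AM": (5.6, 20.0), "PM": (4.7, 20.0)},
        "nonsurge2": {"AM": (10.2, 15.0), "PM": (8.5, 15.0)},
        "surge2": {"AM": (6.6, 12.0), "PM": (5.1, 12.0)},
    },
    "comparison": {
        "prepandemic": {"AM": (25.3, 35.0), "PM": (16.6, 35.0)},
        "rollout": {"AM": (25.8, 35.0), "PM": (17.3, 35.0)},
        "nonsurge1": {"AM": (25.3, 30.0), "PM": (15.9, 30.0)},
        "surge1": {"AM": (23.2, 30.0), "PM": (15.5, 30.0)},
        "nonsurge2": {"AM": (21.3, 30.0), "PM": (13.9, 30.0)},
        "surge2": {"AM": (19.4, 25.0), "PM": (14.0, 25.0)},
    },
}

# Lognormal visit-duration (median minutes, sigma).
_DURATIONS = {
    "covid": {
        "prepandemic": (2.15, 0.6),
        "rollout": (7.1, 0.7),
        "nonsurge1": (4.75, 0.7),
        "surge1": (7.65, 0.6),
        "nonsurge2": (3.95, 0.6),
        "surge2": (7.3, 0.7),
    },
    "comparison": {
        "prepandemic": (2.25, 0.5),
        "rollout": (2.2, 0.5),
        "nonsurge1": (2.1, 0.5),
        "surge1": (2.2, 0.5),
        "nonsurge2": (2.25, 0.5),
        "surge2": (2.45, 0.5),
    },
}

_COVID_FRACTION = {
    "covid": {
        "prepandemic": 0.0,
        "rollout": 0.5,
        "nonsurge1": 0.4,
        "surge1": 0.8,
        "nonsurge2": 0.4,
        "surge2": 0.8,
    },
    "comparison": {
        "prepandemic": 0.0,
        "rollout": 0.02,
        "nonsurge1": 0.02,
        "surge1": 0.05,
        "nonsurge2": 0.02,
        "surge2": 0.15,
    },
}

# (calls per patient-day, lognormal median minutes, sigma).  The duration
# shape reproduces a heavily right-skewed mean ~6.6 min with SD ~13.6 min.
_TELEHEALTH = {
    "covid": {
        "prepandemic": (0.0, 2.9, 1.29),
        "rollout": (2.0, 2.9, 1.29),
        "nonsurge1": (1.5, 2.9, 1.29),
        "surge1": (3.0, 2.9, 1.29),
        "nonsurge2": (1.0, 2.9, 1.29),
        "surge2": (3.0, 2.9, 1.29),
    },
    "comparison": {
        "prepandemic": (0.0, 2.9, 1.29),
        "rollout": (0.05, 2.9, 1.29),
        "nonsurge1": (0.05, 2.9, 1.29),
        "surge1": (0.1, 2.9, 1.29),
        "nonsurge2": (0.05, 2.9, 1.29),
        "surge2": (0.5, 2.9, 1.29),
    },
}

_RATIOS = {
    "prepandemic": 4,
    "rollout": 4,
    "nonsurge1": 3,
    "surge1": 3,
    "nonsurge2": 3,
    "surge2": 3,
}


def default_config(stages=None, seed: int = 0, **overrides) -> WardConfig:
    """The default four-unit, 22-bed ward with study-scale magnitudes.

    ``stages`` may restrict/replace the calendar (e.g. a prepandemic-only
    window for calibration runs); remaining keyword overrides are applied
    with :func:`dataclasses.replace`.
    """
    cfg = WardConfig(
        units={"U1": "covid", "U2": "comparison", "U3": "comparison", "U4": "comparison"},
        stages=tuple(stages) if stages is not None else _DEFAULT_STAGES,
        encounter_rate=_RATES,
        visit_duration=_DURATIONS,
        nurse_to_patient_ratio=_RATIOS,
        covid_positive_fraction=_COVID_FRACTION,
        telehealth=_TELEHEALTH,
        seed=seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg.validate()


# -- simulation -------------------------------------------------------------


def _stage_index(dates, stages) -> np.ndarray:
    """Stage index per date; -1 outside all windows, clamped to the last
    stage for dates beyond the final window (trailing census midnight)."""
    idx = np.full(len(dates), -1, dtype=int)
    for i, st in enumerate(stages):
        for j, d in enumerate(dates):
            if st.start_date <= d <= st.end_date:
                idx[j] = i
    last_end = max(s.end_date for s in stages)
    for j, d in enumerate(dates):
        if d > last_end:
            idx[j] = len(stages) - 1
    return idx


def simulate_ward(config: WardConfig) -> SimulationResult:
    """Generate raw RTLS events, midnight census, telehealth calls, and the
    ground-truth visit ledger for the configured ward.

    Reproducible: identical config + seed give byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    units = list(config.units)
    arms = [config.units[u] for u in units]
    arm_idx = np.array([ARMS.index(a) for a in arms])
    stages = sorted(config.stages, key=lambda s: s.start_date)
    d0 = stages[0].start_date
    d1 = max(s.end_date for s in stages)
    n_days = (d1 - d0).days + 1
    shift_dates = [d0 + dt.timedelta(days=i) for i in range(n_days)]
    census_dates = shift_dates + [d1 + dt.timedelta(days=1)]
    stage_idx_day = _stage_index(shift_dates, stages)
    stage_idx_census = _stage_index(census_dates, stages)
    n_units, n_beds = len(units), config.beds_per_unit
    rooms = [[f"{u}-R{b + 1:02d}" for b in range(n_beds)] for u in units]

    # --- midnight census -------------------------------------------------
    nc = len(census_dates)
    occ = rng.random((n_units, nc, n_beds)) < config.occupancy
    frac_tab = np.zeros((len(ARMS), len(stages)))
    for ai, arm in enumerate(ARMS):
        for si, st in enumerate(stages):
            frac_tab[ai, si] = (
                (config.covid_positive_fraction or {}).get(arm, {}).get(st.name, 0.0)
            )
    frac = frac_tab[arm_idx[:, None], np.clip(stage_idx_census, 0, None)[None, :]]
    positive = occ & (rng.random((n_units, nc, n_beds)) < frac[:, :, None])
    status = np.where(~occ, "unknown", np.where(positive, "positive", "negative"))
    census = pd.DataFrame(
        {
            "unit_id": np.repeat(units, nc * n_beds),
            "room_id": np.tile(np.array(rooms).reshape(n_units, 1, n_beds), (1, nc, 1)).ravel(),
            "census_date": np.tile(np.repeat(census_dates, n_beds), n_units),
            "occupied": occ.ravel(),
            "covid_status": status.ravel(),
        }
    )

    # --- lookup tables ---------------------------------------------------
    ns = len(stages)
    rate_mean = np.zeros((len(ARMS), ns, 2))
    rate_k = np.ones((len(ARMS), ns, 2))
    dur_med = np.ones((len(ARMS), ns))
    dur_sig = np.zeros((len(ARMS), ns))
    for ai, arm in enumerate(ARMS):
        for si, st in enumerate(stages):
            for hi, sh in enumerate(SHIFTS):
                m, k = config.encounter_rate[arm][st.name][sh]
                rate_mean[ai, si, hi], rate_k[ai, si, hi] = m, k
            dur_med[ai, si], dur_sig[ai, si] = config.visit_duration[arm][st.name]
    ratio_by_stage = np.array(
        [config.nurse_to_patient_ratio[s.name] for s in stages], dtype=int
    )

    shift_start = {
        "AM": np.array(
            [np.datetime64(f"{d.isoformat()}T07:00:00") for d in shift_dates]
        ),
        "PM": np.array(
            [np.datetime64(f"{d.isoformat()}T19:00:00") for d in shift_dates]
        ),
    }

    ev_parts, ledger_parts = [], []
    for hi, shift in enumerate(SHIFTS):
        gov = np.arange(n_days) + (1 if shift == "PM" else 0)
        occ_s = occ[:, gov, :]  # (units, days, beds)
        covered = stage_idx_day >= 0
        sidx = np.clip(stage_idx_day, 0, None)
        mean = rate_mean[arm_idx[:, None], sidx[None, :], hi]
        k = rate_k[arm_idx[:, None], sidx[None, :], hi]
        active = occ_s & covered[None, :, None]
        counts = np.zeros((n_units, n_days, n_beds), dtype=int)
        ui, di, bi = np.nonzero(active)
        if len(ui):
            kk = k[ui, di]
            mm = mean[ui, di]
            counts[ui, di, bi] = rng.negative_binomial(kk, kk / (kk + mm))

        vu = np.repeat(np.arange(n_units * n_days * n_beds), counts.ravel())
        u_idx, rem = np.divmod(vu, n_days * n_beds)
        d_idx, b_idx = np.divmod(rem, n_beds)
        n_visits = len(u_idx)

        # durations and start offsets (integer seconds)
        vsig = dur_sig[arm_idx[u_idx], stage_idx_day[d_idx]]
        vmed = dur_med[arm_idx[u_idx], stage_idx_day[d_idx]] * 60.0
        dur = np.maximum(
            np.round(rng.lognormal(np.log(vmed), vsig)).astype(int), 2 * _MIN_FRAGMENT_S
        )
        if config.visit_timing == "clustered":
            offset = (rng.beta(0.6, 0.6, n_visits) * SHIFT_SECONDS).astype(int)
        else:
            offset = rng.integers(0, SHIFT_SECONDS, n_visits)

        # nurse assignment by occupied-room rank within the unit-shift
        rank = np.cumsum(occ_s, axis=2) - 1  # rank among occupied beds
        n_occ = occ_s.sum(axis=2)
        ratio = ratio_by_stage[np.clip(stage_idx_day, 0, None)]  # (days,)
        nurse_of = rank[u_idx, d_idx, b_idx] // ratio[d_idx]
        n_nurses = np.ceil(n_occ / ratio[None, :]).astype(int)

        # serialize each nurse's visits: a badge is in one room at a time,
        # and distinct visits to one room sit >= inter_visit_gap_s apart
        nurse_cell = (u_idx * n_days + d_idx) * (n_beds + 1) + nurse_of
        order = np.lexsort((offset, nurse_cell))
        offset = offset.copy()
        room_gap = config.inter_visit_gap_s
        walk_gap = 15  # seconds between leaving one room and entering another
        prev_cell = -1
        room_end: dict = {}
        nurse_end = -(10 ** 9)
        for i in order:
            c = nurse_cell[i]
            if c != prev_cell:
                room_end = {}
                nurse_end = -(10 ** 9)
                prev_cell = c
            lo = max(
                nurse_end + walk_gap,
                room_end.get(b_idx[i], -(10 ** 9)) + room_gap,
            )
            if offset[i] < lo:
                offset[i] = lo
            e = offset[i] + dur[i]
            nurse_end = max(nurse_end, e)
            room_end[b_idx[i]] = e
        is_float = nurse_of == (n_nurses[u_idx, d_idx] - 1)
        unit_arr = np.array(units)
        nurse_id = np.char.add(
            np.char.add(unit_arr[u_idx], f"-{shift}-N"),
            np.char.zfill(nurse_of.astype(str), 2),
        )
        role = np.where(is_float & (nurse_of > 0), "float nurse", "nurse")
        room_id = np.array(rooms)[u_idx, b_idx]

        t0 = shift_start[shift][d_idx] + offset.astype("timedelta64[s]")

        # fragmentation: one interruption inside the visit, gap < cap
        g = rng.integers(
            config.dropout.gap_min_s, config.dropout.gap_cap_s + 1, n_visits
        )
        frag = (rng.random(n_visits) < config.dropout.prob) & (
            dur >= g + 2 * _MIN_FRAGMENT_S
        )
        hi_split = dur - g - _MIN_FRAGMENT_S
        a = np.where(
            frag,
            rng.integers(
                _MIN_FRAGMENT_S, np.maximum(hi_split, _MIN_FRAGMENT_S + 1)
            ),
            dur,
        )

        def _mk(nid, rol, uidv, ridv, ts, te):
            return pd.DataFrame(
                {
                    "nurse_id": nid,
                    "role": rol,
                    "unit_id": uidv,
                    "room_id": ridv,
                    "t_start": ts,
                    "t_end": te,
                }
            )

        whole = ~frag
        ev_parts.append(
            _mk(
                nurse_id[whole], role[whole], unit_arr[u_idx[whole]],
                room_id[whole], t0[whole],
                t0[whole] + dur[whole].astype("timedelta64[s]"),
            )
        )
        f = frag
        ev_parts.append(
            _mk(
                nurse_id[f], role[f], unit_arr[u_idx[f]], room_id[f],
                t0[f], t0[f] + a[f].astype("timedelta64[s]"),
            )
        )
        ev_parts.append(
            _mk(
                nurse_id[f], role[f], unit_arr[u_idx[f]], room_id[f],
                t0[f] + (a[f] + g[f]).astype("timedelta64[s]"),
                t0[f] + dur[f].astype("timedelta64[s]"),
            )
        )

        # spurious sub-floor noise events
        n_spur = rng.poisson(config.spurious_event_rate, (n_units, n_days))
        su = np.repeat(np.arange(n_units * n_days), n_spur.ravel())
        su_u, su_d = np.divmod(su, n_days)
        if len(su):
            s_off = rng.integers(0, SHIFT_SECONDS, len(su))
            s_dur = rng.integers(1, 6, len(su))  # 1..5 s, all below the floor
            s_bed = rng.integers(0, n_beds, len(su))
            s_t0 = shift_start[shift][su_d] + s_off.astype("timedelta64[s]")
            ev_parts.append(
                _mk(
                    np.char.add(unit_arr[su_u], f"-{shift}-N00"),
                    np.full(len(su), "nurse"),
                    unit_arr[su_u],
                    np.array(rooms)[su_u, s_bed],
                    s_t0,
                    s_t0 + s_dur.astype("timedelta64[s]"),
                )
            )

        ledger_parts.append(
            pd.DataFrame(
                {
                    "unit_id": unit_arr[u_idx],
                    "arm": np.array(arms)[u_idx],
                    "room_id": room_id,
                    "stage": np.array([stages[i].name for i in range(ns)])[
                        np.clip(stage_idx_day, 0, None)
                    ][d_idx],
                    "shift_date": np.array(shift_dates)[d_idx],
                    "shift": shift,
                    "nurse_id": nurse_id,
                    "t_start": t0,
                    "duration_s": dur,
                    "n_fragments": np.where(frag, 2, 1),
                }
            )
        )

    events = (
        pd.concat(ev_parts, ignore_index=True)
        .sort_values(["t_start", "nurse_id", "room_id", "t_end"], kind="mergesort")
        .reset_index(drop=True)
    )
    visits = (
        pd.concat(ledger_parts, ignore_index=True)
        .sort_values(["t_start", "nurse_id", "room_id"], kind="mergesort")
        .reset_index(drop=True)
    )

    # --- telehealth calls ------------------------------------------------
    tel_tab = np.zeros((len(ARMS), ns, 3))
    for ai, arm in enumerate(ARMS):
        for si, st in enumerate(stages):
            tel_tab[ai, si] = (config.telehealth or {}).get(arm, {}).get(
                st.name, (0.0, 1.0, 0.0)
            )
    n_pat = occ[:, :n_days, :].sum(axis=2)
    covered = stage_idx_day >= 0
    cpd = tel_tab[arm_idx[:, None], np.clip(stage_idx_day, 0, None)[None, :], 0]
    lam = np.where(covered[None, :], cpd * n_pat, 0.0)
    n_calls = rng.poisson(lam)
    cu = np.repeat(np.arange(n_units * n_days), n_calls.ravel())
    cu_u, cu_d = np.divmod(cu, n_days)
    if len(cu):
        med = tel_tab[arm_idx[cu_u], stage_idx_day[cu_d], 1] * 60.0
        sig = tel_tab[arm_idx[cu_u], stage_idx_day[cu_d], 2]
        c_dur = np.maximum(np.round(rng.lognormal(np.log(med), sig)).astype(int), 5)
        c_dur = np.minimum(c_dur, 6 * 3600)
        c_off = rng.integers(0, 24 * 3600, len(cu))
        singleton = rng.random(len(cu)) < 0.08
        c_part = np.where(singleton, 1, 2 + rng.poisson(0.8, len(cu)))
        day0 = np.array([np.datetime64(d.isoformat()) for d in shift_dates])
        c_t0 = day0[cu_d] + c_off.astype("timedelta64[s]")
        calls = pd.DataFrame(
            {
                "unit_id": np.array(units)[cu_u],
                "t_start": c_t0,
                "t_end": c_t0 + c_dur.astype("timedelta64[s]"),
                "n_participants": c_part,
            }
        )
    else:
        calls = pd.DataFrame(
            columns=["unit_id", "t_start", "t_end", "n_participants"]
        )
    calls = calls.sort_values(
        ["t_start", "unit_id"], kind="mergesort"
    ).reset_index(drop=True)

    census = census.sort_values(
        ["unit_id", "census_date", "room_id"], kind="mergesort"
    ).reset_index(drop=True)
    return SimulationResult(events, census, calls, visits)


def ping_times(t_start, t_end, ping_interval_s=(1.0, 3.0), rng=None) -> np.ndarray:
    """Badge ping timestamps within one event.

    Pings start at ``t_start`` and successive gaps are uniform within the
    configured bounds; the final ping is the last one not after ``t_end``,
    so every inter-ping gap lies inside the bounds.
    """
    rng = rng or np.random.default_rng()
    lo, hi = ping_interval_s
    total = (pd.Timestamp(t_end) - pd.Timestamp(t_start)).total_seconds()
    gaps = rng.uniform(lo, hi, size=max(int(total / lo) + 1, 1))
    t = np.concatenate([[0.0], np.cumsum(gaps)])
    t = t[t <= total]
    return pd.Timestamp(t_start) + pd.to_timedelta(t, unit="s")


# -- packaged hand-checkable fixtures ---------------------------------------

FIXTURES = ("single_visit", "empty_ward", "two_arm_effect", "adversarial_gaps")


def _fixture_census(units_rooms, dates, occupied=True, covid="negative"):
    rows = [
        {
            "unit_id": u,
            "room_id": r,
            "census_date": d,
            "occupied": occupied,
            "covid_status": covid if occupied else "unknown",
        }
        for (u, r) in units_rooms
        for d in dates
    ]
    return pd.DataFrame(rows)


def make_fixture(name: str):
    """Return a tiny hand-checkable (events, census, calls, manifest) set.

    The manifest records the exact encounters, outcomes and DiD quantities
    an independent hand/arithmetic oracle computes for the scenario; tests
    compare pipeline output against it.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    empty_calls = pd.DataFrame(columns=["unit_id", "t_start", "t_end", "n_participants"])

    if name == "single_visit":
        # one bedside visit fragmented into 3 events (gaps 20 s and 25 s)
        ts = pd.Timestamp("2020-01-02 08:00:00")
        events = pd.DataFrame(
            {
                "nurse_id": ["N1"] * 3,
                "role": ["nurse"] * 3,
                "unit_id": ["U1"] * 3,
                "room_id": ["U1-R01"] * 3,
                "t_start": [ts, ts + pd.Timedelta(seconds=80), ts + pd.Timedelta(seconds=145)],
                "t_end": [
                    ts + pd.Timedelta(seconds=60),
                    ts + pd.Timedelta(seconds=120),
                    ts + pd.Timedelta(seconds=180),
                ],
            }
        )
        census = _fixture_census(
            [("U1", "U1-R01")],
            [dt.date(2020, 1, 1), dt.date(2020, 1, 2), dt.date(2020, 1, 3)],
        )
        manifest = {
            "n_encounters": 1,
            "encounter": {
                "nurse_id": "N1",
                "room_id": "U1-R01",
                "t_start": "2020-01-02T08:00:00",
                "t_end": "2020-01-02T08:03:00",
                "duration_s": 180.0,
                "n_fragments": 3,
            },
            "shift_key": {"shift_date": "2020-01-02", "shift": "AM"},
            "daily": {
                "n_patients": 1,
                "encounters_per_patient": 1.0,
                "median_encounter_min": 3.0,
                "median_total_min_per_patient": 3.0,
            },
        }
        return events, census, empty_calls, manifest

    if name == "empty_ward":
        events = pd.DataFrame(
            columns=["nurse_id", "role", "unit_id", "room_id", "t_start", "t_end"]
        )
        census = _fixture_census(
            [("U1", "U1-R01"), ("U1", "U1-R02")],
            [dt.date(2020, 1, 1), dt.date(2020, 1, 2)],
            occupied=False,
        )
        manifest = {
            "n_encounters": 0,
            "daily": {"n_patients": 0, "per_patient_outcomes": "undefined"},
        }
        return events, census, empty_calls, manifest

    if name == "adversarial_gaps":
        # two fragments separated by 35 s (> 30 s rule): NOT merged
        ts = pd.Timestamp("2020-01-02 09:00:00")
        events = pd.DataFrame(
            {
                "nurse_id": ["N1"] * 2,
                "role": ["nurse"] * 2,
                "unit_id": ["U1"] * 2,
                "room_id": ["U1-R01"] * 2,
                "t_start": [ts, ts + pd.Timedelta(seconds=95)],
                "t_end": [ts + pd.Timedelta(seconds=60), ts + pd.Timedelta(seconds=150)],
            }
        )
        census = _fixture_census(
            [("U1", "U1-R01")], [dt.date(2020, 1, 2), dt.date(2020, 1, 3)]
        )
        manifest = {"n_encounters": 2, "gap_s": 35.0}
        return events, census, empty_calls, manifest

    # "two_arm_effect": two units, two stages, built-in DiD of known size.
    counts = {
        ("U1", dt.date(2020, 1, 1)): 5,
        ("U1", dt.date(2020, 1, 2)): 7,
        ("U1", dt.date(2020, 1, 3)): 2,
        ("U1", dt.date(2020, 1, 4)): 2,
        ("U2", dt.date(2020, 1, 1)): 4,
        ("U2", dt.date(2020, 1, 2)): 4,
        ("U2", dt.date(2020, 1, 3)): 3,
        ("U2", dt.date(2020, 1, 4)): 5,
    }
    rows = []
    for (u, d), n in counts.items():
        for i in range(n):
            t0 = pd.Timestamp(d) + pd.Timedelta(hours=8) + i * pd.Timedelta(minutes=30)
            rows.append(
                {
                    "nurse_id": f"{u}-N1",
                    "role": "nurse",
                    "unit_id": u,
                    "room_id": f"{u}-R01",
                    "t_start": t0,
                    "t_end": t0 + pd.Timedelta(seconds=120),
                }
            )
    events = pd.DataFrame(rows)
    census = _fixture_census(
        [("U1", "U1-R01"), ("U2", "U2-R01")],
        [dt.date(2020, 1, 1) + dt.timedelta(days=i) for i in range(5)],
    )
    stages = (
        StageWindow("prepandemic", dt.date(2020, 1, 1), dt.date(2020, 1, 2)),
        StageWindow("surge1", dt.date(2020, 1, 3), dt.date(2020, 1, 4)),
    )
    # closed-form 2x2 OLS arithmetic on the daily AM counts per patient:
    # covid cells (5,7)->(2,2), comparison (4,4)->(3,5); DiD = (2-6)-(4-4).
    from scipy import stats as sps

    sse = 2.0 + 0.0 + 0.0 + 2.0  # within-cell sums of squares
    s2 = sse / 4.0  # residual df = 8 obs - 4 params
    se = math.sqrt(s2 * (1 / 2 + 1 / 2 + 1 / 2 + 1 / 2))
    t_stat = -4.0 / se
    p = 2 * sps.t.sf(abs(t_stat), 4)
    manifest = {
        "stages": [
            {"name": s.name, "start_date": s.start_date.isoformat(), "end_date": s.end_date.isoformat()}
            for s in stages
        ],
        "arm_of": {"U1": "covid", "U2": "comparison"},
        "n_encounters": sum(counts.values()),
        "did": {
            "outcome": "encounters_per_patient",
            "stage": "surge1",
            "shift": "AM",
            "covid_change": -4.0,
            "comparison_change": 0.0,
            "did": -4.0,
            "t": t_stat,
            "p_raw": p,
        },
        "daily_am_counts": {u: {d.isoformat(): n for (uu, d), n in counts.items() if uu == u} for u in ("U1", "U2")},
    }
    return events, census, empty_calls, manifest
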