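"""Back-of-envelope PPE and nurse-time savings from avoided encounters.

Fewer bedside entries on an isolation unit translate into saved personal
protective equipment (PPE) sets and saved donning/doffing time.  Given the
per-patient per-shift decrease in encounters attributable to the workflow
change (the sign convention is positive = avoided encounters):

* PPE units saved over a horizon of ``days`` days on a fully occupied
  ``beds``-bed unit, with PPE worn for a fraction ``ppe_fraction`` of the
  avoided encounters:

      beds x (delta_AM + delta_PM) x days x ppe_fraction

* nurse time saved per shift, at ``don_min`` + ``doff_min`` minutes of PPE
  handling per avoided entry:

      delta_shift x (don_min + doff_min)

Results are returned at full precision; rounding (half away from zero)
belongs to the rendering layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .inference import round_half_away


@dataclass(frozen=True)
class ResourceParams:
    """Assumptions of the savings model (defaults: a fully occupied 22-bed
    isolation unit over one week, PPE for a quarter of avoided encounters,
    4 min to don and 3 min to doff)."""

    beds: int = 22
    days: float = 7.0
    ppe_fraction: float = 0.25
    don_min: float = 4.0
    doff_min: float = 3.0

    def __post_init__(self):
        if self.beds < 0 or self.days < 0 or self.don_min < 0 or self.doff_min < 0:
            raise ValueError("beds, days, don_min, doff_min must be nonnegative")
        if not 0 <= self.ppe_fraction <= 1:
            raise ValueError("ppe_fraction must be in [0, 1]")


@dataclass(frozen=True)
class EncounterDelta:
    """Avoided encounters per patient per shift (positive = avoided)."""

    delta_am: float
    delta_pm: float


def weighted_delta(did_by_stage, shift: str | None = None) -> float:
    """Day-count-weighted mean decrease in encounters across stages.

    ``did_by_stage`` is a list of (did, n_days) pairs, one per pandemic
    stage, where ``did`` is the difference-in-differences of encounters per
    patient per shift (negative when encounters decreased).  Returns the
    weighted mean of the *decreases* (-did).
    """
    pairs = list(did_by_stage)
    if not pairs:
        raise ValueError("did_by_stage must be non-empty")
    dids = np.array([d for d, _ in pairs], dtype=float)
    w = np.array([n for _, n in pairs], dtype=float)
    if w.sum() <= 0:
        raise ValueError("total day count must be positive")
    return float(-(dids * w).sum() / w.sum())


def ppe_saved(delta: EncounterDelta, params: ResourceParams = ResourceParams()) -> int:
    """PPE units saved over the horizon, rounded to the nearest integer."""
    exact = (
        params.beds
        * (delta.delta_am + delta.delta_pm)
        * params.days
        * params.ppe_fraction
    )
    return int(round_half_away(exact))


def nurse_time_saved(
    delta_per_shift: float, params: ResourceParams = ResourceParams()
) -> float:
    """Minutes of donning/doffing saved per shift, full precision."""
    return delta_per_shift * (params.don_min + params.doff_min)


class ResourceModel(BaseEstimator):
    """Estimator wrapping the savings arithmetic.

    Parameters mirror :class:`ResourceParams`.  ``fit`` takes the per-shift
    DiD series (lists of (did, n_days) pairs for the AM and PM shifts) and
    exposes ``delta_``, ``ppe_saved_`` and ``time_saved_min_`` attributes.
    """

    def __init__(
        self,
        beds: int = 22,
        days: float = 7.0,
        ppe_fraction: float = 0.25,
        don_min: float = 4.0,
        doff_min: float = 3.0,
    ):
        self.beds = beds
        self.days = days
        self.ppe_fraction = ppe_fraction
        self.don_min = don_min
        self.doff_min = doff_min

    def _params(self) -> ResourceParams:
        return ResourceParams(
            beds=self.beds,
            days=self.days,
            ppe_fraction=self.ppe_fraction,
            don_min=self.don_min,
            doff_min=self.doff_min,
        )

    def fit(self, X, y=None):
        """X: {"AM": [(did, n_days), ...], "PM": [(did, n_days), ...]}."""
        params = self._params()
        self.delta_ = EncounterDelta(
            delta_am=weighted_delta(X["AM"]), delta_pm=weighted_delta(X["PM"])
        )
        self.ppe_saved_ = ppe_saved(self.delta_, params)
        self.time_saved_min_ = {
            "AM": nurse_time_saved(self.delta_.delta_am, params),
            "PM": nurse_time_saved(self.delta_.delta_pm, params),
        }
        return self
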