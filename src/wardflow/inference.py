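"""Difference-in-differences inference with adaptive two-stage FDR control.

For each outcome, pandemic stage and shift, the change from the prepandemic
baseline is computed per arm, and the difference-in-differences (DiD) —
(COVID-arm change) minus (comparison-arm change) — is tested with a
Gaussian-family generalized linear model on daily unit-level values:

    value ~ arm + period + arm x period

fitted by ordinary least squares (identity link), where ``period`` contrasts
the stage against the baseline.  On a saturated 2x2 design the fitted
interaction coefficient equals the four-cell-means DiD exactly, balanced or
not; its two-sided p-value is the reported raw p.  The observational unit is
the unit-day: each comparison unit contributes one value per day, with no
clustering correction (a documented simplification).

Across the stage x shift comparisons within one outcome, p-values are
adjusted with the adaptive two-stage linear step-up procedure (the
Benjamini-Krieger-Yekutieli two-stage FDR rule): stage 1 runs the linear
step-up at q' = q/(1+q); its rejection count r1 estimates the number of true
nulls as m0 = m - r1; if r1 = 0 nothing is rejected, if m0 = 0 everything
is, and otherwise stage 2 reruns the step-up at q' * m / m0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .census import AM, PM
from .errors import ConfigError
from .outcomes import OUTCOMES, daily_with_stage

ARMS = ("covid", "comparison")


def change_from_baseline(stage_mean: float, baseline_mean: float) -> float:
    """Stage mean minus prepandemic mean, full precision (round at render)."""
    return stage_mean - baseline_mean


def did(covid_change: float, comparison_change: float) -> float:
    """Difference-in-differences: COVID-arm change minus comparison change."""
    return covid_change - comparison_change


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (table-rendering convention)."""
    factor = 10.0 ** ndigits
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


@dataclass(frozen=True)
class FdrParams:
    """FDR control settings: target level q and the adjustment method."""

    q: float = 0.05
    method: str = "adaptive_two_stage"

    def __post_init__(self):
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.method not in ("adaptive_two_stage", "bh"):
            raise ValueError("method must be 'adaptive_two_stage' or 'bh'")


def fdr_adjust(p_values, q: float = 0.05, method: str = "adaptive_two_stage"):
    """Multiple-testing adjustment controlling the false discovery rate.

    Parameters
    ----------
    p_values : array-like of raw p-values in [0, 1].
    q : target FDR level.
    method : "adaptive_two_stage" (two-stage linear step-up) or "bh"
        (plain Benjamini-Hochberg linear step-up).

    Returns
    -------
    reject : boolean array of per-hypothesis decisions.
    p_adj : adjusted q-values (for the two-stage rule these are the BH
        q-values scaled by the estimated null fraction m0/m; decisions come
        from the explicit step rule, not from thresholding ``p_adj``).
    """
    FdrParams(q=q, method=method)
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)

    if method == "bh":
        reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
        return reject, p_adj

    m = p.size
    q1 = q / (1.0 + q)
    stage1, p_bh, _, _ = multipletests(p, alpha=q1, method="fdr_bh")
    r1 = int(stage1.sum())
    m0 = m - r1
    if r1 == 0:
        return np.zeros(m, dtype=bool), p_bh
    if m0 == 0:
        return np.ones(m, dtype=bool), np.zeros(m)
    reject, _, _, _ = multipletests(p, alpha=q1 * m / m0, method="fdr_bh")
    return reject, np.minimum(p_bh * m0 / m, 1.0)


@dataclass
class DidTestResult:
    """Interaction estimate and two-sided p from the 2x2 daily-value model."""

    estimate: float
    p_value: float
    n_obs: int
    ok: bool
    reason: str = ""


def did_test(
    daily: pd.DataFrame,
    outcome: str,
    stage: str,
    shift: str,
    baseline: str = "prepandemic",
) -> DidTestResult:
    """Test the DiD for one outcome, stage and shift on daily unit values.

    Fits value ~ arm + period + arm x period by OLS on the unit-day values
    of both arms in the baseline and the given stage; returns the
    interaction coefficient (identically the four-cell-means DiD) and its
    two-sided p-value.  Requires at least 2 non-missing unit-days in each
    of the four cells; otherwise the result is flagged undefined.

    ``daily`` must carry a ``stage`` column (see
    :func:`wardflow.outcomes.daily_with_stage`).
    """
    sub = daily[
        daily["stage"].isin([baseline, stage])
        & (daily["shift"] == shift)
        & daily["arm"].isin(ARMS)
    ].dropna(subset=[outcome])
    a = (sub["arm"] == "covid").to_numpy(dtype=float)
    t = (sub["stage"] == stage).to_numpy(dtype=float)
    cells = {(ai, ti): int(((a == ai) & (t == ti)).sum()) for ai in (0, 1) for ti in (0, 1)}
    if min(cells.values()) < 2:
        return DidTestResult(np.nan, np.nan, len(sub), False, f"cell counts {cells}")
    X = np.column_stack([np.ones(len(sub)), a, t, a * t])
    fit = sm.OLS(sub[outcome].to_numpy(dtype=float), X).fit()
    return DidTestResult(float(fit.params[3]), float(fit.pvalues[3]), len(sub), True)


DID_COLUMNS = [
    "outcome",
    "stage",
    "shift",
    "covid_change",
    "comparison_change",
    "did",
    "p_raw",
    "p_fdr",
    "significant",
]


class DifferenceInDifferences(BaseEstimator):
    """Stage-wise difference-in-differences estimator with FDR control.

    Parameters
    ----------
    baseline : str, default "prepandemic"
        Name of the baseline stage all changes are measured against.
    q : float, default 0.05
        Target false discovery rate.
    fdr_method : {"adaptive_two_stage", "bh"}, default "adaptive_two_stage"
        Multiple-testing procedure.
    fdr_family : {"per_outcome", "pooled"}, default "per_outcome"
        Whether p-values are adjusted within each outcome (one family per
        results table) or across all outcomes at once.
    outcomes : sequence of outcome column names, default the three workflow
        outcomes.

    Attributes
    ----------
    results_ : DataFrame with one row per (outcome, stage, shift): per-arm
        changes from baseline, the DiD, raw and FDR-adjusted p, and the
        rejection decision at level ``q``.
    stages_ : the non-baseline stages tested, in input order.
    """

    def __init__(
        self,
        baseline: str = "prepandemic",
        q: float = 0.05,
        fdr_method: str = "adaptive_two_stage",
        fdr_family: str = "per_outcome",
        outcomes=OUTCOMES,
    ):
        self.baseline = baseline
        self.q = q
        self.fdr_method = fdr_method
        self.fdr_family = fdr_family
        self.outcomes = outcomes

    def fit(self, X: pd.DataFrame, y=None):
        """Fit on daily unit-shift outcomes carrying a ``stage`` column."""
        FdrParams(q=self.q, method=self.fdr_method)
        if self.fdr_family not in ("per_outcome", "pooled"):
            raise ConfigError("fdr_family must be 'per_outcome' or 'pooled'")
        if "stage" not in X.columns:
            raise ConfigError(
                "daily table lacks a 'stage' column; use outcomes.daily_with_stage"
            )
        stage_order = list(dict.fromkeys(X["stage"]))
        if self.baseline not in stage_order:
            raise ConfigError(f"baseline stage {self.baseline!r} absent from data")
        self.stages_ = [s for s in stage_order if s != self.baseline]

        rows = []
        for outcome in self.outcomes:
            base_means = {
                (arm, shift): X.loc[
                    (X["stage"] == self.baseline)
                    & (X["arm"] == arm)
                    & (X["shift"] == shift),
                    outcome,
                ].mean()
                for arm in ARMS
                for shift in (AM, PM)
            }
            for stage in self.stages_:
                for shift in (AM, PM):
                    changes = {}
                    for arm in ARMS:
                        stage_mean = X.loc[
                            (X["stage"] == stage)
                            & (X["arm"] == arm)
                            & (X["shift"] == shift),
                            outcome,
                        ].mean()
                        changes[arm] = change_from_baseline(
                            stage_mean, base_means[(arm, shift)]
                        )
                    test = did_test(X, outcome, stage, shift, baseline=self.baseline)
                    rows.append(
                        {
                            "outcome": outcome,
                            "stage": stage,
                            "shift": shift,
                            "covid_change": changes["covid"],
                            "comparison_change": changes["comparison"],
                            "did": did(changes["covid"], changes["comparison"]),
                            "p_raw": test.p_value,
                        }
                    )
        res = pd.DataFrame(rows)

        res["p_fdr"] = np.nan
        res["significant"] = False
        families = (
            [res.index] if self.fdr_family == "pooled"
            else [res.index[res["outcome"] == o] for o in self.outcomes]
        )
        for idx in families:
            testable = idx[res.loc[idx, "p_raw"].notna()]
            if len(testable) == 0:
                continue
            reject, p_adj = fdr_adjust(
                res.loc[testable, "p_raw"], q=self.q, method=self.fdr_method
            )
            res.loc[testable, "p_fdr"] = p_adj
            res.loc[testable, "significant"] = reject
        self.results_ = res[DID_COLUMNS]
        return self


def did_table(
    daily: pd.DataFrame,
    stages=None,
    baseline: str = "prepandemic",
    q: float = 0.05,
    fdr_method: str = "adaptive_two_stage",
    fdr_family: str = "per_outcome",
) -> pd.DataFrame:
    """One-call DiD results table from daily outcomes.

    If ``stages`` (a list of stage windows) is given, stage labels are
    assigned from ``shift_date`` first; otherwise ``daily`` must already
    carry a ``stage`` column.
    """
    d = daily_with_stage(daily, stages) if stages is not None else daily
    est = DifferenceInDifferences(
        baseline=baseline, q=q, fdr_method=fdr_method, fdr_family=fdr_family
    ).fit(d)
    return est.results_


def render_did_table(results: pd.DataFrame, ndigits: int = 1) -> pd.DataFrame:
    """Round the change/DiD columns for table rendering (half away from zero)."""
    out = results.copy()
    for col in ("covid_change", "comparison_change", "did"):
        out[col] = out[col].map(lambda v: round_half_away(v, ndigits))
    return out
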