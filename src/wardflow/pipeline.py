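"""End-to-end composition: raw tables -> encounters -> outcomes -> inference.

``run_pipeline`` chains the sessionizer, census linker, outcome aggregator,
DiD estimator, telehealth summarizer and resource model, and returns every
intermediate table plus a manifest (package version, config hash, row
counts) so a run is fully reproducible and auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .census import CensusLinker
from .errors import WardflowError
from .inference import DifferenceInDifferences
from .outcomes import ShiftOutcomeAggregator, daily_with_stage, stage_summary
from .resources import ResourceModel
from .sessionize import EncounterSessionizer
from .telehealth import TelehealthCallFilter, summarize_calls

logger = logging.getLogger(__name__)


@dataclass
class PipelineReport:
    """All outputs of one end-to-end run."""

    encounters: pd.DataFrame
    linked: pd.DataFrame
    daily: pd.DataFrame
    stage_summary: pd.DataFrame
    did: pd.DataFrame
    telehealth: pd.DataFrame
    resources: dict
    manifest: dict


def _stage_day_counts(daily_staged: pd.DataFrame, baseline: str) -> dict:
    counts = (
        daily_staged[daily_staged["stage"] != baseline]
        .groupby("stage")["shift_date"]
        .nunique()
        .to_dict()
    )
    return counts


def run_pipeline(config, events, census, calls) -> PipelineReport:
    """Run the full analysis on raw tables under a :class:`RunConfig`.

    Deterministic given inputs + config.  Stage names are attached to
    errors so failures locate themselves.
    """
    stage = "sessionize"
    try:
        sess = EncounterSessionizer(
            min_event_s=config.sessionize.min_event_s,
            merge_gap_s=config.sessionize.merge_gap_s,
            included_roles=config.sessionize.included_roles,
        )
        encounters = sess.fit(events).transform(events)

        stage = "link"
        linked = CensusLinker(pm_census=config.pm_census).fit(census).transform(encounters)

        stage = "outcomes"
        agg = ShiftOutcomeAggregator(arm_of=config.arm_of, pm_census=config.pm_census)
        daily = agg.fit(census).transform(linked)
        staged = daily_with_stage(daily, config.stages)
        summary = stage_summary(daily, config.stages)

        stage = "did"
        est = DifferenceInDifferences(
            baseline=config.baseline,
            q=config.fdr.q,
            fdr_method=config.fdr.method,
            fdr_family=config.fdr_family,
        ).fit(staged)
        did = est.results_

        stage = "telehealth"
        kept = TelehealthCallFilter().fit().transform(calls)
        tele = summarize_calls(kept, census, config.stages, config.arm_of)

        stage = "resources"
        day_counts = _stage_day_counts(staged, config.baseline)
        enc = did[did["outcome"] == "encounters_per_patient"]
        series = {
            shift: [
                (row["did"], day_counts.get(row["stage"], 0))
                for _, row in enc[enc["shift"] == shift].iterrows()
                if pd.notna(row["did"])
            ]
            for shift in ("AM", "PM")
        }
        resources = {}
        if all(series.values()):
            model = ResourceModel(
                beds=config.resources.beds,
                days=config.resources.days,
                ppe_fraction=config.resources.ppe_fraction,
                don_min=config.resources.don_min,
                doff_min=config.resources.doff_min,
            ).fit(series)
            resources = {
                "delta_am": model.delta_.delta_am,
                "delta_pm": model.delta_.delta_pm,
                "ppe_saved": model.ppe_saved_,
                "time_saved_min_am": model.time_saved_min_["AM"],
                "time_saved_min_pm": model.time_saved_min_["PM"],
            }
    except WardflowError as exc:
        raise type(exc)(f"[{stage}] {exc}") from exc

    manifest = {
        "wardflow_version": __version__,
        "config_hash": config.config_hash(),
        "rows": {
            "events_in": int(len(events)),
            "encounters": int(len(encounters)),
            "linked": int(len(linked)),
            "daily": int(len(daily)),
            "did": int(len(did)),
            "telehealth_calls_in": int(len(calls)),
            "telehealth_calls_kept": int(len(kept)),
        },
    }
    return PipelineReport(
        encounters=encounters,
        linked=linked,
        daily=daily,
        stage_summary=summary,
        did=did,
        telehealth=tele,
        resources=resources,
        manifest=manifest,
    )
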