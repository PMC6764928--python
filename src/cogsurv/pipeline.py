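"""End-to-end orchestration: norms -> RCIs -> selection -> decline -> survival.

The stages mirror the study's analysis: fit per-test normative retest
regressions on healthy controls; compute each patient's month 0 -> 3 reliable
change and select the three most-recovered tests; re-baseline all later
contrasts at month 3 and classify per-visit decline (two-of-three at RCI <=
-1); expand decline timelines and progression/censoring records into 3-month
counting-process intervals; and fit the discrete proportional-hazards model
with decline status (time-dependent) and age at surgery.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import cohort_io, normative, personalization, survival
from .cohort_io import DEFAULT_ROSTER, Roster
from .normative import NormativeModel, RCIVector
from .personalization import AnalysisCriteria, DeclineTimeline, Selection
from .survival import CoxFit

__all__ = ["PipelineConfig", "PipelineResult", "run_analysis", "run_pipeline"]

log = logging.getLogger("cogsurv")

FOLLOWUP_TIMEPOINTS = tuple(t for t in cohort_io.TIMEPOINTS if t >= 6)


@dataclass(frozen=True)
class PipelineConfig:
    """One serializable source of truth for a reproducible run."""

    controls_path: str | None = None
    scores_path: str | None = None
    events_path: str | None = None
    out_dir: str = "cogsurv_out"
    criteria: AnalysisCriteria = field(default_factory=AnalysisCriteria)
    normative_covariates: tuple[str, ...] = ()
    ties: str = "discrete"
    alpha: float = 0.05
    seed: int = 0
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        crit = AnalysisCriteria(**raw.pop("criteria", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw["normative_covariates"] = tuple(raw.get("normative_covariates", ()))
        return cls(criteria=crit, **raw)

    def digest(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.__dict__.items() if k != "criteria"}
        payload["criteria"] = self.criteria.__dict__
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything a run produces, with a JSON-able summary payload."""

    models: Mapping[str, NormativeModel]
    selections: Mapping[str, Selection]
    timelines: Mapping[str, DeclineTimeline]
    survival_data: pd.DataFrame
    fit: CoxFit
    median_time_to_pd: int | None
    median_time_to_cd: int | None
    n_patients: int
    n_events: int
    excluded: tuple[str, ...] = ()

    def to_payload(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_events": self.n_events,
            "n_declined": sum(tl.first_cd_time is not None
                              for tl in self.timelines.values()),
            "median_time_to_pd": self.median_time_to_pd,
            "median_time_to_cd": self.median_time_to_cd,
            "excluded": list(self.excluded),
            "fit": self.fit.to_payload(),
            "selections": {pid: {"selected": list(s.selected),
                                 "selection_rcis": list(s.selection_rcis)}
                           for pid, s in sorted(self.selections.items())},
            "timelines": {pid: {"first_cd_time": tl.first_cd_time,
                                "flags": {str(t): bool(f)
                                          for t, f in sorted(tl.flags.items())}}
                          for pid, tl in sorted(self.timelines.items())},
        }


def run_analysis(controls: pd.DataFrame, scores: pd.DataFrame, events: pd.DataFrame,
                 criteria: AnalysisCriteria = AnalysisCriteria(),
                 ties: str = "discrete", alpha: float = 0.05,
                 normative_covariates: Sequence[str] = (),
                 roster: Roster = DEFAULT_ROSTER) -> PipelineResult:
    """Run every analysis stage on in-memory tables.

    Patients without both selection-contrast assessments (months 0 and 3) or
    without any follow-up visit are excluded and reported in ``excluded``,
    mirroring the study's handling of incomplete early assessments.
    """
    models = {
        str(test): normative.fit_normative_model(grp, covariates=normative_covariates)
        for test, grp in controls.groupby("test_id")
    }
    log.info("fitted %d normative models", len(models))

    selections: dict[str, Selection] = {}
    timelines: dict[str, DeclineTimeline] = {}
    excluded: list[str] = []
    by_patient = dict(tuple(scores.groupby("patient_id")))
    for pid in events["patient_id"].astype(str):
        pscores = by_patient.get(pid)
        if pscores is None:
            excluded.append(pid)
            continue
        try:
            sel_vec = normative.compute_rci_vector(
                pscores, criteria.selection_baseline, criteria.baseline_timepoint,
                models)
            selection = personalization.select_tests(sel_vec, criteria,
                                                     roster_order=roster.codes)
        except ValueError:
            excluded.append(pid)
            continue
        followups: list[RCIVector] = []
        present = set(pscores["timepoint"].unique())
        for t in FOLLOWUP_TIMEPOINTS:
            if t in present:
                followups.append(normative.compute_rci_vector(
                    pscores, criteria.baseline_timepoint, t, models))
        if not followups:
            excluded.append(pid)
            continue
        selections[pid] = selection
        timelines[pid] = personalization.classify_decline(selection, followups,
                                                          criteria)
    if excluded:
        log.info("excluded %d patients with incomplete assessments: %s",
                 len(excluded), excluded)
    kept = events[events["patient_id"].astype(str).isin(selections)].reset_index(drop=True)
    log.info("analyzing %d patients", len(kept))

    data = survival.build_survival_dataset(kept, timelines)
    fit = survival.fit_discrete_cox(data, covariates=("cd_status", "age"),
                                    ties=ties, alpha=alpha)
    log.info("fit: %d events over %d intervals, HR[cd_status]=%.3g",
             fit.n_events, len(data), fit.hazard_ratios["cd_status"][0])
    pd_times = kept["event_time"].dropna().astype(int).tolist()
    cd_times = [tl.first_cd_time for tl in timelines.values()
                if tl.first_cd_time is not None]
    return PipelineResult(
        models=models, selections=selections, timelines=timelines,
        survival_data=data, fit=fit,
        median_time_to_pd=survival.median_time_to(pd_times),
        median_time_to_cd=survival.median_time_to(cd_times),
        n_patients=len(selections), n_events=fit.n_events,
        excluded=tuple(excluded))


def _persist(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    normative.save_models(result.models.values(), out_dir / "normative_models.json")
    sel_rows = [{"patient_id": pid, "rank": r + 1, "test_id": t, "selection_rci": v}
                for pid, s in sorted(result.selections.items())
                for r, (t, v) in enumerate(zip(s.selected, s.selection_rcis))]
    pd.DataFrame(sel_rows).to_csv(out_dir / "selections.csv", index=False)
    tl_rows = [{"patient_id": pid, "timepoint": t, "declined_count":
                tl.declined_counts[t], "cd_flag": bool(f),
                "first_cd_time": tl.first_cd_time}
               for pid, tl in sorted(result.timelines.items())
               for t, f in sorted(tl.flags.items())]
    pd.DataFrame(tl_rows).to_csv(out_dir / "decline_timelines.csv", index=False)
    result.survival_data.to_csv(out_dir / "survival_intervals.csv", index=False)
    cohort_io.write_report(result, out_dir / "report")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline from a config; persists every intermediate.

    Any stage failure aborts with the stage name prepended to the cause.
    """
    for name in ("controls_path", "scores_path", "events_path"):
        p = getattr(config, name)
        if p is None:
            raise ValueError(f"config error: {name} is required")
        if not Path(p).exists():
            raise FileNotFoundError(f"config error: {name} {p!r} does not exist")
    log.info("run: seed=%d config_hash=%s", config.seed, config.digest())

    stage = "read inputs"
    try:
        controls = pd.read_csv(config.controls_path)
        scores = cohort_io.read_scores(config.scores_path)
        events = cohort_io.read_events(config.events_path)
        stage = "analysis"
        result = run_analysis(
            controls, scores, events, criteria=config.criteria, ties=config.ties,
            alpha=config.alpha, normative_covariates=config.normative_covariates)
        stage = "persist results"
        _persist(result, Path(config.out_dir))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return result


def simulate_to_dir(config: PipelineConfig, out_dir) -> PipelineConfig:
    """Generate a synthetic cohort per the config's simulation block and return
    a config pointing at the emitted files."""
    from .synthetic import SimulationParams, simulate_cohort, simulate_controls

    params = SimulationParams(**{"seed": config.seed, **config.simulation})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    controls = simulate_controls(params)
    scores, events, truth = simulate_cohort(params)
    controls.to_csv(out / "controls.csv", index=False)
    cohort_io.write_scores(scores, out / "scores.csv")
    cohort_io.write_events(events, out / "events.csv")
    truth.to_json(out / "truth.json")
    log.info("simulated %d controls, %d patients (mode %s) into %s",
             params.n_controls, params.n_patients, params.mode, out)
    return replace(config, controls_path=str(out / "controls.csv"),
                   scores_path=str(out / "scores.csv"),
                   events_path=str(out / "events.csv"))
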