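"""Tabular I/O, validation, the packaged per-patient study fixture, and cohort summaries.

All longitudinal tables are plain UTF-8 CSV with a header row.  Scores are
oriented so that *higher = better performance* at ingestion; a per-test
orientation flag in the roster flips sign at read time so the reliable-change
sign convention (positive = improvement) is unambiguous downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Roster",
    "DEFAULT_ROSTER",
    "TIMEPOINTS",
    "CENSOR_REASONS",
    "CohortValidationError",
    "read_scores",
    "write_scores",
    "read_events",
    "write_events",
    "load_study_fixture",
    "summarize_cohort",
    "write_report",
]

#: Valid assessment timepoints, months since surgery.  0 is the pre-surgical
#: assessment (administered the day before surgery; the one-day offset is
#: ignored and the month-based labels are used throughout).
TIMEPOINTS: tuple[int, ...] = (0, 3, 6, 9, 12, 15, 18, 21, 24)

CENSOR_REASONS: tuple[str, ...] = ("dropout", "completed_T24", "stable_at_study_end")


class CohortValidationError(ValueError):
    """A table violates the cohort schema (bad timepoint, duplicate row, ...)."""


@dataclass(frozen=True)
class Roster:
    """The battery of test scores the pipeline operates on.

    ``orientation`` maps test codes to -1 for scores where a *larger raw value
    means worse* performance (e.g. completion times); those are negated at read
    time so every stored score is higher-is-better.
    """

    codes: tuple[str, ...]
    orientation: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise CohortValidationError("roster contains duplicate test codes")
        bad = set(self.orientation) - set(self.codes)
        if bad:
            raise CohortValidationError(f"orientation for unknown tests: {sorted(bad)}")
        if any(v not in (-1, 1) for v in self.orientation.values()):
            raise CohortValidationError("orientation flags must be +1 or -1")

    def sign(self, test_id: str) -> int:
        return self.orientation.get(test_id, 1)

    def index(self, test_id: str) -> int:
        return self.codes.index(test_id)


#: The 10-score battery: seven computerized subtests (verbal/visual memory,
#: finger tapping, symbol digit coding, Stroop, shifting attention, continuous
#: performance) plus digit span forward/backward and letter fluency.
DEFAULT_ROSTER = Roster(
    codes=("VEM", "VIM", "FTT", "SDC", "Stroop", "SAT", "CPT", "DSF", "DSB", "LF")
)

SCORE_COLUMNS = ("patient_id", "timepoint", "test_id", "score")
EVENT_COLUMNS = ("patient_id", "age", "event_time", "censor_time", "censor_reason")


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing columns {missing}")


def read_scores(path, roster: Roster = DEFAULT_ROSTER) -> pd.DataFrame:
    """Read and validate a longitudinal score table.

    Returns a DataFrame with columns ``patient_id`` (str), ``timepoint`` (int),
    ``test_id`` (str), ``score`` (float, oriented higher-is-better).  Raises
    :class:`CohortValidationError` naming the offending CSV row (1-based,
    counting the header as row 1) on any invariant violation.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "test_id": str})
    _require_columns(df, SCORE_COLUMNS, path)
    df = df.loc[:, list(SCORE_COLUMNS)].copy()
    return validate_scores(df, roster=roster, source=str(path))


def validate_scores(df: pd.DataFrame, roster: Roster = DEFAULT_ROSTER,
                    source: str = "<frame>") -> pd.DataFrame:
    df = df.copy()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        tp, test = row.timepoint, row.test_id
        if pd.isna(tp) or float(tp) != int(float(tp)) or int(float(tp)) not in TIMEPOINTS:
            raise CohortValidationError(
                f"{source} row {i}: timepoint {tp!r} is not one of {TIMEPOINTS}")
        if test not in roster.codes:
            raise CohortValidationError(f"{source} row {i}: unknown test_id {test!r}")
        if pd.isna(row.score) or not np.isfinite(float(row.score)):
            raise CohortValidationError(f"{source} row {i}: non-finite score {row.score!r}")
    df["timepoint"] = df["timepoint"].astype(int)
    df["score"] = df["score"].astype(float)
    dup = df.duplicated(subset=["patient_id", "timepoint", "test_id"])
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise CohortValidationError(
            f"{source}: duplicate record for ({first.patient_id}, "
            f"{first.timepoint}, {first.test_id})")
    signs = df["test_id"].map(roster.sign).astype(float)
    df["score"] = df["score"] * signs
    return df.reset_index(drop=True)


def write_scores(df: pd.DataFrame, path, roster: Roster = DEFAULT_ROSTER) -> None:
    """Write a validated score table; inverse of :func:`read_scores` (round-trips)."""
    out = df.loc[:, list(SCORE_COLUMNS)].copy()
    signs = out["test_id"].map(roster.sign).astype(float)
    out["score"] = out["score"] * signs  # undo the ingestion orientation flip
    out.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    """Read and validate the per-patient event/censoring table.

    Exactly one of ``event_time``/``censor_time`` must be present per patient;
    times lie on the 3-month assessment grid with a minimum of 3 months.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "censor_reason": str})
    _require_columns(df, ("patient_id", "age"), path)
    for col in ("event_time", "censor_time", "censor_reason"):
        if col not in df.columns:
            df[col] = np.nan
    df = df.loc[:, list(EVENT_COLUMNS)].copy()
    return validate_events(df, source=str(path))


def validate_events(df: pd.DataFrame, source: str = "<frame>") -> pd.DataFrame:
    df = df.copy()
    if df["patient_id"].duplicated().any():
        pid = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise CohortValidationError(f"{source}: patient {pid!r} appears more than once")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        has_event = pd.notna(row.event_time)
        has_censor = pd.notna(row.censor_time)
        if has_event == has_censor:
            raise CohortValidationError(
                f"{source} row {i}: exactly one of event_time/censor_time required")
        t = float(row.event_time if has_event else row.censor_time)
        if t != int(t) or int(t) not in TIMEPOINTS or int(t) < 3:
            raise CohortValidationError(
                f"{source} row {i}: time {t!r} is not a valid timepoint >= 3")
        if has_censor:
            reason = row.censor_reason
            if pd.isna(reason) or reason not in CENSOR_REASONS:
                raise CohortValidationError(
                    f"{source} row {i}: censor_reason {reason!r} not in {CENSOR_REASONS}")
        if pd.isna(row.age) or not np.isfinite(float(row.age)):
            raise CohortValidationError(f"{source} row {i}: invalid age {row.age!r}")
    df["age"] = df["age"].astype(float)
    df["event_time"] = df["event_time"].astype("Int64")
    df["censor_time"] = df["censor_time"].astype("Int64")
    return df.reset_index(drop=True)


def write_events(df: pd.DataFrame, path) -> None:
    df.loc[:, list(EVENT_COLUMNS)].to_csv(path, index=False)


def load_study_fixture() -> pd.DataFrame:
    """Load the packaged 25-patient per-patient study table.

    The fixture transcribes, verbatim, the published per-patient table of
    diagnosis, age band, tumor location/hemisphere, the three personally
    selected tests, the count of selected tests impaired pre-surgery, and
    progression status with end-of-follow-up reason.  Note the printed table
    reuses the superscript letter "a" both on the impairment column header and
    for the "active participation at end of study" end reason; end reasons here
    follow the printed per-row letters (a=active_at_end, b=dropout,
    c=completed_T24_no_PD).
    """
    with resources.files("cogsurv.data").joinpath("study_fixture.csv").open("r") as fh:
        df = pd.read_csv(fh, dtype=str)
    df["impairment_count_t0"] = df["impairment_count_t0"].astype(int)
    df["pd_during_followup"] = df["pd_during_followup"].map(
        {"True": True, "False": False})
    if len(df) != 25:
        raise CohortValidationError("packaged fixture must contain 25 rows")
    if not df["impairment_count_t0"].isin([0, 1, 2, 3]).all():
        raise CohortValidationError("impairment counts must be 0..3")
    return df


_SUMMARY_VARS = ("diagnosis", "hemisphere", "location", "pd_during_followup",
                 "impairment_count_t0", "end_reason")


def summarize_cohort(rows: pd.DataFrame, variables: tuple[str, ...] = _SUMMARY_VARS
                     ) -> pd.DataFrame:
    """Counts and percentages by categorical variable over a per-patient table.

    Percentages are computed on the total row count.  Raises on empty input.
    """
    if len(rows) == 0:
        raise CohortValidationError("cannot summarize an empty cohort")
    n = len(rows)
    parts = []
    for var in variables:
        if var not in rows.columns:
            continue
        counts = rows[var].value_counts(sort=False)
        parts.append(pd.DataFrame({
            "variable": var,
            "level": counts.index.astype(str),
            "count": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / n,
        }))
    out = pd.concat(parts, ignore_index=True)
    assert (out.groupby("variable")["count"].sum() == n).all()
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_payload"):
        return obj.to_payload()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(results, path) -> tuple[Path, Path]:
    """Write a machine-readable JSON report and a human-readable text summary.

    ``results`` is either a mapping or an object exposing ``to_payload()``
    (e.g. a pipeline result bundle).  Output is deterministic for identical
    inputs: keys are sorted and floats are serialized by ``repr``.  Returns the
    (json_path, text_path) pair.  Raises before writing anything if the bundle
    contains no patients.
    """
    payload = results.to_payload() if hasattr(results, "to_payload") else dict(results)
    if not payload.get("n_patients"):
        raise CohortValidationError("refusing to write a report for an empty cohort")
    path = Path(path)
    json_path = path.with_suffix(".json")
    txt_path = path.with_suffix(".txt")
    json_path.parent.mkdir(parents=True, exist_ok=True)
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    lines = [
        "cogsurv analysis report",
        "=======================",
        f"patients analyzed: {payload.get('n_patients')}",
        f"progression events: {payload.get('n_events')}",
        f"median time to progression (months): {payload.get('median_time_to_pd')}",
        f"median time to cognitive decline (months): {payload.get('median_time_to_cd')}",
        "",
    ]
    fit = payload.get("fit") or {}
    for name, hr in (fit.get("hazard_ratios") or {}).items():
        lines.append(
            f"HR[{name}] = {hr['hr']:.3g} (95% CI {hr['lo']:.3g}-{hr['hi']:.3g})")
    if fit:
        lines.append(
            f"LR chi2({fit.get('lr_df')}) = {fit.get('lr_chi2'):.3g}, "
            f"p = {fit.get('p_value'):.3g}, c-index = {fit.get('c_index'):.3g}")
    with open(txt_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return json_path, txt_path
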