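"""Synthetic healthy-control retest data and longitudinal patient cohorts with
known ground truth.

The generator emulates the study design: a 10-score battery administered one
day before surgery (month 0) and every 3 months thereafter up to month 24,
post-surgical recovery concentrated on a tumor-burdened subset of tests,
decline on those tests ahead of progression, discrete 3-month progression
hazards, and dropout/administrative censoring.

Score model (patients).  Scores follow a trait + occasion model: a stable
per-test trait (with a general-ability factor shared across tests), a one-time
practice gain on the first retest, and per-visit occasion noise (with a
session-level factor shared across the battery within a visit).  Controls are
drawn from the matching bivariate retest law, ``retest = intercept +
slope * baseline + noise``, so the normative regressions fitted on simulated
controls are correctly specified for simulated patients.

Two cohort modes:

* mode A (hazard-driven, estimator validation): decline status switches on at
  a random interval; the per-interval progression hazard follows the discrete
  logistic model ``h = expit(logit(h0) + beta_true * cd)`` — the model whose
  odds parameter the exact discrete-ties partial likelihood estimates — and
  scores are made consistent with the decline status on 2 of the 3 burdened
  tests so the pipeline's classifier can reproduce the truth timeline.
* mode B (tumor-driven, end-to-end phenomenology): progression times are drawn
  from the baseline hazard alone and burdened-test scores drop ``delta_dec``
  residual-SE units starting ``lead_intervals`` intervals before progression.

``delta_pre`` and ``delta_dec`` are specified on the RCI scale: the expected
selection RCI on a burdened test is ``delta_pre`` (the raw-score suppression at
month 0 is ``delta_pre * SEE / slope``) and the expected follow-up RCI on a
declined test is ``-delta_dec``.

Reproducibility: one global seed, split into independent per-subject streams
via ``numpy`` ``SeedSequence`` spawn keys, so adding patients or controls never
perturbs earlier subjects' draws.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_io import DEFAULT_ROSTER

__all__ = ["SimulationParams", "SimulationTruth", "simulate_controls",
           "simulate_cohort"]

_VISITS = np.arange(0, 27, 3)  # months 0..24
_FOLLOWUPS = np.arange(6, 27, 3)  # intervals on which events can occur
_TAG_CONTROL, _TAG_PATIENT = 0, 1


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults are the emulated study conditions."""

    seed: int = 0
    n_controls: int = 300
    n_patients: int = 25
    n_tests: int = 10
    test_mean: float = 50.0
    test_sd: float = 10.0
    reliability: float = 0.8          # test-retest correlation; retest slope
    practice_gain_sd: float = 0.1     # first-retest gain, in test-SD units
    retest_residual_sd: float | None = None  # SEE; default sd*sqrt(1-r^2)
    trait_g_share: float = 0.5        # general-factor share of trait variance
    session_share: float = 0.5        # session share of occasion variance
    age_coef: float = -0.15           # score points per year of age
    sex_coef: float = 1.0
    education_coef: float = 2.0
    burdened_set_size: int = 3
    delta_pre: float = 1.5            # pre-surgical suppression, RCI units
    recovery_fraction: float = 1.0
    delta_dec: float = 1.5            # pre-progression decline, RCI units
    lead_intervals: int = 1
    mode: str = "A"
    h0: float = 0.05                  # baseline discrete hazard per interval
    beta_true: float = float(np.log(5.0))
    cd_onset_prob: float = 0.15       # mode A, per interval
    dropout_prob: float = 0.03        # per interval
    admin_censor_frac: float = 0.15   # fraction enrolled late (study-end censor)
    max_month: int = 24
    age_mean: float = 53.0
    age_sd: float = 14.0

    def __post_init__(self) -> None:
        if self.mode not in ("A", "B"):
            raise ValueError(f"mode must be 'A' or 'B', got {self.mode!r}")
        if self.test_sd <= 0:
            raise ValueError("test_sd must be positive")
        if self.retest_residual_sd is not None and self.retest_residual_sd < 0:
            raise ValueError("retest_residual_sd must be >= 0")
        for name in ("h0", "cd_onset_prob", "dropout_prob", "admin_censor_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.h0 >= 1.0:
            raise ValueError("h0 must be < 1")
        if self.delta_pre < 0 or self.delta_dec < 0:
            raise ValueError("effect sizes must be >= 0")
        if not 0 < self.reliability < 1:
            raise ValueError("reliability must lie in (0, 1)")

    # derived per-test quantities -------------------------------------------
    @property
    def slope(self) -> float:
        return self.reliability

    @property
    def residual_sd(self) -> float:
        if self.retest_residual_sd is not None:
            return self.retest_residual_sd
        return self.test_sd * float(np.sqrt(1.0 - self.reliability ** 2))

    @property
    def intercept(self) -> float:
        return ((1.0 - self.slope) * self.test_mean
                + self.practice_gain_sd * self.test_sd)

    @property
    def test_ids(self) -> tuple[str, ...]:
        if self.n_tests <= len(DEFAULT_ROSTER.codes):
            return DEFAULT_ROSTER.codes[: self.n_tests]
        return tuple(f"T{k:02d}" for k in range(1, self.n_tests + 1))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth emitted alongside a simulated cohort."""

    seed: int
    beta_true: float
    params: SimulationParams
    burdened: Mapping[str, tuple[str, ...]]
    declined_tests: Mapping[str, tuple[str, ...]]
    event_time: Mapping[str, int | None]
    censor_time: Mapping[str, int | None]
    censor_reason: Mapping[str, str | None]
    first_cd_time: Mapping[str, int | None]

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed, "beta_true": self.beta_true,
            "params": self.params.to_dict(),
            "burdened": {k: list(v) for k, v in self.burdened.items()},
            "declined_tests": {k: list(v) for k, v in self.declined_tests.items()},
            "event_time": dict(self.event_time),
            "censor_time": dict(self.censor_time),
            "censor_reason": dict(self.censor_reason),
            "first_cd_time": dict(self.first_cd_time),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _stream(seed: int, tag: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(tag, index)))


def _demographics(rng: np.random.Generator, p: SimulationParams):
    age = float(np.clip(rng.normal(p.age_mean, p.age_sd), 19.0, 80.0))
    sex = int(rng.random() < 0.5)
    education = int(rng.choice([1, 2, 3], p=[0.12, 0.48, 0.40]))
    return age, sex, education


def _demo_shift(p: SimulationParams, age: float, sex: int, education: int) -> float:
    return (p.age_coef * (age - p.age_mean) + p.sex_coef * (sex - 0.5)
            + p.education_coef * (education - 2))


def simulate_controls(params: SimulationParams) -> pd.DataFrame:
    """Healthy-control test-retest table for normative fitting.

    Per subject and test: ``baseline ~ N(mean + demographic shift, SD)`` (with
    a general-ability factor shared across tests) and ``retest = intercept +
    slope * baseline + N(0, SEE)``, so the baseline-only retest regression is
    exactly specified.
    """
    p = params
    rows = []
    for j in range(p.n_controls):
        rng = _stream(p.seed, _TAG_CONTROL, j)
        age, sex, edu = _demographics(rng, p)
        shift = _demo_shift(p, age, sex, edu)
        g = rng.normal()
        z = (np.sqrt(p.trait_g_share) * g
             + np.sqrt(1.0 - p.trait_g_share) * rng.normal(size=p.n_tests))
        baseline = p.test_mean + shift + p.test_sd * z
        retest = (p.intercept + p.slope * baseline
                  + p.residual_sd * rng.normal(size=p.n_tests))
        for k, test in enumerate(p.test_ids):
            rows.append({
                "subject_id": f"C{j + 1:04d}", "test_id": test,
                "baseline_score": baseline[k], "retest_score": retest[k],
                "retest_interval": 3, "age": age, "sex": sex, "education": edu,
            })
    return pd.DataFrame(rows)


def _patient_scores(rng, p: SimulationParams, visits: np.ndarray,
                    burdened_idx: np.ndarray, declined_idx: np.ndarray,
                    t_dec: int | None, shift: float) -> np.ndarray:
    """(n_visits, n_tests) emitted scores for one patient."""
    n_t, n_v = p.n_tests, len(visits)
    s_trait = p.test_sd * np.sqrt(p.reliability)
    s_occ = p.test_sd * np.sqrt(1.0 - p.reliability)
    g = rng.normal()
    trait = (p.test_mean + shift + s_trait * (
        np.sqrt(p.trait_g_share) * g
        + np.sqrt(1.0 - p.trait_g_share) * rng.normal(size=n_t)))
    session = rng.normal(size=len(_VISITS))[:n_v]
    eps = rng.normal(size=(len(_VISITS), n_t))[:n_v]
    occ = s_occ * (np.sqrt(p.session_share) * session[:, None]
                   + np.sqrt(1.0 - p.session_share) * eps)
    scores = trait[None, :] + occ
    practice = p.practice_gain_sd * p.test_sd
    scores[visits >= 3] += practice
    # pre-surgical suppression of the burdened tests, (partially) recovered at T3
    if p.slope > 0 and len(burdened_idx):
        suppression = p.delta_pre * p.residual_sd / p.slope
        scores[np.ix_(visits == 0, burdened_idx)] -= suppression
        residual = (1.0 - p.recovery_fraction) * suppression
        if residual:
            scores[np.ix_(visits >= 3, burdened_idx)] -= residual
    if t_dec is not None and len(declined_idx):
        drop = p.delta_dec * p.residual_sd
        scores[np.ix_(visits >= t_dec, declined_idx)] -= drop
    return scores


def _expit(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(params: SimulationParams
                    ) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate (score table, event table, ground truth) for one cohort."""
    p = params
    logit_h0 = np.log(p.h0 / (1.0 - p.h0)) if p.h0 > 0 else -np.inf
    score_rows, event_rows = [], []
    burdened_m, declined_m, ev_m, cens_m, reason_m, cd_m = {}, {}, {}, {}, {}, {}
    followups = _FOLLOWUPS[_FOLLOWUPS <= p.max_month]
    for i in range(p.n_patients):
        rng = _stream(p.seed, _TAG_PATIENT, i)
        pid = f"P{i + 1:04d}"
        age, sex, edu = _demographics(rng, p)
        shift = _demo_shift(p, age, sex, edu)
        burdened_idx = np.sort(rng.choice(p.n_tests, size=p.burdened_set_size,
                                          replace=False))
        # draw the full event-process uniforms up front so realized follow-up
        # length never changes the stream layout
        u_onset = rng.random(size=len(followups))
        u_event = rng.random(size=len(followups))
        u_drop = rng.random(size=len(followups))
        late_enrol = rng.random() < p.admin_censor_frac
        horizon = int(rng.choice(followups[:-1])) if late_enrol and len(followups) > 1 \
            else int(followups[-1])

        # decline onset (mode A: random switch; mode B: tied to the event)
        onset = None
        if p.mode == "A":
            hits = np.nonzero(u_onset < p.cd_onset_prob)[0]
            if len(hits):
                onset = int(followups[hits[0]])

        event_time = None
        censor_time = None
        reason = None
        for j, t in enumerate(followups):
            cd = int(p.mode == "A" and onset is not None and onset <= t)
            h = _expit(logit_h0 + p.beta_true * cd) if p.h0 > 0 else 0.0
            if u_event[j] < h:
                event_time = int(t)
                break
            if t >= horizon:
                censor_time = int(t)
                reason = ("completed_T24" if censor_time >= p.max_month
                          else "stable_at_study_end")
                break
            if u_drop[j] < p.dropout_prob:
                censor_time = int(t)
                reason = "dropout"
                break
        if event_time is None and censor_time is None:
            censor_time = int(followups[-1])
            reason = "completed_T24" if censor_time >= p.max_month else "stable_at_study_end"

        end = event_time if event_time is not None else censor_time
        if p.mode == "A":
            t_dec = onset if (onset is not None and onset <= end) else None
            declined_idx = burdened_idx[:2]  # decline expressed on 2 of the 3
        else:
            t_dec = (max(6, event_time - 3 * p.lead_intervals)
                     if event_time is not None else None)
            declined_idx = burdened_idx
        visits = _VISITS[_VISITS <= end]
        scores = _patient_scores(rng, p, visits, burdened_idx,
                                 declined_idx if t_dec is not None else np.array([], int),
                                 t_dec, shift)
        for vi, t in enumerate(visits):
            for k, test in enumerate(p.test_ids):
                score_rows.append({"patient_id": pid, "timepoint": int(t),
                                   "test_id": test, "score": scores[vi, k]})
        event_rows.append({"patient_id": pid, "age": age,
                           "event_time": event_time, "censor_time": censor_time,
                           "censor_reason": reason})
        tests = p.test_ids
        burdened_m[pid] = tuple(tests[k] for k in burdened_idx)
        declined_m[pid] = tuple(tests[k] for k in declined_idx) if t_dec is not None else ()
        ev_m[pid] = event_time
        cens_m[pid] = censor_time
        reason_m[pid] = reason
        cd_m[pid] = t_dec
    scores_df = pd.DataFrame(score_rows)
    events_df = pd.DataFrame(event_rows)
    events_df["event_time"] = events_df["event_time"].astype("Int64")
    events_df["censor_time"] = events_df["censor_time"].astype("Int64")
    truth = SimulationTruth(seed=p.seed, beta_true=p.beta_true, params=p,
                            burdened=burdened_m, declined_tests=declined_m,
                            event_time=ev_m, censor_time=cens_m,
                            censor_reason=reason_m, first_cd_time=cd_m)
    return scores_df, events_df, truth
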