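"""Normative test-retest regressions, regression-based Reliable Change Indices,
and demographically corrected impairment z-scores.

The reliable-change construction is the regression-based one: on healthy-control
test-retest data, ordinary least squares regresses the retest score on the
baseline score (optionally plus demographic covariates); a patient's change is
standardized by the standard error of estimate (SEE) of that regression,

    RCI = (observed retest - predicted retest) / SEE .

Practice effects and regression to the mean are absorbed by the control
regression's intercept and slope, so RCI ~ N(0, 1) (approximately) for a stable
patient drawn from the control population.  Positive RCI = improvement,
negative = decline.  The same per-test model is applied to every follow-up
contrast regardless of interval length; the retest interval may optionally
enter as a covariate but does not by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DegenerateDesignError",
    "PerfectFitError",
    "NormativeModel",
    "DemographicNorm",
    "RCIVector",
    "fit_normative_model",
    "fit_demographic_norm",
    "compute_rci",
    "compute_rci_vector",
    "compute_zscore",
    "save_models",
    "load_models",
]

IMPAIRMENT_Z_THRESHOLD = -1.5


class DegenerateDesignError(ValueError):
    """The control design matrix carries no information (e.g. constant baseline)."""


class PerfectFitError(ValueError):
    """The control regression has zero residual scale; the RCI is undefined."""


@dataclass(frozen=True)
class NormativeModel:
    """A fitted per-test control retest regression.

    ``residual_se`` is the standard error of estimate on ``n - p - 2`` degrees
    of freedom (intercept + slope + p demographic covariates).
    """

    test_id: str
    intercept: float
    baseline_coefficient: float
    residual_se: float
    n_controls: int
    demographic_coefficients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residual_se > 0:
            raise PerfectFitError(f"{self.test_id}: residual_se must be > 0")
        if self.n_controls < len(self.demographic_coefficients) + 2:
            raise DegenerateDesignError(f"{self.test_id}: too few controls")

    def predict(self, baseline: float, demographics: Mapping[str, float] | None = None
                ) -> float:
        pred = self.intercept + self.baseline_coefficient * baseline
        if self.demographic_coefficients:
            if demographics is None:
                raise ValueError(f"{self.test_id}: model requires demographics "
                                 f"{sorted(self.demographic_coefficients)}")
            for name, coef in self.demographic_coefficients.items():
                if name not in demographics:
                    raise ValueError(f"{self.test_id}: missing demographic {name!r}")
                pred += coef * demographics[name]
        return pred

    def to_dict(self) -> dict:
        return {
            "test_id": self.test_id,
            "intercept": self.intercept,
            "baseline_coefficient": self.baseline_coefficient,
            "demographic_coefficients": dict(self.demographic_coefficients),
            "residual_se": self.residual_se,
            "n_controls": self.n_controls,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormativeModel":
        return cls(test_id=d["test_id"], intercept=d["intercept"],
                   baseline_coefficient=d["baseline_coefficient"],
                   residual_se=d["residual_se"], n_controls=d["n_controls"],
                   demographic_coefficients=dict(d.get("demographic_coefficients", {})))


@dataclass(frozen=True)
class DemographicNorm:
    """A single-occasion normative regression of a score on age/sex/education."""

    test_id: str
    intercept: float
    coefficients: Mapping[str, float]
    residual_sd: float

    def __post_init__(self) -> None:
        if not self.residual_sd > 0:
            raise PerfectFitError(f"{self.test_id}: residual_sd must be > 0")

    def predict(self, demographics: Mapping[str, float]) -> float:
        pred = self.intercept
        for name, coef in self.coefficients.items():
            if name not in demographics:
                raise ValueError(f"{self.test_id}: missing demographic {name!r}")
            pred += coef * demographics[name]
        return pred


@dataclass(frozen=True)
class RCIVector:
    """Per-test standardized change scores for one patient and one contrast."""

    patient_id: str
    baseline_timepoint: int
    followup_timepoint: int
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.followup_timepoint > self.baseline_timepoint:
            raise ValueError("followup_timepoint must exceed baseline_timepoint")
        if any(not np.isfinite(v) for v in self.values.values()):
            raise ValueError("RCI values must be finite")


def fit_normative_model(controls: pd.DataFrame, test_id: str | None = None,
                        covariates: Sequence[str] = ()) -> NormativeModel:
    """OLS fit of retest on baseline (+ covariates) for one test's control data.

    ``controls`` needs columns ``baseline_score``, ``retest_score`` and any
    requested covariate columns; ``test_id`` defaults to the frame's single
    ``test_id`` value.  Requires at least ``p + 3`` records so the residual
    degrees of freedom ``n - p - 2`` are positive.
    """
    if test_id is None:
        ids = controls["test_id"].unique()
        if len(ids) != 1:
            raise ValueError("controls must contain exactly one test_id")
        test_id = str(ids[0])
    p = len(covariates)
    n = len(controls)
    if n < p + 3:
        raise DegenerateDesignError(f"{test_id}: need >= {p + 3} controls, got {n}")
    y = controls["retest_score"].to_numpy(dtype=float)
    cols = ["baseline_score", *covariates]
    X = controls.loc[:, cols].to_numpy(dtype=float)
    if np.ptp(X[:, 0]) == 0:
        raise DegenerateDesignError(f"{test_id}: baseline scores have zero variance")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < p + 2:
        raise DegenerateDesignError(f"{test_id}: rank-deficient control design")
    fit = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    # statsmodels df_resid = n - (p + 2): exactly the n - p - 2 convention.
    see = float(np.sqrt(fit.scale))
    if not np.isfinite(see) or see <= np.sqrt(np.finfo(float).eps) * max(1.0, y.std()):
        raise PerfectFitError(f"{test_id}: retest is an exact function of the "
                              "predictors; RCI undefined")
    params = np.asarray(fit.params, dtype=float)
    return NormativeModel(
        test_id=test_id,
        intercept=float(params[0]),
        baseline_coefficient=float(params[1]),
        demographic_coefficients={c: float(b) for c, b in zip(covariates, params[2:])},
        residual_se=see,
        n_controls=n,
    )


def fit_demographic_norm(controls: pd.DataFrame, test_id: str | None = None,
                         covariates: Sequence[str] = ("age", "sex", "education"),
                         score_column: str = "baseline_score") -> DemographicNorm:
    """Fit a single-occasion demographic norm (for impairment z-scores)."""
    if test_id is None:
        ids = controls["test_id"].unique()
        if len(ids) != 1:
            raise ValueError("controls must contain exactly one test_id")
        test_id = str(ids[0])
    y = controls[score_column].to_numpy(dtype=float)
    X = controls.loc[:, list(covariates)].to_numpy(dtype=float)
    fit = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    sd = float(np.sqrt(fit.scale))
    if not sd > 0:
        raise PerfectFitError(f"{test_id}: zero residual SD in demographic norm")
    params = np.asarray(fit.params, dtype=float)
    return DemographicNorm(
        test_id=test_id, intercept=float(params[0]),
        coefficients={c: float(b) for c, b in zip(covariates, params[1:])},
        residual_sd=sd)


def compute_rci(baseline: float, retest: float, model: NormativeModel,
                demographics: Mapping[str, float] | None = None) -> float:
    """Standardized change of one observed retest against the normative model."""
    return (retest - model.predict(baseline, demographics)) / model.residual_se


def compute_rci_vector(scores: pd.DataFrame, baseline_timepoint: int,
                       followup_timepoint: int,
                       models: Mapping[str, NormativeModel],
                       demographics: Mapping[str, float] | None = None) -> RCIVector:
    """All per-test RCIs for one patient between two timepoints.

    Tests missing at either timepoint (or without a model) are absent from the
    result — never imputed.  Raises if no test overlaps.
    """
    pids = scores["patient_id"].unique()
    if len(pids) != 1:
        raise ValueError("scores must contain exactly one patient")
    base = scores[scores["timepoint"] == baseline_timepoint].set_index("test_id")["score"]
    follow = scores[scores["timepoint"] == followup_timepoint].set_index("test_id")["score"]
    values: dict[str, float] = {}
    for test in base.index.intersection(follow.index):
        if test in models:
            values[test] = compute_rci(float(base[test]), float(follow[test]),
                                       models[test], demographics)
    if not values:
        raise ValueError(
            f"patient {pids[0]}: no test observed at both months "
            f"{baseline_timepoint} and {followup_timepoint} with a normative model")
    return RCIVector(patient_id=str(pids[0]), baseline_timepoint=baseline_timepoint,
                     followup_timepoint=followup_timepoint, values=values)


def compute_zscore(score: float, demographics: Mapping[str, float],
                   norm: DemographicNorm,
                   threshold: float = IMPAIRMENT_Z_THRESHOLD) -> tuple[float, bool]:
    """Demographically corrected z-score and impairment flag (z <= -1.5, inclusive)."""
    z = (score - norm.predict(demographics)) / norm.residual_sd
    return z, bool(z <= threshold)


def save_models(models: Iterable[NormativeModel], path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in models], fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_models(path) -> dict[str, NormativeModel]:
    with open(path) as fh:
        raw = json.load(fh)
    models = [NormativeModel.from_dict(d) for d in raw]
    return {m.test_id: m for m in models}
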