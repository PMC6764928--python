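"""Discrete-time proportional-hazards modelling of progression with a
time-dependent cognitive-decline covariate.

Assessments sit on a 3-month grid, so event times are heavily tied.  The model
is fit by maximizing the *exact discrete-ties* partial likelihood (Cox's
conditional-logistic form): at an event time with risk set R and d tied
failures F,

    L_t(beta) = prod_{i in F} w_i / e_d({w_j : j in R}),    w_j = exp(x_j' beta),

where e_d is the elementary symmetric polynomial of degree d.  This is the
canonical likelihood for grouped (discrete) survival data; with singleton event
times it coincides exactly with the Breslow and Efron likelihoods, both of
which are available as labelled alternatives for sensitivity analysis.

Risk intervals run from month 3 (the re-baselining visit) in 3-month steps;
the first interval on which progression can occur is (3, 6].  Decline status is
absorbing and applies to the interval ending at the visit where it is observed,
so same-visit decline counts as exposed for a same-visit progression event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .personalization import DeclineTimeline

__all__ = [
    "SurvivalDataError",
    "NoEventsError",
    "CoxFit",
    "build_survival_dataset",
    "fit_discrete_cox",
    "concordance_index",
    "median_time_to",
]

INTERVAL_MONTHS = 3
RISK_START = 3
#: Divergence guard: |beta| beyond this on the unit-SD scale flags separation.
_BETA_CAP_SD = 15.0


class SurvivalDataError(ValueError):
    """Counting-process data violate the interval conventions."""


class NoEventsError(SurvivalDataError):
    """The model cannot be fit because no progression events are present."""


@dataclass(frozen=True)
class CoxFit:
    """A fitted discrete proportional-hazards model."""

    coefficients: Mapping[str, tuple[float, float]]  # name -> (beta, se)
    hazard_ratios: Mapping[str, tuple[float, float, float]]  # name -> (hr, lo, hi)
    lr_chi2: float
    lr_df: int
    p_value: float
    c_index: float
    log_likelihood: float
    log_likelihood_null: float
    converged: bool
    ties_method: str
    n_events: int
    n_subjects: int
    alpha: float = field(default=0.05)

    def to_payload(self) -> dict:
        return {
            "coefficients": {k: {"beta": b, "se": s}
                             for k, (b, s) in self.coefficients.items()},
            "hazard_ratios": {k: {"hr": h, "lo": lo, "hi": hi}
                              for k, (h, lo, hi) in self.hazard_ratios.items()},
            "lr_chi2": self.lr_chi2, "lr_df": self.lr_df, "p_value": self.p_value,
            "c_index": self.c_index, "log_likelihood": self.log_likelihood,
            "log_likelihood_null": self.log_likelihood_null,
            "converged": self.converged, "ties_method": self.ties_method,
            "n_events": self.n_events, "n_subjects": self.n_subjects,
            "alpha": self.alpha,
        }


def build_survival_dataset(events: pd.DataFrame,
                           timelines: Mapping[str, DeclineTimeline] | Sequence[DeclineTimeline],
                           ) -> pd.DataFrame:
    """Expand event records + decline timelines into counting-process rows.

    One row per patient per 3-month risk interval (start, stop], from month 3
    to the event/censoring time.  ``cd_status`` for the interval ending at
    month t is 1 iff the first decline time is <= t (absorbing); the event flag
    is set only on a progressing patient's final interval.
    """
    if not isinstance(timelines, Mapping):
        timelines = {tl.patient_id: tl for tl in timelines}
    rows = []
    for rec in events.itertuples(index=False):
        pid = str(rec.patient_id)
        if pid not in timelines:
            raise SurvivalDataError(f"no decline timeline for patient {pid}")
        tl = timelines[pid]
        has_event = pd.notna(rec.event_time)
        end = int(rec.event_time if has_event else rec.censor_time)
        if end < RISK_START + INTERVAL_MONTHS:
            raise SurvivalDataError(
                f"patient {pid}: end time {end} precedes the first risk "
                f"interval ({RISK_START}, {RISK_START + INTERVAL_MONTHS}]")
        for start in range(RISK_START, end, INTERVAL_MONTHS):
            stop = start + INTERVAL_MONTHS
            rows.append({
                "patient_id": pid, "start": start, "stop": stop,
                "event": int(has_event and stop == end),
                "cd_status": tl.status_at(stop),
                "age": float(rec.age),
            })
    extra = set(timelines) - {str(p) for p in events["patient_id"]}
    if extra:
        raise SurvivalDataError(f"timelines without event records: {sorted(extra)}")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# partial likelihoods

def _risk_groups(data: pd.DataFrame, covariates: Sequence[str]):
    """Per event time: (X_risk, event_row_mask) with covariates centered."""
    X = data.loc[:, list(covariates)].to_numpy(dtype=float)
    center = X.mean(axis=0) if len(X) else np.zeros(len(covariates))
    Xc = X - center
    stops = data["stop"].to_numpy()
    ev = data["event"].to_numpy(dtype=bool)
    groups = []
    for t in np.unique(stops[ev]):
        at_risk = stops == t
        groups.append((Xc[at_risk], ev[at_risk]))
    return groups, center


def _log_esp(logw: np.ndarray, d: int) -> float:
    """log of the elementary symmetric polynomial e_d(exp(logw)), stably."""
    if d == 0:
        return 0.0
    m = float(logw.max())
    w = np.exp(logw - m)
    # coefficients of prod_i (1 + w_i z), truncated at degree d; the recurrence
    # is linear so uniform rescaling (tracked in logscale) dodges overflow
    coef = np.zeros(d + 1)
    coef[0] = 1.0
    logscale = 0.0
    for wi in w:
        coef[1:] += wi * coef[:-1]
        mx = coef.max()
        if mx > 1e250:
            coef /= mx
            logscale += np.log(mx)
    return float(np.log(coef[d]) + logscale + d * m)


def _neg_loglik(beta: np.ndarray, groups, ties: str) -> float:
    ll = 0.0
    for Xr, ev in groups:
        eta = Xr @ beta
        d = int(ev.sum())
        s_event = float(eta[ev].sum())
        if ties == "discrete":
            ll += s_event - _log_esp(eta, d)
        elif ties == "breslow":
            m = eta.max()
            ll += s_event - d * (m + np.log(np.exp(eta - m).sum()))
        elif ties == "efron":
            m = eta.max()
            w = np.exp(eta - m)
            tot = w.sum()
            tied = w[ev].sum()
            for r in range(d):
                ll += -np.log(tot - (r / d) * tied) - m
            ll += s_event
        else:
            raise ValueError(f"unknown ties method {ties!r}")
    return -ll


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    p = len(x)
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h
            ej = np.zeros(p); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def fit_discrete_cox(data: pd.DataFrame,
                     covariates: Sequence[str] = ("cd_status", "age"),
                     ties: str = "discrete",
                     alpha: float = 0.05) -> CoxFit:
    """Maximize the partial likelihood and report HRs, Wald CIs, LR test, c-index.

    ``ties`` is one of ``discrete`` (exact conditional-logistic, the default),
    ``efron`` or ``breslow``.  Raises :class:`NoEventsError` without events and
    :class:`SurvivalDataError` when a covariate is constant within every risk
    set (no information).  Monotone likelihoods (perfect separation) yield a
    capped coefficient, ``converged=False`` and a warning rather than silent
    output.
    """
    if data["event"].sum() == 0:
        raise NoEventsError("no progression events in the survival dataset")
    groups, _ = _risk_groups(data, covariates)
    sds = []
    for j, name in enumerate(covariates):
        if not any(np.ptp(Xr[:, j]) > 0 for Xr, _ in groups):
            raise SurvivalDataError(
                f"covariate {name!r} is constant within every risk set")
        sds.append(max(np.std(data[name].to_numpy(dtype=float)), 1e-12))
    sds = np.asarray(sds)

    nll = lambda b: _neg_loglik(b, groups, ties)
    res = optimize.minimize(nll, np.zeros(len(covariates)), method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
    beta = res.x.copy()
    converged = bool(res.success or np.linalg.norm(res.jac) < 1e-5)
    # monotone-likelihood probe: if pushing a large coefficient further out
    # does not worsen the fit, the MLE sits at infinity (perfect separation)
    diverging = np.zeros(len(beta), dtype=bool)
    for j in range(len(beta)):
        if abs(beta[j]) * sds[j] > 3.0:
            probe = beta.copy()
            probe[j] += np.sign(beta[j]) * 5.0 / sds[j]
            if nll(probe) <= nll(beta) + 1e-8:
                diverging[j] = True
    if diverging.any():
        warnings.warn("diverging coefficient estimate (possible perfect "
                      "separation); beta capped", RuntimeWarning, stacklevel=2)
        cap = _BETA_CAP_SD / sds[diverging]
        beta[diverging] = np.sign(beta[diverging]) * np.minimum(
            np.abs(beta[diverging]), cap)
        converged = False

    H = _numeric_hessian(nll, beta)
    try:
        cov = np.linalg.inv(H)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(len(beta), np.nan)
        converged = False

    ll_fit = -nll(beta)
    ll_null = -_neg_loglik(np.zeros(len(covariates)), groups, ties)
    lr = max(0.0, 2.0 * (ll_fit - ll_null))
    df = len(covariates)
    pval = float(stats.chi2.sf(lr, df))

    z = stats.norm.ppf(1 - alpha / 2)
    coeffs = {name: (float(b), float(s)) for name, b, s in zip(covariates, beta, ses)}
    with np.errstate(over="ignore"):  # capped fits can push CI limits to inf
        hrs = {name: (float(np.exp(b)), float(np.exp(b - z * s)),
                      float(np.exp(b + z * s)))
               for name, (b, s) in coeffs.items()}
    cidx = concordance_index(data, beta, covariates=covariates)
    return CoxFit(coefficients=coeffs, hazard_ratios=hrs, lr_chi2=float(lr),
                  lr_df=df, p_value=pval, c_index=cidx,
                  log_likelihood=float(ll_fit), log_likelihood_null=float(ll_null),
                  converged=converged, ties_method=ties, n_events=int(data["event"].sum()),
                  n_subjects=int(data["patient_id"].nunique()), alpha=alpha)


def concordance_index(data: pd.DataFrame, fit_or_beta,
                      covariates: Sequence[str] = ("cd_status", "age")) -> float:
    """Harrell-type concordance generalized to time-dependent covariates.

    At each event time, the failing subject is compared with every risk-set
    member not failing at that time, using linear predictors evaluated at the
    covariate values current in that interval; c = (concordant + 0.5 ties) /
    comparable.  Returns NaN (with a warning) when no pair is comparable.
    """
    if isinstance(fit_or_beta, CoxFit):
        beta = np.array([fit_or_beta.coefficients[c][0] for c in covariates])
    else:
        beta = np.asarray(fit_or_beta, dtype=float)
    groups, _ = _risk_groups(data, covariates)
    conc = ties = total = 0.0
    for Xr, ev in groups:
        eta = Xr @ beta
        eta_ev, eta_other = eta[ev], eta[~ev]
        for e in eta_ev:
            conc += float((e > eta_other + 1e-12).sum())
            ties += float((np.abs(e - eta_other) <= 1e-12).sum())
            total += len(eta_other)
    if total == 0:
        warnings.warn("concordance undefined: no comparable pairs",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float((conc + 0.5 * ties) / total)


def median_time_to(times: Sequence[int]) -> int | None:
    """Median event time over patients experiencing the event.

    With an even count, the *lower* of the two central order statistics is
    returned so the median always lands on a real assessment timepoint.
    Returns None (undefined) when nobody experiences the event.
    """
    ts = sorted(int(t) for t in times if t is not None and not pd.isna(t))
    if not ts:
        return None
    return ts[(len(ts) - 1) // 2]
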