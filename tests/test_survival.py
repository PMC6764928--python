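import itertools

import numpy as np
import pandas as pd
import pytest

from cogsurv.personalization import DeclineTimeline
from cogsurv.survival import (NoEventsError, SurvivalDataError,
                              build_survival_dataset, concordance_index,
                              fit_discrete_cox, median_time_to)
from conftest import make_interval_rows, random_toy_dataset


def brute_force_discrete_loglik(data, beta):
    """Independent discrete-ties partial log-likelihood by subset enumeration."""
    ll = 0.0
    for t in sorted(data.loc[data["event"] == 1, "stop"].unique()):
        risk = data[data["stop"] == t]
        x = risk["cd_status"].to_numpy(dtype=float)
        ev = risk["event"].to_numpy(dtype=bool)
        d = int(ev.sum())
        num = float(np.exp(beta * x[ev].sum()))
        den = sum(float(np.exp(beta * sum(x[list(c)])))
                  for c in itertools.combinations(range(len(x)), d))
        ll += np.log(num / den)
    return ll


def grid_argmax(data, lo=-10, hi=10, n=4001, refine=3):
    grid = np.linspace(lo, hi, n)
    for _ in range(refine):
        lls = [brute_force_discrete_loglik(data, b) for b in grid]
        best = grid[int(np.argmax(lls))]
        width = grid[1] - grid[0]
        grid = np.linspace(best - width, best + width, 401)
    return best


def timeline(pid, first_cd, horizon=24):
    flags = {t: bool(first_cd is not None and t >= first_cd)
             for t in range(6, horizon + 1, 3)}
    first = min((t for t, f in flags.items() if f), default=None)
    return DeclineTimeline(pid, flags, {t: 0 for t in flags}, first)


class TestBuildDataset:
    def events(self, rows):
        df = pd.DataFrame(rows, columns=["patient_id", "age", "event_time",
                                         "censor_time", "censor_reason"])
        return df

    def test_decline_before_event(self):
        ev = self.events([("p", 60.0, 9, None, None)])
        data = build_survival_dataset(ev, [timeline("p", 6)])
        assert data[["start", "stop", "event", "cd_status"]].values.tolist() == \
            [[3, 6, 0, 1], [6, 9, 1, 1]]

    def test_censored_without_decline(self):
        ev = self.events([("p", 60.0, None, 12, "dropout")])
        data = build_survival_dataset(ev, [timeline("p", None)])
        assert len(data) == 3
        assert data["event"].sum() == 0 and data["cd_status"].sum() == 0

    def test_same_visit_decline_counts_as_exposed(self):
        ev = self.events([("p", 60.0, 6, None, None)])
        data = build_survival_dataset(ev, [timeline("p", 6)])
        assert len(data) == 1
        assert data.loc[0, ["start", "stop", "event", "cd_status", "age"]] \
            .tolist() == [3, 6, 1, 1, 60.0]

    def test_end_before_first_interval_rejected(self):
        ev = self.events([("p", 60.0, None, 3, "dropout")])
        with pytest.raises(SurvivalDataError, match="precedes the first risk"):
            build_survival_dataset(ev, [timeline("p", None)])

    def test_patient_mismatch_rejected(self):
        ev = self.events([("p", 60.0, 9, None, None)])
        with pytest.raises(SurvivalDataError, match="no decline timeline"):
            build_survival_dataset(ev, [timeline("q", None)])


class TestDiscreteCox:
    def test_worked_example_closed_form(self, interval_rows):
        # two singleton event times over risk sets {A,B,C,D} then {B,C,D};
        # the score equation u/(u+1) + u/(u+2) = 1 gives u^2 = 2
        data = interval_rows([("A", 1, 6, True), ("B", 0, 9, False),
                              ("C", 0, 9, True), ("D", 1, 9, False)])
        fit = fit_discrete_cox(data, covariates=("cd_status",))
        assert fit.coefficients["cd_status"][0] == pytest.approx(
            np.log(np.sqrt(2)), abs=1e-6)
        assert fit.hazard_ratios["cd_status"][0] == pytest.approx(np.sqrt(2),
                                                                  abs=1e-5)

    def test_matches_brute_force_grid_on_random_toys(self, rng):
        for _ in range(8):
            data = random_toy_dataset(rng)
            fit = fit_discrete_cox(data, covariates=("cd_status",))
            if not fit.converged:  # separation: the MLE is at infinity
                continue
            beta = fit.coefficients["cd_status"][0]
            assert abs(beta - grid_argmax(data)) < 1e-4

    def test_likelihood_ratio_nonnegative(self, rng):
        for _ in range(5):
            data = random_toy_dataset(rng)
            fit = fit_discrete_cox(data, covariates=("cd_status",))
            assert fit.lr_chi2 >= 0.0
            assert fit.log_likelihood >= fit.log_likelihood_null - 1e-12

    def test_constant_covariate_rejected(self, interval_rows):
        data = interval_rows([("A", 0, 6, True), ("B", 0, 9, True),
                              ("C", 0, 12, False)])
        with pytest.raises(SurvivalDataError, match="constant within every"):
            fit_discrete_cox(data, covariates=("cd_status",))

    def test_no_events_rejected(self, interval_rows):
        data = interval_rows([("A", 1, 6, False), ("B", 0, 9, False)])
        with pytest.raises(NoEventsError):
            fit_discrete_cox(data, covariates=("cd_status",))

    def test_separation_is_flagged_not_silent(self, interval_rows):
        # every event occurs in the exposed group while unexposed never fail
        data = interval_rows([("A", 1, 6, True), ("B", 1, 9, True),
                              ("C", 0, 12, False), ("D", 0, 12, False)])
        with pytest.warns(RuntimeWarning, match="diverging"):
            fit = fit_discrete_cox(data, covariates=("cd_status",))
        assert not fit.converged

    def test_singleton_ties_equal_breslow_and_efron(self, rng):
        for _ in range(5):
            subs = [(f"S{i}", i % 2, end, True)
                    for i, end in enumerate(rng.permutation([6, 9, 12, 15, 18])[:4])]
            subs += [(f"C{i}", int(rng.integers(0, 2)), 24, False)
                     for i in range(3)]
            data = make_interval_rows(subs)
            fits = {m: fit_discrete_cox(data, covariates=("cd_status",), ties=m)
                    for m in ("discrete", "efron", "breslow")}
            lls = [f.log_likelihood for f in fits.values()]
            assert max(lls) - min(lls) < 1e-10

    def test_age_translation_leaves_cd_hazard_ratio(self, rng):
        data = random_toy_dataset(rng)
        data["age"] = rng.normal(60, 8, len(data)).round(1)
        # age must vary within a risk set for the two-covariate fit
        f1 = fit_discrete_cox(data, covariates=("cd_status", "age"))
        shifted = data.assign(age=data["age"] + 25.0)
        f2 = fit_discrete_cox(shifted, covariates=("cd_status", "age"))
        assert f2.hazard_ratios["cd_status"][0] == pytest.approx(
            f1.hazard_ratios["cd_status"][0], abs=1e-8)

    def test_matches_lifelines_on_untied_data(self, rng):
        lifelines = pytest.importorskip("lifelines")
        subs = [("A", 1, 6, True), ("B", 0, 9, True), ("C", 1, 12, True),
                ("D", 0, 15, False), ("E", 1, 18, True), ("F", 0, 18, False)]
        data = make_interval_rows(subs)
        fit = fit_discrete_cox(data, covariates=("cd_status",), ties="discrete")
        ctv = lifelines.CoxTimeVaryingFitter(penalizer=0.0)
        ctv.fit(data[["patient_id", "start", "stop", "event", "cd_status"]],
                id_col="patient_id", start_col="start", stop_col="stop",
                event_col="event")
        assert fit.coefficients["cd_status"][0] == pytest.approx(
            ctv.params_["cd_status"], abs=1e-4)
        assert fit.coefficients["cd_status"][1] == pytest.approx(
            ctv.standard_errors_["cd_status"], rel=1e-2)


class TestConcordance:
    def test_identical_predictors_give_half(self, interval_rows):
        data = interval_rows([("A", 1, 6, True), ("B", 1, 9, False),
                              ("C", 1, 9, True), ("D", 1, 12, False)])
        assert concordance_index(data, [0.7], covariates=("cd_status",)) == 0.5

    def test_single_event_highest_risk(self, interval_rows):
        data = interval_rows([("A", 3, 6, True), ("B", 0, 6, False),
                              ("C", 1, 6, False), ("D", 2, 6, False)])
        assert concordance_index(data, [1.0], covariates=("cd_status",)) == 1.0

    def test_matches_exhaustive_pair_enumeration(self, rng):
        data = random_toy_dataset(rng)
        beta = 0.8
        got = concordance_index(data, [beta], covariates=("cd_status",))
        conc = ties = total = 0
        for t in data.loc[data["event"] == 1, "stop"].unique():
            risk = data[data["stop"] == t]
            for _, i in risk[risk["event"] == 1].iterrows():
                for _, j in risk[risk["event"] == 0].iterrows():
                    total += 1
                    if i["cd_status"] * beta > j["cd_status"] * beta:
                        conc += 1
                    elif i["cd_status"] == j["cd_status"]:
                        ties += 1
        assert got == pytest.approx((conc + 0.5 * ties) / total)

    def test_no_comparable_pairs_flagged(self, interval_rows):
        data = interval_rows([("A", 1, 6, True)])
        with pytest.warns(RuntimeWarning, match="no comparable pairs"):
            assert np.isnan(concordance_index(data, [1.0],
                                              covariates=("cd_status",)))


class TestMedian:
    @pytest.mark.parametrize("times, expected", [
        ([6, 9, 9], 9),
        ([6, 12], 6),   # even count: lower-central so it lands on a visit
        ([6], 6),
        ([], None),
    ])
    def test_conventions(self, times, expected):
        assert median_time_to(times) == expected
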