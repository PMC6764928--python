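"""Validate the discrete-time hazard model on cohorts with known truth.

Simulates hazard-driven cohorts (mode A) where decline multiplies the
per-interval progression odds by exactly 5 (log-HR = ln 5 ~ 1.609), builds
counting-process data from the generator's ground-truth decline times, fits
the exact discrete-ties partial likelihood, and reports the spread of the
estimates and the Wald-interval coverage across replicates.
"""

import numpy as np

from cogsurv import SimulationParams, build_survival_dataset, fit_discrete_cox, \
    simulate_cohort
from cogsurv.personalization import DeclineTimeline

target = np.log(5.0)
betas, covered = [], 0
n_rep = 20
for k in range(n_rep):
    params = SimulationParams(seed=500 + k, n_patients=400, mode="A")
    _, events, truth = simulate_cohort(params)
    timelines = {}
    for pid in events["patient_id"]:
        end = truth.event_time[pid] if truth.event_time[pid] is not None \
            else truth.censor_time[pid]
        fc = truth.first_cd_time[pid]
        flags = {t: bool(fc is not None and fc <= t) for t in range(6, end + 1, 3)}
        first = min((t for t, f in flags.items() if f), default=None)
        timelines[pid] = DeclineTimeline(pid, flags, {t: 0 for t in flags}, first)
    fit = fit_discrete_cox(build_survival_dataset(events, timelines))
    beta, se = fit.coefficients["cd_status"]
    betas.append(beta)
    covered += abs(beta - target) <= 1.96 * se

print(f"true log-HR for decline: {target:.3f}")
print(f"median estimate over {n_rep} cohorts of 400: {np.median(betas):.3f} "
      f"(IQR {np.percentile(betas, 25):.3f}-{np.percentile(betas, 75):.3f})")
print(f"95% Wald interval coverage: {covered}/{n_rep}")
print("\nan unbiased median and ~95% coverage show the exact discrete-ties "
      "fit handles the heavy 3-month-grid ties correctly.")
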