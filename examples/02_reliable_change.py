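"""Fit a normative retest regression and score a patient's change.

Simulates a healthy-control test-retest sample, fits the per-test regression
of retest on baseline, and computes regression-based Reliable Change Indices
(RCI) for two hypothetical patients.  An RCI is the observed retest minus the
regression-predicted retest, divided by the regression's standard error of
estimate: 0 means change exactly as expected from practice and regression to
the mean; -2 means two residual-SDs worse than expected.
"""

from cogsurv import SimulationParams, compute_rci, fit_normative_model, \
    simulate_controls

params = SimulationParams(seed=7, n_controls=500, n_tests=1)
controls = simulate_controls(params)
model = fit_normative_model(controls)

print(f"normative model for {model.test_id} (n={model.n_controls}):")
print(f"  predicted retest = {model.intercept:.2f} "
      f"+ {model.baseline_coefficient:.3f} * baseline,  SEE = {model.residual_se:.2f}")

for baseline, retest, label in [(50.0, 53.0, "improved as expected"),
                                (50.0, 38.0, "well below expectation")]:
    rci = compute_rci(baseline, retest, model)
    print(f"  baseline {baseline:.0f} -> retest {retest:.0f}: "
          f"RCI = {rci:+.2f}  ({label})")
print("positive RCI = improvement beyond norms; RCI <= -1 counts toward the "
      "decline criterion.")
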