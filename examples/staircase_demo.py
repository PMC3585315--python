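"""Simulate the adaptive 3-down 1-up 2IFC procedure on one condition.

Runs a single track of the ramped-increment paradigm (5-ms half-ramps
in 33-dB SPL noise) with the calibrated stochastic model observer, then
compares the tracked threshold with the analytic rate-criterion
solution.
"""

from centraljnd import CentralParams, condition_registry, solve_jnd
from centraljnd.staircase_sim import ModelObserver, StaircaseConfig, run_track

params = CentralParams()
cond = condition_registry("supplementary_ramps", half_ramps_ms=[5.0])[0]

analytic = solve_jnd(cond, params)
print(f"analytic threshold (rate criterion at equality): "
      f"{analytic.increment_db:.2f} dB")

observer = ModelObserver(ModelObserver.calibrated_sd(params))
threshold, log = run_track(cond, observer, StaircaseConfig(), seed=7,
                           params=params)
print(f"staircase threshold (mean of last 10 reversals): {threshold:.2f} dB "
      f"over {len(log)} trials")
print(log.tail(8).to_string(index=False))
print("\nThe track holds ~79.4% correct at convergence (3-down 1-up rule),")
print("so the tracked threshold sits at the criterion of the rate detector.")
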