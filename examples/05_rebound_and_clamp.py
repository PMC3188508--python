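"""Error-clamp decay and spontaneous rebound.

In an error clamp the display shows a straight, error-free reach no matter
what the arm does; the evidence is uninformative, relevance relaxes toward
0.5, and the estimates decay at their forgetting rates.  After a brief
counter-block, the fast body estimate decays away first and the retained
world estimate re-expresses the first-learned compensation: the rebound.
"""

import numpy as np

from reachsim import RunConfig, build_schedule, run_experiment
from reachsim.protocols import records_to_frame

cfg = RunConfig()

clamp = records_to_frame(run_experiment(build_schedule("error_clamp", cfg), cfg, 1))
c = clamp[clamp.block == "C1"]
print("error clamp after 80 adaptation trials:")
print(f"  entering clamp: theta_b={c.theta_b_deg.iloc[0]:5.2f}, theta_w={c.theta_w_deg.iloc[0]:5.2f} deg")
print(f"  after 100 clamp trials: theta_b={c.theta_b_deg.iloc[-1]:5.2f}, theta_w={c.theta_w_deg.iloc[-1]:5.2f} deg")
print(f"  relevance: {c.relevance_posterior.iloc[0]:.3f} -> {c.relevance_posterior.iloc[-1]:.3f} (relaxing toward 0.5)")

reb = records_to_frame(run_experiment(build_schedule("rebound", cfg), cfg, 1))
b = reb[reb.block == "B1"]; c = reb[reb.block == "C1"]
comp = c.total_compensation_deg.to_numpy()
print("\nspontaneous rebound (80 trials at +30, 20 at -30, then clamp):")
print(f"  compensation at end of counter-block: {b.total_compensation_deg.iloc[-1]:+6.2f} deg")
print(f"  peak compensation during clamp:       {comp.max():+6.2f} deg"
      f"  (crosses zero at clamp trial {int(np.argmax(comp > 0)) + 1})")
print("  The output transiently returns toward the FIRST-learned disturbance")
print("  even though it was counter-adapted away: the world estimate was stored.")
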