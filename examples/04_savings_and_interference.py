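"""Long-term savings and A-B-A interference across two simulated days.

In the savings paradigm the world estimate survives the inter-session
washout (only the body de-adapts), so day-2 errors start lower.  In the
A-B-A paradigm the counter-block B degrades the world estimate and day 2
looks naive.
"""

import numpy as np

from reachsim import RunConfig, build_schedule, run_experiment
from reachsim.protocols import records_to_frame

cfg = RunConfig()

def initial_error(df, block):
    return df[df.block == block].error_deg.abs().iloc[:3].mean()

sav = records_to_frame(run_experiment(build_schedule("long_term_savings", cfg), cfg, 1))
print("long-term savings (A, washout overnight, A):")
print(f"  day-1 initial error: {initial_error(sav, 'A1'):5.1f} deg")
print(f"  day-2 initial error: {initial_error(sav, 'A2'):5.1f} deg"
      "   <- lower: the retained world estimate is re-engaged at P=0.75")

aba = records_to_frame(run_experiment(build_schedule("aba_interference", cfg), cfg, 1))
print("\nA-B-A interference (A, counter-B, washout overnight, A):")
print(f"  end-of-B world estimate: {aba[aba.block=='B1'].theta_w_deg.iloc[-1]:5.1f} deg"
      "   <- block B hijacked the stored estimate")
print(f"  day-2 initial error:     {initial_error(aba, 'A2'):5.1f} deg"
      f"   (naive is ~{initial_error(sav, 'A1'):.1f} deg: savings abolished)")
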