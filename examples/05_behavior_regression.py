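"""Relate coupling strength to behavioral completion times.

Simulates a 10-animal cohort whose spatial-memory task completion time
grows linearly with IED-HFO coupling strength, then recovers the slope by
ordinary least squares with Pearson r — and shows the null result for an
uncoupled control cohort.
"""

import numpy as np

import hfocoupling as hc
from hfocoupling.coupling import build_peth, coupling_strength

rng = np.random.default_rng(9)


def cohort_strengths(probs, seed0):
    hs = []
    for i, p in enumerate(probs):
        cfg = hc.SimulationConfig(duration_s=1800.0, seed=seed0 + i,
                                  coupling_prob=float(p))
        ied, hfo, _ = hc.generate_event_times(cfg)
        times = np.array([r["time_s"] for r in hfo])
        hs.append(coupling_strength(build_peth(ied, times)))
    return np.array(hs)


h_pos = cohort_strengths(rng.uniform(0.2, 1.0, 10), seed0=300)
y_pos = hc.generate_behavior_scores(h_pos, slope=120.0, intercept=40.0,
                                    noise_sd=3.0, seed=1)
res = hc.regress_behavior(h_pos, y_pos, predictor="coupling strength")
print(f"coupled cohort:   slope = {res.slope:.1f} s per unit h "
      f"(true 120), R^2 = {res.r_squared:.2f}, p = {res.p_value:.4f}")

h_neg = cohort_strengths(np.zeros(10), seed0=400)
y_neg = hc.generate_behavior_scores(np.zeros(10), slope=0.0, intercept=40.0,
                                    noise_sd=3.0, seed=2)
res0 = hc.regress_behavior(h_neg, y_neg, predictor="coupling strength")
print(f"uncoupled cohort: slope = {res0.slope:.1f}, "
      f"R^2 = {res0.r_squared:.2f}, p = {res0.p_value:.4f}")
# The coupled cohort recovers the generating slope with a significant
# positive association; the uncoupled control shows none.
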