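"""Quantify IED-HFO coupling and test it against a surrogate null.

Builds the peri-event time histogram (PETH) of HFO times around IED
anchors (+/- 500 ms, 10 ms bins), computes the Shannon-entropy coupling
strength h = (ln N - S)/ln N, and bootstraps a count-preserving null.
"""

import numpy as np

import hfocoupling as hc
from hfocoupling.coupling import build_peth, bootstrap_significance

for label, prob in (("coupled session", 0.8), ("uncoupled session", 0.0)):
    cfg = hc.SimulationConfig(duration_s=1800.0, seed=21, coupling_prob=prob)
    ied_times, hfo_records, _ = hc.generate_event_times(cfg)
    hfo_times = np.array([r["time_s"] for r in hfo_records])

    peth = build_peth(ied_times, hfo_times)
    res = bootstrap_significance(ied_times, hfo_times, cfg.duration_s,
                                 n_boot=1000, seed=5)
    print(f"{label}: {len(ied_times)} IEDs, {len(hfo_times)} HFOs, "
          f"{peth.n_events_in_window} in-window pairs")
    print(f"  S = {res.entropy:.3f} nats (S_max = {res.max_entropy:.3f}), "
          f"h = {res.strength:.3f}, bootstrap p = {res.p_boot:.4g}")
# The coupled session concentrates counts near the +50 ms lag bin, giving
# h far above the surrogate null (p ~ 1/1001); the uncoupled session's h
# is explained by its own null (p >> 0.05).
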