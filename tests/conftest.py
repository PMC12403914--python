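import numpy as np
import pytest

import hfocoupling as hc


@pytest.fixture(scope="session")
def short_session():
    """A 10-minute coupled session with ground truth, shared across tests."""
    cfg = hc.SimulationConfig(duration_s=600.0, seed=42, coupling_prob=0.5)
    rec, truth = hc.generate_coupled_session(cfg)
    return cfg, rec, truth


@pytest.fixture()
def quiet_recording():
    """A 30-second pure-background recording (no injected events)."""
    cfg = hc.SimulationConfig(duration_s=30.0, seed=7, ied_rate_per_min=0.0,
                              hfo_rate_per_min=0.0, coupling_prob=0.0)
    return hc.generate_background(cfg)


def match_events(detected_times, truth_times, tol_s=0.05):
    """Greedy one-to-one matching; returns (precision, recall)."""
    det = np.sort(np.asarray(detected_times, float))
    tru = np.sort(np.asarray(truth_times, float))
    used = np.zeros(tru.size, dtype=bool)
    tp = 0
    for t in det:
        i = np.searchsorted(tru, t)
        best = None
        for j in (i - 1, i):
            if 0 <= j < tru.size and not used[j] and abs(tru[j] - t) <= tol_s:
                if best is None or abs(tru[j] - t) < abs(tru[best] - t):
                    best = j
        if best is not None:
            used[best] = True
            tp += 1
    precision = tp / det.size if det.size else float("nan")
    recall = used.sum() / tru.size if tru.size else float("nan")
    return precision, recall
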