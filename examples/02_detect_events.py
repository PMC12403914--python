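"""Run both detectors on a synthetic session and score them against truth.

The HFO detector is the four-stage cascade (envelope threshold, sharp-
transient rejection, bulb-shape morphology, background cleaning); the IED
detector thresholds the normalized squared signal (NSS) at 5/20 baseline
SDs with a 30-250 ms duration window and an entropy shape filter.
"""

import numpy as np

import hfocoupling as hc

cfg = hc.SimulationConfig(duration_s=600.0, seed=7, coupling_prob=0.5)
rec, truth = hc.generate_coupled_session(cfg)

hfo_ev = hc.detect_hfos(rec, states_filter=("NREM",))
ied_ev = hc.detect_ieds(rec, states_filter=("NREM",))


def score(detected, injected, tol=0.05):
    det = np.sort(detected)
    tru = np.sort(injected)
    hit = [np.min(np.abs(tru - t)) <= tol for t in det]
    found = [np.min(np.abs(det - t)) <= tol for t in tru] if len(det) else []
    return np.mean(hit), np.mean(found)


hp, hr = score(hfo_ev.peak_time_s.values, truth.hfo.time_s.values)
ip, ir = score(ied_ev.peak_time_s.values, truth.ied.time_s.values)

print(f"HFOs: {len(hfo_ev)} detected / {len(truth.hfo)} injected "
      f"-> precision {hp:.2f}, recall {hr:.2f}")
print(hfo_ev["class"].value_counts().to_string())
print(f"IEDs: {len(ied_ev)} detected / {len(truth.ied)} injected "
      f"-> precision {ip:.2f}, recall {ir:.2f}")
print(f"median IED peak: {ied_ev.peak_nss_sd.median():.0f} baseline SDs")
# Precision/recall near 1.0 at the default 6x-SNR amplitudes; detected
# peak frequencies straddle the 200 Hz ripple / fast-ripple boundary.
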