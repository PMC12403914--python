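# hfocoupling

Detection of high-frequency oscillations (HFOs) and interictal
epileptiform discharges (IEDs) in local field potential (LFP) recordings,
and quantification of their temporal coupling by a Shannon-entropy
statistic with bootstrap significance — plus a synthetic-LFP generator
with ground truth so the whole pipeline is testable without any recording
on disk.

## The scientific problem

In rodent models of Alzheimer's disease (and in patients), hippocampal
networks become hyperexcitable: interictal spikes (IEDs) appear between
seizures, and the balance of physiological ripples (80–200 Hz) versus
pathological fast ripples (200–500 Hz) shifts. A growing body of work
suggests that it is not the raw *rates* of these events but their
*temporal coupling* — IEDs triggering HFOs at short lags — that tracks
memory impairment. This package implements that analysis chain for
wide-band LFP sampled at 3 kHz with per-channel region labels
(striatum, mPFC, hippocampus, thalamus) and NREM/REM sleep annotations:

1. **HFO detection** — a four-stage cascade: 80–520 Hz band-pass and
   analytic (Hilbert) envelope thresholded against a robust per-state
   baseline; wavelet time–frequency rejection of sharp transients;
   "bulb-shape" morphology filtering (compact, isolated blob on the TF
   map); and a final background-percentile cleaning. Accepted events are
   classified ripple / fast ripple at a 200 Hz boundary.
2. **IED detection** — the LFP is band-passed 60–80 Hz, resampled to
   1250 Hz and converted to a normalized squared signal (NSS); events
   must exceed 5 baseline SDs at onset and 20 SDs at peak, last
   30–250 ms, and pass a Shannon-entropy shape filter that discards
   plateau-like profiles.
3. **Coupling** — with IED times as anchors (t = 0), HFO occurrences in a
   ±500 ms window are binned into a peri-event time histogram (PETH) of
   N = 100 bins with probabilities p_i, and

       S      = −Σᵢ p_i ln p_i
       S_max  = ln N
       h      = (S_max − S) / S_max ∈ [0, 1]

   so h = 0 for temporally unstructured co-occurrence and h = 1 for
   perfect lag locking. Significance comes from bootstrap surrogates
   (count-preserving uniform-lag null by default; circular time-shift and
   Poisson redraw available).
4. **Statistics** — state/region-stratified occurrence rates
   (events/min), Welch group summaries, and OLS regression of behavioral
   completion times on electrophysiological measures (Pearson r, R²,
   two-sided p).

Because no public dataset accompanies this design, the `simulate` module
generates sessions with known truth: 1/f^α background, Gabor HFO atoms,
spike-wave IED atoms, NREM/REM schedules, a tunable probability that each
IED triggers an HFO at a jittered lag, and behavior scores linearly tied
to coupling strength.

## Worked example

```python
import hfocoupling as hc

cfg = hc.SimulationConfig(duration_s=600.0, seed=7, coupling_prob=0.5)
rec, truth = hc.generate_coupled_session(cfg)
hfo_ev = hc.detect_hfos(rec, states_filter=("NREM",))
ied_ev = hc.detect_ieds(rec, states_filter=("NREM",))
```

Running `examples/02_detect_events.py` (exactly this session) prints:

```
HFOs: 31 detected / 33 injected -> precision 1.00, recall 0.94
class
ripple         22
fast_ripple     9
IEDs: 17 detected / 17 injected -> precision 1.00, recall 1.00
median IED peak: 115 baseline SDs
```

i.e. at the default 6× signal-to-noise amplitudes both detectors recover
essentially all injected events with no false alarms; detected classes
split at the 200 Hz boundary. `examples/03_coupling_significance.py`
shows the coupling statistic on a 30-minute session:

```
coupled session: 56 IEDs, 96 HFOs, 47 in-window pairs
  S = 1.768 nats (S_max = 4.605), h = 0.616, bootstrap p = 0.000999
uncoupled session: 56 IEDs, 56 HFOs, 2 in-window pairs
  S = 0.693 nats (S_max = 4.605), h = 0.849, bootstrap p = 1
```

The coupled session concentrates PETH mass near the +50 ms lag and is
significant at the resolution of 1000 surrogates; the uncoupled session's
seemingly large h is entirely an artifact of having only 2 in-window
events (the entropy statistic is biased upward at small counts), which
the count-preserving null accounts for — hence p = 1. The remaining
examples cover session simulation and I/O, state-stratified rates, and
the behavior regression.

## Layout

- `src/hfocoupling/io.py` — recording/event/state containers, fixture and
  EDF formats, config loading
- `src/hfocoupling/simulate.py` — synthetic sessions with ground truth
- `src/hfocoupling/hfo.py`, `ied.py` — the two detectors
- `src/hfocoupling/coupling.py` — PETH, entropy strength, bootstrap
- `src/hfocoupling/stats.py` — rates, group summaries, regression
- `docs/methods.md` — model assumptions, parameter rationale, limitations
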