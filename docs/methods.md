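# Methods

This note documents the models, numerical choices and their rationale, in
enough detail to judge what passing tests do and do not establish.

## Signal model and conventions

All public times are seconds; intervals (events, sleep states) are
half-open `[start, end)`; sample `k` of a channel occupies
`[k/fs, (k+1)/fs)`. Recordings are wide-band LFP, nominally 3000 Hz, with
a region label per channel and NREM/REM/WAKE annotations consumed as
input (sleep staging itself is out of scope). The lossless fixture format
(float32 + JSON sidecar) is the canonical test medium because EDF is
16-bit quantized; EDF is supported for interchange (read via mne, written
by a minimal 16-bit encoder).

## Band-pass filter design

All filtering is zero-phase so event timestamps are unbiased: linear-phase
window-method FIR (1001 taps), applied once with the group delay removed.
A window-method FIR has half-*amplitude* gain at its nominal cutoff, which
would place the half-power point several Hz inside the printed band edges.
The design therefore calibrates the cutoffs numerically so both nominal
edges sit inside the passband at ≥ −2.5 dB; the convention is that the
printed band edges (80–520 Hz for HFOs, 60–80 Hz for IEDs) are guaranteed
at least half power, with the −3 dB points within ~2 Hz outside them.
Transition width at 3 kHz is ≈ 8–10 Hz.

## HFO detector

Stage 1 thresholds the analytic envelope of the 80–520 Hz signal.
Baseline statistics are robust (median and 1.4826·MAD) per channel and
sleep state, so detection is invariant to global signal scaling and a
high event load cannot inflate its own threshold. Two choices here go
beyond the bare "threshold the envelope" recipe, both forced by short
(≈6-cycle) bursts:

* the envelope used for thresholding is smoothed with a 5 ms moving
  average — beating between a burst and the background produces envelope
  nulls that otherwise fragment one burst into several sub-threshold
  pieces;
* a two-threshold rule: detection at `k_env = 3` robust SDs, event
  *extent* delimited at `k_edge = 1` SD. With a single threshold a
  6-cycle Hann-windowed burst keeps fewer than 4 cycles above the
  detection level, and any cycles-based duration floor then rejects
  genuine events. The duration floor is
  `max(6 ms, min_cycles/f_est)` with `f_est` the zero-crossing frequency
  over the extent and `min_cycles = 2` (threshold-trimmed extents retain
  ~2–3 cycles; filter-ringing rejection is the job of the time-frequency
  stages, not this floor). Candidates closer than 10 ms are merged.

Stages 2–3 operate on a Morlet time–frequency map (7 cycles, 32
log-spaced frequencies 60–600 Hz), with each frequency row normalized by
its baseline median estimated from ≤ 40 evenly spaced 0.4 s windows of
the analyzed state (sampling keeps the cost linear in session length and
deterministic). A candidate is rejected as `sharp_transient` when the
mean normalized power below the band (60–80 Hz rows) at the peak column
exceeds the in-band peak (ratio 1.0) — spikes smear power vertically,
oscillations do not. The morphology stage keeps a candidate iff the
normalized in-band peak ≥ `power_floor = 22`, the supra-half-maximum blob
containing the peak spans ≤ 1.0 of the peak frequency, and a trough ≥
6 dB below the peak separates the blob from the low-frequency edge.
`power_floor` is the detector's operating point: on synthetic sessions at
6× SNR, genuine bursts measure ≥ 30× the baseline row median (10th
percentile ≈ 31–36) while background excursions reach ≈ 26× at most;
22 balances sensitivity against a background false-alarm rate of
~0.1/min. Stage 4 additionally requires the peak envelope to clear the
99.5th percentile of the state's envelope distribution. Peak frequency is
read off the TF map; events classify as ripple below 200 Hz and fast
ripple at or above it (the shared 200 Hz endpoint of the two printed
ranges is assigned upward, a deterministic tie-break).

## IED detector

The NSS chain: zero-phase 60–80 Hz band-pass at the native rate,
polyphase resampling to 1250 Hz, squaring, moving-average smoothing, then
normalization to baseline-SD units. The smoothing window is 7.2 ms = one
period of the 140 Hz ripple that squaring a band-center (70 Hz) tone
produces, so that ripple is nulled exactly rather than attenuated (a
10 ms window leaves 21 % of it, enough to fragment events). Baseline
mean/SD are computed over the analyzed state excluding samples above the
onset threshold, iterated once, so events do not inflate their own
threshold; detections are therefore scale-invariant.

Thresholds are the printed constants: onset 5 SD, peak 20 SD, duration
30–250 ms measured at the onset crossings. The entropy shape filter bins
each event's NSS profile into 10 equal time bins, normalizes to a
probability vector and computes S; events with
S > 0.97·ln(10) are rejected as plateau/transition-like. The 0.97 factor
sits between a flat plateau (S = ln 10 exactly) and a triangular
single-peak profile (S ≈ 0.948·ln 10) — a tighter factor would reject the
peaked profiles the filter exists to keep. Manual visual curation is not
implemented; the automated filters replace it, and rejected candidates
carry exactly one machine-readable reason
(`low_peak`, `duration`, `shape_entropy`, `degenerate`).

## Coupling statistic and its null

PETH: anchors are IED times, events are HFO times, window ±500 ms,
half-open 10 ms bins (N = 100; a lag of exactly +500 ms is excluded,
−500 ms included). Entropy uses natural logarithms over all N bins with
0·ln 0 = 0; h = (ln N − S)/ln N. An empty-window PETH yields h = 0 with
an `undefined` flag rather than an error, so batch runs survive sessions
with no co-occurrences.

The entropy statistic has a strong small-count bias: with n events spread
over N bins, S is bounded by ln n, so h ≥ 1 − ln n/ln N even for
perfectly unstructured data (h → 1 as n → 0). Two consequences shape the
design:

* **Surrogates.** The default null (`uniform_lags`) redraws the observed
  number of in-window lags uniformly over the window, i.e. it conditions
  on the co-occurrence count and randomizes only the temporal structure —
  exactly what h measures. This makes the test an exact conditional test;
  measured type-I error is ≈ 0.03–0.05 at α = 0.05 and power against
  strong lag-locking at 2 events/min × 30 min is essentially 1. A
  circular time-shift of the event stream (the classic point-process
  null) is available, but at desk-scale rates it collapses the in-window
  count from ~50 (coupled) to ~3, and the count bias then pushes the
  *null* h above the observed h, destroying power; it remains appropriate
  when event counts are large. A homogeneous-Poisson redraw is the third
  option. `p_boot = (1 + #{h* ≥ h}) / (n_boot + 1)`.
* **Pooling.** Comparisons of h across conditions with different counts
  (e.g. coupling probability sweeps) are made on PETHs pooled across
  sessions — counts are summed before the entropy is taken, mirroring the
  practice of collecting HFO occurrences across all recordings — so the
  bias is both small and comparable between conditions. The mean of
  single-session raw h values is *not* monotone in coupling probability
  at 2/min rates, purely through this bias.

## Synthetic data

The generator emulates the statistical structure the analyses assume, not
the biophysics: background is FFT-shaped Gaussian 1/f^α noise (α = 1,
SD 1 µV); HFO atoms are 6-cycle Hann-windowed sinusoids with ripple
frequencies drawn U(100, 180) Hz and fast-ripple frequencies
U(220, 400) Hz (ripple fraction 0.7), amplitude 6× the background's
80–520 Hz envelope SD; IED atoms are a sharp difference-of-Gaussians
spike (peak 6× the broadband background SD) plus a Hann-windowed 70 Hz
fast-activity component at 0.4× the spike peak spanning the event width
(default 100 ms) and an optional half-sine slow wave. The 70 Hz component
exists because a smooth spike of 30–250 ms width carries essentially no
60–80 Hz energy — without it no amplitude whatsoever would make the atom
visible to the NSS detector; physiological spikes do carry superimposed
fast activity, which is precisely why a 60–80 Hz detection band works.
IED amplitude is referenced to the broadband SD because "spike versus
trace" is the natural visual SNR; at the 6× default the NSS peak is
~100 baseline SDs, comfortably above the printed 20 SD floor.

Event times: IEDs are homogeneous Poisson (2/min) within NREM intervals;
each IED triggers one HFO with probability `coupling_prob` at lag
N(50 ms, 20 ms²) (the lag values are simulation knobs, not empirical
claims); uncoupled HFOs are an independent Poisson process (2/min). A
0.5 s margin keeps atoms clear of interval edges; a coupled placement
whose lag leaves the recording is redrawn once, then dropped and counted.
The state schedule repeats 25 min NREM / 5 min REM. Behavior scores are
`y = intercept + slope·h + N(0, σ²)`.

What the generator does **not** emulate: non-stationarity, volume
conduction and cross-channel correlation, artifacts, spindles/sharp-wave
complexes, realistic IED morphology diversity, seizures, or WAKE
behavior. Detector performance numbers on this synthetic data (precision
and recall ≥ 0.9 at 6× SNR over 30-minute sessions) therefore demonstrate
correctness of the implementation under the stated model, not expected
field performance on real recordings.

## Problem sizes used in the test suite

Detector performance runs 3 × 30-minute single-channel sessions;
bootstrap calibration uses 100 replicates × 200 surrogates with
20 events/min independent streams (at 2/min the in-window count is ~3 and
the discrete conditional test grossly under-rejects, which would make a
binomial check of the rejection fraction uninformative); monotonicity
uses 20 sessions per coupling probability, event times only. These sizes
give stable statistics at desk scale; all randomness is seeded.

## Known limitations

* The morphology "bulb" criteria (half-max blob, relative bandwidth,
  6 dB isolation) are one reasonable quantification of a qualitative
  published description; alternatives (e.g. 2-D Gaussian fits) would
  differ in edge cases.
* The entropy shape filter for IEDs is likewise one defensible reading of
  "eliminate shape transitions"; it is isolated behind a single function
  so it can be swapped.
* Coupling is within-channel/within-region by design; cross-regional
  coupling and phase–amplitude metrics are out of scope.
* Occurrence-rate tables operate per session; multi-animal cohorts are
  assembled by concatenating per-session outputs with animal/group
  columns.
* Rates default to events/min (matching the axis convention of the
  figures this feeds); an `unit="per_sec"` flag covers the per-second
  convention, and the two differ only by the factor 60.
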