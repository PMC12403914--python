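"""High-frequency oscillation (HFO) detection.

The detector finds 80-520 Hz oscillatory bursts in the LFP and classifies
them as ripples (< 200 Hz) or fast ripples (>= 200 Hz).  It is a four-stage
cascade:

1. band-pass + analytic envelope; epochs where the envelope exceeds the
   state-specific baseline by ``k_env`` robust SDs become candidates;
2. sharp-transient rejection on a Morlet time-frequency (TF) map — spikes
   smear power vertically across frequencies, genuine oscillations do not;
3. morphology: the supra-half-maximum region around the TF peak must be a
   single compact "bulb", powerful enough relative to baseline and isolated
   from the low-frequency edge of the map;
4. background cleaning: the peak envelope must also clear a strict
   percentile of the state's envelope distribution.

All thresholds are baseline-relative, so detection is invariant to global
signal scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, ValidationError
from .filters import (analytic_envelope, bandpass_zero_phase, morlet_power,
                      tf_frequency_grid)
from .io import LfpRecording

#: columns of the HFO event table
HFO_COLUMNS = ("channel", "region", "kind", "start_s", "end_s", "peak_time_s",
               "peak_freq_hz", "peak_envelope_sd", "class", "rejection_stage")


@dataclass
class HfoDetectionConfig:
    """Tunable parameters of the HFO detector (defaults in docstrings).

    ``k_env`` is in multiples of the robust baseline SD of the envelope
    (median / 1.4826*MAD); ``power_floor`` and the sharp-transient ratio act
    on TF power normalized by the per-frequency baseline median.
    """

    band_low_hz: float = 80.0
    band_high_hz: float = 520.0
    boundary_hz: float = 200.0          # ripple/fast-ripple split
    k_env: float = 3.0                  # envelope threshold, baseline SDs
    k_edge: float = 1.0                 # extent threshold, baseline SDs
    env_smooth_ms: float = 5.0          # envelope smoothing for thresholding
    min_cycles: int = 2
    min_duration_ms: float = 6.0
    merge_gap_ms: float = 10.0
    tf_low_hz: float = 60.0
    tf_high_hz: float = 600.0
    tf_n_freqs: int = 32
    tf_n_cycles: float = 7.0
    sharp_ratio_max: float = 1.0        # below-band mean / in-band peak
    power_floor: float = 22.0           # in-band peak vs baseline TF median
    max_rel_bandwidth: float = 1.0      # blob frequency extent / peak freq
    min_isolation_db: float = 6.0       # trough below blob vs peak
    background_percentile: float = 99.5  # stage-4 envelope percentile

    def validate(self):
        if not (self.band_low_hz < self.boundary_hz <= self.band_high_hz):
            raise ConfigurationError(
                "require band_low < boundary_hz <= band_high")
        if self.k_env <= 0:
            raise ConfigurationError("k_env must be > 0")
        if not 0 < self.k_edge <= self.k_env:
            raise ConfigurationError("require 0 < k_edge <= k_env")
        if self.min_cycles < 1:
            raise ConfigurationError("min_cycles must be >= 1")
        if not (0 < self.background_percentile < 100):
            raise ConfigurationError("background_percentile in (0, 100)")
        return self

    def tf_freqs(self) -> np.ndarray:
        return tf_frequency_grid(self.tf_low_hz, self.tf_high_hz,
                                 self.tf_n_freqs)


@dataclass
class BaselineStats:
    """Robust envelope baseline plus per-frequency TF medians for one
    channel/state combination."""

    center: float
    scale: float
    strict_percentile_value: float
    tf_row_median: np.ndarray = field(repr=False)

    @property
    def threshold(self) -> float:
        # populated by compute_baseline with k_env folded in
        return self._threshold

    _threshold: float = 0.0


# ---------------------------------------------------------------------------
# stage 1
# ---------------------------------------------------------------------------

def smooth_envelope(envelope: np.ndarray, fs_hz: float,
                    config: HfoDetectionConfig) -> np.ndarray:
    """Moving-average smoothing of the envelope used for thresholding;
    removes interference nulls that fragment burst extents."""
    win = max(1, int(round(config.env_smooth_ms * 1e-3 * fs_hz)))
    if win == 1:
        return envelope
    from scipy.signal import oaconvolve
    return oaconvolve(envelope, np.ones(win) / win, mode="same")


def bandpass_and_envelope(x: np.ndarray, fs_hz: float,
                          config: HfoDetectionConfig | None = None):
    """Zero-phase band-pass and its analytic-signal envelope."""
    config = (config or HfoDetectionConfig()).validate()
    if fs_hz <= 2 * config.band_high_hz:
        raise ConfigurationError(
            f"fs {fs_hz} Hz too low for band up to {config.band_high_hz} Hz")
    filtered = bandpass_zero_phase(np.asarray(x, float), fs_hz,
                                   config.band_low_hz, config.band_high_hz)
    return filtered, analytic_envelope(filtered)


def compute_baseline(envelope: np.ndarray, filtered: np.ndarray, fs_hz: float,
                     sample_slices: list[slice],
                     config: HfoDetectionConfig) -> BaselineStats:
    """Robust baseline of the envelope (median, 1.4826*MAD) and the
    per-frequency median of TF power, estimated from evenly spaced windows
    of the analyzed state."""
    samples = np.concatenate([envelope[s] for s in sample_slices])
    center = float(np.median(samples))
    scale = float(1.4826 * np.median(np.abs(samples - center)))
    if scale == 0:
        raise ValidationError("degenerate envelope baseline (zero spread)")
    strict = float(np.percentile(samples, config.background_percentile))

    # sampled baseline TF medians: up to 40 evenly spaced 0.4 s windows
    freqs = config.tf_freqs()
    win = int(round(0.4 * fs_hz))
    segs = []
    for sl in sample_slices:
        n = sl.stop - sl.start
        if n < win:
            continue
        k = max(1, min(40 // max(1, len(sample_slices)) + 1, n // win))
        starts = np.linspace(sl.start, sl.stop - win, k).astype(int)
        segs.extend(filtered[s:s + win] for s in starts)
    if not segs:
        segs = [filtered[sl] for sl in sample_slices]
    pw = [morlet_power(seg, fs_hz, freqs, config.tf_n_cycles) for seg in segs]
    tf_row_median = np.median(np.concatenate(pw, axis=1), axis=1)
    tf_row_median[tf_row_median == 0] = np.finfo(float).tiny

    stats = BaselineStats(center=center, scale=scale,
                          strict_percentile_value=strict,
                          tf_row_median=tf_row_median)
    stats._threshold = center + config.k_env * scale
    return stats


def detect_candidate_epochs(envelope: np.ndarray, fs_hz: float,
                            baseline: BaselineStats,
                            config: HfoDetectionConfig,
                            filtered: np.ndarray | None = None,
                            sample_slice: slice | None = None,
                            smoothed: np.ndarray | None = None) -> list[tuple]:
    """Candidate epochs from the envelope, duration-filtered and gap-merged.
    Returns ``(start_idx, stop_idx)`` half-open sample pairs.

    Detection uses the high threshold ``center + k_env*scale`` on the raw
    envelope (a single suprathreshold sample suffices); each detection's
    extent is then delimited at the lower edge threshold
    ``center + k_edge*scale`` on the *smoothed* envelope (the standard
    two-threshold rule; smoothing removes the interference nulls that
    fragment extents).  The duration floor is
    ``max(min_duration_ms, min_cycles/f_est)`` where ``f_est`` is the
    zero-crossing frequency of the filtered segment over the extent.
    """
    sl = sample_slice or slice(0, envelope.size)
    seg = envelope[sl]
    seg_smooth = smoothed[sl] if smoothed is not None else seg
    if seg.size == 0:
        return []

    def runs(mask):
        d = np.diff(mask.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        stops = np.flatnonzero(d == -1) + 1
        if mask[0]:
            starts = np.r_[0, starts]
        if mask[-1]:
            stops = np.r_[stops, mask.size]
        return starts, stops

    above = seg > baseline._threshold
    if not above.any():
        return []
    det_starts, det_stops = runs(above)

    # event extent delimited at the lower edge threshold (two-threshold
    # rule: detect high, delimit low), then deduplicated
    edge_thr = baseline.center + config.k_edge * baseline.scale
    edge_mask = seg_smooth > edge_thr
    # every detection sample must lie in an edge run; guarantee it
    edge_mask |= above
    e_starts, e_stops = runs(edge_mask)
    exts = []
    for a in det_starts:
        j = np.searchsorted(e_starts, a, side="right") - 1
        exts.append((int(e_starts[j]), int(e_stops[j])))
    exts = sorted(set(exts))

    # merge extents closer than merge_gap_ms
    gap = int(round(config.merge_gap_ms * 1e-3 * fs_hz))
    merged = []
    for a, b in exts:
        if merged and a - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])

    out = []
    for a, b in merged:
        dur_s = (b - a) / fs_hz
        min_dur = config.min_duration_ms * 1e-3
        if filtered is not None:
            fseg = filtered[sl][a:b]
            zc = np.count_nonzero(np.diff(np.sign(fseg)) != 0)
            f_est = zc / (2.0 * dur_s) if dur_s > 0 else np.inf
            if f_est > 0:
                min_dur = max(min_dur, config.min_cycles / f_est)
        if dur_s >= min_dur:
            out.append((a + sl.start, b + sl.start))
    return out


# ---------------------------------------------------------------------------
# stages 2+3: time-frequency analysis of one candidate
# ---------------------------------------------------------------------------

def candidate_tf_map(filtered: np.ndarray, fs_hz: float, a: int, b: int,
                     config: HfoDetectionConfig):
    """Normalized Morlet TF map around candidate [a, b); returns
    (tfmap_over_window, column_range_of_candidate, pad)."""
    if a < 0 or b > filtered.size:
        raise IndexError("candidate outside signal bounds")
    pad = int(round(0.15 * fs_hz))
    lo = max(0, a - pad)
    hi = min(filtered.size, b + pad)
    freqs = config.tf_freqs()
    tf = morlet_power(filtered[lo:hi], fs_hz, freqs, config.tf_n_cycles)
    return tf, (a - lo, b - lo), freqs


def evaluate_candidate(tf: np.ndarray, cols: tuple[int, int],
                       freqs: np.ndarray, baseline: BaselineStats,
                       config: HfoDetectionConfig):
    """Apply the sharp-transient and morphology criteria to one candidate.

    Returns ``(verdict, peak_freq_hz, peak_col)`` where verdict is '' for
    keep or one of 'sharp_transient', 'low_power', 'non_bulb'.
    """
    norm = tf / baseline.tf_row_median[:, None]
    in_band = (freqs >= config.band_low_hz) & (freqs <= config.band_high_hz)
    below = freqs < config.band_low_hz
    c0, c1 = cols
    sub = norm[:, c0:c1]
    if sub.size == 0 or not np.any(sub[in_band] > 0):
        return "low_power", np.nan, c0

    band_rows = np.flatnonzero(in_band)
    flat = np.argmax(sub[in_band])
    r_rel, peak_col_rel = np.unravel_index(flat, sub[in_band].shape)
    peak_row = band_rows[r_rel]
    peak_col = c0 + peak_col_rel
    peak_val = float(norm[peak_row, peak_col])
    peak_freq = float(freqs[peak_row])

    # stage 2: sharp transients smear power down into the below-band rows
    if below.any():
        low_mean = float(np.mean(norm[below, peak_col]))
        if low_mean / peak_val > config.sharp_ratio_max:
            return "sharp_transient", peak_freq, peak_col

    # stage 3a: absolute power floor (baseline-relative)
    if peak_val < config.power_floor:
        return "low_power", peak_freq, peak_col

    # stage 3b: bulb shape — supra-half-max blob containing the peak
    mask = norm[:, c0:c1] >= peak_val / 2.0
    labels, _ = ndimage.label(mask)
    blob = labels == labels[peak_row, peak_col_rel]
    rows = np.flatnonzero(blob.any(axis=1))
    f_lo, f_hi = freqs[rows[0]], freqs[rows[-1]]
    if (f_hi - f_lo) / peak_freq > config.max_rel_bandwidth:
        return "non_bulb", peak_freq, peak_col
    # isolation: a power trough below the blob at the peak column
    if rows[0] == 0:
        return "non_bulb", peak_freq, peak_col
    trough = float(np.min(norm[:rows[0], peak_col]))
    if trough > peak_val / (10.0 ** (config.min_isolation_db / 10.0)):
        return "non_bulb", peak_freq, peak_col
    return "", peak_freq, peak_col


def classify_hfo(peak_freq_hz: float,
                 config: HfoDetectionConfig | None = None) -> str:
    """'ripple' below the boundary (default 200 Hz), 'fast_ripple' at or
    above it (the boundary itself is assigned upward)."""
    config = config or HfoDetectionConfig()
    if not (config.band_low_hz <= peak_freq_hz <= config.band_high_hz):
        raise ValidationError(
            f"peak frequency {peak_freq_hz} Hz outside band "
            f"[{config.band_low_hz}, {config.band_high_hz}]")
    return "ripple" if peak_freq_hz < config.boundary_hz else "fast_ripple"


def clean_background(peak_env: float, baseline: BaselineStats) -> bool:
    """Stage 4: keep only events whose peak envelope clears the strict
    background percentile."""
    return peak_env > baseline.strict_percentile_value


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def detect_hfos(recording: LfpRecording,
                config: HfoDetectionConfig | None = None,
                states_filter=("NREM",),
                keep_rejected: bool = False) -> pd.DataFrame:
    """Run the four-stage HFO detector per channel within the requested
    sleep states and return an event table."""
    config = (config or HfoDetectionConfig()).validate()
    slices = recording.state_sample_slices(states_filter)
    rows = []
    if not slices:
        import warnings
        warnings.warn("no samples in the selected states; empty event table")
        return pd.DataFrame(columns=list(HFO_COLUMNS))

    for ci, (ch, region) in enumerate(zip(recording.channels,
                                          recording.regions)):
        x = recording.data[ci]
        filtered, envelope = bandpass_and_envelope(x, recording.fs_hz, config)
        envelope = smooth_envelope(envelope, recording.fs_hz, config)
        env_smooth = envelope
        baseline = compute_baseline(envelope, filtered, recording.fs_hz,
                                    slices, config)
        for sl in slices:
            cands = detect_candidate_epochs(envelope, recording.fs_hz,
                                            baseline, config,
                                            filtered=filtered,
                                            sample_slice=sl,
                                            smoothed=env_smooth)
            for a, b in cands:
                tf, cols, freqs = candidate_tf_map(filtered, recording.fs_hz,
                                                   a, b, config)
                verdict, peak_freq, peak_col_w = evaluate_candidate(
                    tf, cols, freqs, baseline, config)
                peak_idx = a + int(np.argmax(envelope[a:b]))
                peak_env_sd = (envelope[peak_idx] - baseline.center) \
                    / baseline.scale
                if verdict == "":
                    if not clean_background(envelope[peak_idx], baseline):
                        verdict = "background"
                if verdict == "":
                    cls = classify_hfo(
                        float(np.clip(peak_freq, config.band_low_hz,
                                      config.band_high_hz)), config)
                else:
                    cls = ""
                if verdict and not keep_rejected:
                    continue
                t0 = recording.start_time_s
                rows.append({
                    "channel": ch, "region": region, "kind": "hfo",
                    "start_s": t0 + a / recording.fs_hz,
                    "end_s": t0 + b / recording.fs_hz,
                    "peak_time_s": t0 + peak_idx / recording.fs_hz,
                    "peak_freq_hz": peak_freq,
                    "peak_envelope_sd": float(peak_env_sd),
                    "class": cls, "rejection_stage": verdict,
                })
    df = pd.DataFrame(rows, columns=list(HFO_COLUMNS))
    return df.sort_values(["channel", "start_s"]).reset_index(drop=True)
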