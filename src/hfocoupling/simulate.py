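"""Synthetic LFP sessions with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: 1/f^alpha background noise, Gabor-atom HFO bursts in the ripple
(80-200 Hz) and fast-ripple (200-500 Hz) bands, spike-wave IED transients,
an alternating NREM/REM state schedule, a tunable probability that each IED
triggers an HFO at a lagged and jittered offset, and behavioral completion
times linearly related to coupling strength plus Gaussian noise.

Amplitudes are parameterized as multiples of the background's band-limited
envelope/signal SD so detector signal-to-noise ratios are interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, OutOfRangeError
from .filters import analytic_envelope, bandpass_zero_phase
from .io import LfpRecording, StateInterval

TRUTH_COLUMNS = ("channel", "time_s", "kind", "freq_hz", "n_cycles",
                 "amplitude", "width_ms", "parent_ied_time_s", "class")


@dataclass
class SimulationConfig:
    """Session-level simulation parameters (defaults are the study
    conditions the analyses are verified under)."""

    duration_s: float = 1800.0
    fs_hz: float = 3000.0
    channels: tuple = (("hpc1", "hippocampus"),)
    background_exponent: float = 1.0   # spectral slope alpha of 1/f^alpha
    background_sd: float = 1.0         # signal units (µV)
    ied_rate_per_min: float = 2.0
    hfo_rate_per_min: float = 2.0      # baseline (uncoupled) HFO rate
    ripple_fraction: float = 0.7       # P(atom drawn from the ripple band)
    coupling_prob: float = 0.5         # P(an IED triggers an HFO)
    coupling_lag_ms: float = 50.0
    coupling_jitter_ms: float = 20.0
    hfo_snr: float = 6.0               # x background 80-520 Hz envelope SD
    ied_snr: float = 6.0               # spike peak, x broadband background SD
    hfo_n_cycles: int = 6
    ied_width_ms: float = 100.0
    ied_slow_wave: bool = True
    state_schedule: tuple = (("NREM", 25.0), ("REM", 5.0))  # minutes, repeats
    seed: int = 0

    def validate(self):
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.fs_hz <= 2 * 520:
            raise ConfigurationError(
                "fs_hz must exceed twice the highest injected frequency")
        for name in ("ied_rate_per_min", "hfo_rate_per_min"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.coupling_prob <= 1:
            raise ConfigurationError("coupling_prob must be in [0, 1]")
        if not 0 <= self.ripple_fraction <= 1:
            raise ConfigurationError("ripple_fraction must be in [0, 1]")
        return self

    def state_intervals(self) -> list[StateInterval]:
        """Expand the repeating schedule over the session duration."""
        out, t = [], 0.0
        if not self.state_schedule:
            return [StateInterval("NREM", 0.0, self.duration_s)]
        while t < self.duration_s:
            for label, minutes in self.state_schedule:
                end = min(t + minutes * 60.0, self.duration_s)
                if end > t:
                    out.append(StateInterval(label, t, end))
                t = end
                if t >= self.duration_s:
                    break
        return out


@dataclass
class SimulationTruth:
    """Ground truth for scoring the detectors and the coupling analysis."""

    ied: pd.DataFrame           # channel, time_s, amplitude, width_ms, tag
    hfo: pd.DataFrame           # channel, time_s, freq_hz, n_cycles,
    #                             amplitude, triggered_by_ied,
    #                             parent_ied_time_s, lag_ms, class
    behavior_slope: float = 0.0
    behavior_intercept: float = 0.0
    behavior_noise_sd: float = 0.0
    dropped_couplings: int = 0

    def to_tsv(self, path):
        rows = []
        for r in self.ied.itertuples():
            rows.append((r.channel, r.time_s, "ied", np.nan, np.nan,
                         r.amplitude, r.width_ms, np.nan, r.tag))
        for _, r in self.hfo.iterrows():
            rows.append((r["channel"], r["time_s"], "hfo", r["freq_hz"],
                         r["n_cycles"], r["amplitude"], np.nan,
                         r["parent_ied_time_s"] if r["triggered_by_ied"]
                         else np.nan, r["class"]))
        pd.DataFrame(rows, columns=list(TRUTH_COLUMNS)).to_csv(
            path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def generate_background(config: SimulationConfig) -> LfpRecording:
    """Spectrally shaped Gaussian noise with a 1/f^alpha power spectrum,
    scaled to ``background_sd`` per channel; reproducible under the seed."""
    config.validate()
    n = int(round(config.duration_s * config.fs_hz))
    rng = np.random.default_rng(config.seed)
    n_ch = len(config.channels)
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs_hz)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-config.background_exponent / 2.0)
    data = np.empty((n_ch, n))
    for c in range(n_ch):
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white) * shaping
        x = np.fft.irfft(spec, n=n)
        x *= config.background_sd / np.std(x)
        data[c] = x
    channels = [name for name, _ in config.channels]
    regions = [region for _, region in config.channels]
    return LfpRecording(data=data, fs_hz=config.fs_hz, channels=channels,
                        regions=regions, states=config.state_intervals())


def band_envelope_sd(x: np.ndarray, fs_hz: float, low_hz: float,
                     high_hz: float, max_seconds: float = 60.0) -> float:
    """SD of the analytic envelope of the band-passed signal (first
    ``max_seconds`` of the input), the amplitude yardstick for HFO atoms."""
    n = min(x.size, int(max_seconds * fs_hz))
    filt = bandpass_zero_phase(x[:n], fs_hz, low_hz, high_hz)
    return float(np.std(analytic_envelope(filt)))


def band_signal_sd(x: np.ndarray, fs_hz: float, low_hz: float,
                   high_hz: float, max_seconds: float = 60.0) -> float:
    """SD of the band-passed signal itself, the yardstick for IED atoms."""
    n = min(x.size, int(max_seconds * fs_hz))
    return float(np.std(bandpass_zero_phase(x[:n], fs_hz, low_hz, high_hz)))


# ---------------------------------------------------------------------------
# atoms
# ---------------------------------------------------------------------------

def hfo_class(freq_hz: float) -> str:
    return "ripple" if freq_hz < 200.0 else "fast_ripple"


def inject_hfo_burst(recording: LfpRecording, channel, time_s: float,
                     freq_hz: float, n_cycles: int = 6,
                     amplitude: float = 1.0) -> dict:
    """Add a Hann-windowed sinusoidal (Gabor) atom centered at ``time_s``;
    returns the truth record.  The recording is modified in place."""
    if not 80.0 <= freq_hz <= 500.0:
        raise OutOfRangeError(f"HFO frequency {freq_hz} Hz outside 80-500 Hz")
    ci = recording.channel_index(channel)
    fs = recording.fs_hz
    dur = n_cycles / freq_hz
    n = int(round(dur * fs))
    a = int(round((time_s - dur / 2.0) * fs))
    if a < 0 or a + n > recording.n_samples:
        raise OutOfRangeError(
            f"burst at {time_s:.3f} s extends past the recording")
    t = (np.arange(n) - (n - 1) / 2.0) / fs
    atom = amplitude * np.hanning(n) * np.sin(2 * np.pi * freq_hz * t)
    recording.data[ci, a:a + n] += atom
    return {"channel": recording.channels[ci], "time_s": time_s,
            "freq_hz": freq_hz, "n_cycles": n_cycles, "amplitude": amplitude,
            "triggered_by_ied": False, "parent_ied_time_s": np.nan,
            "lag_ms": np.nan, "class": hfo_class(freq_hz)}


def _ied_atom(fs_hz: float, width_ms: float, amplitude: float,
              slow_wave: bool):
    """Spike-wave atom.  ``amplitude`` is the peak of the sharp
    difference-of-Gaussians spike; a Hann-windowed 70 Hz fast-activity
    component at 0.4x that amplitude spans ``width_ms`` (a smooth spike
    alone carries almost no 60-80 Hz energy, so this component is what the
    NSS detector measures, and its extent realizes the event width); an
    optional half-sine slow wave follows.

    Returns (samples, offset_of_spike_peak_in_samples).
    """
    w = width_ms * 1e-3
    sigma1 = min(0.005, w / 12.0)
    sigma2 = 2.5 * sigma1
    half = w / 2.0
    tail = 1.5 * w if slow_wave else 0.0
    t = np.arange(-half, half + tail + 1.0 / fs_hz, 1.0 / fs_hz)
    spike = np.exp(-t ** 2 / (2 * sigma1 ** 2)) \
        - 0.6 * np.exp(-t ** 2 / (2 * sigma2 ** 2))
    spike *= amplitude / np.max(np.abs(spike))
    rider = np.where(np.abs(t) <= half,
                     np.cos(np.pi * t / w) ** 2
                     * np.sin(2 * np.pi * 70.0 * t), 0.0) * 0.4 * amplitude
    wave = np.zeros_like(t)
    if slow_wave:
        in_tail = (t > half) & (t <= half + tail)
        wave[in_tail] = -0.5 * amplitude * np.sin(
            np.pi * (t[in_tail] - half) / tail)
    atom = spike + rider + wave
    return atom, int(round(half * fs_hz))


def inject_ied_transient(recording: LfpRecording, channel, time_s: float,
                         amplitude: float, width_ms: float = 100.0,
                         slow_wave: bool = True) -> dict:
    """Add a spike-wave IED transient centered (spike peak) at ``time_s``;
    returns the truth record.  Widths outside 30-250 ms are permitted and
    tagged ``subthreshold_duration`` as negative controls."""
    ci = recording.channel_index(channel)
    atom, center = _ied_atom(recording.fs_hz, width_ms, amplitude, slow_wave)
    a = int(round(time_s * recording.fs_hz)) - center
    if a < 0 or a + atom.size > recording.n_samples:
        raise OutOfRangeError(
            f"IED at {time_s:.3f} s extends past the recording")
    recording.data[ci, a:a + atom.size] += atom
    tag = "" if 30.0 <= width_ms <= 250.0 else "subthreshold_duration"
    return {"channel": recording.channels[ci], "time_s": time_s,
            "amplitude": amplitude, "width_ms": width_ms, "tag": tag}


# ---------------------------------------------------------------------------
# coupled sessions
# ---------------------------------------------------------------------------

def generate_event_times(config: SimulationConfig,
                         rng: np.random.Generator | None = None):
    """Draw IED anchor times and (coupled + uncoupled) HFO records without
    rendering any waveform.

    IEDs are a homogeneous Poisson process at ``ied_rate_per_min`` within
    NREM intervals; each IED independently triggers one HFO with
    probability ``coupling_prob`` at lag ~ N(lag, jitter); uncoupled HFOs
    form an independent Poisson process over the same intervals.

    Returns ``(ied_times, hfo_records, n_dropped)`` for the first channel.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    nrem = [s for s in config.state_intervals() if s.label == "NREM"]
    if not nrem and (config.ied_rate_per_min > 0
                     or config.hfo_rate_per_min > 0):
        raise ConfigurationError(
            "nonzero event rates with an empty NREM schedule")
    margin = 0.5  # s, keeps atoms clear of recording/interval edges

    def poisson_times(rate_per_min):
        times = []
        for s in nrem:
            lo, hi = s.start_s + margin, s.end_s - margin
            if hi <= lo:
                continue
            n = rng.poisson(rate_per_min * (hi - lo) / 60.0)
            times.extend(rng.uniform(lo, hi, size=n))
        return np.sort(np.array(times))

    ied_times = poisson_times(config.ied_rate_per_min)

    def draw_freq():
        if rng.uniform() < config.ripple_fraction:
            return rng.uniform(100.0, 180.0)
        return rng.uniform(220.0, 400.0)

    hfo_records = []
    dropped = 0
    lo_ok, hi_ok = margin, config.duration_s - margin
    for t_ied in ied_times:
        if rng.uniform() >= config.coupling_prob:
            continue
        placed = False
        for _ in range(2):  # one redraw when the lag leaves the recording
            lag = rng.normal(config.coupling_lag_ms, config.coupling_jitter_ms)
            t = t_ied + lag * 1e-3
            if lo_ok <= t <= hi_ok:
                hfo_records.append({"time_s": t, "freq_hz": draw_freq(),
                                    "triggered_by_ied": True,
                                    "parent_ied_time_s": t_ied,
                                    "lag_ms": lag})
                placed = True
                break
        if not placed:
            dropped += 1
    for t in poisson_times(config.hfo_rate_per_min):
        hfo_records.append({"time_s": t, "freq_hz": draw_freq(),
                            "triggered_by_ied": False,
                            "parent_ied_time_s": np.nan, "lag_ms": np.nan})
    hfo_records.sort(key=lambda r: r["time_s"])
    return ied_times, hfo_records, dropped


def generate_coupled_session(config: SimulationConfig
                             ) -> tuple[LfpRecording, SimulationTruth]:
    """Render a full synthetic session: background + injected IED and HFO
    atoms on every channel, with per-channel independent event draws."""
    config.validate()
    rec = generate_background(config)
    rng = np.random.default_rng(config.seed + 1)

    ied_rows, hfo_rows = [], []
    dropped_total = 0
    for ci, name in enumerate(rec.channels):
        env_sd = band_envelope_sd(rec.data[ci], rec.fs_hz, 80.0, 520.0)
        hfo_amp = config.hfo_snr * env_sd
        ied_amp = config.ied_snr * float(np.std(rec.data[ci]))
        ied_times, hfo_records, dropped = generate_event_times(config, rng)
        dropped_total += dropped
        for t in ied_times:
            ied_rows.append(inject_ied_transient(
                rec, ci, t, ied_amp, config.ied_width_ms,
                config.ied_slow_wave))
        for r in hfo_records:
            truth = inject_hfo_burst(rec, ci, r["time_s"], r["freq_hz"],
                                     config.hfo_n_cycles, hfo_amp)
            truth.update({k: r[k] for k in ("triggered_by_ied",
                                            "parent_ied_time_s", "lag_ms")})
            hfo_rows.append(truth)

    ied_df = pd.DataFrame(ied_rows, columns=["channel", "time_s", "amplitude",
                                             "width_ms", "tag"])
    hfo_df = pd.DataFrame(hfo_rows, columns=["channel", "time_s", "freq_hz",
                                             "n_cycles", "amplitude",
                                             "triggered_by_ied",
                                             "parent_ied_time_s", "lag_ms",
                                             "class"])
    return rec, SimulationTruth(ied=ied_df, hfo=hfo_df,
                                dropped_couplings=dropped_total)


def generate_behavior_scores(coupling_values, slope: float, intercept: float,
                             noise_sd: float, seed: int | None = None
                             ) -> np.ndarray:
    """Completion times y_i = intercept + slope*h_i + N(0, noise_sd^2)."""
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    h = np.asarray(coupling_values, float)
    rng = np.random.default_rng(seed)
    return intercept + slope * h + rng.normal(0.0, noise_sd, size=h.size)
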