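"""Recording/event/state containers and their on-disk contracts.

Two signal formats are supported:

* **fixture** — the canonical lossless medium: one little-endian float32
  binary per channel plus a JSON sidecar with sampling rate, channel/region
  labels and sleep-state intervals.  Round-trips bit-exactly.
* **EDF** — the interchange standard for continuous neurophysiology.
  Reading goes through :mod:`mne`; writing uses a minimal 16-bit EDF
  encoder (EDF is quantized, so EDF round-trips are only exact to the
  16-bit step).

All public times are seconds; intervals are half-open ``[start, end)``;
sample ``k`` occupies ``[k/fs, (k+1)/fs)``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError, ValidationError

REGIONS = ("striatum", "mPFC", "hippocampus", "thalamus", "other")
STATE_LABELS = ("NREM", "REM", "WAKE")

EVENT_REQUIRED_COLUMNS = (
    "channel", "region", "kind", "start_s", "end_s", "peak_time_s")


@dataclass(frozen=True)
class StateInterval:
    """A sleep/wake state annotation, half-open in seconds."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.label not in STATE_LABELS:
            raise ValidationError(
                f"unknown state {self.label!r}; allowed: {STATE_LABELS}")
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"state interval requires start < end, got "
                f"[{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass
class LfpRecording:
    """Continuous multi-channel local field potential recording.

    Attributes
    ----------
    data : float array, shape (n_channels, n_samples), signal units (µV).
    fs_hz : sampling rate, samples/second.
    channels : ordered channel names.
    regions : brain region per channel, from :data:`REGIONS`.
    start_time_s : recording start time (default 0).
    states : sleep-state intervals on the same time base.
    """

    data: np.ndarray
    fs_hz: float
    channels: list[str]
    regions: list[str]
    start_time_s: float = 0.0
    states: list[StateInterval] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs_hz <= 0:
            raise ConfigurationError(f"fs_hz must be > 0, got {self.fs_hz}")
        if self.data.size == 0:
            raise ValidationError("empty recording (0 samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} channel labels for "
                f"{self.data.shape[0]} channels of data")
        if len(self.regions) != len(self.channels):
            raise ValidationError("regions must match channels 1:1")
        for r in self.regions:
            if r not in REGIONS:
                raise ValidationError(
                    f"unknown region {r!r}; allowed regions: {REGIONS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel_index(self, channel: str | int) -> int:
        if isinstance(channel, (int, np.integer)):
            return int(channel)
        return self.channels.index(channel)

    def state_intervals(self, labels) -> list[StateInterval]:
        labels = {labels} if isinstance(labels, str) else set(labels)
        return [s for s in self.states if s.label in labels]

    def state_sample_slices(self, labels) -> list[slice]:
        """Sample-index slices covered by the requested states.

        A sample k belongs to an interval iff k/fs lies in [start, end).
        """
        out = []
        for s in self.state_intervals(labels):
            a = max(0, math.ceil((s.start_s - self.start_time_s) * self.fs_hz))
            b = min(self.n_samples,
                    math.ceil((s.end_s - self.start_time_s) * self.fs_hz))
            if b > a:
                out.append(slice(a, b))
        return out

    def copy(self) -> "LfpRecording":
        return replace(self, data=self.data.copy(),
                       channels=list(self.channels),
                       regions=list(self.regions),
                       states=list(self.states))


# ---------------------------------------------------------------------------
# fixture format
# ---------------------------------------------------------------------------

def write_recording(recording: LfpRecording, path, format: str = "fixture"):
    """Write a recording; ``format`` is 'fixture' (lossless) or 'edf'."""
    if format == "fixture":
        _write_fixture(recording, Path(path))
    elif format == "edf":
        _write_edf(recording, Path(path))
    else:
        raise ConfigurationError(f"unknown format {format!r}")


def read_recording(path, format: str = "fixture") -> LfpRecording:
    if format == "fixture":
        return _read_fixture(Path(path))
    if format == "edf":
        return _read_edf(Path(path))
    raise ConfigurationError(f"unknown format {format!r}")


def _write_fixture(rec: LfpRecording, root: Path):
    root.mkdir(parents=True, exist_ok=True)
    header = {
        "fs_hz": rec.fs_hz,
        "channels": rec.channels,
        "regions": rec.regions,
        "start_time_s": rec.start_time_s,
        "n_samples": rec.n_samples,
        "states": [[s.label, s.start_s, s.end_s] for s in rec.states],
        "dtype": "<f4",
    }
    (root / "recording.json").write_text(json.dumps(header, indent=1))
    for i, name in enumerate(rec.channels):
        rec.data[i].astype("<f4").tofile(root / f"{name}.f32")


def _read_fixture(root: Path) -> LfpRecording:
    header_path = root / "recording.json"
    if not header_path.exists():
        raise FileNotFoundError(f"no fixture header at {header_path}")
    header = json.loads(header_path.read_text())
    data = np.stack([
        np.fromfile(root / f"{name}.f32", dtype="<f4").astype(np.float64)
        for name in header["channels"]])
    states = [StateInterval(lbl, a, b) for lbl, a, b in header["states"]]
    return LfpRecording(data=data, fs_hz=header["fs_hz"],
                        channels=header["channels"],
                        regions=header["regions"],
                        start_time_s=header["start_time_s"], states=states)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _write_edf(rec: LfpRecording, path: Path):
    """Minimal EDF writer: 16-bit, one data record per second.

    Channel labels are stored as ``name::region`` and must fit EDF's
    16-character label field.
    """
    fs = rec.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ConfigurationError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    labels = []
    for name, region in zip(rec.channels, rec.regions):
        lab = f"{name}::{region}"
        if len(lab) > 16:
            raise ValidationError(
                f"EDF channel label {lab!r} exceeds 16 characters")
        labels.append(lab)

    n_rec = math.ceil(rec.n_samples / fs)
    nchan = rec.n_channels
    pad = n_rec * fs - rec.n_samples
    data = np.pad(rec.data, ((0, 0), (0, pad)))

    phys_max = float(np.max(np.abs(data))) or 1.0
    dig_max, dig_min = 32767, -32768
    scale = dig_max / phys_max
    digital = np.clip(np.round(data * scale), dig_min, dig_max).astype("<i2")

    def f(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8), f("synthetic", 80), f("lfp recording", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(256 + 256 * nchan, 8), f("", 44), f(n_rec, 8), f("1", 8), f(nchan, 4),
    ])
    header += b"".join(f(lab, 16) for lab in labels)
    header += b"".join(f("AgAgCl electrode", 80) for _ in labels)
    header += b"".join(f("uV", 8) for _ in labels)
    header += b"".join(f(f"{-phys_max:.6g}"[:8], 8) for _ in labels)
    header += b"".join(f(f"{phys_max:.6g}"[:8], 8) for _ in labels)
    header += b"".join(f(dig_min, 8) for _ in labels)
    header += b"".join(f(dig_max, 8) for _ in labels)
    header += b"".join(f("", 80) for _ in labels)
    header += b"".join(f(fs, 8) for _ in labels)
    header += b"".join(f("", 32) for _ in labels)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            chunk = digital[:, r * fs:(r + 1) * fs]
            fh.write(chunk.tobytes())


def _read_edf(path: Path) -> LfpRecording:
    import mne
    # reject mixed per-channel sampling rates before mne resamples silently
    with open(path, "rb") as fh:
        header = fh.read(256)
        nchan = int(header[252:256].decode("ascii").strip())
        per_chan = fh.read(nchan * 256)
    ns_block = per_chan[nchan * 216:nchan * 224]
    ns = {int(ns_block[i * 8:(i + 1) * 8].decode("ascii").strip())
          for i in range(nchan)}
    if len(ns) > 1:
        raise ValidationError(
            f"mixed sampling rates in EDF are unsupported (got {sorted(ns)} "
            "samples per record)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs_set = {float(raw.info["sfreq"])}
    if len(fs_set) != 1:
        raise ValidationError("mixed sampling rates are unsupported")
    channels, regions = [], []
    for lab in raw.ch_names:
        if "::" in lab:
            name, region = lab.rsplit("::", 1)
        else:
            name, region = lab, "other"
        if region not in REGIONS:
            raise ValidationError(
                f"unknown region tag {region!r} in channel {lab!r}; "
                f"allowed regions: {REGIONS}")
        channels.append(name)
        regions.append(region)
    # mne stores EEG data in volts; recover the file's physical unit (µV)
    data = raw.get_data() * 1e6
    return LfpRecording(data=data, fs_hz=float(raw.info["sfreq"]),
                        channels=channels, regions=regions)


# ---------------------------------------------------------------------------
# event tables / state tables
# ---------------------------------------------------------------------------

def write_events(events: pd.DataFrame, path):
    """Write an event table as TSV (header always present)."""
    validate_events(events, allow_empty=True)
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    validate_events(df, allow_empty=True)
    return df


def validate_events(df: pd.DataFrame, allow_empty: bool = True) -> pd.DataFrame:
    missing = [c for c in EVENT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"event table missing required columns: {missing}")
    if len(df):
        bad = df[(df.end_s < df.start_s)
                 | (df.peak_time_s < df.start_s)
                 | (df.peak_time_s > df.end_s)]
        if len(bad):
            raise ValidationError(
                f"{len(bad)} event rows violate start <= peak <= end "
                f"(first bad row index {bad.index[0]})")
    elif not allow_empty:
        raise ValidationError("empty event table")
    return df


def write_states(states: list[StateInterval], path):
    pd.DataFrame([(s.label, s.start_s, s.end_s) for s in states],
                 columns=["label", "start_s", "end_s"]).to_csv(
        path, sep="\t", index=False)


def read_states(path) -> list[StateInterval]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("label", "start_s", "end_s") if c not in df.columns]
    if missing:
        raise SchemaError(f"state table missing columns: {missing}")
    return [StateInterval(r.label, r.start_s, r.end_s)
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved configuration for every pipeline stage."""

    hfo: "HfoDetectionConfig"
    ied: "IedDetectionConfig"
    coupling: "PethConfig"


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML/JSON config; unknown keys are rejected, every threshold
    resolves to its documented default when absent."""
    from .hfo import HfoDetectionConfig
    from .ied import IedDetectionConfig
    from .coupling import PethConfig

    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        doc = yaml.safe_load(text) or {}
    if overrides:
        for section, vals in overrides.items():
            doc.setdefault(section, {}).update(vals)

    known_sections = {"hfo": HfoDetectionConfig, "ied": IedDetectionConfig,
                      "coupling": PethConfig}
    unknown = set(doc) - set(known_sections)
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")

    built = {}
    for section, cls in known_sections.items():
        vals = doc.get(section) or {}
        fields = {f for f in cls.__dataclass_fields__}
        bad = set(vals) - fields
        if bad:
            raise ConfigurationError(
                f"unknown keys in section {section!r}: {sorted(bad)}")
        cfg = cls(**vals)
        cfg.validate()
        built[section] = cfg
    return PipelineConfig(**built)
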