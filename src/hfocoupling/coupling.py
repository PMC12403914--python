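"""IED-HFO coupling: peri-event time histogram (PETH), Shannon-entropy
coupling strength, bootstrap significance.

IED timestamps are the anchors (time = 0); HFO occurrences within a
+/- 500 ms window are binned relative to each anchor.  With bin
probabilities p_i over N bins, the entropy is S = -sum p_i ln p_i, its
maximum is S_max = ln N (uniform histogram), and the coupling strength is

    h = (S_max - S) / S_max,

0 for no temporal structure, 1 for perfect lag locking.  Significance is
assessed against surrogates that circularly time-shift the HFO stream,
which preserves both streams' own structure while destroying their
cross-dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError


@dataclass
class PethConfig:
    """PETH geometry and surrogate settings."""

    window_ms: float = 500.0   # half-width of the peri-event window
    bin_width_ms: float = 10.0
    n_boot: int = 1000
    #: null model for the bootstrap.  "uniform_lags" redraws the observed
    #: number of in-window lags uniformly (conditions on the co-occurrence
    #: count, so the entropy statistic's small-count bias cancels exactly);
    #: "circular_shift" shifts the whole event stream (preserves both
    #: streams' structure but lets the in-window count vary, which at low
    #: event rates biases the null toward high h); "poisson_redraw" redraws
    #: the event stream as a homogeneous Poisson process.
    surrogate: str = "uniform_lags"

    def validate(self):
        if self.window_ms <= 0 or self.bin_width_ms <= 0:
            raise ConfigurationError("window and bin width must be > 0")
        n = 2.0 * self.window_ms / self.bin_width_ms
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "window_ms must be divisible by bin_width_ms")
        if round(n) < 2:
            raise ConfigurationError("need at least 2 bins")
        if self.surrogate not in ("uniform_lags", "circular_shift",
                                  "poisson_redraw"):
            raise ConfigurationError(f"unknown surrogate {self.surrogate!r}")
        return self

    @property
    def n_bins(self) -> int:
        return int(round(2.0 * self.window_ms / self.bin_width_ms))


@dataclass
class Peth:
    """Binned peri-event time histogram."""

    counts: np.ndarray                 # int, length N
    edges_ms: np.ndarray               # length N+1, ms relative to anchor
    n_anchors: int
    window_ms: float
    bin_width_ms: float

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def n_events_in_window(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray | None:
        """Counts normalized to sum 1; None when no event fell in-window."""
        total = self.counts.sum()
        if total == 0:
            return None
        return self.counts / total


def build_peth(anchor_times, event_times, window_ms: float = 500.0,
               bin_width_ms: float = 10.0) -> Peth:
    """Bin event lags (event - anchor) relative to every anchor.

    Bins are half-open: a lag l falls in bin i iff
    ``edges[i] <= l < edges[i+1]``; lags of exactly +window_ms are excluded.
    """
    cfg = PethConfig(window_ms=window_ms, bin_width_ms=bin_width_ms).validate()
    anchors = np.sort(np.asarray(anchor_times, float))
    events = np.sort(np.asarray(event_times, float))
    if anchors.size == 0:
        raise ValidationError("PETH requires at least one anchor")
    n = cfg.n_bins
    w = window_ms * 1e-3
    bw = bin_width_ms * 1e-3
    counts = np.zeros(n, dtype=np.int64)
    lo = np.searchsorted(events, anchors - w, side="left")
    hi = np.searchsorted(events, anchors + w, side="left")
    for a, i0, i1 in zip(anchors, lo, hi):
        if i1 > i0:
            lags = events[i0:i1] - a
            idx = np.floor((lags + w) / bw).astype(int)
            idx = idx[(idx >= 0) & (idx < n)]
            np.add.at(counts, idx, 1)
    edges = np.linspace(-window_ms, window_ms, n + 1)
    return Peth(counts=counts, edges_ms=edges, n_anchors=anchors.size,
                window_ms=window_ms, bin_width_ms=bin_width_ms)


def pool_peths(peths: list[Peth]) -> Peth:
    """Sum counts across sessions' PETHs of identical geometry (events are
    pooled across recordings before the entropy is taken, which keeps the
    small-count bias of the entropy statistic negligible)."""
    if not peths:
        raise ValidationError("no PETHs to pool")
    first = peths[0]
    for p in peths[1:]:
        if (p.n_bins != first.n_bins or p.window_ms != first.window_ms
                or p.bin_width_ms != first.bin_width_ms):
            raise ValidationError("PETH geometries differ; cannot pool")
    return Peth(counts=np.sum([p.counts for p in peths], axis=0),
                edges_ms=first.edges_ms,
                n_anchors=sum(p.n_anchors for p in peths),
                window_ms=first.window_ms, bin_width_ms=first.bin_width_ms)


def shannon_entropy(p) -> float:
    """S = -sum p_i ln p_i in nats, with 0*ln(0) = 0."""
    p = np.asarray(p, float)
    if np.any(p < 0):
        raise ValidationError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"probabilities must sum to 1, got {p.sum()}")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def coupling_strength(peth: Peth) -> float:
    """h = (ln N - S)/ln N over all N bins (empty bins contribute 0 to S).

    An empty-window PETH yields h = 0 (no measurable structure)."""
    if peth.n_bins < 2:
        raise ConfigurationError("coupling strength needs at least 2 bins")
    p = peth.probabilities
    if p is None:
        return 0.0
    s_max = np.log(peth.n_bins)
    return float((s_max - shannon_entropy(p)) / s_max)


@dataclass
class CouplingResult:
    """Observed coupling strength and its bootstrap null distribution."""

    entropy: float                 # S, nats
    max_entropy: float             # ln N, nats
    strength: float                # h in [0, 1]
    n_boot: int
    boot_null: np.ndarray = field(repr=False)
    p_boot: float | None = None
    undefined: bool = False        # True when fewer than 2 in-window events
    seed: int | None = None


def bootstrap_significance(anchor_times, event_times, span_s: float,
                           config: PethConfig | None = None,
                           n_boot: int | None = None,
                           seed: int | None = None) -> CouplingResult:
    """Observed h plus a surrogate null distribution (see
    :class:`PethConfig.surrogate` for the null models).

    ``p_boot = (1 + #{h_surrogate >= h_observed}) / (n_boot + 1)``.
    """
    config = (config or PethConfig()).validate()
    n_boot = config.n_boot if n_boot is None else n_boot
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    anchors = np.sort(np.asarray(anchor_times, float))
    events = np.sort(np.asarray(event_times, float))
    if span_s <= 0 or (events.size and events.max() >= span_s) \
            or (anchors.size and anchors.max() >= span_s):
        raise ValidationError("span_s must cover all event/anchor times")

    peth = build_peth(anchors, events, config.window_ms, config.bin_width_ms)
    s_max = float(np.log(peth.n_bins))
    p = peth.probabilities
    s = shannon_entropy(p) if p is not None else s_max
    h_obs = coupling_strength(peth)

    if events.size < 2:
        return CouplingResult(entropy=s, max_entropy=s_max, strength=h_obs,
                              n_boot=0, boot_null=np.empty(0), p_boot=None,
                              undefined=True, seed=seed)

    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    rate = events.size / span_s
    n_bins = peth.n_bins
    n_in = peth.n_events_in_window
    for k in range(n_boot):
        if config.surrogate == "uniform_lags":
            counts = rng.multinomial(n_in, np.full(n_bins, 1.0 / n_bins))
            sp = Peth(counts=counts, edges_ms=peth.edges_ms,
                      n_anchors=peth.n_anchors, window_ms=config.window_ms,
                      bin_width_ms=config.bin_width_ms)
        else:
            if config.surrogate == "circular_shift":
                surr = np.sort((events + rng.uniform(0.0, span_s)) % span_s)
            else:
                m = rng.poisson(rate * span_s)
                surr = np.sort(rng.uniform(0.0, span_s, size=m))
            sp = build_peth(anchors, surr, config.window_ms,
                            config.bin_width_ms)
        null[k] = coupling_strength(sp)
    p_boot = (1.0 + np.count_nonzero(null >= h_obs)) / (n_boot + 1.0)
    return CouplingResult(entropy=s, max_entropy=s_max, strength=h_obs,
                          n_boot=n_boot, boot_null=null, p_boot=float(p_boot),
                          undefined=peth.n_events_in_window == 0, seed=seed)
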