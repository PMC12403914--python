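"""IED detector: NSS preprocessing, thresholds, entropy shape filter."""

import numpy as np
import pandas as pd
import pytest

import hfocoupling as hc
from hfocoupling import ied as I
from hfocoupling.errors import ConfigurationError, ValidationError

FS = 3000.0


def brute_force_candidates(nss, fs, cfg):
    """Sample-wise reimplementation of the candidate contract."""
    out = []
    i, n = 0, nss.size
    while i < n:
        if nss[i] > cfg.onset_sd:
            a = i
            while i < n and nss[i] > cfg.onset_sd:
                i += 1
            b = i
            peak = float(np.max(nss[a:b]))
            dur_ms = (b - a) / fs * 1e3
            if peak < cfg.peak_sd:
                reason = "low_peak"
            elif not cfg.min_duration_ms <= dur_ms <= cfg.max_duration_ms:
                reason = "duration"
            else:
                reason = ""
            out.append((a, b, reason))
        else:
            i += 1
    return out


class TestPreprocess:
    def test_resampled_length(self):
        rng = np.random.default_rng(0)
        ns = hc.preprocess_nss(rng.standard_normal(int(10 * FS)), FS)
        assert ns.nss.size == 12_500
        assert ns.fs_hz == 1250.0

    def test_pure_tone_gives_flat_nss(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 70.0 * t)
        ns = hc.preprocess_nss(x, FS)
        raw = ns.nss * ns.baseline_sd + ns.baseline_mean  # undo normalization
        core = raw[int(1.0 * 1250):-int(1.0 * 1250)]
        assert np.std(core) / np.mean(core) < 0.10

    def test_all_zeros_degenerate_baseline(self):
        with pytest.raises(ValidationError, match="degenerate"):
            hc.preprocess_nss(np.zeros(int(5 * FS)), FS)

    def test_fs_below_resample_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            hc.preprocess_nss(np.zeros(5000), 1000.0)


class TestCandidates:
    def _session_with_ieds(self, widths_amps, seconds=30.0, seed=2):
        cfg = hc.SimulationConfig(duration_s=seconds, seed=seed,
                                  ied_rate_per_min=0, hfo_rate_per_min=0)
        rec = hc.generate_background(cfg)
        bb = float(np.std(rec.data[0]))
        times = np.linspace(3.0, seconds - 5.0, len(widths_amps))
        for t, (w, snr) in zip(times, widths_amps):
            hc.inject_ied_transient(rec, 0, t, amplitude=snr * bb, width_ms=w)
        return rec, times

    def test_threshold_and_duration_semantics(self):
        # strong 100 ms event accepted; weak one low_peak; overlong duration
        rec, times = self._session_with_ieds(
            [(100.0, 6.0), (100.0, 2.0), (400.0, 6.0)])
        ev = hc.detect_ieds(rec, states_filter=("NREM",), keep_rejected=True)

        def near(t):
            m = ev[(ev.peak_time_s - t).abs() < 0.25]
            return m
        strong = near(times[0])
        assert (strong.accepted).any()
        weak = near(times[1])
        assert not weak.accepted.any()
        if len(weak):
            assert set(weak.rejection_reason) <= {"low_peak"}
        overlong = near(times[2])
        assert not overlong.accepted.any()
        assert "duration" in set(overlong.rejection_reason)

    def test_oracle_equivalence_on_short_inputs(self):
        cfg = I.IedDetectionConfig()
        for seed in range(5):
            rec, _ = self._session_with_ieds(
                [(100.0, 6.0), (60.0, 4.0)], seconds=10.0, seed=seed)
            ns = hc.preprocess_nss(rec.data[0], FS)
            got = I.detect_ied_candidates(ns, cfg)
            want = brute_force_candidates(ns.nss, ns.fs_hz, cfg)
            assert len(got) == len(want)
            for row, (a, b, reason) in zip(got.itertuples(), want):
                assert (row.start_idx, row.stop_idx) == (a, b)
                assert row.rejection_reason == reason

    def test_threshold_monotonicity(self):
        # lowering onset_sd / peak_sd never decreases accepted-event count
        rec, _ = self._session_with_ieds(
            [(100.0, 6.0), (80.0, 3.0), (120.0, 1.5)], seconds=40.0)
        counts = []
        for peak_sd in (30.0, 20.0, 10.0):
            cfg = I.IedDetectionConfig(peak_sd=peak_sd)
            ev = hc.detect_ieds(rec, cfg, states_filter=("NREM",))
            counts.append(len(ev))
        assert counts == sorted(counts)

    def test_scale_invariance(self):
        rec, _ = self._session_with_ieds([(100.0, 6.0), (70.0, 5.0)])
        scaled = rec.copy()
        scaled.data = scaled.data * 0.013
        a = hc.detect_ieds(rec, states_filter=("NREM",))
        b = hc.detect_ieds(scaled, states_filter=("NREM",))
        assert len(a) == len(b)
        np.testing.assert_allclose(a.peak_nss_sd.values, b.peak_nss_sd.values,
                                   rtol=1e-9)


class TestEntropyShapeFilter:
    def _wrap(self, profile):
        ns = I.NormalizedSignal(nss=np.asarray(profile, float), fs_hz=1250.0,
                                baseline_mean=0.0, baseline_sd=1.0)
        cands = pd.DataFrame([{
            "start_idx": 0, "stop_idx": len(profile), "peak_idx":
            int(np.argmax(profile)), "peak_nss_sd": float(np.max(profile)),
            "duration_ms": len(profile) / 1.25, "accepted": True,
            "rejection_reason": ""}])
        return I.entropy_shape_filter(cands, ns)

    def test_triangular_profile_kept(self):
        profile = np.r_[np.linspace(0, 30, 50), np.linspace(30, 0, 50)]
        out = self._wrap(profile)
        assert bool(out.accepted.iloc[0])
        # independent direct evaluation of the entropy formula
        p = np.histogram(np.arange(100), bins=10, weights=profile)[0]
        p = p / p.sum()
        s_direct = float(-(p[p > 0] * np.log(p[p > 0])).sum())
        assert out.shape_entropy.iloc[0] == pytest.approx(s_direct, rel=1e-9)

    def test_flat_plateau_rejected_with_max_entropy(self):
        out = self._wrap(np.full(100, 25.0))
        assert not bool(out.accepted.iloc[0])
        assert out.rejection_reason.iloc[0] == "shape_entropy"
        # uniform profile attains the ln(N_bins) maximum
        assert out.shape_entropy.iloc[0] == pytest.approx(np.log(10))

    def test_degenerate_segment_rejected(self):
        ns = I.NormalizedSignal(nss=np.array([30.0]), fs_hz=1250.0,
                                baseline_mean=0.0, baseline_sd=1.0)
        cands = pd.DataFrame([{
            "start_idx": 0, "stop_idx": 1, "peak_idx": 0,
            "peak_nss_sd": 30.0, "duration_ms": 0.8, "accepted": True,
            "rejection_reason": ""}])
        out = I.entropy_shape_filter(cands, ns)
        assert out.rejection_reason.iloc[0] == "degenerate"

    def test_empty_candidate_list_passes_through(self):
        ns = I.NormalizedSignal(nss=np.zeros(100), fs_hz=1250.0,
                                baseline_mean=0.0, baseline_sd=1.0)
        out = I.entropy_shape_filter(I.detect_ied_candidates(ns), ns)
        assert len(out) == 0


class TestPipeline:
    def test_rejection_reasons_unique(self):
        cfg = hc.SimulationConfig(duration_s=120.0, seed=8)
        rec, _ = hc.generate_coupled_session(cfg)
        ev = hc.detect_ieds(rec, states_filter=("NREM",), keep_rejected=True)
        rejected = ev[~ev.accepted]
        assert set(rejected.rejection_reason) <= {
            "low_peak", "duration", "shape_entropy", "degenerate"}
        assert (rejected.rejection_reason != "").all()

    def test_state_mask_excludes_rem(self):
        cfg = hc.SimulationConfig(
            duration_s=600.0, seed=44,
            state_schedule=(("NREM", 5.0), ("REM", 5.0)))
        rec, truth = hc.generate_coupled_session(cfg)
        ev = hc.detect_ieds(rec, states_filter=("NREM",))
        nrem = [s for s in rec.states if s.label == "NREM"]
        for t in ev.peak_time_s:
            assert any(s.contains(t) for s in nrem)
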