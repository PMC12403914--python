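"""HFO detector: filtering, candidate logic, rejection stages, pipeline."""

import numpy as np
import pytest

import hfocoupling as hc
from hfocoupling import hfo as H
from hfocoupling.errors import ConfigurationError, ValidationError

FS = 3000.0


def brute_force_candidates(env, fs, center, scale, cfg, filtered):
    """Independent sample-by-sample reimplementation of the candidate
    contract: high-threshold detection, low-threshold extent, dedup,
    gap-merge, duration floor."""
    thr_hi = center + cfg.k_env * scale
    thr_lo = center + cfg.k_edge * scale
    n = env.size
    exts = []
    i = 0
    while i < n:
        if env[i] > thr_hi:
            a = i
            while a > 0 and env[a - 1] > thr_lo:
                a -= 1
            b = i
            while b < n and env[b] > thr_lo:
                b += 1
            if (a, b) not in exts:
                exts.append((a, b))
            i = b
        else:
            i += 1
    gap = int(round(cfg.merge_gap_ms * 1e-3 * fs))
    merged = []
    for a, b in exts:
        if merged and a - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    out = []
    for a, b in merged:
        dur = (b - a) / fs
        zc = np.count_nonzero(np.diff(np.sign(filtered[a:b])) != 0)
        f_est = zc / (2 * dur) if dur > 0 else np.inf
        min_dur = cfg.min_duration_ms * 1e-3
        if f_est > 0:
            min_dur = max(min_dur, cfg.min_cycles / f_est)
        if dur >= min_dur:
            out.append((a, b))
    return out


class TestBandpassAndEnvelope:
    def test_in_band_tone_has_flat_envelope(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 150.0 * t)
        _, env = hc.bandpass_and_envelope(x, FS)
        core = env[int(0.3 * FS):-int(0.3 * FS)]
        assert np.max(np.abs(core - np.median(core))) / np.median(core) < 0.05

    def test_stop_band_tone_suppressed(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 30.0 * t)
        filt, _ = hc.bandpass_and_envelope(x, FS)
        core = filt[int(0.3 * FS):-int(0.3 * FS)]
        assert np.sqrt(np.mean(core ** 2)) < 0.01 * np.sqrt(np.mean(x ** 2))

    def test_white_noise_output_band_limited(self):
        # spectral-mass oracle: periodogram mass outside the band + rolloff
        from scipy.signal import welch
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(20 * FS))
        filt, _ = hc.bandpass_and_envelope(x, FS)
        f, p = welch(filt, fs=FS, nperseg=1 << 13)
        inside = p[(f >= 70) & (f <= 530)].sum()
        outside = p[(f < 60) | (f > 545)].sum()
        assert outside < 0.01 * inside

    def test_fs_too_low_rejected(self):
        with pytest.raises(ConfigurationError):
            hc.bandpass_and_envelope(np.zeros(4000), 1000.0)


class TestCandidates:
    def _setup(self, seconds=8.0, seed=1):
        cfg = hc.SimulationConfig(duration_s=seconds, seed=seed,
                                  ied_rate_per_min=0, hfo_rate_per_min=0)
        rec = hc.generate_background(cfg)
        return rec

    def test_flat_envelope_yields_no_candidates(self):
        hcfg = hc.HfoDetectionConfig()
        base = H.BaselineStats(center=1.0, scale=0.1,
                               strict_percentile_value=2.0,
                               tf_row_median=np.ones(hcfg.tf_n_freqs))
        base._threshold = 1.3
        env = np.zeros(3000)
        assert H.detect_candidate_epochs(env, FS, base, hcfg) == []

    def test_injected_burst_yields_one_covering_candidate(self):
        rec = self._setup()
        from hfocoupling.simulate import band_envelope_sd
        amp = 6 * band_envelope_sd(rec.data[0], FS, 80, 520)
        hc.inject_hfo_burst(rec, 0, 4.0, freq_hz=150.0, n_cycles=6,
                            amplitude=amp)
        hcfg = hc.HfoDetectionConfig()
        filt, env = H.bandpass_and_envelope(rec.data[0], FS)
        env = H.smooth_envelope(env, FS, hcfg)
        sls = [slice(0, env.size)]
        base = H.compute_baseline(env, filt, FS, sls, hcfg)
        cands = H.detect_candidate_epochs(env, FS, base, hcfg, filtered=filt)
        covering = [c for c in cands if c[0] / FS <= 4.0 <= c[1] / FS]
        assert len(covering) == 1

    def test_nearby_bursts_merged_by_gap_rule(self):
        rec = self._setup(seed=3)
        from hfocoupling.simulate import band_envelope_sd
        amp = 8 * band_envelope_sd(rec.data[0], FS, 80, 520)
        # two 20 ms bursts whose envelopes end/start ~5 ms apart
        hc.inject_hfo_burst(rec, 0, 4.000, 300.0, 6, amp)
        hc.inject_hfo_burst(rec, 0, 4.025, 300.0, 6, amp)
        hcfg = hc.HfoDetectionConfig()
        filt, env = H.bandpass_and_envelope(rec.data[0], FS)
        env = H.smooth_envelope(env, FS, hcfg)
        base = H.compute_baseline(env, filt, FS, [slice(0, env.size)], hcfg)
        cands = H.detect_candidate_epochs(env, FS, base, hcfg, filtered=filt)
        covering = [c for c in cands
                    if c[0] / FS < 4.0 and c[1] / FS > 4.025]
        assert len(covering) == 1

    def test_oracle_equivalence_with_sample_scan(self):
        # exact agreement with an independent brute-force threshold scan
        hcfg = hc.HfoDetectionConfig()
        for seed in range(5):
            rec = self._setup(seconds=8.0, seed=seed)
            from hfocoupling.simulate import band_envelope_sd
            amp = 6 * band_envelope_sd(rec.data[0], FS, 80, 520)
            rng = np.random.default_rng(seed)
            for t in rng.uniform(1.0, 7.0, size=4):
                hc.inject_hfo_burst(rec, 0, t, rng.uniform(100, 400), 6, amp)
            filt, env = H.bandpass_and_envelope(rec.data[0], FS)
            env = H.smooth_envelope(env, FS, hcfg)
            base = H.compute_baseline(env, filt, FS, [slice(0, env.size)],
                                      hcfg)
            got = H.detect_candidate_epochs(env, FS, base, hcfg,
                                            filtered=filt)
            want = brute_force_candidates(env, FS, base.center, base.scale,
                                          hcfg, filt)
            assert [tuple(c) for c in got] == [tuple(w) for w in want]


class TestRejectionStages:
    def test_sharp_ied_transient_rejected_as_sharp_or_nonbulb(self):
        cfg = hc.SimulationConfig(duration_s=20.0, seed=9,
                                  ied_rate_per_min=0, hfo_rate_per_min=0)
        rec = hc.generate_background(cfg)
        # a very large bare spike (no slow wave) leaks into the HFO band
        hc.inject_ied_transient(rec, 0, 10.0, amplitude=40.0, width_ms=60.0,
                                slow_wave=False)
        ev = hc.detect_hfos(rec, states_filter=("NREM",), keep_rejected=True)
        near = ev[(ev.peak_time_s > 9.9) & (ev.peak_time_s < 10.1)]
        assert len(near) >= 1
        assert (near.rejection_stage != "").all()

    def test_gabor_atom_retained_through_tf_stages(self, short_session):
        _, rec, truth = short_session
        ev = hc.detect_hfos(rec, states_filter=("NREM",))
        assert len(ev) > 0
        # every accepted event passed all stages
        assert (ev.rejection_stage == "").all()

    def test_degenerate_tf_map_rejected_low_power(self):
        hcfg = hc.HfoDetectionConfig()
        base = H.BaselineStats(center=0.5, scale=0.1,
                               strict_percentile_value=1.0,
                               tf_row_median=np.ones(hcfg.tf_n_freqs))
        tf = np.zeros((hcfg.tf_n_freqs, 100))
        verdict, _, _ = H.evaluate_candidate(tf, (20, 80), hcfg.tf_freqs(),
                                             base, hcfg)
        assert verdict == "low_power"

    def test_background_cleaning_monotone_in_amplitude(self):
        # acceptance must be monotone: once an amplitude is accepted, all
        # larger amplitudes are too
        cfg = hc.SimulationConfig(duration_s=30.0, seed=21,
                                  ied_rate_per_min=0, hfo_rate_per_min=0)
        base_rec = hc.generate_background(cfg)
        from hfocoupling.simulate import band_envelope_sd
        unit = band_envelope_sd(base_rec.data[0], FS, 80, 520)
        kept = []
        for snr in (1.0, 2.0, 4.0, 6.0, 8.0, 12.0):
            rec = base_rec.copy()
            hc.inject_hfo_burst(rec, 0, 15.0, 150.0, 6, snr * unit)
            ev = hc.detect_hfos(rec, states_filter=("NREM",))
            hit = ((ev.peak_time_s - 15.0).abs() < 0.05).any() \
                if len(ev) else False
            kept.append(bool(hit))
        first_kept = kept.index(True) if True in kept else len(kept)
        assert all(kept[first_kept:])


class TestClassification:
    @pytest.mark.parametrize("freq,label", [
        (150.0, "ripple"), (300.0, "fast_ripple"), (200.0, "fast_ripple"),
        (199.9, "ripple")])
    def test_boundary_rule(self, freq, label):
        assert hc.classify_hfo(freq) == label

    def test_out_of_band_frequency_rejected(self):
        with pytest.raises(ValidationError):
            hc.classify_hfo(50.0)


class TestPipeline:
    def test_scale_invariance(self, short_session):
        _, rec, _ = short_session
        scaled = rec.copy()
        scaled.data = scaled.data * 7.3
        a = hc.detect_hfos(rec, states_filter=("NREM",))
        b = hc.detect_hfos(scaled, states_filter=("NREM",))
        assert len(a) == len(b)
        np.testing.assert_allclose(a.peak_time_s.values, b.peak_time_s.values)
        np.testing.assert_allclose(a.peak_envelope_sd.values,
                                   b.peak_envelope_sd.values, rtol=1e-6)

    def test_state_mask_excludes_rem_events(self):
        cfg = hc.SimulationConfig(
            duration_s=600.0, seed=33, coupling_prob=0.0,
            state_schedule=(("NREM", 5.0), ("REM", 5.0)))
        rec, truth = hc.generate_coupled_session(cfg)
        ev = hc.detect_hfos(rec, states_filter=("NREM",))
        nrem = [s for s in rec.states if s.label == "NREM"]
        for t in ev.peak_time_s:
            assert any(s.contains(t) for s in nrem)

    def test_no_state_samples_warns_and_returns_empty(self, quiet_recording):
        rec = quiet_recording.copy()
        rec.states = [hc.StateInterval("WAKE", 0.0, rec.duration_s)]
        with pytest.warns(UserWarning):
            ev = hc.detect_hfos(rec, states_filter=("NREM",))
        assert len(ev) == 0
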