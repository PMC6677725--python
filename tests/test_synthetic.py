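"""Generator correctness: determinism, Poisson statistics, template shape,
LFP sink construction, and on-disk round-trips."""

import numpy as np
import pytest
from scipy import stats

from laminarsc import (
    GeneratorConfig, TrialEvents, generate_session, laminar_rate_template,
    sample_inhomogeneous_poisson, save_session, load_session, synth_lfp,
    synth_eye_velocity,
)
from laminarsc.csd import compute_csd, detect_reference_channel
from laminarsc.synthetic import _draw_events

NOMINAL = TrialEvents(0, "VG", 300.0, 1050.0, 1350.0, 750.0)


def _zero_rate_config(**kw):
    return GeneratorConfig(
        baseline_rate=0.0, visual_amp_max=0.0, visual_amp_floor=0.0,
        burst_rate_max=0.0, burst_rate_floor=0.0, delay_fraction=0.0,
        n_trials=5, **kw,
    )


class TestGenerateSession:
    def test_identical_seed_identical_bundle(self):
        cfg = GeneratorConfig(seed=1, n_trials=12)
        a = generate_session(cfg)
        b = generate_session(cfg)
        assert [e.__dict__ for e in a.events] == [e.__dict__ for e in b.events]
        for ch in range(cfg.n_channels):
            for ta, tb in zip(a.spikes[ch], b.spikes[ch]):
                np.testing.assert_array_equal(ta, tb)
        np.testing.assert_array_equal(a.lfp, b.lfp)

    def test_zero_rate_yields_empty_trains(self):
        bundle = generate_session(_zero_rate_config(seed=2))
        assert all(t.size == 0 for ch in bundle.spikes for t in ch)

    def test_event_invariants(self):
        cfg = GeneratorConfig(seed=9, n_trials=60)
        for ev in generate_session(cfg).events:
            assert ev.target_onset < ev.go_cue < ev.saccade_onset
            assert cfg.delay_range[0] <= ev.delay_duration <= cfg.delay_range[1]
            lat = ev.saccade_onset - ev.go_cue
            assert cfg.saccade_latency_range[0] <= lat <= cfg.saccade_latency_range[1]

    def test_spike_counts_match_rate_integral(self):
        """Counts in the visual epoch agree with the template integral and
        with an independent per-bin Poisson simulation of the same rate."""
        cfg = GeneratorConfig(seed=7, n_trials=250, task_mix={"VG": 1.0})
        bundle = generate_session(cfg)
        ch = cfg.reference_channel + cfg.visual_peak_channel
        lat = bundle.ground_truth["visual_latency"][ch - 1]
        counts = []
        for i in bundle.trials("VG"):
            ev = bundle.events[i]
            t0 = ev.target_onset + lat
            sp = bundle.spikes[ch - 1][i]
            counts.append(np.sum((sp >= t0) & (sp < t0 + 100.0)))
        observed = np.mean(counts)

        # oracle: direct Monte-Carlo of the closed-form rate, 1-ms bins
        rng = np.random.default_rng(999)
        tpl = laminar_rate_template(ch, "VG", cfg, NOMINAL)
        t0 = NOMINAL.target_onset + lat
        grid = np.arange(t0, t0 + 100.0)
        lam = tpl(grid + 0.5) / 1000.0
        oracle_counts = rng.poisson(lam, size=(4000, lam.size)).sum(axis=1)
        expected = oracle_counts.mean()
        sem = np.sqrt(expected / len(counts)) + oracle_counts.std() / np.sqrt(4000)
        assert abs(observed - expected) < 3.0 * sem


class TestRateTemplate:
    def test_visual_amp_max_at_peak_channel(self):
        cfg = GeneratorConfig()
        peak_ch = cfg.reference_channel + cfg.visual_peak_channel
        amps = [
            laminar_rate_template(ch, "VG", cfg, NOMINAL).visual_amp
            for ch in range(1, cfg.n_channels + 1)
        ]
        assert np.argmax(amps) + 1 == peak_ch
        assert amps[peak_ch - 1] == pytest.approx(cfg.visual_amp_max)

    def test_latency_span_dorsal_to_ventral(self):
        cfg = GeneratorConfig()
        most_ventral = laminar_rate_template(1, "VG", cfg, NOMINAL)
        most_dorsal = laminar_rate_template(cfg.n_channels, "VG", cfg, NOMINAL)
        span = most_ventral.visual_latency - most_dorsal.visual_latency
        assert span == pytest.approx(cfg.visual_latency_span)

    def test_burst_onset_synchronous(self):
        """The motor burst hinge sits at the same time on every channel."""
        cfg = GeneratorConfig()
        t_burst = NOMINAL.saccade_onset + cfg.burst_onset
        onsets = []
        for ch in range(1, cfg.n_channels + 1):
            tpl = laminar_rate_template(ch, "VG", cfg, NOMINAL)
            t = np.arange(t_burst - 40.0, NOMINAL.saccade_onset, 0.25)
            slope = np.diff(tpl(t)) / 0.25
            # hinge = first sample where the slope jumps above the ramp slope
            jump = np.flatnonzero(np.diff(slope) > 1e-6)
            onsets.append(t[jump[-1] + 1])
        assert np.ptp(onsets) <= 0.25 + 1e-9

    def test_mg_motor_peak_below_vg(self):
        cfg = GeneratorConfig()
        ch = cfg.reference_channel + cfg.motor_peak_channel
        vg = laminar_rate_template(ch, "VG", cfg, NOMINAL)
        mg = laminar_rate_template(ch, "MG", cfg, NOMINAL)
        assert mg.peak_rate < vg.peak_rate

    def test_rate_is_nonnegative_and_bounded(self):
        cfg = GeneratorConfig()
        tpl = laminar_rate_template(8, "VG", cfg, NOMINAL)
        t = np.arange(0.0, NOMINAL.saccade_onset + 150.0, 0.5)
        r = tpl(t)
        assert np.all(r >= 0)
        assert np.all(r <= tpl.max_rate + 1e-9)


class TestPoissonSampler:
    def test_zero_rate_empty(self, rng):
        out = sample_inhomogeneous_poisson(lambda t: 0 * t, 0, 1000, rng,
                                           max_rate=0.0)
        assert out.size == 0

    def test_unbounded_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_inhomogeneous_poisson(lambda t: t, 0, 1000, rng)

    def test_constant_rate_mean_count(self):
        counts = [
            sample_inhomogeneous_poisson(
                lambda t: np.full_like(t, 100.0), 0, 1000,
                np.random.default_rng(s), max_rate=100.0,
            ).size
            for s in range(1000)
        ]
        assert abs(np.mean(counts) - 100.0) < 3.0 * np.sqrt(100.0 / 1000.0)

    def test_time_rescaling_to_unit_exponential(self):
        """Rescaled ISIs under the true cumulative rate pass a KS test
        against Exp(1) in at least 95% of seeded runs."""
        passed = 0
        for s in range(100):
            rng = np.random.default_rng(10_000 + s)
            spikes = sample_inhomogeneous_poisson(
                lambda t: np.full_like(t, 100.0), 0, 2000, rng, max_rate=100.0
            )
            rescaled = np.diff(spikes * 0.1)  # Lambda(t) = 0.1 t
            p = stats.kstest(rescaled, "expon").pvalue
            passed += p >= 0.01
        assert passed >= 95


class TestSynthLfp:
    def test_noiseless_recovers_reference_exactly(self):
        cfg = GeneratorConfig(seed=3, n_trials=4, lfp_noise_uv=0.0)
        rng = np.random.default_rng(3)
        events = _draw_events(cfg, rng)
        lfp, t = synth_lfp(cfg, events, rng)
        prof = compute_csd(lfp.mean(axis=0), cfg.contact_spacing_um, time=t,
                          detection_window=(20, 170))
        assert detect_reference_channel(prof) == cfg.reference_channel
        assert not prof.flagged

    def test_pre_target_window_zero_mean(self):
        cfg = GeneratorConfig(seed=4, n_trials=50)
        rng = np.random.default_rng(4)
        events = _draw_events(cfg, rng)
        lfp, t = synth_lfp(cfg, events, rng)
        pre = lfp[:, :, t < 0]
        sem = pre.std() / np.sqrt(pre.size)
        assert abs(pre.mean()) < 3.0 * sem

    def test_linear_depth_profile_gives_zero_csd(self):
        depth = np.arange(16, dtype=float)
        lfp = np.outer(depth, np.ones(100)) * 7.0  # linear in depth, any time
        prof = compute_csd(lfp, 150.0)
        np.testing.assert_allclose(prof.matrix, 0.0, atol=1e-9)


class TestEyeVelocity:
    def test_crosses_threshold_at_saccade_onset(self):
        v = synth_eye_velocity(NOMINAL, n_samples=2000)
        first = int(np.flatnonzero(v >= 30.0)[0])
        assert abs(first - NOMINAL.saccade_onset) <= 1


class TestSessionIO:
    def test_round_trip(self, tmp_path):
        cfg = GeneratorConfig(seed=5, n_trials=6)
        bundle = generate_session(cfg)
        save_session(bundle, tmp_path / "s")
        loaded = load_session(tmp_path / "s")
        assert len(loaded.events) == len(bundle.events)
        for field in ("trial_id", "task", "target_in_rf"):
            assert getattr(loaded.events[2], field) == getattr(bundle.events[2], field)
        for field in ("target_onset", "go_cue", "saccade_onset", "delay_duration"):
            assert getattr(loaded.events[2], field) == pytest.approx(
                getattr(bundle.events[2], field))
        for ch in range(cfg.n_channels):
            for a, b in zip(bundle.spikes[ch], loaded.spikes[ch]):
                np.testing.assert_allclose(a, b)
        np.testing.assert_allclose(bundle.lfp, loaded.lfp, atol=1e-3)
        assert loaded.ground_truth["reference_channel"] == cfg.reference_channel

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_channels=3)
        with pytest.raises(ValueError):
            GeneratorConfig(delay_range=(900, 600))
        with pytest.raises(ValueError):
            GeneratorConfig(baseline_rate=-1)
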