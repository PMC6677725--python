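"""Pre-saccadic event detection: detrending, E1/E2/E3 single-replicate
detectors, bootstrap aggregation, and Buildup/Burst classification."""

import numpy as np
import pytest

from laminarsc import (
    GeneratorConfig, generate_session, bootstrap_events, classify_channel,
    detrend_presaccadic, spike_density,
)
from laminarsc.presaccadic import (
    EventEstimate, detect_e1_single, detect_e2_single, detect_e3_single,
)
from laminarsc.spikes import RateWaveform

TIME = np.arange(-300.0, 76.0)


def _wf(values, n_trials=1):
    values = np.asarray(values, dtype=float)
    mat = np.tile(values, (n_trials, 1))
    return RateWaveform(time=TIME[: values.size], values=values,
                        trial_matrix=mat, alignment="saccade_onset")


class TestDetrend:
    def test_pure_line_removed(self):
        vals = 2.0 + 0.1 * TIME
        out, (slope, _) = detrend_presaccadic(_wf(vals))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)
        assert slope == pytest.approx(0.1)

    def test_trend_free_waveform_unchanged(self):
        # zero-net-slope ripple: the slope gate keeps the waveform flat
        vals = 15.0 + 0.5 * np.sin(2 * np.pi * TIME / 25.0)
        out, (slope, intercept) = detrend_presaccadic(_wf(vals))
        assert slope == 0.0  # insignificant slope gated to zero
        np.testing.assert_allclose(out.values, vals - intercept, atol=1e-9)

    def test_line_plus_burst_recovers_burst(self):
        line = 5.0 + 0.05 * TIME
        burst = np.where(TIME > -30, 40.0 * np.clip((TIME + 30) / 30, 0, 1), 0.0)
        out, _ = detrend_presaccadic(_wf(line + burst))
        np.testing.assert_allclose(out.values, burst, atol=1e-6)

    def test_insufficient_coverage_rejected(self):
        short = RateWaveform(time=np.arange(-100.0, 76.0),
                             values=np.zeros(176),
                             trial_matrix=np.zeros((1, 176)))
        with pytest.raises(ValueError):
            detrend_presaccadic(short)


class TestE1:
    def test_activity_equal_to_baseline_gives_none(self):
        act = np.full((5, TIME.size), 12.0)
        base = np.full(500, 12.0)
        assert detect_e1_single(act, TIME, base) is None

    def test_noiseless_step_detected_at_onset(self):
        vals = np.where(TIME >= -120, 30.0, 0.0)
        act = np.tile(vals, (5, 1))
        assert detect_e1_single(act, TIME, np.zeros(500)) == -120.0

    def test_noisy_step_matches_bruteforce_scan(self):
        """Seeded noisy steps: E1 lands in [-120, -100] in >=90% of runs and
        always equals an independent re-implementation of the scan."""
        from scipy import stats as st
        hits = 0
        n_runs = 60
        for s in range(n_runs):
            rng = np.random.default_rng(40_000 + s)
            vals = np.where(TIME >= -120, 30.0, 0.0)
            act = vals + rng.normal(0, 12.0, size=(50, TIME.size))
            base = rng.normal(0, 12.0, size=5000)
            got = detect_e1_single(act, TIME, base)

            # brute-force oracle: per-bin Welch t test + run scan
            cols = TIME >= -200
            p = np.array([
                st.ttest_ind(act[:, i], base, equal_var=False).pvalue
                for i in np.flatnonzero(cols)
            ])
            sig = p < 0.01
            expected = None
            for i in range(sig.size - 99):
                if sig[i : i + 100].all():
                    expected = TIME[cols][i]
                    break
            assert got == expected
            if got is not None and -120 <= got <= -100:
                hits += 1
        assert hits / n_runs >= 0.9


class TestE2E3:
    def test_flat_then_ramp_hinge(self):
        vals = np.where(TIME < -90, 8.0, 8.0 + 0.9 * (TIME + 90))
        e2 = detect_e2_single(vals, TIME, e1b=-50.0)
        assert e2 == pytest.approx(-90.0, abs=1.0)

    def test_pure_line_tie_returns_earliest(self):
        vals = 3.0 + 0.02 * TIME
        e2 = detect_e2_single(vals, TIME, e1b=-100.0)
        assert e2 == -198.0  # earliest admissible breakpoint in [-200, -100]

    def test_hinge_close_to_window_edge(self):
        # the accumulation hinge sits just inside the window's right edge,
        # emulating E1 firing shortly after the onset it certifies
        vals = np.where(TIME < -70, 5.0, 5.0 + 2.0 * (TIME + 70))
        e2 = detect_e2_single(vals, TIME, e1b=-60.0)
        assert e2 == pytest.approx(-70.0, abs=1.0)
        assert e2 <= -60.0  # E2b precedes or equals E1b

    def test_slow_then_steep_hinge_with_slopes(self):
        vals = np.where(TIME < -30, 0.5 * (TIME + 300),
                        135.0 + 4.0 * (TIME + 30))
        out = detect_e3_single(vals, TIME, e2b=-90.0, pb=10.0)
        assert out is not None
        e3, before, after = out
        assert e3 == pytest.approx(-30.0, abs=1.0)
        assert after > before

    def test_window_too_short_skipped(self):
        assert detect_e3_single(np.zeros(TIME.size), TIME, -10.0, -6.0) is None


def _session_channel_matrices(bundle, ch, task="VG"):
    events = bundle.events
    mov = [i for i in bundle.trials(task)
           if 200 <= events[i].saccade_latency <= 400]
    go = [events[i].go_cue for i in mov]
    sac = [events[i].saccade_onset for i in mov]
    trains = [bundle.spikes[ch - 1][i] for i in mov]
    wf_g = spike_density(trains, go, (-100, 0), alignment="go_cue")
    wf_m = spike_density(trains, sac, (-300, 75), alignment="saccade_onset")
    return wf_m, wf_g


class TestBootstrap:
    def test_zero_variance_trials_give_degenerate_ci(self):
        vals = np.where(TIME < -80, 10.0, 10.0 + 0.6 * (TIME + 80))
        vals = np.where(TIME >= -27, vals[TIME == -27] + 4.0 * (TIME + 27), vals)
        mat = np.tile(vals, (20, 1))
        base = np.full((20, 101), 10.0)
        est = bootstrap_events(mat, TIME, base, n_boot=20, seed=0)
        for name in ("E1", "E2", "E3", "P"):
            e = est[name]
            assert e.detected
            assert e.ci[1] - e.ci[0] == pytest.approx(0.0)
        assert est["E1"].reliable and est["E2"].reliable
        assert est["E2"].mean <= est["E1"].mean

    def test_unmodulated_channel_detects_nothing(self, rng):
        mat = rng.poisson(3.0, size=(40, TIME.size)).astype(float)
        base = rng.poisson(3.0, size=(40, 101)).astype(float)
        est = bootstrap_events(mat, TIME, base, n_boot=30, seed=1)
        assert est["E1"].detection_rate <= 0.1
        assert not est["E1"].reliable

    def test_replicate_ordering_invariants(self, small_session):
        """E2 <= E1 and E2 < E3 <= P wherever all are defined."""
        wf_m, wf_g = _session_channel_matrices(small_session, ch=6)
        est = bootstrap_events(wf_m.trial_matrix, wf_m.time, wf_g.trial_matrix,
                               n_boot=40, seed=3)
        e1, e2 = est["E1"].replicates, est["E2"].replicates
        e3, pk = est["E3"].replicates, est["P"].replicates
        ok = ~np.isnan(e1) & ~np.isnan(e2)
        assert np.all(e2[ok] <= e1[ok])
        ok3 = ok & ~np.isnan(e3)
        assert np.all(e2[ok3] < e3[ok3])
        assert np.all(e3[ok3] <= pk[ok3])

    def test_shuffled_null_rarely_reliable(self):
        """Flat Poisson channels (no pre-saccadic modulation) almost never
        produce reliable hinge events."""
        reliable = 0
        for s in range(8):
            rng = np.random.default_rng(60_000 + s)
            mat = rng.poisson(8.0, size=(60, TIME.size)).astype(float)
            base = rng.poisson(8.0, size=(60, 101)).astype(float)
            est = bootstrap_events(mat, TIME, base, n_boot=50, seed=s)
            reliable += est["E2"].reliable + est["E3"].reliable
        assert reliable <= 1

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_events(np.zeros((1, TIME.size)), TIME,
                             np.zeros((1, 101)), n_boot=5)


def _estimate(name, mean, ci, reliable=True):
    return EventEstimate(
        name=name, replicates=np.full(10, mean), mean=mean, ci=ci,
        normalized_ci_range=(ci[1] - ci[0]) / 100.0,
        detection_rate=1.0, reliable=reliable,
    )


class TestClassification:
    WF = RateWaveform(
        time=TIME,
        values=np.clip(TIME + 120.0, 0.0, None) * 0.5,
        trial_matrix=np.zeros((2, TIME.size)),
    )

    def test_buildup_and_burst_when_cis_disjoint(self):
        cls = classify_channel(
            _estimate("E2", -90.0, (-95.0, -85.0)),
            _estimate("E3", -20.0, (-25.0, -15.0)),
            self.WF,
        )
        assert cls.category == "Buildup-Burst"
        assert cls.buildup_onset == -90.0
        assert cls.burst_onset == -20.0
        assert cls.buildup_rate == pytest.approx(15.0)

    def test_only_late_hinge_is_burst_only(self):
        cls = classify_channel(
            _estimate("E2", -90.0, (-95.0, -85.0), reliable=False),
            _estimate("E3", -25.0, (-30.0, -20.0)),
            self.WF,
        )
        assert cls.category == "Burst-only"

    def test_single_event_later_than_boundary_is_burst(self):
        cls = classify_channel(
            _estimate("E2", -30.0, (-35.0, -25.0)),
            _estimate("E3", -20.0, (-25.0, -15.0), reliable=False),
            self.WF,
        )
        assert cls.category == "Burst-only"
        assert cls.burst_onset == -30.0

    def test_no_reliable_events_is_none(self):
        cls = classify_channel(
            _estimate("E2", -90.0, (-95.0, -85.0), reliable=False),
            _estimate("E3", -20.0, (-25.0, -15.0), reliable=False),
            self.WF,
        )
        assert cls.category == "none"

    def test_two_early_hinges_are_buildup_only(self):
        cls = classify_channel(
            _estimate("E2", -110.0, (-115.0, -105.0)),
            _estimate("E3", -70.0, (-75.0, -65.0)),
            self.WF,
        )
        assert cls.category == "Buildup-only"
        assert cls.buildup_onset == -110.0
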