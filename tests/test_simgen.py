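"""Generator unit tests: amplitude ramp, kernel, multiplexing, determinism."""

import numpy as np
import pytest

from mealphot.session import SessionMeta
from mealphot.signal import ChannelTrace, PulseSchedule, demultiplex_stream
from mealphot.simgen import (
    GroupParams,
    SimConfig,
    delivery_template,
    multiplex,
    response_kernel,
    simulate_cohort,
    simulate_session,
    trial_amplitude,
)


class TestTrialAmplitude:
    def test_boundaries_and_midpoint(self):
        gp = GroupParams(a_early=0.2, a_late=0.8, satiation_capacity=60)
        assert trial_amplitude(0, gp) == pytest.approx(0.2)
        assert trial_amplitude(60, gp) == pytest.approx(0.8)
        assert trial_amplitude(200, gp) == pytest.approx(0.8)
        assert trial_amplitude(30, gp) == pytest.approx(0.5)

    def test_saturation_index_grows_with_capacity(self):
        def sat_index(cap):
            gp = GroupParams(a_early=0.0, a_late=1.0, satiation_capacity=cap)
            return next(k for k in range(500)
                        if trial_amplitude(k, gp) >= 1.0 - 1e-12)
        assert sat_index(20) < sat_index(40) < sat_index(80)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            trial_amplitude(-1, GroupParams())
        with pytest.raises(ValueError):
            GroupParams(satiation_capacity=0)


class TestResponseKernel:
    def test_zero_at_onset_and_decays(self):
        assert response_kernel(0.0) == pytest.approx(0.0)
        assert response_kernel(100.0) == pytest.approx(0.0, abs=1e-12)
        assert np.all(response_kernel(np.array([-1.0, -0.1])) == 0.0)

    def test_unit_peak_at_analytic_argmax(self):
        rise, decay = 0.2, 1.5
        t = np.linspace(0, 10, 200001)
        k = response_kernel(t, rise, decay)
        # numeric maximisation oracle
        assert k.max() == pytest.approx(1.0, abs=1e-6)
        t_star = rise * np.log((rise + decay) / rise)
        assert t[np.argmax(k)] == pytest.approx(t_star, abs=1e-3)

    def test_invalid_taus(self):
        with pytest.raises(ValueError):
            response_kernel(1.0, rise_tau=0.0)


class TestMultiplex:
    def test_constant_traces_alternating_blocks(self, schedule):
        tr465 = ChannelTrace(np.full(5, 2.0), channel="465")
        tr405 = ChannelTrace(np.full(5, 1.0), channel="405")
        raw = multiplex(tr465, tr405, schedule, noise_sd=0.0)
        assert raw.size == 5 * schedule.samples_per_cycle
        cycles = raw.reshape(5, -1)
        assert np.all(cycles[:, :6] == 2.0)
        assert np.all(cycles[:, 6:] == 1.0)

    def test_roundtrip_identity_at_zero_noise(self, schedule, rng):
        v465 = rng.uniform(1, 3, size=200)
        v405 = rng.uniform(0.5, 1.5, size=200)
        raw = multiplex(ChannelTrace(v465), ChannelTrace(v405), schedule, 0.0)
        assert np.array_equal(demultiplex_stream(raw, schedule, "465").values, v465)
        assert np.array_equal(demultiplex_stream(raw, schedule, "405").values, v405)

    def test_noisy_median_close_to_truth(self, schedule, rng):
        n, sd = 1000, 0.5
        v = np.full(n, 2.0)
        raw = multiplex(ChannelTrace(v), ChannelTrace(v), schedule, sd, rng)
        out = demultiplex_stream(raw, schedule, "465").values
        assert np.mean(np.abs(out - 2.0)) < 3 * sd / np.sqrt(6)

    def test_length_mismatch(self, schedule):
        with pytest.raises(ValueError, match="equal length"):
            multiplex(ChannelTrace(np.ones(3)), ChannelTrace(np.ones(4)), schedule)


class TestSimulateSession:
    def test_cue_times_match_trial_protocol(self, small_config):
        cfg = small_config(n_trials=90)
        cues = cfg.cue_times()
        assert cues[0] == pytest.approx(300.0)
        assert cues[-1] == pytest.approx(300.0 + 89 * 60.0)

    def test_zero_signal_config_yields_constant_465(self, small_config, meta):
        gp = GroupParams(a_early=0.0, a_late=0.0)
        cfg = small_config(gp=gp, noise_sd=0.0, bleach_tau=np.inf, level="raw")
        rec, _ = simulate_session(cfg, gp, meta, np.random.default_rng(0))
        tr = demultiplex_stream(rec.raw_samples, rec.schedule, "465")
        assert np.allclose(tr.values, cfg.f0_base, atol=1e-12)

    def test_all_trials_triggered_at_floor_one(self, small_config, meta):
        gp = GroupParams(trigger_floor=1.0)
        rec, gt = simulate_session(small_config(gp=gp), gp, meta,
                                   np.random.default_rng(0))
        assert gt.trials["triggered"].all()
        assert gt.noiseless["meal_size"] == 60

    def test_no_licks_no_triggers(self, small_config, meta):
        gp = GroupParams(vigor0=0.0, trigger_floor=0.0)
        rec, gt = simulate_session(small_config(gp=gp), gp, meta,
                                   np.random.default_rng(0))
        assert not gt.trials["triggered"].any()
        assert rec.lick_times.size == 0
        assert rec.delivery_times.size == 0

    def test_delivery_pulse_train(self, small_config, meta):
        gp = GroupParams(trigger_floor=1.0)
        cfg = small_config(gp=gp, n_trials=3)
        rec, _ = simulate_session(cfg, gp, meta, np.random.default_rng(0))
        first = rec.delivery_times[:10]
        assert first[0] == pytest.approx(300.0 + 1.0)  # cue + 1 s
        assert np.allclose(np.diff(first), 0.3)  # 150 ms on + 150 ms gap
        assert rec.delivery_times.size == 3 * 10

    def test_ground_truth_consistency(self, small_config, meta):
        gp = GroupParams()
        _, gt = simulate_session(small_config(gp=gp), gp, meta,
                                 np.random.default_rng(3))
        assert gt.noiseless == gt.recompute_noiseless()

    def test_noiseless_roundtrip_through_raw_path(self, meta, small_config):
        """Full signal path at zero noise recovers programmed dF/F exactly."""
        from mealphot.trials import AnalysisParams, analyze_session

        gp = GroupParams(a_early=0.5, a_late=0.5, trigger_floor=1.0)
        cfg = small_config(gp=gp, n_trials=5, noise_sd=0.0, bleach_tau=np.inf,
                           level="raw")
        rec, gt = simulate_session(cfg, gp, meta, np.random.default_rng(0))
        sa = analyze_session(rec, AnalysisParams(lowpass_cutoff=None, min_triggered=1))
        tpl = delivery_template(cfg)
        for row in sa.dff.values:
            post = row[sa.dff.time_axis >= 0]
            assert np.max(np.abs(post - 0.5 * tpl)) < 1e-9


class TestSimulateCohort:
    def test_deterministic_given_seed(self, small_config):
        cfg = small_config(n_mice=2, sessions_per_mouse=2, noise_sd=1.0,
                           mouse_effect_sd=0.2, session_vigor_jitter_sd=0.2)
        c1, c2 = simulate_cohort(cfg), simulate_cohort(cfg)
        for r1, r2 in zip(c1.sessions, c2.sessions):
            assert np.array_equal(r1.trace465.values, r2.trace465.values)
            assert np.array_equal(r1.lick_times, r2.lick_times)
        for g1, g2 in zip(c1.ground_truth, c2.ground_truth):
            assert g1.trials.equals(g2.trials)

    def test_session_files_byte_identical(self, small_config, tmp_path):
        from mealphot.io import write_session_h5

        cfg = small_config(n_trials=10, noise_sd=1.0)
        r1 = simulate_cohort(cfg).sessions[0]
        r2 = simulate_cohort(cfg).sessions[0]
        p1 = write_session_h5(r1, tmp_path / "a.h5")
        p2 = write_session_h5(r2, tmp_path / "b.h5")
        assert p1.read_bytes() == p2.read_bytes()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="n_trials"):
            SimConfig(n_trials=0)
        with pytest.raises(ValueError, match="integer sample count"):
            SimConfig(schedule=PulseSchedule(raw_rate=925.0))
        with pytest.raises(ValueError, match="iti"):
            SimConfig(iti=30.0)

    def test_mean_meal_size_monotone_in_vigor_decline_tau(self, small_config, meta):
        sizes = []
        for tau in (15.0, 30.0, 60.0):
            gp = GroupParams(vigor_decline_tau=tau, trigger_floor=0.0)
            cfg = small_config(gp=gp, n_trials=90)
            ms = [simulate_session(cfg, gp, meta, np.random.default_rng(100 + i)
                                   )[1].noiseless["meal_size"] for i in range(15)]
            sizes.append(np.mean(ms))
        assert sizes[0] < sizes[1] < sizes[2]
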