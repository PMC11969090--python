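import numpy as np
import pytest

from mrgating import (
    GatingConfig,
    MotionTrace,
    delay_transitions,
    duty_cycle_signal,
    gate_decision,
    ideal_gate_signal,
    overlap_fraction,
    simulate_gated_delivery,
    simulate_tracking,
    transition_times,
)
from mrgating.gating import load_gating_config, save_gating_config
from oracles import (
    crossing_times_roots,
    duty_fraction_dense,
    linear_extrapolation_replay,
    overlap_monte_carlo,
)


def linear_motion(speed=10.0, duration=10.0, fs=100.0):
    t = np.arange(int(duration * fs) + 1) / fs
    return MotionTrace(t=t, z=speed * t, fs=fs, x=np.zeros_like(t), y=np.zeros_like(t))


class TestSimulateTracking:
    def test_passthrough_predictor_is_exact(self, trace_10bpm_3d):
        log = simulate_tracking(trace_10bpm_3d, GatingConfig(predictor="none"))
        true = trace_10bpm_3d.interp_positions(log.frame_t)
        assert np.array_equal(log.predicted, true)
        assert not log.inhibit.any()

    def test_linear_predictor_exact_on_constant_velocity(self):
        motion = linear_motion(speed=10.0)
        cfg = GatingConfig(predictor="linear", system_delay=0.2)
        log = simulate_tracking(motion, cfg)
        k = ~log.inhibit
        # linear extrapolation is exact for linear motion: predicted leads by delay
        expected_z = motion.interp_positions(log.frame_t[k])[:, 2] + 10.0 * 0.2
        assert np.allclose(log.predicted[k, 2], expected_z, atol=1e-9)

    def test_linear_predictor_matches_stepwise_replay(self, trace_10bpm_3d):
        cfg = GatingConfig(predictor="linear", history=3, system_delay=0.2)
        log = simulate_tracking(trace_10bpm_3d, cfg)
        true = trace_10bpm_3d.interp_positions(log.frame_t)
        replay = linear_extrapolation_replay(log.frame_t, true, history=3, lookahead=0.2)
        k = ~log.inhibit
        assert np.allclose(log.predicted[k], replay[k], atol=1e-8)

    def test_learn_time_frames_inhibited(self, trace_10bpm_3d):
        log = simulate_tracking(trace_10bpm_3d, GatingConfig(learn_time=4.0))
        assert log.inhibit[log.frame_t < 4.0].all()
        assert not log.inhibit[log.frame_t >= 4.0].any()

    def test_noise_reproducible_under_seed(self, trace_10bpm_3d):
        cfg = GatingConfig(prediction_noise_sd=0.3, seed=9)
        a = simulate_tracking(trace_10bpm_3d, cfg)
        b = simulate_tracking(trace_10bpm_3d, cfg)
        assert np.array_equal(a.predicted, b.predicted)


class TestGateDecision:
    def test_displacement_threshold(self, latency_gate_cfg):
        assert gate_decision(np.array([0.0, 0.0, 4.9]), latency_gate_cfg)
        assert not gate_decision(np.array([0.0, 0.0, 5.1]), latency_gate_cfg)

    def test_bounds_are_inclusive(self, latency_gate_cfg):
        assert gate_decision(np.array([0.0, 0.0, 5.0]), latency_gate_cfg)
        assert gate_decision(np.array([0.0, 0.0, -5.0]), latency_gate_cfg)

    def test_overlap_mode_full_overlap_permits(self):
        cfg = GatingConfig(
            mode="overlap",
            target_radius=10.0,
            envelope={"x": (-10, 10), "y": (-10, 10), "z": (-10, 10)},
        )
        assert gate_decision(np.zeros(3), cfg)


class TestOverlapFraction:
    def test_sphere_inside_box(self):
        assert overlap_fraction(np.zeros(3), 5.0, {"z": (-20, 20)}) == 1.0

    def test_half_space_through_center(self):
        f = overlap_fraction(np.zeros(3), 10.0, {"z": (0.0, 100.0)})
        assert f == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_monte_carlo_oracle(self, seed):
        rng = np.random.default_rng(seed)
        center = rng.uniform(-6, 6, 3)
        box = {"x": (-5.0, 8.0), "z": (-4.0, 9.0)}
        f = overlap_fraction(center, 10.0, box)
        f_mc = overlap_monte_carlo(center, 10.0, box, n=100_000, seed=seed + 50)
        assert f == pytest.approx(f_mc, abs=0.01)


class TestDutyCycleSignal:
    @pytest.mark.parametrize(
        "on,off,expected",
        [(2.0, 1.0, 2.0 / 3.0), (0.5, 1.0, 1.0 / 3.0), (0.05, 0.05, 0.5)],
    )
    def test_on_fraction(self, on, off, expected):
        sig = duty_cycle_signal(on, off, 30.0, 2000.0)
        assert sig.on_fraction == pytest.approx(expected, abs=1e-3)

    def test_zero_off_always_on(self):
        sig = duty_cycle_signal(1.0, 0.0, 5.0, 100.0)
        assert sig.state.all()

    def test_starts_on(self):
        assert duty_cycle_signal(0.5, 1.0, 5.0, 100.0).state[0] == 1


class TestIdealGateSignal:
    def test_motion_within_bounds_always_on(self, constant_motion, window_gate_cfg):
        sig = ideal_gate_signal(constant_motion, window_gate_cfg)
        assert sig.state.all()

    def test_duty_cycle_matches_dense_grid_oracle(self, trace_10bpm, window_gate_cfg):
        sig = ideal_gate_signal(trace_10bpm, window_gate_cfg)
        assert sig.on_fraction == pytest.approx(duty_fraction_dense(3, 0.5), abs=2e-3)

    def test_crossings_match_root_finder_oracle(self, trace_10bpm, window_gate_cfg):
        sig = ideal_gate_signal(trace_10bpm, window_gate_cfg, fs=2000.0)
        on_t, off_t = transition_times(sig)
        roots = crossing_times_roots(30.0, 6.0, 3, 15.0, 12.0)
        measured = np.sort(np.concatenate([on_t, off_t]))
        for r in roots:
            assert np.min(np.abs(measured - r)) <= 1.0 / 2000.0 + 1e-12


class TestGatedDelivery:
    def test_zero_latency_matches_ideal_at_frame_resolution(self, trace_10bpm_3d, window_gate_cfg):
        beam, _ = simulate_gated_delivery(trace_10bpm_3d, window_gate_cfg)
        ideal = ideal_gate_signal(trace_10bpm_3d, window_gate_cfg, fs=beam.fs)
        for bt, it in zip(transition_times(beam), transition_times(ideal)):
            assert len(bt) == len(it)
            assert np.max(np.abs(bt - it)) <= window_gate_cfg.cine_interval + 1e-9

    def test_constant_delay_shifts_every_transition(self, trace_10bpm_3d):
        # window starting above the rest position so the beam starts off and
        # both runs see the same transition set
        cfg0 = GatingConfig(thresholds={"z": (5.0, 15.0)})
        cfgd = GatingConfig(
            thresholds={"z": (5.0, 15.0)},
            beam_on_delay=(0.05, 0.0),
            beam_off_delay=(0.05, 0.0),
        )
        beam0, _ = simulate_gated_delivery(trace_10bpm_3d, cfg0)
        beamd, _ = simulate_gated_delivery(trace_10bpm_3d, cfgd)
        for t0, td in zip(transition_times(beam0), transition_times(beamd)):
            assert len(t0) == len(td)
            assert np.allclose(td - t0, 0.05, atol=1.0 / beam0.fs)

    def test_gaussian_delays_recovered_from_recorded_draws(self, window_gate_cfg):
        # signal-level injection with explicit per-transition draws: the
        # transition-time differences must equal the draws to one sample
        from mrgating import generate_regular_trace

        trace = generate_regular_trace(10.0, 30.0, 3, 600.0, 100.0)
        ideal = ideal_gate_signal(trace, window_gate_cfg, fs=2000.0)
        on_t, off_t = transition_times(ideal)
        rng = np.random.default_rng(3)
        on_draws = rng.normal(0.0, 0.06, len(on_t))
        off_draws = rng.normal(0.0, 0.06, len(off_t))
        shifted = delay_transitions(ideal, on_draws, off_draws)
        s_on, s_off = transition_times(shifted)
        assert len(s_on) == len(on_t) and len(s_off) == len(off_t)
        got = np.concatenate([s_on - on_t, s_off - off_t])
        want = np.concatenate([on_draws, off_draws])
        assert np.max(np.abs(np.sort(got) - np.sort(want))) <= 1.0 / 2000.0
        assert abs(np.mean(got) - np.mean(want)) < 2e-3
        assert abs(np.std(got) - np.std(want)) < 2e-3

    def test_transition_counts_balanced(self, trace_10bpm_3d, window_gate_cfg):
        beam, _ = simulate_gated_delivery(trace_10bpm_3d, window_gate_cfg)
        on_t, off_t = transition_times(beam)
        assert abs(len(on_t) - len(off_t)) <= 1

    def test_no_beam_during_learn_time(self, trace_10bpm_3d):
        cfg = GatingConfig(thresholds={"z": (0.0, 15.0)}, learn_time=5.0)
        beam, _ = simulate_gated_delivery(trace_10bpm_3d, cfg)
        assert not beam.state[beam.t < 5.0].any()

    def test_reproducible_under_seed(self, trace_10bpm_3d):
        cfg = GatingConfig(
            thresholds={"z": (0.0, 15.0)},
            prediction_noise_sd=0.3,
            beam_on_delay=(0.0, 0.06),
            beam_off_delay=(0.0, 0.06),
            seed=4,
        )
        a, _ = simulate_gated_delivery(trace_10bpm_3d, cfg)
        b, _ = simulate_gated_delivery(trace_10bpm_3d, cfg)
        assert np.array_equal(a.state, b.state)


def test_gating_config_yaml_round_trip(tmp_path):
    cfg = GatingConfig(
        thresholds={"z": (0.0, 15.0), "x": (-3.0, 3.0)},
        predictor="linear",
        prediction_noise_sd=0.3,
        beam_on_delay=(0.01, 0.06),
        learn_time=4.0,
        seed=7,
    )
    path = tmp_path / "cfg.yaml"
    save_gating_config(cfg, path)
    assert load_gating_config(path) == cfg
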