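"""Synthetic motion generator: physics consistency, determinism, designs."""

import math

import numpy as np
import pytest

from ffhdetect.detector import run_detector
from ffhdetect.imu_core import G_SI, NONFFH_CLASSES
from ffhdetect.synthetic import (
    MotionSpec,
    make_suite,
    simulate_adl,
    simulate_forward_fall,
    simulate_jump_down,
    simulate_ladder_fall,
    simulate_vertical_fall,
)


# ---------------------------------------------------------------------------
# closed-form physics checks
# ---------------------------------------------------------------------------


def test_vertical_fall_closed_forms(noiseless_spec):
    trial = simulate_vertical_fall(2.0, noiseless_spec, np.random.default_rng(0))
    gt = trial.ground_truth
    t_fall = math.sqrt(2 * 2.0 / G_SI)  # 0.6386 s
    release = trial.collision_time - t_fall
    assert t_fall == pytest.approx(0.6386, abs=5e-4)
    # impact speed sqrt(2 g h) = 6.264 m/s
    assert gt.v_vert.max() == pytest.approx(math.sqrt(2 * G_SI * 2.0), rel=0.02)
    # specific force vanishes mid-fall
    mid = int((release + t_fall / 2) * trial.trace.fs)
    np.testing.assert_allclose(trial.trace.acc[mid], 0.0, atol=1e-9)
    assert gt.v_vert[0] == 0.0


def test_vertical_fall_height_limit():
    with pytest.raises(ValueError):
        simulate_vertical_fall(0.0)


@pytest.mark.parametrize("height", [0.7, 2.0])
def test_forward_fall_energy_consistency(noiseless_spec, height):
    """Impact speed equals sqrt(2 g h_eff) for the sensor's total drop.

    Independent oracle: fine-step RK4 integration of the pendulum ODE,
    compared with the generator's ground truth.
    """
    trial = simulate_forward_fall(height, noiseless_spec, np.random.default_rng(1))
    gt = trial.ground_truth
    arm = noiseless_spec.sensor_arm
    theta0 = math.radians(2.0)

    # independent integrator for the topple phase
    def rk4_pendulum(theta, omega, dt=1e-5):
        t = 0.0
        while theta < math.pi / 2:
            def f(y):
                return np.array([y[1], (G_SI / arm) * math.sin(y[0])])
            y = np.array([theta, omega])
            k1 = f(y)
            k2 = f(y + dt / 2 * k1)
            k3 = f(y + dt / 2 * k2)
            k4 = f(y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            theta, omega = y
            t += dt
        return t, omega

    t_top, omega_release = rk4_pendulum(theta0, math.radians(5.0))
    v_release = arm * omega_release
    drop2 = height + arm * math.cos(math.pi / 2) - 0.15
    v_imp_oracle = math.sqrt(v_release**2 + 2 * G_SI * (height - 0.15))
    assert gt.v_vert.max() == pytest.approx(v_imp_oracle, rel=0.01)

    # energy: total sensor drop from standing to floor contact
    h_eff = height + arm * math.cos(theta0) - 0.15
    assert gt.v_vert.max() == pytest.approx(math.sqrt(2 * G_SI * h_eff), rel=0.01)


def test_forward_fall_tilt_monotone_until_impact(default_spec):
    trial = simulate_forward_fall(1.0, default_spec, np.random.default_rng(2))
    gt = trial.ground_truth
    i_imp = np.searchsorted(trial.trace.t, gt.impact_time)
    pitch = gt.pitch[:i_imp]
    assert np.all(np.diff(pitch) >= -1e-9)
    # the trunk crosses the 40 degree threshold strictly before impact
    assert pitch.max() > 40.0


def test_ladder_fall_energy_consistency(noiseless_spec):
    """Sensor speed during the topple obeys conservation of energy:
    v_z = sqrt(2 g R (cos th0 - cos th)) sin th at the sampled tilt."""
    trial = simulate_ladder_fall(3.0, noiseless_spec, np.random.default_rng(3))
    gt = trial.ground_truth
    radius = 3.0
    i = int(np.argmax(gt.v_vert))
    theta_i = math.radians(-gt.pitch[i])
    drop = radius * (math.cos(math.radians(2.0)) - math.cos(theta_i))
    expected = math.sqrt(2 * G_SI * drop) * math.sin(theta_i)
    assert gt.v_vert[i] == pytest.approx(expected, rel=0.01)


def test_jump_peak_speed_closed_form(noiseless_spec):
    # sampled peak lies within one sample interval below sqrt(2 g h)
    trial = simulate_jump_down(0.7, noiseless_spec, np.random.default_rng(4))
    closed_form = math.sqrt(2 * G_SI * 0.7)  # 3.71 m/s
    peak = trial.ground_truth.v_vert.max()
    dt = trial.trace.dt
    assert closed_form - 1.5 * G_SI * dt <= peak <= closed_form + 1e-9
    assert not trial.is_ffh and trial.collision_time is None


def test_jump_pipeline_velocity_brackets_reported_range(default_spec):
    """Estimated peak descent speed of the 0.7 m jump lies in 3.0-4.6 m/s."""
    from ffhdetect.detector import process_trace

    for seed in range(5):
        trial = simulate_jump_down(0.7, default_spec, np.random.default_rng(40 + seed))
        _, _, kin = process_trace(trial.trace)
        assert 3.0 <= kin.v_v.max() <= 4.6


def test_jump_height_restricted_to_non_ffh_regime():
    with pytest.raises(ValueError):
        simulate_jump_down(1.5)


# ---------------------------------------------------------------------------
# occupational motions
# ---------------------------------------------------------------------------


def test_unknown_adl_class_rejected():
    with pytest.raises(ValueError):
        simulate_adl("moonwalk")


def test_elevator_stays_below_integration_gate(default_spec):
    from ffhdetect.detector import process_trace

    trial = simulate_adl("elevator", default_spec, np.random.default_rng(5))
    _, _, kin = process_trace(trial.trace)
    assert np.max(np.abs(kin.a_v)) <= 0.15
    np.testing.assert_array_equal(kin.v_v, 0.0)


def test_lifting_exceeds_angle_threshold_without_detection(default_spec):
    """Deep bends pass 40 degrees but descend too slowly to fire."""
    from ffhdetect.detector import process_trace

    trial = simulate_adl("lift_front", default_spec, np.random.default_rng(6))
    _, orient, kin = process_trace(trial.trace)
    assert orient.vertical_angle.max() > 40.0
    assert kin.v_v.max() < 1.0
    assert not run_detector(trial.trace).detected


def test_no_adl_fires_default_thresholds(default_spec):
    for cls in NONFFH_CLASSES:
        trial = simulate_adl(cls, default_spec, np.random.default_rng(hash(cls) % 2**31))
        assert not run_detector(trial.trace).detected, cls


# ---------------------------------------------------------------------------
# suites
# ---------------------------------------------------------------------------


def test_experiment1_suite_counts():
    suite = make_suite("experiment-1", seed=20)
    assert len(suite) == 300
    assert sum(t.is_ffh for t in suite) == 30
    assert sum(not t.is_ffh for t in suite) == 270


def test_mannequin_suite_counts():
    suite = make_suite("mannequin", seed=21)
    assert len(suite) == 30  # 2 fall types x 3 heights x 5 reps
    assert all(t.is_ffh for t in suite)
    heights = sorted({t.height for t in suite})
    assert heights == [2.0, 2.5, 3.0]


def test_worksite_suite_covers_scenarios():
    suite = make_suite("worksite", seed=22)
    assert len(suite) == 9
    classes = {t.motion_class for t in suite}
    assert classes == {"scaffold_ffh", "roof_ffh", "ladder_ffh"}


def test_suites_bit_reproducible_under_seed():
    a = make_suite("experiment-1", n_subjects=1, reps=1, seed=33)
    b = make_suite("experiment-1", n_subjects=1, reps=1, seed=33)
    assert len(a) == len(b) == 10
    for ta, tb in zip(a, b):
        assert ta.trial_id == tb.trial_id
        np.testing.assert_array_equal(ta.trace.acc, tb.trace.acc)
        np.testing.assert_array_equal(ta.trace.gyro, tb.trace.gyro)
    c = make_suite("experiment-1", n_subjects=1, reps=1, seed=34)
    assert not np.array_equal(a[0].trace.acc, c[0].trace.acc)


def test_unknown_design_rejected():
    with pytest.raises(ValueError):
        make_suite("experiment-3")


def test_suite_level_velocity_separation():
    """Peak estimated descent speed separates falls from every other motion."""
    from ffhdetect.evaluation import precompute_series

    suite = make_suite("experiment-1", n_subjects=4, reps=1, seed=35)
    series = precompute_series(suite)
    ffh_min = min(s.vv.max() for s in series if s.trial.is_ffh)
    non_max = max(s.vv.max() for s in series if not s.trial.is_ffh)
    assert ffh_min > non_max
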