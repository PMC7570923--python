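"""Physics-based generator of labeled IMU trials with ground truth.

Every trial is built from an explicit kinematic script of the trunk
sensor: roll/pitch profiles (degrees) plus world-frame acceleration of
the sensor (m/s^2, z positive downward). The specific force delivered to
the virtual accelerometer is the world acceleration minus gravity rotated
into the sensor frame; gyroscope channels follow from the exact
Euler-rate mapping. White noise and a constant gyro bias are then added
and the channels are clipped to the sensor ranges.

Three families of trials are provided:

* occupational non-fall motions (sitting, lifting, climbing, digging,
  beam walking, elevator rides, stretching, a 0.7 m jump down);
* rigid-body falls: vertical free fall and forward topple-plus-fall at
  configurable platform heights (mannequin surrogates);
* worksite fall scenarios: scaffold collapse, roof slide, backward
  ladder topple (rigid kinematic surrogates of the dynamics scenarios).

Falls carry a ground-truth impact time and per-sample vertical velocity,
so detector lead times can be scored against the true collision.
All randomness flows from a numpy Generator; the same seed reproduces a
suite bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .imu_core import (
    EXP1_NONFFH,
    G_SI,
    GroundTruth,
    ImuTrace,
    LabeledTrial,
    NONFFH_CLASSES,
)

#: clip margins kept inside the sensor ranges so generated files re-ingest
_ACC_CLIP = 15.9
_GYRO_CLIP = 1995.0

#: ground clearance of the trunk sensor when the body lies on the floor (m)
_SENSOR_CLEARANCE = 0.15

#: trunk-sensor lever arm for bending motions (hip pivot to T7, m)
_TRUNK_ARM = 0.45


@dataclass
class MotionSpec:
    """Generator conditions: sampling, subject, noise and jitter models.

    Noise defaults are typical consumer-MEMS figures: accelerometer white
    noise 0.01 g per sample, gyro white noise 0.5 deg/s, constant gyro
    bias drawn uniformly in +/-1 deg/s per trial. Timing and amplitude
    jitter emulate within- and between-subject variability as uniform
    +/-10% scalings of phase durations and movement amplitudes.
    """

    fs: float = 100.0
    stature: float = 1.74
    sensor_height_frac: float = 0.75  # sensor height as fraction of stature
    accel_noise_sd: float = 0.01  # g
    gyro_noise_sd: float = 0.5  # deg/s
    gyro_bias_range: float = 1.0  # deg/s, uniform +/-
    timing_jitter: float = 0.10
    amplitude_jitter: float = 0.10
    quiet_prefix: float = 1.0  # s of quiet standing before the motion
    tail: float = 0.5  # s of quiet after the motion

    @property
    def sensor_arm(self) -> float:
        """Pivot-to-sensor distance for whole-body topples (m)."""
        return self.sensor_height_frac * self.stature


# ---------------------------------------------------------------------------
# low-level assembly
# ---------------------------------------------------------------------------


def _jit(rng: np.random.Generator, scale: float) -> float:
    return 1.0 + scale * rng.uniform(-1.0, 1.0)


def _smoothstep(n: int, total: float):
    """Minimum-jerk-like ramp: s, s', s'' arrays over a phase of ``total`` s."""
    u = (np.arange(1, n + 1)) / n
    s = 3 * u**2 - 2 * u**3
    ds = (6 * u - 6 * u**2) / total
    dds = (6 - 12 * u) / total**2
    return s, ds, dds


def _assemble(
    spec: MotionSpec,
    rng: np.random.Generator,
    roll_deg: np.ndarray,
    pitch_deg: np.ndarray,
    acc_world: np.ndarray,  # (n, 3) m/s^2, z positive downward
    v_vert: np.ndarray,  # m/s, positive downward
    motion_class: str,
    is_ffh: bool,
    collision_time: Optional[float],
    height: Optional[float],
    trial_id: str,
) -> LabeledTrial:
    n = roll_deg.shape[0]
    dt = 1.0 / spec.fs
    t = np.arange(n) * dt

    # specific force in g: (a_world - g_vec) / g rotated into the sensor frame
    f_world = acc_world / G_SI
    f_world = f_world - np.array([0.0, 0.0, 1.0])
    r = np.radians(roll_deg)
    p = np.radians(pitch_deg)
    cr, sr, cp, sp = np.cos(r), np.sin(r), np.cos(p), np.sin(p)
    fx, fy, fz = f_world[:, 0], f_world[:, 1], f_world[:, 2]
    # transpose of the local-to-global roll/pitch rotation
    a_l = np.column_stack(
        [
            cp * fx - sp * fz,
            sp * sr * fx + cr * fy + cp * sr * fz,
            sp * cr * fx - sr * fy + cp * cr * fz,
        ]
    )

    # exact Euler-rate mapping: body rates from roll/pitch derivatives
    roll_dot = np.gradient(roll_deg, dt)
    pitch_dot = np.gradient(pitch_deg, dt)
    wx = roll_dot
    wy = pitch_dot * cr
    wz = -pitch_dot * sr

    bias = rng.uniform(-spec.gyro_bias_range, spec.gyro_bias_range, size=3)
    acc = a_l + rng.normal(0.0, spec.accel_noise_sd, size=(n, 3))
    gyro = (
        np.column_stack([wx, wy, wz])
        + bias
        + rng.normal(0.0, spec.gyro_noise_sd, size=(n, 3))
    )
    np.clip(acc, -_ACC_CLIP, _ACC_CLIP, out=acc)
    np.clip(gyro, -_GYRO_CLIP, _GYRO_CLIP, out=gyro)

    trace = ImuTrace(t=t, acc=acc, gyro=gyro, fs=spec.fs)
    gt = GroundTruth(
        roll=roll_deg.copy(),
        pitch=pitch_deg.copy(),
        v_vert=v_vert.copy(),
        impact_time=collision_time,
    )
    return LabeledTrial(
        trace=trace,
        motion_class=motion_class,
        is_ffh=is_ffh,
        collision_time=collision_time,
        height=height,
        ground_truth=gt,
        trial_id=trial_id,
    )


def _impact_pulse(v_impact: float, fs: float, tau: float = 0.06):
    """Half-sine deceleration cancelling ``v_impact`` over ``tau`` seconds.

    Returns (az_world, v_vert) arrays; the amplitude is capped so the
    rotated specific force stays inside the accelerometer range (the
    residual velocity after a clipped pulse is irrelevant to detection,
    which happens before impact).
    """
    n = max(2, round(tau * fs))
    tt = (np.arange(1, n + 1)) / fs
    amp = math.pi * v_impact / (2.0 * tau)
    amp = min(amp, (_ACC_CLIP - 1.5) * G_SI)
    az = -amp * np.sin(math.pi * tt / tau)
    v = np.maximum(0.0, v_impact - amp * (tau / math.pi) * (1 - np.cos(math.pi * tt / tau)))
    return az, v


def _quiet(n: int):
    z = np.zeros(n)
    return z, z.copy()


def _pendulum(theta0: float, omega0: float, arm: float, fs: float, theta_end: float):
    """Integrate an inverted point-mass pendulum to ``theta_end`` (rad).

    Returns sampled (theta, theta_dot) at 1/fs and the event time.
    """

    def rhs(_t, y):
        return [y[1], (G_SI / arm) * math.sin(y[0])]

    def hit(_t, y):
        return y[0] - theta_end

    hit.terminal = True
    hit.direction = 1
    sol = solve_ivp(
        rhs,
        (0.0, 30.0),
        [theta0, omega0],
        events=hit,
        dense_output=True,
        rtol=1e-9,
        atol=1e-11,
    )
    t_end = float(sol.t_events[0][0])
    k = np.arange(1, int(t_end * fs) + 1)
    ts = k / fs
    theta, theta_dot = sol.sol(ts)
    return ts, theta, theta_dot, t_end


# ---------------------------------------------------------------------------
# fall generators
# ---------------------------------------------------------------------------


def simulate_vertical_fall(
    height: float,
    spec: MotionSpec | None = None,
    rng: np.random.Generator | None = None,
    trial_id: str = "vertical_ffh",
    motion_class: str = "vertical_ffh",
) -> LabeledTrial:
    """Rigid vertical free fall from ``height`` metres after quiet standing.

    During the fall the specific force vanishes and the orientation is
    constant; impact is a high-deceleration pulse. The ground-truth
    impact time is sqrt(2 h / g) after release.
    """
    if height <= 0:
        raise ValueError("height must be positive")
    spec = spec or MotionSpec()
    rng = rng or np.random.default_rng()
    fs = spec.fs

    n_pre = round(spec.quiet_prefix * _jit(rng, spec.timing_jitter) * fs)
    t_fall = math.sqrt(2.0 * height / G_SI)
    n_fall = int(t_fall * fs)
    tt = np.arange(1, n_fall + 1) / fs
    v_imp = G_SI * t_fall

    az_imp, v_imp_arr = _impact_pulse(v_imp, fs)
    n_tail = round(spec.tail * fs)

    az = np.concatenate([np.zeros(n_pre), np.full(n_fall, G_SI), az_imp, np.zeros(n_tail)])
    vz = np.concatenate([np.zeros(n_pre), G_SI * tt, v_imp_arr, np.zeros(n_tail)])
    n = az.shape[0]
    acc_world = np.column_stack([np.zeros(n), np.zeros(n), az])
    zeros = np.zeros(n)

    # sample k of the fall phase sits at index n_pre - 1 + k, i.e. at time
    # release + k*dt with release at the last quiet sample
    release = (n_pre - 1) / fs
    collision = release + t_fall
    return _assemble(
        spec,
        rng,
        zeros,
        zeros.copy(),
        acc_world,
        vz,
        motion_class,
        True,
        collision,
        height,
        trial_id,
    )


def simulate_forward_fall(
    height: float,
    spec: MotionSpec | None = None,
    rng: np.random.Generator | None = None,
    trial_id: str = "forward_ffh",
) -> LabeledTrial:
    """Forward topple about the feet chained to a fall off the edge.

    The trunk rotates as an inverted pendulum (sensor at
    ``spec.sensor_arm`` above the pivot) from a small initial lean until
    horizontal, then the sensor follows a ballistic drop of the platform
    height. Ground-truth trunk tilt crosses 40 degrees strictly before
    impact, so the angle-and-velocity branch of the detector applies.
    """
    if height < _SENSOR_CLEARANCE:
        raise ValueError("height must exceed the sensor ground clearance")
    spec = spec or MotionSpec()
    rng = rng or np.random.default_rng()
    fs = spec.fs

    arm = spec.sensor_arm * _jit(rng, 0.05)
    theta0 = math.radians(2.0 * _jit(rng, 0.3))
    omega0 = math.radians(5.0 * _jit(rng, 0.3))
    n_pre = round(spec.quiet_prefix * _jit(rng, spec.timing_jitter) * fs)

    ts, theta, theta_dot, t_top = _pendulum(theta0, omega0, arm, fs, math.pi / 2)
    theta_ddot = (G_SI / arm) * np.sin(theta)
    ax_top = arm * (theta_ddot * np.cos(theta) - theta_dot**2 * np.sin(theta))
    az_top = arm * (theta_ddot * np.sin(theta) + theta_dot**2 * np.cos(theta))
    vz_top = arm * theta_dot * np.sin(theta)
    pitch_top = np.degrees(theta)

    # ballistic drop from the last topple sample to sensor ground clearance
    theta_m = float(theta[-1])
    v0 = float(vz_top[-1])
    drop = height + arm * math.cos(theta_m) - _SENSOR_CLEARANCE
    t_fall = (-v0 + math.sqrt(v0 * v0 + 2.0 * G_SI * drop)) / G_SI
    n_fall = int(t_fall * fs)
    tf = np.arange(1, n_fall + 1) / fs
    v_imp = v0 + G_SI * t_fall

    az_imp, v_imp_arr = _impact_pulse(v_imp, fs)
    n_tail = round(spec.tail * fs)
    pitch_hold = math.degrees(theta_m)

    az = np.concatenate(
        [np.zeros(n_pre), az_top, np.full(n_fall, G_SI), az_imp, np.zeros(n_tail)]
    )
    ax = np.concatenate(
        [np.zeros(n_pre), ax_top, np.zeros(n_fall + az_imp.shape[0] + n_tail)]
    )
    vz = np.concatenate(
        [np.zeros(n_pre), vz_top, v0 + G_SI * tf, v_imp_arr, np.zeros(n_tail)]
    )
    pitch = np.concatenate(
        [
            np.zeros(n_pre),
            pitch_top,
            np.full(n_fall + az_imp.shape[0] + n_tail, pitch_hold),
        ]
    )
    n = az.shape[0]
    acc_world = np.column_stack([ax, np.zeros(n), az])
    roll = np.zeros(n)

    t_release = (n_pre - 1) / fs + ts[-1]
    collision = t_release + t_fall
    return _assemble(
        spec,
        rng,
        roll,
        pitch,
        acc_world,
        vz,
        "forward_ffh",
        True,
        collision,
        height,
        trial_id,
    )


def simulate_jump_down(
    height: float,
    spec: MotionSpec | None = None,
    rng: np.random.Generator | None = None,
    trial_id: str = "jump",
) -> LabeledTrial:
    """Step-off jump from up to 1 m: crouch, flight, knee-flexion landing.

    Labeled non-FFH. The trunk pitch stays well below the detector's
    angle threshold while the descent speed is high; the knee-flexion
    pitch peak comes a quarter second after touchdown, by which time the
    attenuated velocity estimate has already decayed.
    """
    if not 0 < height <= 1.0:
        raise ValueError("jump height must lie in (0, 1] m")
    spec = spec or MotionSpec()
    rng = rng or np.random.default_rng()
    fs = spec.fs
    dt = 1.0 / fs

    n_pre = round(spec.quiet_prefix * _jit(rng, spec.timing_jitter) * fs)

    # crouch: smooth 0.15 m dip of the trunk over ~0.45 s
    t_crouch = 0.45 * _jit(rng, spec.timing_jitter)
    d_crouch = 0.15 * _jit(rng, spec.amplitude_jitter)
    n_crouch = round(t_crouch * fs)
    s, ds, dds = _smoothstep(n_crouch, t_crouch)
    az_crouch = d_crouch * dds
    vz_crouch = d_crouch * ds
    pitch_crouch = 12.0 * s

    # flight: ballistic drop of the platform height
    t_fall = math.sqrt(2.0 * height / G_SI)
    n_fall = int(t_fall * fs)
    tf = np.arange(1, n_fall + 1) / fs
    v_land = G_SI * t_fall
    pitch_flight = np.full(n_fall, 10.0)

    # landing: knee-flexion deceleration over 100-200 ms
    tau = 0.15 * _jit(rng, spec.timing_jitter)
    az_land, v_land_arr = _impact_pulse(v_land, fs, tau=tau)
    n_land = az_land.shape[0]

    # post-landing trunk flexion peaking ~0.25 s after touchdown
    n_flex = round(0.6 * fs)
    p_peak = float(np.clip(rng.normal(22.0, 4.0), 12.0, 32.0))
    t_up = 0.25
    n_up = round(t_up * fs)
    s_up, _, _ = _smoothstep(n_up, t_up)
    s_dn, _, _ = _smoothstep(n_flex - n_up, (n_flex - n_up) * dt)
    pitch_flex = np.concatenate(
        [10.0 + (p_peak - 10.0) * s_up, p_peak - (p_peak - 8.0) * s_dn]
    )
    n_tail = round(spec.tail * fs)

    az = np.concatenate(
        [
            np.zeros(n_pre),
            az_crouch,
            np.full(n_fall, G_SI),
            az_land,
            np.zeros(n_flex - n_land + n_tail),
        ]
    )
    vz = np.concatenate(
        [
            np.zeros(n_pre),
            vz_crouch,
            G_SI * tf,
            v_land_arr,
            np.zeros(n_flex - n_land + n_tail),
        ]
    )
    pitch = np.concatenate(
        [
            np.zeros(n_pre),
            pitch_crouch,
            pitch_flight,
            pitch_flex,
            np.full(n_tail, 8.0),
        ]
    )
    n = az.shape[0]
    acc_world = np.column_stack([np.zeros(n), np.zeros(n), az])
    roll = np.zeros(n)
    return _assemble(
        spec, rng, roll, pitch, acc_world, vz, "jump", False, None, height, trial_id
    )


# ---------------------------------------------------------------------------
# worksite fall scenarios
# ---------------------------------------------------------------------------


def simulate_scaffold_fall(
    height: float,
    spec: MotionSpec | None = None,
    rng: np.random.Generator | None = None,
    trial_id: str = "scaffold_ffh",
) -> LabeledTrial:
    """Scaffold collapse: partial outward tilt, then near-vertical fall.

    The trunk tilts to ~22 degrees as the platform gives way, staying
    below the angle threshold, so detection relies on the velocity-only
    branch during the fall.
    """
    spec = spec or MotionSpec()
    rng = rng or np.random.default_rng()
    fs = spec.fs
    arm = spec.sensor_arm

    n_pre = round(spec.quiet_prefix * _jit(rng, spec.timing_jitter) * fs)
    tilt = math.radians(22.0 * _jit(rng, 0.15))
    t_tilt = 0.8 * _jit(rng, spec.timing_jitter)
    n_tilt = round(t_tilt * fs)
    s, ds, dds = _smoothstep(n_tilt, t_tilt)
    d_tilt = arm * (1.0 - math.cos(tilt))  # sensor dip while tilting
    az_tilt = d_tilt * dds
    vz_tilt = d_tilt * ds
    pitch_tilt = np.degrees(tilt) * s

    drop = height - d_tilt - _SENSOR_CLEARANCE
    t_fall = math.sqrt(2.0 * drop / G_SI)
    n_fall = int(t_fall * fs)
    tf = np.arange(1, n_fall + 1) / fs
    v_imp = G_SI * t_fall
    az_imp, v_imp_arr = _impact_pulse(v_imp, fs)
    n_tail = round(spec.tail * fs)
    n_post = az_imp.shape[0] + n_tail

    az = np.concatenate([np.zeros(n_pre), az_tilt, np.full(n_fall, G_SI), az_imp, np.zeros(n_tail)])
    vz = np.concatenate([np.zeros(n_pre), vz_tilt, G_SI * tf, v_imp_arr, np.zeros(n_tail)])
    pitch = np.concatenate(
        [np.zeros(n_pre), pitch_tilt, np.full(n_fall + n_post, np.degrees(tilt))]
    )
    n = az.shape[0]
    acc_world = np.column_stack([np.zeros(n), np.zeros(n), az])
    collision = (n_pre + n_tilt - 1) / fs + t_fall
    return _assemble(
        spec,
        rng,
        np.zeros(n),
        pitch,
        acc_world,
        vz,
        "scaffold_ffh",
        True,
        collision,
        height,
        trial_id,
    )


def simulate_roof_fall(
    height: float,
    spec: MotionSpec | None = None,
    rng: np.random.Generator | None = None,
    trial_id: str = "roof_ffh",
) -> LabeledTrial:
    """Roof slide followed by a near-vertical fall off the eave.

    The worker lies on a ~28 degree pitch while sliding slowly (the
    vertical acceleration stays below the integration gate), then drops
    off the eave with a small initial downward speed.
    """
    spec = spec or MotionSpec()
    rng = rng or np.random.default_rng()
    fs = spec.fs

    n_pre = round(spec.quiet_prefix * _jit(rng, spec.timing_jitter) * fs)
    slope = 28.0 * _jit(rng, 0.1)
    t_lean = 0.5
    n_lean = round(t_lean * fs)
    s_lean, _, _ = _smoothstep(n_lean, t_lean)
    pitch_lean = slope * s_lean

    t_slide = 1.5 * _jit(rng, spec.timing_jitter)
    n_slide = round(t_slide * fs)
    a_slide = 0.2  # m/s^2 vertical component of the slide acceleration
    ts = np.arange(1, n_slide + 1) / fs
    az_slide = np.full(n_slide, a_slide)
    vz_slide = a_slide * ts
    v0 = float(vz_slide[-1])

    drop = height - _SENSOR_CLEARANCE
    t_fall = (-v0 + math.sqrt(v0 * v0 + 2.0 * G_SI * drop)) / G_SI
    n_fall = int(t_fall * fs)
    tf = np.arange(1, n_fall + 1) / fs
    v_imp = v0 + G_SI * t_fall
    az_imp, v_imp_arr = _impact_pulse(v_imp, fs)
    n_tail = round(spec.tail * fs)

    az = np.concatenate(
        [np.zeros(n_pre + n_lean), az_slide, np.full(n_fall, G_SI), az_imp, np.zeros(n_tail)]
    )
    vz = np.concatenate(
        [np.zeros(n_pre + n_lean), vz_slide, v0 + G_SI * tf, v_imp_arr, np.zeros(n_tail)]
    )
    pitch = np.concatenate(
        [
            np.zeros(n_pre),
            pitch_lean,
            np.full(n_slide + n_fall + az_imp.shape[0] + n_tail, slope),
        ]
    )
    n = az.shape[0]
    acc_world = np.column_stack([np.zeros(n), np.zeros(n), az])
    collision = (n_pre + n_lean + n_slide - 1) / fs + t_fall
    return _assemble(
        spec,
        rng,
        np.zeros(n),
        pitch,
        acc_world,
        vz,
        "roof_ffh",
        True,
        collision,
        height,
        trial_id,
    )


def simulate_ladder_fall(
    height: float,
    spec: MotionSpec | None = None,
    rng: np.random.Generator | None = None,
    trial_id: str = "ladder_ffh",
) -> LabeledTrial:
    """Backward topple from a ladder: pendulum of radius ``height``.

    The trunk angle grows through the detector's angle threshold well
    before floor contact, so this scenario is detected by the
    angle-and-velocity branch, like forward falls.
    """
    spec = spec or MotionSpec()
    rng = rng or np.random.default_rng()
    fs = spec.fs
    radius = height

    n_pre = round(spec.quiet_prefix * _jit(rng, spec.timing_jitter) * fs)
    theta0 = math.radians(2.0 * _jit(rng, 0.3))
    omega0 = math.radians(5.0 * _jit(rng, 0.3))
    theta_imp = math.acos(min(1.0, _SENSOR_CLEARANCE / radius))
    ts, theta, theta_dot, t_top = _pendulum(theta0, omega0, radius, fs, theta_imp)
    theta_ddot = (G_SI / radius) * np.sin(theta)
    ax_top = radius * (theta_ddot * np.cos(theta) - theta_dot**2 * np.sin(theta))
    az_top = radius * (theta_ddot * np.sin(theta) + theta_dot**2 * np.cos(theta))
    vz_top = radius * theta_dot * np.sin(theta)
    pitch_top = -np.degrees(theta)  # backward lean

    v_imp = float(radius * theta_dot[-1])  # sensor speed at floor contact
    az_imp, v_imp_arr = _impact_pulse(float(vz_top[-1]), fs)
    n_tail = round(spec.tail * fs)
    n_post = az_imp.shape[0] + n_tail

    az = np.concatenate([np.zeros(n_pre), az_top, az_imp, np.zeros(n_tail)])
    ax = np.concatenate([np.zeros(n_pre), ax_top, np.zeros(n_post)])
    vz = np.concatenate([np.zeros(n_pre), vz_top, v_imp_arr, np.zeros(n_tail)])
    pitch = np.concatenate([np.zeros(n_pre), pitch_top, np.full(n_post, pitch_top[-1])])
    n = az.shape[0]
    acc_world = np.column_stack([ax, np.zeros(n), az])
    collision = (n_pre - 1) / fs + t_top
    return _assemble(
        spec,
        rng,
        np.zeros(n),
        pitch,
        acc_world,
        vz,
        "ladder_ffh",
        True,
        collision,
        height,
        trial_id,
    )


# ---------------------------------------------------------------------------
# occupational non-fall motions
# ---------------------------------------------------------------------------


def _osc(n: int, fs: float, amp_g: float, freq: float, ramp: float = 0.3):
    """Windowed vertical oscillation: returns az (m/s^2) with smooth edges."""
    tt = np.arange(1, n + 1) / fs
    total = n / fs
    env = np.minimum(1.0, np.minimum(tt / ramp, (total - tt) / ramp).clip(min=0.0))
    return amp_g * G_SI * np.sin(2 * math.pi * freq * tt) * env


def _angle_move(n_total, fs, t0, t_up, hold, t_down, amp):
    """Angle profile: ramp up, hold, ramp back down (degrees)."""
    out = np.zeros(n_total)
    i0 = round(t0 * fs)
    n_up = round(t_up * fs)
    n_hold = round(hold * fs)
    n_down = round(t_down * fs)
    s_up, _, _ = _smoothstep(n_up, t_up)
    s_down, _, _ = _smoothstep(n_down, t_down)
    i = i0
    out[i : i + n_up] = amp * s_up
    i += n_up
    out[i : i + n_hold] = amp
    i += n_hold
    out[i : i + n_down] = amp * (1 - s_down)
    out[i + n_down :] = 0.0
    return out


def _zmove(n_total, fs, t0, duration, depth):
    """Vertical dip contribution: returns (az, vz) for a smoothstep descent."""
    az = np.zeros(n_total)
    vz = np.zeros(n_total)
    i0 = round(t0 * fs)
    n = round(duration * fs)
    _, ds, dds = _smoothstep(n, duration)
    az[i0 : i0 + n] = depth * dds
    vz[i0 : i0 + n] = depth * ds
    return az, vz


def _build_adl(spec, rng, motion_class, duration, pitch, roll, az, trial_id):
    """Common tail for ADL builders: integrate vz numerically and assemble."""
    n = az.shape[0]
    dt = 1.0 / spec.fs
    vz = np.concatenate([[0.0], np.cumsum((az[1:] + az[:-1]) * 0.5 * dt)])
    acc_world = np.column_stack([np.zeros(n), np.zeros(n), az])
    return _assemble(
        spec, rng, roll, pitch, acc_world, vz, motion_class, False, None, None, trial_id
    )


def simulate_adl(
    motion_class: str,
    spec: MotionSpec | None = None,
    rng: np.random.Generator | None = None,
    trial_id: str | None = None,
) -> LabeledTrial:
    """Generate one non-fall occupational motion trial by class name."""
    spec = spec or MotionSpec()
    rng = rng or np.random.default_rng()
    if motion_class == "jump":
        return simulate_jump_down(0.7, spec, rng, trial_id or "jump")
    if motion_class not in NONFFH_CLASSES:
        raise ValueError(f"unknown non-FFH motion class {motion_class!r}")
    fs = spec.fs
    tj = spec.timing_jitter
    aj = spec.amplitude_jitter
    pre = spec.quiet_prefix * _jit(rng, tj)
    trial_id = trial_id or motion_class

    if motion_class == "sit_quick":
        total = pre + 3.0
        n = round(total * fs)
        pitch = _angle_move(n, fs, pre, 0.5, 0.8, 0.7, 18.0 * _jit(rng, aj))
        az1, _ = _zmove(n, fs, pre, 0.7 * _jit(rng, tj), 0.35 * _jit(rng, aj))
        az2, _ = _zmove(n, fs, pre + 1.6, 0.8, -0.35 * _jit(rng, aj))
        return _build_adl(spec, rng, motion_class, total, pitch, np.zeros(n), az1 + az2, trial_id)

    if motion_class == "sit_floor":
        total = pre + 4.0
        n = round(total * fs)
        pitch = _angle_move(n, fs, pre, 1.0, 1.2, 1.0, 25.0 * _jit(rng, aj))
        az1, _ = _zmove(n, fs, pre, 1.1 * _jit(rng, tj), 0.6 * _jit(rng, aj))
        az2, _ = _zmove(n, fs, pre + 2.4, 1.2, -0.6 * _jit(rng, aj))
        return _build_adl(spec, rng, motion_class, total, pitch, np.zeros(n), az1 + az2, trial_id)

    if motion_class in ("stairs", "ladder_climb", "scaffold_climb"):
        amp, freq = {
            "stairs": (0.25, 1.6),
            "ladder_climb": (0.20, 1.2),
            "scaffold_climb": (0.22, 1.0),
        }[motion_class]
        total = pre + 5.0
        n = round(total * fs)
        n_move = n - round(pre * fs) - round(spec.tail * fs)
        az = np.zeros(n)
        i0 = round(pre * fs)
        az[i0 : i0 + n_move] = _osc(n_move, fs, amp * _jit(rng, aj), freq * _jit(rng, tj))
        sway = 6.0 * _jit(rng, aj)
        tt = np.arange(n) / fs
        gait = np.sin(2 * math.pi * freq * (tt - pre)) * (az != 0)
        pitch = 8.0 * _jit(rng, aj) * gait * 0.5 + (
            10.0 if motion_class == "ladder_climb" else 0.0
        ) * (az != 0)
        roll = sway * 0.5 * np.sin(2 * math.pi * 0.5 * freq * (tt - pre)) * (az != 0)
        return _build_adl(spec, rng, motion_class, total, pitch, roll, az, trial_id)

    if motion_class in ("pickaxe", "shovel"):
        swing_amp = (30.0 if motion_class == "pickaxe" else 32.0) * _jit(rng, aj)
        swing_freq = (0.8 if motion_class == "pickaxe" else 0.5) * _jit(rng, tj)
        burst_amp = (1.0 if motion_class == "pickaxe" else 0.5) * _jit(rng, aj)
        burst_freq = 10.0 if motion_class == "pickaxe" else 8.0
        n_strikes = 4 if motion_class == "pickaxe" else 3
        period = 1.0 / swing_freq
        total = pre + n_strikes * period + spec.tail
        n = round(total * fs)
        tt = np.arange(n) / fs
        work = (tt >= pre) & (tt < pre + n_strikes * period)
        pitch = swing_amp * 0.5 * (1 - np.cos(2 * math.pi * swing_freq * (tt - pre))) * work
        az = np.zeros(n)
        for k in range(n_strikes):
            t_hit = pre + (k + 0.95) * period
            i0 = round(t_hit * fs)
            n_b = round(0.2 * fs)
            if i0 + n_b > n:
                break
            tb = np.arange(1, n_b + 1) / fs
            az[i0 : i0 + n_b] += (
                burst_amp
                * G_SI
                * np.exp(-25.0 * tb)
                * np.sin(2 * math.pi * burst_freq * tb)
            )
        return _build_adl(spec, rng, motion_class, total, pitch, np.zeros(n), az, trial_id)

    if motion_class in ("lift_front", "lift_back", "lift_side"):
        amp = {
            "lift_front": 75.0,
            "lift_back": 80.0,
            "lift_side": 42.0,
        }[motion_class] * _jit(rng, 0.08)
        t_bend = (1.8 if motion_class != "lift_back" else 2.2) * _jit(rng, tj)
        total = pre + t_bend * 2 + 1.0 + spec.tail
        n = round(total * fs)
        angle = _angle_move(n, fs, pre, t_bend, 1.0, t_bend, amp)
        # trunk dip as the body bends over the hip pivot
        depth = _TRUNK_ARM * (1.0 - math.cos(math.radians(amp)))
        az1, _ = _zmove(n, fs, pre, t_bend, depth)
        az2, _ = _zmove(n, fs, pre + t_bend + 1.0, t_bend, -depth)
        if motion_class == "lift_side":
            return _build_adl(spec, rng, motion_class, total, np.zeros(n), angle, az1 + az2, trial_id)
        return _build_adl(spec, rng, motion_class, total, angle, np.zeros(n), az1 + az2, trial_id)

    if motion_class in ("beam_walk", "beam_walk_luggage"):
        total = pre + 6.0
        n = round(total * fs)
        freq = 1.8 * _jit(rng, tj)
        roll_amp = (6.0 if motion_class == "beam_walk" else 9.0) * _jit(rng, aj)
        tt = np.arange(n) / fs
        i0 = round(pre * fs)
        n_move = n - i0 - round(spec.tail * fs)
        az = np.zeros(n)
        az[i0 : i0 + n_move] = _osc(n_move, fs, 0.12 * _jit(rng, aj), freq)
        walking = az != 0
        roll = roll_amp * np.sin(2 * math.pi * 0.5 * freq * (tt - pre)) * walking
        pitch = 3.0 * np.sin(2 * math.pi * freq * (tt - pre)) * walking
        return _build_adl(spec, rng, motion_class, total, pitch, roll, az, trial_id)

    if motion_class == "stretch":
        total = pre + 7.0
        n = round(total * fs)
        pitch_back = _angle_move(n, fs, pre, 1.5, 0.5, 1.5, -25.0 * _jit(rng, aj))
        pitch_fwd = _angle_move(n, fs, pre + 3.5, 1.2, 0.5, 1.2, 45.0 * _jit(rng, 0.08))
        roll = _angle_move(n, fs, pre + 1.0, 1.0, 0.3, 1.0, 25.0 * _jit(rng, aj))
        az = np.zeros(n)
        return _build_adl(spec, rng, motion_class, total, pitch_back + pitch_fwd, roll, az, trial_id)

    if motion_class == "elevator":
        total = pre + 6.0
        n = round(total * fs)
        az = np.zeros(n)
        amp = 0.1 * _jit(rng, aj) * G_SI
        for t0, sign in ((pre, 1.0), (pre + 1.9, -1.0), (pre + 2.8, -1.0), (pre + 4.7, 1.0)):
            i0 = round(t0 * fs)
            n_p = round(0.4 * fs)
            s, _, dds = _smoothstep(n_p, 0.4)
            az[i0 : i0 + n_p] += sign * amp * np.sin(math.pi * np.arange(1, n_p + 1) / n_p)
        return _build_adl(spec, rng, motion_class, total, np.zeros(n), np.zeros(n), az, trial_id)

    raise ValueError(f"no template for motion class {motion_class!r}")


# ---------------------------------------------------------------------------
# suite designs
# ---------------------------------------------------------------------------

DESIGNS = ("experiment-1", "experiment-2", "mannequin", "worksite")

_DESIGN_DEFAULTS = {
    "experiment-1": (10, 3),
    "experiment-2": (20, 3),
    "mannequin": (1, 5),
    "worksite": (1, 1),
}


def make_suite(
    design: str,
    n_subjects: int | None = None,
    reps: int | None = None,
    seed: int = 0,
    spec: MotionSpec | None = None,
) -> list[LabeledTrial]:
    """Generate a full labeled suite for one of the study designs.

    * ``experiment-1``: 9 non-FFH motion classes plus the 0.7 m forward
      fall, per subject and repetition (defaults 10 subjects x 3 reps).
    * ``experiment-2``: all 15 non-FFH classes plus the 0.7 m forward
      fall (defaults 20 subjects x 3 reps).
    * ``mannequin``: vertical and forward falls at 2, 2.5 and 3 m,
      5 repetitions each.
    * ``worksite``: scaffold, roof and ladder falls at 3, 4.5 and 6 m.

    Subject stature and per-trial jitter are drawn from a seeded stream;
    the same seed reproduces the suite bit-for-bit.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    base_spec = spec or MotionSpec()
    d_subj, d_reps = _DESIGN_DEFAULTS[design]
    n_subjects = d_subj if n_subjects is None else n_subjects
    reps = d_reps if reps is None else reps
    if n_subjects < 1 or reps < 1:
        raise ValueError("n_subjects and reps must be >= 1")
    root = np.random.SeedSequence(seed)
    trials: list[LabeledTrial] = []

    if design in ("experiment-1", "experiment-2"):
        classes = list(EXP1_NONFFH if design == "experiment-1" else NONFFH_CLASSES)
        for subj, ss in enumerate(root.spawn(n_subjects)):
            rng = np.random.default_rng(ss)
            subj_spec = replace(base_spec, stature=float(rng.normal(1.74, 0.049)))
            for rep in range(reps):
                for cls in classes:
                    tid = f"{design}_s{subj:02d}_{cls}_r{rep}"
                    trials.append(simulate_adl(cls, subj_spec, rng, tid))
                tid = f"{design}_s{subj:02d}_forward_ffh_r{rep}"
                trials.append(simulate_forward_fall(0.7, subj_spec, rng, tid))
        return trials

    if design == "mannequin":
        rng = np.random.default_rng(root)
        spec_m = replace(base_spec, stature=1.80)
        for height in (2.0, 2.5, 3.0):
            for rep in range(reps):
                tid = f"mannequin_vertical_{height:g}m_r{rep}"
                trials.append(simulate_vertical_fall(height, spec_m, rng, tid))
                tid = f"mannequin_forward_{height:g}m_r{rep}"
                trials.append(simulate_forward_fall(height, spec_m, rng, tid))
        return trials

    # worksite
    rng = np.random.default_rng(root)
    spec_w = replace(base_spec, stature=1.70)
    builders = {
        "scaffold": simulate_scaffold_fall,
        "roof": simulate_roof_fall,
        "ladder": simulate_ladder_fall,
    }
    for scenario, builder in builders.items():
        for height in (3.0, 4.5, 6.0):
            for rep in range(reps):
                tid = f"worksite_{scenario}_{height:g}m_r{rep}"
                trials.append(builder(height, spec_w, rng, tid))
    return trials
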