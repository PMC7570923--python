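"""Roll/pitch estimation with a PI-corrected complementary filter.

Per axis, the gyroscope rate is integrated while the quasi-static tilt
implied by the accelerometer is fed back through a proportional-integral
controller: the angle advance rate is the gyro rate plus Kp*e + Ki*int(e),
where e is the accelerometer-minus-estimate error. The integral term
absorbs constant gyro bias. The accelerometer branch is gated out whenever
the specific-force magnitude deviates from 1 g by more than a configurable
amount, so the filter is purely gyro-driven in free fall and during
impacts, exactly when the accelerometer carries no tilt information.

The vertical angle (VA) is the tilt of the trunk longitudinal axis from
the gravity vertical, acos(cos(roll) * cos(pitch)); it is yaw-invariant,
symmetric in the sign of roll and pitch, and zero when upright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imu_core import ImuTrace

_RAD2DEG = 180.0 / math.pi


@dataclass
class OrientationConfig:
    """Complementary-filter gains and accelerometer gating.

    kp : proportional gain (1/s per degree of tilt error, dimensionless
         in the degrees domain), default 1.0.
    ki : integral gain (1/s^2 equivalent), default 0.1.
    accel_gate : accelerometer branch is ignored when | |a| - 1 g |
         exceeds this value (g), default 0.5.
    """

    kp: float = 1.0
    ki: float = 0.1
    accel_gate: float = 0.5


@dataclass
class OrientationState:
    """Filter state: angles (deg) and the per-axis PI accumulators (deg*s)."""

    roll: float = 0.0
    pitch: float = 0.0
    ierr_roll: float = 0.0
    ierr_pitch: float = 0.0


@dataclass
class OrientationSeries:
    """Per-sample roll, pitch and vertical angle, all in degrees."""

    roll: np.ndarray
    pitch: np.ndarray
    vertical_angle: np.ndarray


def _wrap(angle: float) -> float:
    return (angle + 180.0) % 360.0 - 180.0


def accel_tilt(a: np.ndarray) -> tuple[float, float, bool]:
    """Quasi-static tilt implied by gravity on the specific force ``a`` (g).

    Returns ``(roll_deg, pitch_deg, reliable)``. The tilt is unreliable
    (and the returned flag False) when the specific-force norm is near
    zero, i.e. in free fall, where the direction of gravity cannot be
    inferred from the accelerometer.
    """
    ax, ay, az = float(a[0]), float(a[1]), float(a[2])
    norm = math.sqrt(ax * ax + ay * ay + az * az)
    if norm < 1e-6:
        return 0.0, 0.0, False
    # 0.0 - x instead of -x: keeps atan2(+0, +0) = 0 when a channel is zero
    roll = math.atan2(0.0 - ay, 0.0 - az) * _RAD2DEG
    pitch = math.atan2(ax, 0.0 - az) * _RAD2DEG
    return roll, pitch, True


def update_orientation(
    state: OrientationState,
    w: np.ndarray,
    a: np.ndarray,
    dt: float,
    cfg: OrientationConfig | None = None,
) -> OrientationState:
    """Advance the filter by one sample (w in deg/s, a in g)."""
    cfg = cfg or OrientationConfig()
    if dt <= 0:
        raise ValueError("dt must be positive")
    wx, wy, wz = float(w[0]), float(w[1]), float(w[2])
    ax, ay, az = float(a[0]), float(a[1]), float(a[2])
    roll, pitch = state.roll, state.pitch
    ierr_r, ierr_p = state.ierr_roll, state.ierr_pitch

    norm = math.sqrt(ax * ax + ay * ay + az * az)
    use_accel = abs(norm - 1.0) <= cfg.accel_gate and norm > 1e-6
    if use_accel:
        roll_acc = math.atan2(0.0 - ay, 0.0 - az) * _RAD2DEG
        pitch_acc = math.atan2(ax, 0.0 - az) * _RAD2DEG
        e_r = _wrap(roll_acc - roll)
        e_p = _wrap(pitch_acc - pitch)
        ierr_r += e_r * dt
        ierr_p += e_p * dt
    else:
        e_r = e_p = 0.0

    # Euler-rate mapping for the y-x rotation order (yaw not estimated):
    # body rates (p, q, r) give roll' = p, pitch' = q cos(roll) - r sin(roll).
    roll_rad = math.radians(roll)
    roll_rate = wx + cfg.kp * e_r + cfg.ki * ierr_r
    pitch_rate = (
        wy * math.cos(roll_rad)
        - wz * math.sin(roll_rad)
        + cfg.kp * e_p
        + cfg.ki * ierr_p
    )
    return OrientationState(
        roll=_wrap(roll + roll_rate * dt),
        pitch=_wrap(pitch + pitch_rate * dt),
        ierr_roll=ierr_r,
        ierr_pitch=ierr_p,
    )


def vertical_angle(roll, pitch):
    """Combined tilt of the trunk axis from vertical, in degrees [0, 180]."""
    r = np.radians(roll)
    p = np.radians(pitch)
    return np.degrees(np.arccos(np.clip(np.cos(r) * np.cos(p), -1.0, 1.0)))


def estimate_orientation(
    trace: ImuTrace,
    cfg: OrientationConfig | None = None,
    init: tuple[float, float] | None = None,
) -> OrientationSeries:
    """Run the complementary filter over a (filtered) trace.

    The initial angles default to the accelerometer tilt of the first
    sample when it is reliable, otherwise (0, 0). The loop is written
    with plain floats: it is the per-sample hot path of the pipeline.
    """
    cfg = cfg or OrientationConfig()
    dt = trace.dt
    kp, ki, gate = cfg.kp, cfg.ki, cfg.accel_gate
    axs, ays, azs = (trace.acc[:, j].tolist() for j in range(3))
    wxs, wys, wzs = (trace.gyro[:, j].tolist() for j in range(3))
    n = trace.n

    if init is not None:
        roll, pitch = float(init[0]), float(init[1])
    else:
        roll, pitch, ok = accel_tilt(trace.acc[0])
        if not ok:
            roll = pitch = 0.0
    ierr_r = ierr_p = 0.0
    rolls = [roll]
    pitches = [pitch]

    atan2, sqrt, cos, sin, radians = (
        math.atan2,
        math.sqrt,
        math.cos,
        math.sin,
        math.radians,
    )
    for i in range(1, n):
        ax, ay, az = axs[i], ays[i], azs[i]
        norm = sqrt(ax * ax + ay * ay + az * az)
        if abs(norm - 1.0) <= gate and norm > 1e-6:
            e_r = (atan2(0.0 - ay, 0.0 - az) * _RAD2DEG - roll + 180.0) % 360.0 - 180.0
            e_p = (atan2(ax, 0.0 - az) * _RAD2DEG - pitch + 180.0) % 360.0 - 180.0
            ierr_r += e_r * dt
            ierr_p += e_p * dt
        else:
            e_r = e_p = 0.0
        roll_rad = radians(roll)
        roll += (wxs[i] + kp * e_r + ki * ierr_r) * dt
        pitch += (
            wys[i] * cos(roll_rad) - wzs[i] * sin(roll_rad) + kp * e_p + ki * ierr_p
        ) * dt
        roll = (roll + 180.0) % 360.0 - 180.0
        pitch = (pitch + 180.0) % 360.0 - 180.0
        rolls.append(roll)
        pitches.append(pitch)

    roll_arr = np.asarray(rolls)
    pitch_arr = np.asarray(pitches)
    return OrientationSeries(
        roll=roll_arr,
        pitch=pitch_arr,
        vertical_angle=vertical_angle(roll_arr, pitch_arr),
    )
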