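"""Gravity-compensated vertical acceleration and gated velocity integration.

The measured specific force is rotated into the global frame with the
roll/pitch Euler transform; the vertical channel plus 1 g is the vertical
acceleration a_v (0 g at rest, +1 g in ideal free fall, downward positive).
The vertical velocity v_v is obtained by a conditionally gated Simpson
integration: while a_v exceeds a gate (default 0.24 g) the three-point
Simpson rule advances the estimate, scaled by a correction factor
(default 1.2) that compensates for the velocity missed before the gate
opens; otherwise the estimate is attenuated geometrically (default 0.9
per sample), which resets it toward zero between movements and kills
integration drift.

The Simpson recurrence advances v_t from v_{t-2} at every sample, so two
interleaved integration chains coexist; they mix whenever the attenuation
branch fires. This literal per-sample form is the package default; a
non-overlapping "strided" variant is available for sensitivity analysis
via :class:`IntegrationConfig.mode`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imu_core import G_SI, ImuTrace
from .orientation import OrientationSeries


@dataclass
class IntegrationConfig:
    """Gated-integration constants (gate in g, correction dimensionless)."""

    gate: float = 0.24
    attenuation: float = 0.9
    correction: float = 1.2
    g_si: float = G_SI
    mode: str = "interleaved"  # or "strided"

    def __post_init__(self) -> None:
        if not 0 < self.attenuation < 1:
            raise ValueError("attenuation must lie in (0, 1)")
        if self.gate <= 0 or self.correction <= 0:
            raise ValueError("gate and correction must be positive")
        if self.mode not in ("interleaved", "strided"):
            raise ValueError(f"unknown integration mode {self.mode!r}")


@dataclass
class KinematicSeries:
    """Global acceleration (g), vertical acceleration (g), velocity (m/s)."""

    a_g: np.ndarray
    a_v: np.ndarray
    v_v: np.ndarray


def rotation_matrix(roll_deg: float, pitch_deg: float) -> np.ndarray:
    """Local-to-global rotation for roll about x and pitch about y."""
    r = np.radians(roll_deg)
    p = np.radians(pitch_deg)
    cr, sr, cp, sp = np.cos(r), np.sin(r), np.cos(p), np.sin(p)
    return np.array(
        [
            [cp, sp * sr, sp * cr],
            [0.0, cr, -sr],
            [-sp, cp * sr, cp * cr],
        ]
    )


def global_acceleration(acc: np.ndarray, roll_deg, pitch_deg) -> np.ndarray:
    """Rotate specific force (n, 3) into the global frame, vectorized."""
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    r = np.radians(np.asarray(roll_deg, dtype=float))
    p = np.radians(np.asarray(pitch_deg, dtype=float))
    cr, sr, cp, sp = np.cos(r), np.sin(r), np.cos(p), np.sin(p)
    ax, ay, az = acc[:, 0], acc[:, 1], acc[:, 2]
    return np.column_stack(
        [
            cp * ax + sp * sr * ay + sp * cr * az,
            cr * ay - sr * az,
            -sp * ax + cp * sr * ay + cp * cr * az,
        ]
    )


def vertical_acceleration(az_g) -> np.ndarray:
    """a_v = a_z,global + 1 g: zero at rest, +1 g in ideal free fall."""
    return np.asarray(az_g, dtype=float) + 1.0


def update_vv(
    v_prev2: float,
    v_prev1: float,
    a_window: tuple[float, float, float],
    dt: float,
    cfg: IntegrationConfig | None = None,
) -> float:
    """One step of the gated Simpson recurrence (window = a_{t-2..t}, g)."""
    cfg = cfg or IntegrationConfig()
    a2, a1, a0 = a_window
    if a0 > cfg.gate:
        v = v_prev2 + cfg.correction * cfg.g_si * (a2 + 4.0 * a1 + a0) * dt / 3.0
    else:
        v = v_prev1 * cfg.attenuation
    return max(0.0, v)


def integrate_vertical_velocity(
    a_v: np.ndarray, dt: float, cfg: IntegrationConfig | None = None
) -> np.ndarray:
    """Run the recurrence over a vertical-acceleration series (g -> m/s).

    The first two samples are the warm-up of the three-point rule and are
    zero by definition. The estimate is clamped at zero from below: it is
    a downward-speed estimate and upward motion must not accumulate a
    negative "fall speed".
    """
    cfg = cfg or IntegrationConfig()
    a = np.asarray(a_v, dtype=float).tolist()
    n = len(a)
    v = [0.0] * n
    if n < 3:
        return np.asarray(v)
    k = cfg.correction * cfg.g_si * dt / 3.0
    gate = cfg.gate
    att = cfg.attenuation
    if cfg.mode == "interleaved":
        for i in range(2, n):
            if a[i] > gate:
                vi = v[i - 2] + k * (a[i - 2] + 4.0 * a[i - 1] + a[i])
            else:
                vi = v[i - 1] * att
            v[i] = vi if vi > 0.0 else 0.0
    else:  # strided: non-overlapping Simpson windows, hold in between
        anchor = 0
        for i in range(2, n):
            if a[i] > gate:
                if (i - anchor) % 2 == 0:
                    vi = v[i - 2] + k * (a[i - 2] + 4.0 * a[i - 1] + a[i])
                else:
                    vi = v[i - 1]
            else:
                vi = v[i - 1] * att
                anchor = i
            v[i] = vi if vi > 0.0 else 0.0
    return np.asarray(v)


def compute_kinematics(
    trace: ImuTrace,
    orient: OrientationSeries,
    cfg: IntegrationConfig | None = None,
) -> KinematicSeries:
    """Full kinematic stage on an already low-pass-filtered trace."""
    cfg = cfg or IntegrationConfig()
    a_g = global_acceleration(trace.acc, orient.roll, orient.pitch)
    a_v = vertical_acceleration(a_g[:, 2])
    v_v = integrate_vertical_velocity(a_v, trace.dt, cfg)
    return KinematicSeries(a_g=a_g, a_v=a_v, v_v=v_v)
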