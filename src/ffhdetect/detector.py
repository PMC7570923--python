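"""Streaming two-branch threshold detector with latching.

A fall from height is declared at the first sample where either

* the vertical angle exceeds ``va_th`` AND the vertical velocity exceeds
  ``vv_low`` (angle-and-velocity branch: topples, forward falls), or
* the vertical velocity alone exceeds ``vv_high`` (velocity-only branch:
  vertical falls in which the trunk angle never changes).

The decision latches: the first firing sample is the detection time and
later samples cannot change it. The scan is strictly causal, so the same
decision would be produced sample-by-sample in real time on the sensor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .imu_core import ImuTrace, MIN_SAMPLES
from .kinematics import IntegrationConfig, KinematicSeries, compute_kinematics
from .orientation import OrientationConfig, OrientationSeries, estimate_orientation
from .preprocessing import FilterConfig, lowpass

BRANCH_ANGLE = "angle-and-velocity"
BRANCH_VELOCITY = "velocity-only"


@dataclass
class ThresholdConfig:
    """Detector thresholds: va_th (deg), vv_low and vv_high (m/s)."""

    va_th: float = 40.0
    vv_low: float = 1.8
    vv_high: float = 5.0

    def __post_init__(self) -> None:
        if not self.vv_low < self.vv_high:
            raise ValueError("vv_low must be below vv_high")
        if self.va_th <= 0:
            raise ValueError("va_th must be positive")


@dataclass
class PipelineConfig:
    """Bundle of the signal-processing stages ahead of the thresholds."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    orientation: OrientationConfig = field(default_factory=OrientationConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)


@dataclass
class DetectionResult:
    detected: bool
    detection_time: Optional[float] = None
    branch: Optional[str] = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)

    def to_dict(self) -> dict:
        return {
            "detected": self.detected,
            "detection_time": self.detection_time,
            "branch": self.branch,
            "thresholds": {
                "va_th": self.thresholds.va_th,
                "vv_low": self.thresholds.vv_low,
                "vv_high": self.thresholds.vv_high,
            },
        }


def step(va: float, vv: float, cfg: ThresholdConfig | None = None):
    """Single-sample decision. Returns (fire, branch).

    The angle-and-velocity branch takes precedence when both disjuncts
    hold at the same sample.
    """
    cfg = cfg or ThresholdConfig()
    if va > cfg.va_th and vv > cfg.vv_low:
        return True, BRANCH_ANGLE
    if vv > cfg.vv_high:
        return True, BRANCH_VELOCITY
    return False, None


def detect_series(
    t: np.ndarray,
    va: np.ndarray,
    vv: np.ndarray,
    cfg: ThresholdConfig | None = None,
    confirm: int = 1,
) -> DetectionResult:
    """Scan precomputed VA/VV series causally and latch on the first fire.

    ``confirm`` requires that many consecutive firing samples before
    latching (default 1: one-shot, as for airbag deployment); detection
    time is the first sample of the confirmed run.
    """
    cfg = cfg or ThresholdConfig()
    if confirm < 1:
        raise ValueError("confirm must be >= 1")
    angle_fire = (va > cfg.va_th) & (vv > cfg.vv_low)
    vel_fire = vv > cfg.vv_high
    fire = angle_fire | vel_fire
    run = 0
    for i, f in enumerate(fire):
        run = run + 1 if f else 0
        if run >= confirm:
            first = i - confirm + 1
            branch = BRANCH_ANGLE if angle_fire[first] else BRANCH_VELOCITY
            return DetectionResult(
                detected=True,
                detection_time=float(t[first]),
                branch=branch,
                thresholds=cfg,
            )
    return DetectionResult(detected=False, thresholds=cfg)


def process_trace(
    trace: ImuTrace, pipe: PipelineConfig | None = None
) -> tuple[ImuTrace, OrientationSeries, KinematicSeries]:
    """Filter -> orientation -> kinematics; returns all three stages."""
    pipe = pipe or PipelineConfig()
    filtered = lowpass(trace, pipe.filter)
    orient = estimate_orientation(filtered, pipe.orientation)
    kin = compute_kinematics(filtered, orient, pipe.integration)
    return filtered, orient, kin


def run_detector(
    trace: ImuTrace,
    thresholds: ThresholdConfig | None = None,
    pipe: PipelineConfig | None = None,
    confirm: int = 1,
) -> DetectionResult:
    """Run the full causal pipeline on a raw trace and decide."""
    thresholds = thresholds or ThresholdConfig()
    if trace.n < MIN_SAMPLES:
        warnings.warn("trace shorter than the integration warm-up; no detection")
        return DetectionResult(detected=False, thresholds=thresholds)
    _, orient, kin = process_trace(trace, pipe)
    return detect_series(trace.t, orient.vertical_angle, kin.v_v, thresholds, confirm)
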