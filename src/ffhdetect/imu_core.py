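"""Data model for trunk-worn IMU traces and labeled motion trials.

Conventions used throughout the package:

* axes: x anteroposterior, y mediolateral, z superoinferior;
* specific force in units of g (the vertical channel reads -1 g at
  upright rest, 0 g in ideal free fall);
* angular rate in deg/s, time in seconds from trial start, velocity
  in m/s (positive downward), angles in degrees.

All unit conversion happens at the I/O boundary (:func:`read_trace`);
internal code never converts units twice.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: standard gravity used for all g <-> m/s^2 conversions (m/s^2)
G_SI = 9.81

#: accelerometer full-scale range of the sensor model (g)
ACC_RANGE_G = 16.0
#: gyroscope full-scale range of the sensor model (deg/s)
GYRO_RANGE_DPS = 2000.0
#: minimum trace length required by the three-point velocity recurrence
MIN_SAMPLES = 3
#: default sampling rate (Hz)
DEFAULT_FS = 100.0

#: relative timestamp jitter tolerated at ingest
JITTER_TOL = 0.01

TRACE_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")

# closed vocabulary of motion classes -------------------------------------

#: non-fall occupational motions of the first experiment design
EXP1_NONFFH = (
    "sit_quick",
    "sit_floor",
    "stairs",
    "ladder_climb",
    "pickaxe",
    "lift_front",
    "lift_back",
    "lift_side",
    "jump",
)

#: additional non-fall motions of the second experiment design
EXP2_EXTRA_NONFFH = (
    "beam_walk",
    "beam_walk_luggage",
    "shovel",
    "stretch",
    "scaffold_climb",
    "elevator",
)

NONFFH_CLASSES = EXP1_NONFFH + EXP2_EXTRA_NONFFH

#: fall-from-height classes, parameterized by height
FFH_CLASSES = ("forward_ffh", "vertical_ffh", "scaffold_ffh", "roof_ffh", "ladder_ffh")

MOTION_CLASSES = frozenset(NONFFH_CLASSES) | frozenset(FFH_CLASSES)


class IngestError(ValueError):
    """Raised when a trace file violates a range or sampling invariant."""


@dataclass
class ImuTrace:
    """Synchronized tri-axial specific force (g) and angular rate (deg/s).

    Parameters
    ----------
    t : ndarray, shape (n,)
        Sample times in seconds, strictly increasing and uniform at 1/fs.
    acc : ndarray, shape (n, 3)
        Specific force in g, columns (ax, ay, az).
    gyro : ndarray, shape (n, 3)
        Angular rate in deg/s, columns (gx, gy, gz).
    fs : float
        Sampling rate in Hz.
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.t.shape[0]
        if n < MIN_SAMPLES:
            raise IngestError(
                f"trace has {n} samples; at least {MIN_SAMPLES} are required "
                "by the three-point integration recurrence"
            )
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise IngestError("acc and gyro must have shape (n, 3) matching t")
        if self.fs <= 0:
            raise IngestError("sampling rate must be positive")
        dt = np.diff(self.t)
        nominal = 1.0 / self.fs
        if np.any(np.abs(dt - nominal) > 1e-9 + 1e-9 * nominal):
            raise IngestError("timestamps are not uniform at 1/fs")
        if abs(nominal * self.fs - 1.0) > 1e-9:
            raise IngestError("dt * fs != 1")

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.t.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def validate_ranges(self) -> None:
        """Reject samples outside the sensor's measurement ranges."""
        bad = np.nonzero(np.any(np.abs(self.acc) > ACC_RANGE_G, axis=1))[0]
        if bad.size:
            raise IngestError(
                f"row {bad[0]}: acceleration outside the +/-{ACC_RANGE_G:g} g "
                "sensor range"
            )
        bad = np.nonzero(np.any(np.abs(self.gyro) > GYRO_RANGE_DPS, axis=1))[0]
        if bad.size:
            raise IngestError(
                f"row {bad[0]}: angular rate outside the +/-{GYRO_RANGE_DPS:g} "
                "deg/s sensor range"
            )


@dataclass
class GroundTruth:
    """Per-sample ground truth carried by synthetic trials.

    ``v_vert`` is the true vertical velocity of the sensor in m/s,
    positive downward. ``impact_time`` is the floor-contact time in
    seconds from trial start (None for motions without a collision).
    """

    roll: np.ndarray
    pitch: np.ndarray
    v_vert: np.ndarray
    impact_time: Optional[float] = None

    def vertical_angle(self) -> np.ndarray:
        r = np.radians(self.roll)
        p = np.radians(self.pitch)
        return np.degrees(np.arccos(np.clip(np.cos(r) * np.cos(p), -1.0, 1.0)))


@dataclass
class LabeledTrial:
    """A trace plus its motion label and (for falls) the collision time."""

    trace: ImuTrace
    motion_class: str
    is_ffh: bool
    collision_time: Optional[float] = None
    height: Optional[float] = None
    ground_truth: Optional[GroundTruth] = None
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.motion_class not in MOTION_CLASSES:
            raise ValueError(
                f"unknown motion class {self.motion_class!r}; expected one of "
                f"{sorted(MOTION_CLASSES)}"
            )
        if self.is_ffh:
            if self.collision_time is None:
                raise ValueError("FFH trials must carry a collision time")
            if not (self.trace.t[0] <= self.collision_time <= self.trace.t[-1]):
                raise ValueError("collision time outside the trace span")


# ---------------------------------------------------------------------------
# trace file I/O
# ---------------------------------------------------------------------------

_ACC_UNITS = {"g": 1.0, "m/s2": 1.0 / G_SI, "m/s^2": 1.0 / G_SI}
_GYRO_UNITS = {"deg/s": 1.0, "rad/s": 180.0 / np.pi}


def read_trace(
    path: str | Path,
    acc_unit: str = "g",
    gyro_unit: str = "deg/s",
) -> ImuTrace:
    """Read a delimiter-separated trace file into a validated :class:`ImuTrace`.

    The file carries one comment line ``# fs=<Hz>`` followed by a header
    naming the columns ``t,ax,ay,az,gx,gy,gz``. ``acc_unit`` may be ``"g"``
    or ``"m/s2"``; ``gyro_unit`` may be ``"deg/s"`` or ``"rad/s"``.
    Timestamps are regularized to the declared sampling rate after a 1%
    jitter check; range violations are rejected with the offending row.
    """
    path = Path(path)
    if acc_unit not in _ACC_UNITS:
        raise IngestError(f"unknown acceleration unit {acc_unit!r}")
    if gyro_unit not in _GYRO_UNITS:
        raise IngestError(f"unknown angular-rate unit {gyro_unit!r}")
    fs = None
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#") and "fs=" in first:
            fs = float(first.split("fs=")[1])
            body = fh.read()
        else:
            body = first + "\n" + fh.read()
    df = pd.read_csv(io.StringIO(body))
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"missing columns: {', '.join(missing)}")
    t_raw = df["t"].to_numpy(dtype=float)
    if t_raw.size < MIN_SAMPLES:
        raise IngestError(
            f"trace has {t_raw.size} samples; at least {MIN_SAMPLES} required"
        )
    dt_raw = np.diff(t_raw)
    if np.any(dt_raw <= 0):
        row = int(np.nonzero(dt_raw <= 0)[0][0]) + 1
        raise IngestError(f"row {row}: timestamps not strictly increasing")
    if fs is None:
        fs = 1.0 / float(np.median(dt_raw))
    nominal = 1.0 / fs
    jitter = np.abs(dt_raw - nominal)
    if np.any(jitter > JITTER_TOL * nominal):
        row = int(np.argmax(jitter)) + 1
        raise IngestError(
            f"row {row}: sampling jitter exceeds {JITTER_TOL:.0%} of 1/fs"
        )
    n = t_raw.size
    t = np.arange(n) / fs
    acc = df[["ax", "ay", "az"]].to_numpy(dtype=float) * _ACC_UNITS[acc_unit]
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float) * _GYRO_UNITS[gyro_unit]
    trace = ImuTrace(t=t, acc=acc, gyro=gyro, fs=fs)
    trace.validate_ranges()
    return trace


def write_trace(trace: ImuTrace, path: str | Path) -> Path:
    """Write a trace as CSV (internal units: g, deg/s) with an fs header."""
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([trace.t, trace.acc, trace.gyro]), columns=TRACE_COLUMNS
    )
    with open(path, "w") as fh:
        fh.write(f"# fs={trace.fs:g}\n")
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# suite manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("path", "trial_id", "motion_class", "is_ffh", "collision_time", "height")


def save_suite(trials: Sequence[LabeledTrial], out_dir: str | Path) -> Path:
    """Write trace CSVs plus a ``manifest.csv`` table for a trial suite.

    Ground truth, when present, is stored in one JSON sidecar per trial so
    that synthetic suites round-trip losslessly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, trial in enumerate(trials):
        name = trial.trial_id or f"trial_{i:04d}"
        fname = f"{name}.csv"
        write_trace(trial.trace, out_dir / fname)
        if trial.ground_truth is not None:
            gt = trial.ground_truth
            payload = {
                "roll": gt.roll.tolist(),
                "pitch": gt.pitch.tolist(),
                "v_vert": gt.v_vert.tolist(),
                "impact_time": gt.impact_time,
            }
            (out_dir / f"{name}.truth.json").write_text(json.dumps(payload))
        rows.append(
            {
                "path": fname,
                "trial_id": name,
                "motion_class": trial.motion_class,
                "is_ffh": trial.is_ffh,
                "collision_time": trial.collision_time,
                "height": trial.height,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def load_suite(manifest_path: str | Path, infer_collision: bool = False) -> list[LabeledTrial]:
    """Load a suite from a manifest written by :func:`save_suite`.

    Fall trials whose manifest lacks a collision time are either rejected
    or, with ``infer_collision=True``, assigned the time of peak filtered
    acceleration magnitude (heuristic for recorded data without video or
    motion-capture collision marks).
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    trials = []
    for _, row in df.iterrows():
        trace = read_trace(base / str(row["path"]))
        collision = row.get("collision_time")
        collision = None if pd.isna(collision) else float(collision)
        is_ffh = bool(row["is_ffh"])
        if is_ffh and collision is None:
            if not infer_collision:
                raise ValueError(
                    f"trial {row['trial_id']}: FFH trial without collision time "
                    "(pass infer_collision=True to use the impact-peak heuristic)"
                )
            collision = infer_collision_time(trace)
        gt = None
        truth_path = base / f"{row['trial_id']}.truth.json"
        if truth_path.exists():
            payload = json.loads(truth_path.read_text())
            gt = GroundTruth(
                roll=np.asarray(payload["roll"], dtype=float),
                pitch=np.asarray(payload["pitch"], dtype=float),
                v_vert=np.asarray(payload["v_vert"], dtype=float),
                impact_time=payload["impact_time"],
            )
        height = row.get("height")
        trials.append(
            LabeledTrial(
                trace=trace,
                motion_class=str(row["motion_class"]),
                is_ffh=is_ffh,
                collision_time=collision,
                height=None if pd.isna(height) else float(height),
                ground_truth=gt,
                trial_id=str(row["trial_id"]),
            )
        )
    return trials


def infer_collision_time(trace: ImuTrace) -> float:
    """Collision-time heuristic: time of peak low-pass-filtered |a|."""
    from .preprocessing import FilterConfig, lowpass  # local import: avoid cycle

    filtered = lowpass(trace, FilterConfig())
    mag = np.linalg.norm(filtered.acc, axis=1)
    return float(trace.t[int(np.argmax(mag))])
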