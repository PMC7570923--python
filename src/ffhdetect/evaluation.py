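"""Trial-level metrics, lead times, threshold tuning and calibration.

A trial counts as detected when the detector fires anywhere in its
trace. Sensitivity, specificity and accuracy are the usual confusion
ratios in percent. Lead time is collision time minus detection time,
reported in milliseconds; a detection after the collision still counts
toward sensitivity but is flagged as a negative lead and excluded from
the lead-time statistics.

Threshold tuning follows a modified ROC procedure: accuracy is evaluated
on a grid of vertical-angle and vertical-velocity thresholds (the
velocity-only branch is held fixed during the search), every cell
achieving the maximum accuracy is a candidate, and the candidate with
the longest mean lead time on a held-out validation suite wins (ties
broken toward the larger angle threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .detector import (
    PipelineConfig,
    ThresholdConfig,
    detect_series,
    process_trace,
)
from .imu_core import LabeledTrial


@dataclass
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class Metrics:
    """Sensitivity/specificity/accuracy in percent; None when undefined."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]


def metrics(c: ConfusionCounts) -> Metrics:
    """Confusion ratios in percent, exact rational arithmetic underneath."""

    def ratio(num: int, den: int) -> Optional[float]:
        if den == 0:
            return None
        return float(Fraction(num, den) * 100)

    return Metrics(
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
        accuracy=ratio(c.tp + c.tn, c.total),
    )


@dataclass
class LeadTimeSummary:
    """Per-trial lead times in ms (pre-impact detections only)."""

    leads_ms: list[float] = field(default_factory=list)
    n_negative: int = 0

    @property
    def mean_ms(self) -> Optional[float]:
        return float(np.mean(self.leads_ms)) if self.leads_ms else None

    @property
    def sd_ms(self) -> Optional[float]:
        if len(self.leads_ms) < 2:
            return None
        return float(np.std(self.leads_ms, ddof=1))

    @property
    def min_ms(self) -> Optional[float]:
        return float(min(self.leads_ms)) if self.leads_ms else None


@dataclass
class TrialSeries:
    """Cached pipeline output for one trial (used by the tuning grid)."""

    trial: LabeledTrial
    t: np.ndarray
    va: np.ndarray
    vv: np.ndarray


def precompute_series(
    trials: Sequence[LabeledTrial], pipe: PipelineConfig | None = None
) -> list[TrialSeries]:
    """Run the pipeline once per trial; detection is cheap afterwards."""
    pipe = pipe or PipelineConfig()
    out = []
    for trial in trials:
        _, orient, kin = process_trace(trial.trace, pipe)
        out.append(
            TrialSeries(trial=trial, t=trial.trace.t, va=orient.vertical_angle, vv=kin.v_v)
        )
    return out


def _score(
    series: Sequence[TrialSeries], cfg: ThresholdConfig, confirm: int = 1
) -> tuple[ConfusionCounts, LeadTimeSummary]:
    counts = ConfusionCounts()
    leads = LeadTimeSummary()
    for s in series:
        res = detect_series(s.t, s.va, s.vv, cfg, confirm)
        if s.trial.is_ffh:
            if res.detected:
                counts.tp += 1
                lead = (s.trial.collision_time - res.detection_time) * 1000.0
                if lead >= 0:
                    leads.leads_ms.append(lead)
                else:
                    leads.n_negative += 1
            else:
                counts.fn += 1
        else:
            if res.detected:
                counts.fp += 1
            else:
                counts.tn += 1
    return counts, leads


def evaluate_suite(
    trials: Sequence[LabeledTrial],
    cfg: ThresholdConfig | None = None,
    pipe: PipelineConfig | None = None,
    confirm: int = 1,
    series: Sequence[TrialSeries] | None = None,
) -> tuple[ConfusionCounts, LeadTimeSummary]:
    """Score a labeled suite under one threshold configuration."""
    if not trials and not series:
        raise ValueError("empty trial suite")
    cfg = cfg or ThresholdConfig()
    if series is None:
        series = precompute_series(trials, pipe)
    return _score(series, cfg, confirm)


@dataclass
class RocGrid:
    """Accuracy surface over the (va_th, vv_low) threshold grid, in %."""

    va_values: np.ndarray
    vv_values: np.ndarray
    accuracy: np.ndarray  # shape (len(va_values), len(vv_values))
    vv_high: float = 5.0

    def best_cells(self) -> list[tuple[float, float]]:
        """All (va, vv) combinations achieving the maximum accuracy."""
        best = np.max(self.accuracy)
        cells = []
        for i, va in enumerate(self.va_values):
            for j, vv in enumerate(self.vv_values):
                if self.accuracy[i, j] == best:
                    cells.append((float(va), float(vv)))
        return cells

    def accuracy_at(self, va: float, vv: float) -> float:
        i = int(np.argmin(np.abs(self.va_values - va)))
        j = int(np.argmin(np.abs(self.vv_values - vv)))
        return float(self.accuracy[i, j])


DEFAULT_VA_GRID = np.array([25.0, 30.0, 35.0, 40.0])
DEFAULT_VV_GRID = np.round(np.arange(1.0, 3.0 + 1e-9, 0.1), 10)


def roc_grid(
    trials: Sequence[LabeledTrial],
    va_values: np.ndarray = DEFAULT_VA_GRID,
    vv_values: np.ndarray = DEFAULT_VV_GRID,
    vv_high: float = 5.0,
    pipe: PipelineConfig | None = None,
    series: Sequence[TrialSeries] | None = None,
) -> RocGrid:
    """Accuracy over the threshold grid (the vv_high branch is fixed)."""
    if series is None:
        series = precompute_series(trials, pipe)
    va_values = np.asarray(va_values, dtype=float)
    vv_values = np.asarray(vv_values, dtype=float)
    acc = np.zeros((va_values.size, vv_values.size))
    labels = np.array([s.trial.is_ffh for s in series])
    n = labels.size
    for i, va in enumerate(va_values):
        for j, vv in enumerate(vv_values):
            fired = np.array(
                [
                    bool(np.any(((s.va > va) & (s.vv > vv)) | (s.vv > vv_high)))
                    for s in series
                ]
            )
            acc[i, j] = 100.0 * np.mean(fired == labels)
    return RocGrid(va_values=va_values, vv_values=vv_values, accuracy=acc, vv_high=vv_high)


def select_thresholds(
    candidates: Sequence[tuple[float, float]],
    validation_trials: Sequence[LabeledTrial],
    vv_high: float = 5.0,
    pipe: PipelineConfig | None = None,
    series: Sequence[TrialSeries] | None = None,
) -> ThresholdConfig:
    """Pick the winning combination on a held-out validation suite.

    Maximum accuracy first, then the longest mean lead time, then the
    larger angle threshold (a deterministic tie-break).
    """
    if not candidates:
        raise ValueError("no candidate threshold combinations")
    if series is None:
        series = precompute_series(validation_trials, pipe)
    scored = []
    for va, vv in candidates:
        cfg = ThresholdConfig(va_th=va, vv_low=vv, vv_high=vv_high)
        counts, leads = _score(series, cfg)
        acc = metrics(counts).accuracy or 0.0
        mean_lead = leads.mean_ms if leads.mean_ms is not None else -np.inf
        scored.append((acc, mean_lead, va, vv))
    acc_best = max(s[0] for s in scored)
    pool = [s for s in scored if s[0] == acc_best]
    lead_best = max(s[1] for s in pool)
    pool = [s for s in pool if s[1] == lead_best]
    _, _, va, vv = max(pool, key=lambda s: s[2])
    return ThresholdConfig(va_th=va, vv_low=vv, vv_high=vv_high)


def calibrate_correction(
    trials: Sequence[LabeledTrial], pipe: PipelineConfig | None = None
) -> float:
    """Estimate the velocity correction factor from free-fall trials.

    Runs the pipeline with the correction factor forced to 1, compares
    the uncorrected velocity estimate at the impact sample with the
    ground-truth impact speed, and returns the mean true/estimated ratio
    over trials. The factor compensates for the velocity missed before
    the integration gate opens plus the filter group delay.
    """
    if not trials:
        raise ValueError("no free-fall trials")
    pipe = pipe or PipelineConfig()
    pipe_uncorr = PipelineConfig(
        filter=pipe.filter,
        orientation=pipe.orientation,
        integration=replace(pipe.integration, correction=1.0),
    )
    ratios = []
    for trial in trials:
        gt = trial.ground_truth
        if gt is None or gt.impact_time is None:
            raise ValueError(f"trial {trial.trial_id!r} lacks ground truth")
        _, _, kin = process_trace(trial.trace, pipe_uncorr)
        # compare estimate and truth at the last sample before floor contact:
        # the ground-truth velocity is discontinuous across the impact pulse
        i_imp = int(np.searchsorted(trial.trace.t, gt.impact_time, side="right")) - 1
        v_est = float(kin.v_v[i_imp])
        v_true = float(gt.v_vert[i_imp])
        if v_est <= 0:
            raise ValueError(f"trial {trial.trial_id!r}: no integrated velocity at impact")
        ratios.append(v_true / v_est)
    return float(np.mean(ratios))
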