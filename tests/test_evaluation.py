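"""Metrics, lead times, ROC grid, threshold selection and calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ffhdetect.detector import ThresholdConfig
from ffhdetect.evaluation import (
    ConfusionCounts,
    calibrate_correction,
    evaluate_suite,
    metrics,
    precompute_series,
    roc_grid,
    select_thresholds,
    TrialSeries,
)
from ffhdetect.imu_core import G_SI, LabeledTrial
from ffhdetect.synthetic import (
    MotionSpec,
    make_suite,
    simulate_adl,
    simulate_vertical_fall,
)


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts, sens, spec, acc",
    [
        (ConfusionCounts(tp=30, fn=0, tn=270, fp=0), 100.0, 100.0, 100.0),
        (ConfusionCounts(tp=30, fn=0, tn=262, fp=8), 100.0, 97.04, 97.33),
        (ConfusionCounts(tp=1, fn=1, tn=1, fp=1), 50.0, 50.0, 50.0),
    ],
)
def test_metric_percentages(counts, sens, spec, acc):
    m = metrics(counts)
    assert m.sensitivity == pytest.approx(sens, abs=0.005)
    assert m.specificity == pytest.approx(spec, abs=0.005)
    assert m.accuracy == pytest.approx(acc, abs=0.005)


def test_zero_denominator_reported_as_undefined():
    m = metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=0))
    assert m.sensitivity is None
    assert m.specificity == 100.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
def test_metrics_agree_with_brute_force_recount(outcomes):
    """Recount (is_ffh, detected) pairs naively and compare the ratios."""
    c = ConfusionCounts()
    for is_ffh, detected in outcomes:
        if is_ffh and detected:
            c.tp += 1
        elif is_ffh:
            c.fn += 1
        elif detected:
            c.fp += 1
        else:
            c.tn += 1
    m = metrics(c)
    n_pos = sum(1 for f, _ in outcomes if f)
    n_neg = len(outcomes) - n_pos
    if n_pos:
        assert m.sensitivity == pytest.approx(
            100.0 * sum(1 for f, d in outcomes if f and d) / n_pos
        )
    else:
        assert m.sensitivity is None
    if n_neg:
        assert m.specificity == pytest.approx(
            100.0 * sum(1 for f, d in outcomes if not f and not d) / n_neg
        )
    assert m.accuracy == pytest.approx(
        100.0 * sum(1 for f, d in outcomes if f == d) / len(outcomes)
    )


# ---------------------------------------------------------------------------
# suite evaluation and lead times
# ---------------------------------------------------------------------------


def test_perfectly_separated_suite_hits_extremes(default_spec):
    rng = np.random.default_rng(10)
    trials = [simulate_vertical_fall(2.0, default_spec, rng) for _ in range(3)]
    trials += [simulate_adl("elevator", default_spec, rng) for _ in range(3)]
    counts, leads = evaluate_suite(trials)
    assert (counts.tp, counts.fn, counts.tn, counts.fp) == (3, 0, 3, 0)
    assert leads.n_negative == 0
    assert len(leads.leads_ms) == 3


def test_lead_time_is_collision_minus_detection(noiseless_spec):
    trial = simulate_vertical_fall(2.0, noiseless_spec, np.random.default_rng(11))
    from ffhdetect.detector import run_detector

    res = run_detector(trial.trace)
    counts, leads = evaluate_suite([trial])
    expected = (trial.collision_time - res.detection_time) * 1000.0
    assert leads.leads_ms[0] == pytest.approx(expected, abs=1e-9)
    # sanity on magnitude: collision ~0.639 s after release, detection ~0.45 s
    assert 100.0 < leads.leads_ms[0] < 250.0


def test_empty_suite_rejected():
    with pytest.raises(ValueError):
        evaluate_suite([])


# ---------------------------------------------------------------------------
# ROC grid and threshold selection
# ---------------------------------------------------------------------------


def test_grid_dimensions_4_by_21(default_spec):
    rng = np.random.default_rng(12)
    trials = [simulate_adl("sit_quick", default_spec, rng)]
    grid = roc_grid(trials)
    assert grid.accuracy.shape == (4, 21)


def test_degenerate_all_negative_suite_accuracy_equals_specificity(default_spec):
    rng = np.random.default_rng(13)
    trials = [simulate_adl("elevator", default_spec, rng) for _ in range(3)]
    grid = roc_grid(trials)
    series = precompute_series(trials)
    for i, va in enumerate(grid.va_values):
        for j, vv in enumerate(grid.vv_values):
            counts, _ = evaluate_suite(
                trials,
                ThresholdConfig(va_th=va, vv_low=vv),
                series=series,
            )
            assert grid.accuracy[i, j] == pytest.approx(metrics(counts).specificity)


def _fake_series(t, va, vv, is_ffh, collision):
    trial = LabeledTrial.__new__(LabeledTrial)
    object.__setattr__(trial, "trace", None)
    trial.motion_class = "vertical_ffh" if is_ffh else "elevator"
    trial.is_ffh = is_ffh
    trial.collision_time = collision
    trial.height = None
    trial.ground_truth = None
    trial.trial_id = "fake"
    return TrialSeries(trial=trial, t=t, va=va, vv=vv)


def test_selection_prefers_longer_lead_then_larger_angle():
    # one synthetic FFH: the angle crosses every candidate threshold early,
    # so the lower velocity threshold (1.8) fires before 1.9 does
    t = np.arange(200) / 100.0
    va = np.linspace(0, 100, 200)
    vv = np.linspace(0, 3, 200)
    series = [_fake_series(t, va, vv, True, collision=1.99)]
    sel = select_thresholds([(35.0, 1.9), (40.0, 1.8)], [], series=series)
    assert (sel.va_th, sel.vv_low) == (40.0, 1.8)

    # identical detection time for both combos -> larger va_th tie-break
    va2 = np.full(200, 90.0)
    series2 = [_fake_series(t, va2, vv, True, collision=1.99)]
    sel2 = select_thresholds([(35.0, 1.8), (40.0, 1.8)], [], series=series2)
    assert sel2.va_th == 40.0

    with pytest.raises(ValueError):
        select_thresholds([], [], series=series)


def test_single_candidate_returned_as_is(default_spec):
    rng = np.random.default_rng(14)
    trials = [simulate_vertical_fall(2.0, default_spec, rng)]
    sel = select_thresholds([(30.0, 2.0)], trials)
    assert (sel.va_th, sel.vv_low) == (30.0, 2.0)


# ---------------------------------------------------------------------------
# correction-factor calibration
# ---------------------------------------------------------------------------


def test_calibration_recovers_true_impact_speed_within_5pct(noiseless_spec):
    """One shared factor must reconcile 1, 1.5 and 2 m drops with their
    closed-form impact speeds sqrt(2 g h)."""
    rng = np.random.default_rng(15)
    trials = [
        simulate_vertical_fall(h, noiseless_spec, rng) for h in (1.0, 1.5, 2.0)
    ]
    factor = calibrate_correction(trials)
    assert factor > 1.0
    from dataclasses import replace
    from ffhdetect.detector import PipelineConfig, process_trace

    pipe = PipelineConfig()
    pipe.integration = replace(pipe.integration, correction=1.0)
    for trial, h in zip(trials, (1.0, 1.5, 2.0)):
        _, _, kin = process_trace(trial.trace, pipe)
        i = np.searchsorted(trial.trace.t, trial.ground_truth.impact_time, "right") - 1
        recovered = factor * kin.v_v[i]
        assert recovered == pytest.approx(trial.ground_truth.v_vert[i], rel=0.05)


def test_default_conditions_bracket_published_factor(default_spec):
    """On default noise at 1/1.5/2 m the fitted factor lands in [1.1, 1.3]."""
    rng = np.random.default_rng(16)
    trials = [
        simulate_vertical_fall(h, default_spec, rng)
        for h in (1.0, 1.5, 2.0)
        for _ in range(5)
    ]
    factor = calibrate_correction(trials)
    assert 1.1 <= factor <= 1.3


def test_calibration_requires_ground_truth(static_trace):
    trial = LabeledTrial(trace=static_trace, motion_class="elevator", is_ffh=False)
    with pytest.raises(ValueError):
        calibrate_correction([trial])
    with pytest.raises(ValueError):
        calibrate_correction([])
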