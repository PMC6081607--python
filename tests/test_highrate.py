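"""High-rate (60 Hz) arm: midpoints, I-DT fixations, NP, exclusion, flags."""

import math

import numpy as np
import pytest

from conftest import make_stream
from vpcscore.highrate_scoring import (FilterParams, detect_fixations,
                                       exclude_missing, fixation_time_ms,
                                       flag_aberrant, gaze_midpoint,
                                       sample_period_ms, trial_np_highrate)
from vpcscore.types import AOIPair, ScreenPoint

AOIS = AOIPair()
LEFT_C = (0.25, 0.5)   # inside the left AOI
RIGHT_C = (0.75, 0.5)  # inside the right AOI


# ---------------------------------------------------------------------------
# midpoint
# ---------------------------------------------------------------------------

def test_midpoint_both_eyes():
    mid = gaze_midpoint(ScreenPoint(0.2, 0.4), ScreenPoint(0.4, 0.4))
    assert mid == pytest.approx((0.3, 0.4))


def test_midpoint_single_eye_fallback():
    assert gaze_midpoint(ScreenPoint(0.2, 0.4), None) == ScreenPoint(0.2, 0.4)
    assert gaze_midpoint(None, ScreenPoint(0.7, 0.1)) == ScreenPoint(0.7, 0.1)


def test_midpoint_both_missing():
    assert gaze_midpoint(None, None) is None


# ---------------------------------------------------------------------------
# fixation detection
# ---------------------------------------------------------------------------

def test_two_constructed_clusters():
    pts = [(0.3, 0.5)] * 150 + [(0.7, 0.5)] * 150
    fixations = detect_fixations(make_stream(pts))
    assert len(fixations) == 2
    assert fixations[0].centroid == pytest.approx((0.3, 0.5))
    assert fixations[1].centroid == pytest.approx((0.7, 0.5))
    assert fixations[0].n_samples == fixations[1].n_samples == 150


def test_fast_linear_sweep_has_no_fixations():
    # crosses the screen in 1 s: every dispersion window is outrun
    pts = np.column_stack([np.linspace(0.0, 1.0, 60), np.full(60, 0.5)])
    assert detect_fixations(make_stream(pts)) == []


def test_jittered_cluster_centroid():
    rng = np.random.default_rng(1)
    pts = rng.normal(0, 0.005, (120, 2)) + [0.4, 0.6]
    fixations = detect_fixations(make_stream(pts))
    assert len(fixations) == 1
    assert fixations[0].centroid.x == pytest.approx(0.4, abs=0.01)
    assert fixations[0].centroid.y == pytest.approx(0.6, abs=0.01)


def brute_force_idt(t, pts, params):
    """Independent oracle: left-to-right maximal runs with the bounding-box
    diagonal computed from scratch over every candidate window."""
    out = []
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j + 1 < n:
            window = pts[i:j + 2]
            dx = window[:, 0].max() - window[:, 0].min()
            dy = window[:, 1].max() - window[:, 1].min()
            if math.hypot(dx, dy) > params.dispersion_threshold:
                break
            j += 1
        if t[j] - t[i] >= params.min_duration_ms - 1e-6:
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


@pytest.mark.parametrize("seed", range(5))
def test_idt_matches_run_scan_oracle(seed):
    rng = np.random.default_rng(seed)
    # mixture of stationary clusters and drifts, <= 200 samples
    parts = []
    for _ in range(rng.integers(2, 5)):
        kind = rng.random()
        n = int(rng.integers(10, 60))
        center = rng.uniform(0.1, 0.9, 2)
        if kind < 0.6:
            parts.append(center + rng.normal(0, 0.006, (n, 2)))
        else:
            target = rng.uniform(0.1, 0.9, 2)
            parts.append(np.linspace(center, target, n))
    pts = np.vstack(parts)[:200]
    stream = make_stream(pts)
    params = FilterParams()
    fixations = detect_fixations(stream, params)
    t = stream["t_ms"].to_numpy()
    expected = brute_force_idt(t, pts, params)
    assert [(f.start_ms, f.end_ms, f.n_samples) for f in fixations] == \
        [(t[i], t[j], j - i + 1) for i, j in expected]


def test_total_fixation_time_bounded_by_valid_time(small_cohort):
    params, datasets, _ = small_cohort
    d = datasets[0]
    for trial, grp in d.gaze.groupby("trial"):
        fixations = detect_fixations(grp)
        period = sample_period_ms(grp["t_ms"].to_numpy())
        total = sum(fixation_time_ms(f, period) for f in fixations)
        valid_ms = grp["valid"].sum() * 1000.0 / params.sample_hz
        assert total <= valid_ms + 1e-9


def test_empty_stream():
    assert detect_fixations(make_stream(np.empty((0, 2)))) == []


# ---------------------------------------------------------------------------
# trial NP
# ---------------------------------------------------------------------------

def _alternating_stream(n_novel, n_familiar, novel_side="left"):
    novel_c = LEFT_C if novel_side == "left" else RIGHT_C
    familiar_c = RIGHT_C if novel_side == "left" else LEFT_C
    pts = [novel_c] * n_novel + [familiar_c] * n_familiar
    return make_stream(pts)


def test_np_formula_three_to_one():
    # 3000 ms on the novel AOI, 1000 ms on the familiar -> NP = 0.75
    stream = _alternating_stream(180, 60)
    score = trial_np_highrate(stream, AOIS, "left")
    assert score.np_score == pytest.approx(0.75)
    assert score.novel_ms == pytest.approx(3000.0)
    assert score.familiar_ms == pytest.approx(1000.0)


def test_np_all_novel_is_one():
    score = trial_np_highrate(_alternating_stream(300, 0), AOIS, "left")
    assert score.np_score == pytest.approx(1.0)


def test_np_side_swap_symmetry():
    stream = _alternating_stream(200, 100)
    a = trial_np_highrate(stream, AOIS, "left")
    b = trial_np_highrate(stream, AOIS, "right")
    assert a.np_score + b.np_score == pytest.approx(1.0)


def test_np_zero_viewing():
    pts = [(0.5, 0.05)] * 300  # fixating well away from both AOIs
    score = trial_np_highrate(make_stream(pts), AOIS, "left")
    assert math.isnan(score.np_score)
    assert score.reason == "zero_viewing"
    assert not score.excluded


def test_np_recovers_truth_on_clean_cohort(clean_cohort):
    from vpcscore import score_trials_highrate
    params, datasets, truth = clean_cohort
    for si, d in enumerate(datasets):
        scores = score_trials_highrate(d.gaze, d.trials)
        for t, s in enumerate(scores):
            assert abs(s.np_score - truth.trial_true_np[si][t]) <= 0.02


# ---------------------------------------------------------------------------
# missing-data exclusion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_invalid,excluded", [
    (240, False),  # exactly 4000 ms is not more than 4 s
    (241, True),   # ~4017 ms is
    (0, False),
])
def test_missing_data_rule(n_invalid, excluded):
    valid = np.ones(300, dtype=bool)
    valid[:n_invalid] = False
    stream = make_stream([LEFT_C] * 300, valid=valid)
    flag, reason = exclude_missing(stream, sample_hz=60.0)
    assert flag is excluded
    assert reason == ("missing_gt_4s" if excluded else "none")


# ---------------------------------------------------------------------------
# aberrant-trial flags
# ---------------------------------------------------------------------------

def test_gaze_clustering_flag():
    # one 5 s fixation dead-center between the AOIs
    stream = make_stream([(0.5, 0.5)] * 300)
    fixations = detect_fixations(stream)
    flags = flag_aberrant(fixations, stream, AOIS)
    assert "gaze_clustering" in flags
    assert "off_aoi" in flags


def test_normal_trial_unflagged():
    stream = _alternating_stream(180, 120)
    fixations = detect_fixations(stream)
    assert flag_aberrant(fixations, stream, AOIS) == []


def test_erratic_saccade_flag_from_cohort_z():
    stream = _alternating_stream(180, 120)
    fixations = detect_fixations(stream)
    flags = flag_aberrant(fixations, stream, AOIS, saccade_rate_z=5.0)
    assert flags == ["erratic_saccades"]
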