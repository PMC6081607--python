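"""Synthetic cohort generator: determinism, honesty, coupling recovery."""

import math

import numpy as np
import pytest

from vpcscore import (CohortParams, noise_free, score_trials_frames,
                      score_trials_highrate, simulate_cohort,
                      simulate_composites, simulate_rater_codes,
                      simulate_trial_gaze)
from vpcscore.stats import spearman
from vpcscore.synthetic_data import subject_mean_np_from_ability
from vpcscore.types import AOIPair


def test_seeded_determinism_byte_identical():
    params = CohortParams(n_subjects=2, seed=7)
    a_sets, a_truth = simulate_cohort(params)
    b_sets, b_truth = simulate_cohort(params)
    np.testing.assert_array_equal(a_truth.ability, b_truth.ability)
    np.testing.assert_array_equal(a_truth.trial_true_np, b_truth.trial_true_np)
    assert a_truth.true_codes == b_truth.true_codes
    for a, b in zip(a_sets, b_sets):
        assert a.gaze.to_csv() == b.gaze.to_csv()
        assert a.codes.to_csv() == b.codes.to_csv()
        assert a.trials.to_csv() == b.trials.to_csv()
        assert a.cognition == b.cognition


def test_zero_noise_raters_reproduce_truth(clean_cohort):
    params, datasets, truth = clean_cohort
    for si, d in enumerate(datasets):
        for t in range(params.n_trials):
            sub = d.codes[d.codes["trial"] == t]
            for _, rater_codes in sub.groupby("rater"):
                assert rater_codes.sort_values("frame")["code"].tolist() == \
                    truth.true_codes[si][t]


def test_point_mass_subject_distribution():
    params = CohortParams(n_subjects=30, seed=5,
                          subject_np_dist=("point", 0.5))
    _, truth = simulate_cohort(params)
    assert np.all(truth.subject_mean_np == 0.5)
    # mean of clipped Normal(0.5, sd) trial NPs stays at 0.5 up to MC error
    assert truth.trial_true_np.mean() == pytest.approx(
        0.5, abs=3 * params.trial_np_sd / math.sqrt(30 * 20))


def test_novel_sides_balanced(small_cohort):
    params, datasets, truth = small_cohort
    for sides in truth.novel_side:
        assert abs(sides.count("left") - sides.count("right")) <= 1


# ---------------------------------------------------------------------------
# single-trial gaze generator
# ---------------------------------------------------------------------------

def _stream_np(stream, aois):
    """Raw on-AOI viewing ratio of a stream's valid samples (novel=left)."""
    from vpcscore.highrate_scoring import midpoints
    pts = midpoints(stream)
    sides = [aois.side_of(x, y) for x, y in pts if not math.isnan(x)]
    n_left = sides.count("left")
    n_right = sides.count("right")
    return n_left, n_right


def test_trial_gaze_sample_count():
    params = noise_free(CohortParams(n_subjects=1))
    rng = np.random.default_rng(0)
    stream, codes = simulate_trial_gaze(0.7, "left", params, rng)
    assert len(stream) == 300  # 5000 ms at 60 Hz
    assert len(codes) == 15


def test_trial_gaze_extreme_np_all_on_novel():
    params = noise_free(CohortParams(n_subjects=1))
    rng = np.random.default_rng(1)
    aois = AOIPair()
    stream, _ = simulate_trial_gaze(1.0, "right", params, rng, aois)
    n_left, n_right = _stream_np(stream, aois)
    assert n_left == 0 and n_right == 300


@pytest.mark.parametrize("true_np", [0.5, 0.3, 0.85])
def test_trial_gaze_viewing_ratio_matches_true_np(true_np):
    params = noise_free(CohortParams(n_subjects=1))
    aois = AOIPair()
    rng = np.random.default_rng(9)
    for _ in range(5):
        stream, _ = simulate_trial_gaze(true_np, "left", params, rng, aois)
        n_left, n_right = _stream_np(stream, aois)
        ratio = n_left / (n_left + n_right)
        assert abs(ratio - true_np) <= 1.0 / (n_left + n_right)


def test_generator_honesty_three_way(clean_cohort):
    """With no missing data and zero coder error, duration NP, frame NP and
    true NP agree within one frame's weight (plus sample rounding)."""
    params, datasets, truth = clean_cohort
    frame_w = 1.0 / params.frames_per_trial
    sample_w = 2.0 / params.samples_per_trial
    for si, d in enumerate(datasets):
        hr = score_trials_highrate(d.gaze, d.trials)
        fr = score_trials_frames(d.codes, d.trials)
        for t in range(params.n_trials):
            tnp = truth.trial_true_np[si][t]
            assert abs(hr[t].np_score - tnp) <= 0.02
            assert abs(fr[t].np_score - tnp) <= frame_w + sample_w
            assert abs(fr[t].np_score - hr[t].np_score) <= frame_w + 0.02


# ---------------------------------------------------------------------------
# rater error model
# ---------------------------------------------------------------------------

def test_rater_error_swap_only_touches_sides():
    params = CohortParams(n_subjects=1, coder_error_rate=1.0)
    rng = np.random.default_rng(3)
    truth = ["left", "right", "neither"] * 5
    codes = simulate_rater_codes(truth, params, rng)
    for _, row in codes.iterrows():
        true = truth[row["frame"]]
        if true == "neither":
            assert row["code"] == "neither"
        else:
            assert row["code"] == ("right" if true == "left" else "left")


def test_rater_error_rate_zero_is_identity():
    params = CohortParams(n_subjects=1, coder_error_rate=0.0)
    rng = np.random.default_rng(3)
    truth = ["left", "right", "neither"] * 5
    codes = simulate_rater_codes(truth, params, rng)
    for rater, grp in codes.groupby("rater"):
        assert grp.sort_values("frame")["code"].tolist() == truth


# ---------------------------------------------------------------------------
# composite coupling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("coupling", [0.2, 0.4, 0.6])
def test_component_coupling_recovered_at_large_n(coupling):
    rng = np.random.default_rng(17)
    ability = rng.standard_normal(5000)
    cognition = simulate_composites(ability, coupling, rng)
    r = np.corrcoef(ability, cognition["mmse"])[0, 1]
    se = (1 - coupling ** 2) / math.sqrt(5000)
    assert abs(r - coupling) <= 3 * se


def test_zero_coupling_independent():
    rng = np.random.default_rng(23)
    ability = rng.standard_normal(1000)
    cognition = simulate_composites(ability, 0.0, rng)
    rho = spearman(ability, cognition["pvt"]).rho
    assert abs(rho) < 3.0 / math.sqrt(1000)


def test_full_coupling_is_monotone():
    ability = np.linspace(-2, 2, 50)
    rng = np.random.default_rng(2)
    cognition = simulate_composites(ability, 1.0, rng)
    assert spearman(ability, cognition["digit_symbol"]).rho == pytest.approx(1.0)
    # reverse-scored components are perfectly anti-monotone
    assert spearman(ability, cognition["trails_a"]).rho == pytest.approx(-1.0)


def test_ability_to_np_map_is_monotone_and_in_range():
    ability = np.linspace(-3, 3, 101)
    mean_np = subject_mean_np_from_ability(ability, ("uniform", 0.45, 0.90))
    assert np.all(np.diff(mean_np) > 0)
    assert mean_np.min() >= 0.45 and mean_np.max() <= 0.90


# ---------------------------------------------------------------------------
# parameter validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs,msg", [
    ({"n_subjects": 0}, "n_subjects"),
    ({"n_subjects": 2, "n_raters": 2}, "n_raters"),
    ({"n_subjects": 2, "coder_error_rate": 1.5}, "coder_error_rate"),
    ({"n_subjects": 2, "sample_hz": 50.0}, "divisible"),
    ({"n_subjects": 2, "composite_coupling": 2.0}, "composite_coupling"),
])
def test_invalid_params_name_the_field(kwargs, msg):
    with pytest.raises(ValueError, match=msg):
        CohortParams(**kwargs)


def test_coupling_bounds_checked_in_simulator():
    with pytest.raises(ValueError):
        simulate_composites(np.zeros(5), 1.5, np.random.default_rng(0))
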