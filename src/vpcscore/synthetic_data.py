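"""Synthetic VPC cohorts with known ground truth.

Real recordings for this task (gaze logs, webcam videos, neuropsychological
scores) are not public, so every downstream stage is exercised on simulated
cohorts in which the quantity each stage estimates is known exactly:

* a per-subject latent memory ability (z-scored) drives the subject's mean
  novelty preference (NP) through a monotone quantile map;
* each trial's true NP is the subject mean plus independent trial noise,
  clipped to [0, 1];
* a 60 Hz gaze stream realizes each trial's true NP as alternating
  fixation/saccade structure whose on-stimulus sample split matches the
  true NP to within one sample;
* 3 FPS frame codes are read off the same stream at the down-sampled
  instants, then corrupted independently per rater;
* cognitive composite components are generated with a chosen population
  correlation (coupling) to the latent ability.

The gaze generator lays trials out as side "segments" whose boundaries sit
inside frame blocks, so that with no missing data and no coder error the
duration-scored NP, the frame-scored NP and the true NP agree to within one
frame's weight — the generator-honesty property the test suite checks
exactly rather than statistically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from .types import AOIPair, Rect

#: samples consumed by the between-AOI travel (saccade) at a side switch
_SWITCH_TRAVEL_SAMPLES = 4
#: fixation duration bounds within a side segment, ms
_FIX_MS_RANGE = (300.0, 900.0)
#: per-sample gaze jitter around a fixation center, normalized units
_FIX_JITTER_SD = 0.004
#: horizontal half-separation of the two eyes' gaze estimates
_EYE_OFFSET_X = 0.012


@dataclass(frozen=True)
class CohortParams:
    """Study-design constants and noise levels for a simulated cohort.

    Defaults mirror the assessment's design: 20 test trials of 5 s at
    60 Hz, down-sampled to 3 FPS (15 frames per trial) and coded by 3
    independent raters; subject mean NP spread over Uniform(0.45, 0.90).
    """

    n_subjects: int
    n_trials: int = 20
    familiarization_ms: float = 5000.0
    test_phase_ms: float = 5000.0
    sample_hz: float = 60.0
    frame_fps: float = 3.0
    n_raters: int = 3
    coder_error_rate: float = 0.03
    coder_error_mode: str = "swap"  # "swap" (left<->right) or "uniform"
    missing_run_rate: float = 0.5   # expected missing-sample runs per trial
    blink_rate: float = 0.05        # per-frame blink ("neither") probability
    subject_np_dist: tuple = ("uniform", 0.45, 0.90)
    trial_np_sd: float = 0.08
    composite_coupling: float = 0.4
    delay_split: float = 0.5        # fraction of trials at the 2 s delay
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        for name in ("test_phase_ms", "familiarization_ms", "sample_hz",
                     "frame_fps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("coder_error_rate", "blink_rate", "delay_split"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.missing_run_rate < 0:
            raise ValueError("missing_run_rate must be non-negative")
        if self.trial_np_sd < 0:
            raise ValueError("trial_np_sd must be non-negative")
        if self.n_raters < 1 or self.n_raters % 2 == 0:
            raise ValueError("n_raters must be odd (majority vote)")
        if not -1.0 <= self.composite_coupling <= 1.0:
            raise ValueError("composite_coupling must lie in [-1, 1]")
        if self.coder_error_mode not in ("swap", "uniform"):
            raise ValueError("coder_error_mode must be 'swap' or 'uniform'")
        step = self.sample_hz / self.frame_fps
        if abs(step - round(step)) > 1e-9:
            raise ValueError("sample_hz must be divisible by frame_fps")
        kind = self.subject_np_dist[0]
        if kind not in ("uniform", "point", "normal"):
            raise ValueError(f"unknown subject_np_dist kind: {kind!r}")

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.test_phase_ms / 1000.0 * self.sample_hz))

    @property
    def frames_per_trial(self) -> int:
        return self.samples_per_trial // int(round(self.sample_hz / self.frame_fps))


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    ability: np.ndarray            # (n_subjects,) latent z-scores
    subject_mean_np: np.ndarray    # (n_subjects,)
    trial_true_np: np.ndarray      # (n_subjects, n_trials)
    novel_side: list[list[str]]    # (n_subjects, n_trials)
    true_codes: list[list[list[str]]]  # subject -> trial -> frame codes


@dataclass
class SubjectDataset:
    """One subject's complete simulated record."""

    subject_id: str
    trials: pd.DataFrame     # trial, novel_side, delay_condition, timings
    gaze: pd.DataFrame       # trial, t_ms, per-eye coords, valid
    codes: pd.DataFrame      # trial, frame, rater, code
    cognition: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Normative table for the simulated cognition components (synthetic values:
# plausible means/SDs for clinically normal older adults, used both to
# generate raw scores and as the default norms when re-standardizing them).
# ---------------------------------------------------------------------------
SYNTHETIC_NORMS: dict[str, dict] = {
    "lm_dr": {"mean": 13.5, "sd": 4.0},
    "fcsrt": {"mean": 46.0, "sd": 2.5},
    "digit_symbol": {"mean": 52.0, "sd": 12.0},
    "mmse": {"mean": 28.8, "sd": 1.2},
    "trails_a": {"mean": 35.0, "sd": 11.0, "reverse": True},
    "letter_fluency": {"mean": 42.0, "sd": 11.0},
    "category_fluency": {"mean": 20.0, "sd": 5.0},
    "flanker": {"mean": 100.0, "sd": 15.0},
    "pcpst": {"mean": 100.0, "sd": 15.0},
    "dccs": {"mean": 100.0, "sd": 15.0},
    "psmt": {"mean": 100.0, "sd": 15.0},
    "pvt": {"mean": 100.0, "sd": 15.0},
}


def subject_mean_np_from_ability(ability: np.ndarray, dist: tuple) -> np.ndarray:
    """Map latent ability z-scores to subject mean NP through the stated
    distribution (monotone, so rank correlation with ability is preserved).
    """
    kind = dist[0]
    if kind == "uniform":
        a, b = float(dist[1]), float(dist[2])
        return a + (b - a) * _norm.cdf(ability)
    if kind == "point":
        return np.full_like(ability, float(dist[1]))
    if kind == "normal":
        mu, sd = float(dist[1]), float(dist[2])
        return np.clip(mu + sd * ability, 0.0, 1.0)
    raise ValueError(f"unknown subject_np_dist kind: {kind!r}")


def _fixation_centers_box(aois: AOIPair, side: str) -> Rect:
    """Where fixation centers may land: the stimulus box inset so jitter
    stays inside the expanded AOI with wide margin."""
    box = aois.left_box if side == "left" else aois.right_box
    inset_x = 0.02 + 4 * _FIX_JITTER_SD
    inset_y = 0.04 + 4 * _FIX_JITTER_SD
    return Rect(box.x0 + inset_x, box.y0 + inset_y,
                box.x1 - inset_x, box.y1 - inset_y)


def _segment_positions(n: int, side: str, aois: AOIPair,
                       rng: np.random.Generator) -> np.ndarray:
    """Gaze positions for n samples dwelling on one side: a chain of
    fixations with small within-fixation jitter."""
    lo_ms, hi_ms = _FIX_MS_RANGE
    # chunk lengths in samples at 60 Hz equivalent; derived from n's share
    out = np.empty((n, 2))
    box = _fixation_centers_box(aois, side)
    i = 0
    while i < n:
        chunk = int(rng.integers(int(lo_ms / 1000 * 60), int(hi_ms / 1000 * 60) + 1))
        chunk = min(chunk, n - i)
        # avoid a trailing sliver shorter than the fixation minimum
        if n - (i + chunk) < 6:
            chunk = n - i
        cx = rng.uniform(box.x0, box.x1)
        cy = rng.uniform(box.y0, box.y1)
        out[i:i + chunk, 0] = cx + rng.normal(0, _FIX_JITTER_SD, chunk)
        out[i:i + chunk, 1] = cy + rng.normal(0, _FIX_JITTER_SD, chunk)
        i += chunk
    return out


def simulate_trial_gaze(true_np: float, novel_side: str, params: CohortParams,
                        rng: np.random.Generator,
                        aois: AOIPair = AOIPair()) -> tuple[pd.DataFrame, list[str]]:
    """One trial's 60 Hz gaze stream realizing the given true NP.

    The trial is two dwell segments (novel-side and familiar-side, order
    randomized) joined by a short between-AOI saccade whose samples stay
    strictly between the expanded AOIs, so the on-stimulus sample split
    equals ``true_np`` up to rounding of one sample. Blinks and missing
    runs are then stamped in as invalid samples.

    Returns the stream and the true 3 FPS frame codes (``left``/``right``/
    ``neither``) read off the finished stream at the down-sampled instants.
    """
    t_ms, left, right, valid, true_codes = _trial_gaze_arrays(
        true_np, novel_side, params, rng, aois)
    stream = pd.DataFrame({
        "t_ms": t_ms,
        "left_x": left[:, 0], "left_y": left[:, 1],
        "right_x": right[:, 0], "right_y": right[:, 1],
        "valid": valid,
    })
    return stream, true_codes


def _trial_gaze_arrays(true_np: float, novel_side: str, params: CohortParams,
                       rng: np.random.Generator, aois: AOIPair):
    if not 0.0 <= true_np <= 1.0:
        raise ValueError("true_np must lie in [0, 1]")
    if novel_side not in ("left", "right"):
        raise ValueError("novel_side must be 'left' or 'right'")
    n = params.samples_per_trial
    step = int(round(params.sample_hz / params.frame_fps))
    w = _SWITCH_TRAVEL_SAMPLES
    n_on = n - w
    n_nov = int(round(true_np * n_on))
    familiar_side = "left" if novel_side == "right" else "right"
    if n_nov == 0 or n_nov == n_on:
        # single-side trial: no switch, no travel samples
        side = novel_side if n_nov > 0 else familiar_side
        pos = _segment_positions(n, side, aois, rng)
    else:
        n_fam = n_on - n_nov
        novel_first = bool(rng.integers(0, 2))
        first_side, n_first = ((novel_side, n_nov) if novel_first
                               else (familiar_side, n_fam))
        second_side, n_second = ((familiar_side, n_fam) if novel_first
                                 else (novel_side, n_nov))
        seg1 = _segment_positions(n_first, first_side, aois, rng)
        seg2 = _segment_positions(n_second, second_side, aois, rng)
        lb, rb = aois.expanded()
        gap_lo, gap_hi = lb.x1 + 0.03, rb.x0 - 0.03
        tx = np.linspace(gap_lo, gap_hi, w + 2)[1:-1]
        if first_side == "right":
            tx = tx[::-1]
        ty = np.linspace(seg1[-1, 1], seg2[0, 1], w + 2)[1:-1]
        travel = np.column_stack([tx, ty])
        pos = np.vstack([seg1, travel, seg2])
    t_ms = np.arange(n) * (1000.0 / params.sample_hz)
    valid = np.ones(n, dtype=bool)
    # blinks: short invalid runs anchored at down-sampled frame instants
    for f in range(params.frames_per_trial):
        if rng.random() < params.blink_rate:
            valid[f * step: f * step + 3] = False
    # tracker dropouts: longer invalid runs at random positions
    for _ in range(rng.poisson(params.missing_run_rate)):
        start = int(rng.integers(0, n))
        length = int(rng.integers(6, 31))
        valid[start: start + length] = False
    left = pos + [-_EYE_OFFSET_X, 0.0]
    right = pos + [_EYE_OFFSET_X, 0.0]
    left[~valid] = np.nan
    right[~valid] = np.nan
    true_codes = []
    for f in range(params.frames_per_trial):
        i = f * step
        if not valid[i]:
            true_codes.append("neither")
        elif pos[i, 0] < 0.5:
            true_codes.append("left")
        elif pos[i, 0] > 0.5:
            true_codes.append("right")
        else:
            true_codes.append("neither")
    return t_ms, left, right, valid, true_codes


def simulate_rater_codes(true_codes: list[str], params: CohortParams,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Independent rater codes for one trial's true frame codes.

    In ``swap`` mode each rater misreads the horizontal direction
    (left<->right) with probability ``coder_error_rate``; blink frames stay
    ``neither``. In ``uniform`` mode an erring rater reports one of the
    other two categories uniformly, whatever the truth.
    """
    truth = np.asarray(true_codes, dtype=object)
    n = truth.size
    frames = np.tile(np.arange(n), params.n_raters)
    raters = np.repeat([f"R{r + 1}" for r in range(params.n_raters)], n)
    reported = np.tile(truth, params.n_raters)
    err = rng.random(reported.size) < params.coder_error_rate
    if params.coder_error_mode == "swap":
        swap_left = err & (reported == "left")
        swap_right = err & (reported == "right")
        reported[swap_left] = "right"
        reported[swap_right] = "left"
    else:
        pick = rng.integers(0, 2, size=reported.size)
        others = {"left": ("right", "neither"), "right": ("left", "neither"),
                  "neither": ("left", "right")}
        for i in np.flatnonzero(err):
            reported[i] = others[reported[i]][pick[i]]
    return pd.DataFrame({"frame": frames, "rater": raters, "code": reported})


def simulate_composites(ability: np.ndarray, coupling: float,
                        rng: np.random.Generator,
                        norms: dict[str, dict] | None = None) -> pd.DataFrame:
    """Cognition component scores correlated with latent ability.

    Each component's z-score is ``coupling * ability + sqrt(1 - coupling^2)
    * noise`` with independent standard-normal noise, then rescaled to its
    normative mean/SD (reverse-scored components flip sign on the raw
    scale), so the population Pearson correlation of every component with
    ability equals ``coupling`` exactly.
    """
    if not -1.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [-1, 1]")
    norms = norms or SYNTHETIC_NORMS
    ability = np.asarray(ability, dtype=float)
    slack = math.sqrt(1.0 - coupling * coupling)
    out = {"subject_id": [f"S{i + 1:03d}" for i in range(len(ability))]}
    for comp, spec in norms.items():
        z = coupling * ability + slack * rng.standard_normal(len(ability))
        if spec.get("reverse", False):
            z = -z
        out[comp] = spec["mean"] + spec["sd"] * z
    return pd.DataFrame(out)


def implied_np_composite_spearman(coupling: float, n_components: int = 4
                                  ) -> float:
    """Population Spearman between subject mean NP and a composite.

    Each component correlates ``coupling`` with ability, so the mean of
    ``n_components`` components correlates
    ``c / sqrt(c^2 + (1 - c^2)/k)`` (Pearson). Subject mean NP is a
    monotone map of ability, and for a bivariate normal pair the Spearman
    coefficient is ``(6/pi) * asin(r/2)``.
    """
    c = float(coupling)
    r = c / math.sqrt(c * c + (1.0 - c * c) / n_components)
    return 6.0 / math.pi * math.asin(r / 2.0)


def _balanced_sides(n_trials: int, rng: np.random.Generator) -> list[str]:
    sides = ["left"] * (n_trials // 2) + ["right"] * (n_trials - n_trials // 2)
    rng.shuffle(sides)
    return sides


def simulate_cohort(params: CohortParams,
                    aois: AOIPair = AOIPair()
                    ) -> tuple[list[SubjectDataset], GroundTruth]:
    """A full cohort: gaze streams, rater codes, cognition, ground truth.

    Deterministic given ``params.seed``; per-subject sub-streams are spawned
    from one root generator so subjects are independent but reproducible.
    """
    rng = np.random.default_rng(params.seed)
    n, k = params.n_subjects, params.n_trials
    ability = rng.standard_normal(n)
    mean_np = subject_mean_np_from_ability(ability, params.subject_np_dist)
    trial_np = np.clip(
        mean_np[:, None] + rng.normal(0.0, params.trial_np_sd, (n, k)),
        0.0, 1.0)
    cognition = simulate_composites(ability, params.composite_coupling, rng)
    n_short = int(round(params.delay_split * k))
    datasets: list[SubjectDataset] = []
    all_sides: list[list[str]] = []
    all_codes: list[list[list[str]]] = []
    for s in range(n):
        subject_id = f"S{s + 1:03d}"
        sides = _balanced_sides(k, rng)
        delays = ["2s"] * n_short + ["2min"] * (k - n_short)
        rng.shuffle(delays)
        gaze_parts, code_parts, subj_codes = [], [], []
        for t in range(k):
            t_ms, left, right, valid, true_codes = _trial_gaze_arrays(
                float(trial_np[s, t]), sides[t], params, rng, aois)
            gaze_parts.append((t_ms, left, right, valid))
            codes = simulate_rater_codes(true_codes, params, rng)
            codes.insert(0, "trial", t)
            code_parts.append(codes)
            subj_codes.append(true_codes)
        n_samp = params.samples_per_trial
        left = np.vstack([g[1] for g in gaze_parts])
        right = np.vstack([g[2] for g in gaze_parts])
        gaze = pd.DataFrame({
            "trial": np.repeat(np.arange(k), n_samp),
            "t_ms": np.concatenate([g[0] for g in gaze_parts]),
            "left_x": left[:, 0], "left_y": left[:, 1],
            "right_x": right[:, 0], "right_y": right[:, 1],
            "valid": np.concatenate([g[3] for g in gaze_parts]),
        })
        trials = pd.DataFrame({
            "trial": range(k),
            "novel_side": sides,
            "delay_condition": delays,
            "familiarization_ms": params.familiarization_ms,
            "test_phase_ms": params.test_phase_ms,
        })
        cog_row = cognition[cognition["subject_id"] == subject_id].iloc[0]
        datasets.append(SubjectDataset(
            subject_id=subject_id,
            trials=trials,
            gaze=gaze,
            codes=pd.concat(code_parts, ignore_index=True),
            cognition=cog_row.drop("subject_id").to_dict(),
        ))
        all_sides.append(sides)
        all_codes.append(subj_codes)
    truth = GroundTruth(ability=ability, subject_mean_np=mean_np,
                        trial_true_np=trial_np, novel_side=all_sides,
                        true_codes=all_codes)
    return datasets, truth


def noise_free(params: CohortParams) -> CohortParams:
    """The same design with every noise source silenced (no coder error,
    no blinks, no dropouts) — the regime of the generator-honesty checks."""
    return replace(params, coder_error_rate=0.0, blink_rate=0.0,
                   missing_run_rate=0.0)
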