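"""Scoring the high-frame-rate (60 Hz) eye-tracker arm.

The raw stream carries one row per sample with per-eye normalized screen
coordinates and a validity flag. Scoring proceeds: binocular midpoint ->
dispersion-based fixation detection (I-DT) -> fixation-time assignment to
the novel/familiar areas of interest -> novelty preference
NP = novel time / (novel time + familiar time). Trials with more than 4 s
of missing samples are excluded automatically; aberrant gaze paths are
flagged for review but never auto-excluded.

Gaze streams are pandas DataFrames with columns
``t_ms, left_x, left_y, right_x, right_y, valid`` (one trial per frame of
reference; timestamps strictly increasing within a trial).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import AOIPair, Fixation, ScreenPoint, TrialScore

GAZE_COLUMNS = ["t_ms", "left_x", "left_y", "right_x", "right_y", "valid"]

#: exclusion threshold on accumulated missing-sample time
MISSING_LIMIT_MS = 4000.0


@dataclass(frozen=True)
class FilterParams:
    """Fixation-filter settings (I-DT).

    dispersion_threshold:
        Maximum bounding-box diagonal of a fixation's samples, in
        normalized screen units.
    min_duration_ms:
        Minimum span (first to last sample timestamp) of a fixation.
    """

    dispersion_threshold: float = 0.05
    min_duration_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.dispersion_threshold <= 0:
            raise ValueError("dispersion_threshold must be positive")
        if self.min_duration_ms <= 0:
            raise ValueError("min_duration_ms must be positive")


def gaze_midpoint(left: ScreenPoint | None, right: ScreenPoint | None
                  ) -> ScreenPoint | None:
    """Definitive gaze estimate for one sample.

    The midpoint of the two eyes when both are present; the present eye
    alone when one is missing; ``None`` when both are missing.
    """
    if left is not None and right is not None:
        return ScreenPoint((left.x + right.x) / 2.0, (left.y + right.y) / 2.0)
    return left if left is not None else right


def midpoints(stream: pd.DataFrame) -> np.ndarray:
    """Vectorized gaze midpoints for a stream; NaN rows where both eyes miss.

    Invalid samples (``valid == False``) are forced to NaN regardless of
    coordinates.
    """
    lx = stream["left_x"].to_numpy(float)
    ly = stream["left_y"].to_numpy(float)
    rx = stream["right_x"].to_numpy(float)
    ry = stream["right_y"].to_numpy(float)
    x = np.where(np.isnan(lx), rx, np.where(np.isnan(rx), lx, (lx + rx) / 2.0))
    y = np.where(np.isnan(ly), ry, np.where(np.isnan(ry), ly, (ly + ry) / 2.0))
    out = np.column_stack([x, y])
    invalid = ~stream["valid"].to_numpy(bool)
    out[invalid] = np.nan
    return out


def sample_period_ms(t_ms: np.ndarray) -> float:
    """Nominal sample period, from the median timestamp step."""
    if len(t_ms) < 2:
        return math.nan
    return float(np.median(np.diff(t_ms)))


def detect_fixations(stream: pd.DataFrame, params: FilterParams = FilterParams()
                     ) -> list[Fixation]:
    """Dispersion-based (I-DT) fixation detection.

    Scans each maximal run of valid samples left to right: a candidate
    window grows while the bounding-box diagonal of its samples stays at or
    below the dispersion threshold; a maximal window that also spans at
    least ``min_duration_ms`` becomes a fixation. Invalid samples break
    candidate windows. Fixations are non-overlapping and time-ordered.
    """
    if len(stream) == 0:
        return []
    t = stream["t_ms"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing within a trial")
    pts = midpoints(stream)
    ok = ~np.isnan(pts).any(axis=1)
    fixations: list[Fixation] = []
    # segment boundaries: runs of consecutive usable samples
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    seg_starts = np.concatenate([[0], breaks + 1])
    seg_ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(seg_starts, seg_ends):
        seg = idx[s:e + 1]
        fixations.extend(_idt_segment(t[seg], pts[seg], params))
    return fixations


def _idt_segment(t: np.ndarray, pts: np.ndarray, params: FilterParams
                 ) -> list[Fixation]:
    thr2 = params.dispersion_threshold ** 2
    out: list[Fixation] = []
    n = len(t)
    i = 0
    while i < n:
        xmin = xmax = pts[i, 0]
        ymin = ymax = pts[i, 1]
        j = i
        while j + 1 < n:
            nx, ny = pts[j + 1]
            xmn, xmx = min(xmin, nx), max(xmax, nx)
            ymn, ymx = min(ymin, ny), max(ymax, ny)
            if (xmx - xmn) ** 2 + (ymx - ymn) ** 2 > thr2:
                break
            xmin, xmax, ymin, ymax = xmn, xmx, ymn, ymx
            j += 1
        # tolerance absorbs float error in timestamps built from a rational
        # sample period (e.g. 1000/60 ms)
        if t[j] - t[i] >= params.min_duration_ms - 1e-6:
            cx, cy = pts[i:j + 1].mean(axis=0)
            out.append(Fixation(start_ms=float(t[i]), end_ms=float(t[j]),
                                centroid=ScreenPoint(float(cx), float(cy)),
                                n_samples=j - i + 1))
            i = j + 1
        else:
            i += 1
    return out


def fixation_time_ms(fix: Fixation, period_ms: float) -> float:
    """Viewing time credited to a fixation: one sample period per sample."""
    return fix.n_samples * period_ms


def trial_np_highrate(stream: pd.DataFrame, aois: AOIPair, novel_side: str,
                      params: FilterParams = FilterParams(),
                      trial: int = 0) -> TrialScore:
    """Duration-based novelty preference for one trial.

    Fixations are assigned to an AOI by centroid; NP is novel fixation time
    over total on-AOI fixation time. Both durations zero -> NP undefined
    with reason ``zero_viewing``.
    """
    if novel_side not in ("left", "right"):
        raise ValueError("novel_side must be 'left' or 'right'")
    fixations = detect_fixations(stream, params)
    period = sample_period_ms(stream["t_ms"].to_numpy(float))
    side_ms = {"left": 0.0, "right": 0.0}
    for fix in fixations:
        side = aois.side_of(fix.centroid.x, fix.centroid.y)
        if side is not None:
            side_ms[side] += fixation_time_ms(fix, period)
    novel_ms = side_ms[novel_side]
    familiar_ms = side_ms["left" if novel_side == "right" else "right"]
    total = novel_ms + familiar_ms
    if total == 0.0:
        return TrialScore(trial=trial, np_score=math.nan, novel_ms=0.0,
                          familiar_ms=0.0, excluded=False, reason="zero_viewing")
    return TrialScore(trial=trial, np_score=novel_ms / total,
                      novel_ms=novel_ms, familiar_ms=familiar_ms)


def exclude_missing(stream: pd.DataFrame, sample_hz: float,
                    limit_ms: float = MISSING_LIMIT_MS) -> tuple[bool, str]:
    """Apply the automatic missing-data exclusion rule.

    Missing time is the number of invalid samples times the sample period.
    A trial is excluded only when that time strictly exceeds ``limit_ms``
    (4 s by default): exactly 4 s of missing data is retained.
    """
    n_invalid = int((~stream["valid"].to_numpy(bool)).sum())
    missing_ms = n_invalid * 1000.0 / sample_hz
    if missing_ms > limit_ms:
        return True, "missing_gt_4s"
    return False, "none"


def flag_aberrant(fixations: list[Fixation], stream: pd.DataFrame,
                  aois: AOIPair, *, single_cluster_frac: float = 0.95,
                  off_aoi_frac: float = 0.5,
                  saccade_rate_z: float | None = None,
                  z_threshold: float = 3.0) -> list[str]:
    """Advisory flags for aberrant gaze paths.

    Flags (never auto-excluding; human consensus decides):

    * ``gaze_clustering`` — more than ``single_cluster_frac`` of fixation
      time sits in a single fixation.
    * ``off_aoi`` — at least ``off_aoi_frac`` of fixation time lies outside
      both AOIs.
    * ``erratic_saccades`` — the trial's saccade-count z-score within its
      cohort (supplied by the caller) exceeds ``z_threshold``.
    """
    flags: list[str] = []
    period = sample_period_ms(stream["t_ms"].to_numpy(float))
    times = [fixation_time_ms(f, period) for f in fixations]
    total = sum(times)
    if total > 0:
        if max(times) / total > single_cluster_frac:
            flags.append("gaze_clustering")
        off = sum(t for f, t in zip(fixations, times)
                  if aois.side_of(f.centroid.x, f.centroid.y) is None)
        if off / total >= off_aoi_frac:
            flags.append("off_aoi")
    if saccade_rate_z is not None and abs(saccade_rate_z) > z_threshold:
        flags.append("erratic_saccades")
    return flags


def saccade_count(fixations: list[Fixation]) -> int:
    """Number of between-fixation transitions, the basis of the rate flag."""
    return max(len(fixations) - 1, 0)


def score_trials_highrate(gaze: pd.DataFrame, trials: pd.DataFrame,
                          aois: AOIPair = AOIPair(),
                          params: FilterParams = FilterParams(),
                          sample_hz: float = 60.0) -> list[TrialScore]:
    """Score every trial of one subject's gaze table.

    ``gaze`` holds all trials (column ``trial`` selects rows); ``trials``
    carries per-trial ``novel_side``. The missing-data exclusion runs
    before scoring; excluded trials carry NaN NP.
    """
    by_trial = {t: g for t, g in gaze.groupby("trial", sort=True)}
    scores: list[TrialScore] = []
    for row in trials.itertuples():
        sub = by_trial.get(row.trial, gaze.iloc[0:0])
        excluded, reason = exclude_missing(sub, sample_hz)
        if excluded:
            scores.append(TrialScore(trial=int(row.trial), excluded=True,
                                     reason=reason))
            continue
        score = trial_np_highrate(sub, aois, row.novel_side, params,
                                  trial=int(row.trial))
        scores.append(score)
    return scores
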