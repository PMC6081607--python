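"""Scoring the down-sampled (3 FPS) webcam arm.

The webcam video is down-sampled to instantaneous frames; independent human
coders label each frame ``left``, ``right`` or ``neither`` (blink or
unusable image). The per-frame majority vote across coders yields the
consensus code; trial novelty preference is novel-side frames over
(novel + familiar) frames, with ``neither`` frames dropped from both
numerator and denominator. The subject's overall score is the unweighted
mean NP over retained, defined trials.

Frame codes are pandas DataFrames with columns
``trial, frame, rater, code``.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd

from .types import CODES, SubjectNP, TrialScore

CODE_COLUMNS = ["trial", "frame", "rater", "code"]


def downsample_indices(n_samples: int, sample_hz: float, frame_fps: float
                       ) -> list[int]:
    """Sample indices retained when down-sampling a stream to frames.

    Every ``sample_hz / frame_fps``-th sample starting at 0: a frame is an
    instantaneous sample, not a window average. The rates must divide
    evenly (e.g. 60 Hz -> 3 FPS keeps every 20th sample; 300 samples give
    exactly 15 frames).
    """
    if sample_hz <= 0 or frame_fps <= 0:
        raise ValueError("rates must be positive")
    step = sample_hz / frame_fps
    if abs(step - round(step)) > 1e-9:
        raise ValueError(
            f"sample_hz={sample_hz} is not divisible by frame_fps={frame_fps}")
    return list(range(0, n_samples, int(round(step))))


def majority_vote(codes) -> str:
    """Consensus code for one frame from the raters' codes.

    The strictly most frequent code wins; any tie for first place (possible
    with three raters and three categories) abstains to ``neither``: a tied
    frame carries no directional evidence.
    """
    codes = list(codes)
    if not codes:
        raise ValueError("majority_vote needs at least one rater")
    for c in codes:
        if c not in CODES:
            raise ValueError(f"unknown code: {c!r}")
    counts = Counter(codes).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return "neither"
    return counts[0][0]


def _vote_matrix(arr: np.ndarray) -> list[str]:
    """Vectorized majority vote over a (frames, raters) code matrix."""
    counts = np.stack([(arr == c).sum(axis=1) for c in CODES], axis=1)
    top = counts.max(axis=1)
    tied = (counts == top[:, None]).sum(axis=1) > 1
    winner = np.asarray(CODES, dtype=object)[counts.argmax(axis=1)]
    winner[tied] = "neither"
    return winner.tolist()


def vote_frames(codes: pd.DataFrame, trial: int) -> list[str]:
    """Majority-voted code per frame for one trial, in frame order."""
    sub = codes[codes["trial"] == trial]
    wide = sub.pivot(index="frame", columns="rater", values="code")
    return _vote_matrix(wide.to_numpy(dtype=object))


def trial_np_frames(voted: list[str], novel_side: str, trial: int = 0
                    ) -> TrialScore:
    """Frame-count novelty preference for one trial's voted codes.

    NP = novel-side frames / (novel-side + familiar-side frames). All
    frames ``neither`` -> NP undefined with reason ``zero_viewing``.
    """
    if novel_side not in ("left", "right"):
        raise ValueError("novel_side must be 'left' or 'right'")
    familiar_side = "left" if novel_side == "right" else "right"
    counts = Counter(voted)
    n_novel = counts.get(novel_side, 0)
    n_familiar = counts.get(familiar_side, 0)
    n_neither = counts.get("neither", 0)
    if n_novel + n_familiar == 0:
        return TrialScore(trial=trial, np_score=math.nan, excluded=False,
                          reason="zero_viewing", n_novel=0, n_familiar=0,
                          n_neither=n_neither)
    return TrialScore(trial=trial, np_score=n_novel / (n_novel + n_familiar),
                      n_novel=n_novel, n_familiar=n_familiar,
                      n_neither=n_neither)


def mean_np(subject: str, trial_scores: list[TrialScore]) -> SubjectNP:
    """Overall novelty preference: unweighted mean over retained trials."""
    return SubjectNP.from_trials(subject, trial_scores)


def score_trials_frames(codes: pd.DataFrame, trials: pd.DataFrame,
                        *, neither_exclusion_limit: int | None = None
                        ) -> list[TrialScore]:
    """Score every trial of one subject's frame-code table.

    ``neither_exclusion_limit``, if set, excludes a trial whose voted
    ``neither`` count exceeds it (an optional webcam-arm analogue of the
    high-rate missing-data rule; off by default).
    """
    wide = codes.pivot(index=["trial", "frame"], columns="rater", values="code")
    voted_all = np.asarray(_vote_matrix(wide.to_numpy(dtype=object)),
                           dtype=object)
    trial_ids = wide.index.get_level_values("trial").to_numpy()
    scores: list[TrialScore] = []
    for row in trials.itertuples():
        voted = voted_all[trial_ids == row.trial].tolist()
        score = trial_np_frames(voted, row.novel_side, trial=int(row.trial))
        if (neither_exclusion_limit is not None
                and score.n_neither is not None
                and score.n_neither > neither_exclusion_limit):
            score = TrialScore(trial=int(row.trial), excluded=True,
                               reason="missing_gt_4s",
                               n_neither=score.n_neither)
        scores.append(score)
    return scores
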