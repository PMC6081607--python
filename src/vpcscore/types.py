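"""Core domain types shared across the scoring pipeline.

Coordinates are normalized to the unit square with the origin at the top
left of the screen: (0, 0) is top-left, (1, 1) is bottom-right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

SIDES = ("left", "right")
CODES = ("left", "right", "neither")


class ScreenPoint(NamedTuple):
    """A gaze location in normalized screen coordinates."""

    x: float
    y: float

    def in_unit_square(self) -> bool:
        return 0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0


class Rect(NamedTuple):
    """Axis-aligned rectangle (x0, y0) top-left to (x1, y1) bottom-right."""

    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    def expand(self, margin: float) -> "Rect":
        """Grow the rectangle by ``margin`` times its own width/height per side."""
        dx = margin * self.width
        dy = margin * self.height
        return Rect(self.x0 - dx, self.y0 - dy, self.x1 + dx, self.y1 + dy)


@dataclass(frozen=True)
class AOIPair:
    """The pair of stimulus areas of interest for one trial.

    The screening rectangles are drawn slightly larger than the stimulus
    boxes themselves; ``margin`` is the fractional expansion applied per side
    before any containment test.
    """

    left_box: Rect = Rect(0.15, 0.30, 0.35, 0.70)
    right_box: Rect = Rect(0.65, 0.30, 0.85, 0.70)
    margin: float = 0.10

    def __post_init__(self) -> None:
        lb, rb = self.expanded()
        if lb.x1 >= rb.x0:
            raise ValueError("AOI boxes overlap after margin expansion")
        for box in (lb, rb):
            if not (0 <= box.x0 and box.x1 <= 1 and 0 <= box.y0 and box.y1 <= 1):
                raise ValueError("expanded AOI box leaves the unit square")

    def expanded(self) -> tuple[Rect, Rect]:
        return self.left_box.expand(self.margin), self.right_box.expand(self.margin)

    def side_of(self, x: float, y: float) -> str | None:
        """Which AOI (``left``/``right``) contains the point, or None."""
        lb, rb = self.expanded()
        if lb.contains(x, y):
            return "left"
        if rb.contains(x, y):
            return "right"
        return None


@dataclass(frozen=True)
class Fixation:
    """A run of gaze samples stationary within the dispersion threshold."""

    start_ms: float
    end_ms: float
    centroid: ScreenPoint
    n_samples: int

    @property
    def span_ms(self) -> float:
        return self.end_ms - self.start_ms


#: exclusion / degeneracy reasons carried on a TrialScore
REASONS = ("none", "missing_gt_4s", "aberrant", "zero_viewing")


@dataclass
class TrialScore:
    """Novelty preference for one test trial.

    ``np_score`` is novel viewing over total on-stimulus viewing; it is NaN
    when the trial is excluded or no on-stimulus viewing exists.
    """

    trial: int
    np_score: float = math.nan
    novel_ms: float = 0.0
    familiar_ms: float = 0.0
    excluded: bool = False
    reason: str = "none"
    # frame-arm bookkeeping (counts of majority-voted frames)
    n_novel: int | None = None
    n_familiar: int | None = None
    n_neither: int | None = None

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown exclusion reason: {self.reason!r}")

    @property
    def defined(self) -> bool:
        return not self.excluded and not math.isnan(self.np_score)


@dataclass
class SubjectNP:
    """Overall novelty preference: mean over retained, defined trials."""

    subject: str
    trial_scores: list[TrialScore] = field(default_factory=list)
    mean_np: float = math.nan
    n_retained: int = 0

    @classmethod
    def from_trials(cls, subject: str, scores: list[TrialScore]) -> "SubjectNP":
        defined = [s.np_score for s in scores if s.defined]
        mean = sum(defined) / len(defined) if defined else math.nan
        return cls(subject=subject, trial_scores=list(scores),
                   mean_np=mean, n_retained=len(defined))
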