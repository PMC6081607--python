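"""Calibration path, coder-accuracy validation, and gaze-map fitting.

Before the task, the subject tracks a dot that pauses at nine screen
positions. Human coders label each calibration video frame with the screen
region the subject appears to look at; a coder whose labels match the dot's
true region on fewer than 90% of dwell frames must recode. The dwell-phase
gaze estimates are also used to fit a per-subject affine map from raw gaze
coordinates to screen coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ScreenPoint

#: the dot's waypoints, in presentation order, normalized screen coordinates
CALIBRATION_WAYPOINTS: tuple[ScreenPoint, ...] = tuple(
    ScreenPoint(*p) for p in [
        (0.5, 0.5), (0.1, 0.1), (0.1, 0.9), (0.9, 0.9), (0.5, 0.5),
        (0.9, 0.1), (0.5, 0.1), (0.1, 0.5), (0.5, 0.9),
    ]
)

#: nominal dwell at each waypoint
DEFAULT_DWELL_MS = 2000.0

#: coders must match the true region on at least this fraction of frames
CODER_ACCURACY_THRESHOLD = 0.90


@dataclass(frozen=True)
class CalibrationPath:
    waypoints: tuple[ScreenPoint, ...]
    dwell_ms: float = DEFAULT_DWELL_MS

    def __post_init__(self) -> None:
        if len(self.waypoints) != 9:
            raise ValueError("calibration path must have exactly 9 waypoints")
        for p in self.waypoints:
            if not p.in_unit_square():
                raise ValueError(f"waypoint {p} outside the unit square")


def calibration_path(dwell_ms: float = DEFAULT_DWELL_MS) -> CalibrationPath:
    """The predetermined nine-point dot path with its per-point dwell."""
    return CalibrationPath(waypoints=CALIBRATION_WAYPOINTS, dwell_ms=dwell_ms)


def grid_region(x: float, y: float, n: int = 3) -> str:
    """Label the n-by-n grid cell containing a point, e.g. ``"r0c2"``.

    Coders judge gaze direction, not exact coordinates; a 3x3 grid makes
    per-frame accuracy well defined. Points on a cell edge belong to the
    lower-index cell except at the far screen edge.
    """
    col = min(int(x * n), n - 1)
    row = min(int(y * n), n - 1)
    return f"r{row}c{col}"


@dataclass
class CalibrationReport:
    """Per-coder accuracy on dwell frames and the pass/recode outcome."""

    accuracy: dict[str, float]
    passed: bool
    recode_required: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": dict(self.accuracy),
            "passed": self.passed,
            "recode_required": list(self.recode_required),
            "threshold": CODER_ACCURACY_THRESHOLD,
        }


def validate_calibration(coded: dict[str, dict[int, str]],
                         expected: dict[int, str]) -> CalibrationReport:
    """Score each coder's calibration-frame labels against the true regions.

    Parameters
    ----------
    coded:
        ``{coder_id: {frame: region_label}}``. Every coder must label
        exactly the frames in ``expected`` (the dwell frames; transition
        frames between waypoints are not scored).
    expected:
        ``{frame: region_label}`` — the region of the dot at each dwell frame.

    Returns
    -------
    CalibrationReport
        Accuracy per coder; ``passed`` iff every coder reaches 90%;
        coders below 90% are listed in ``recode_required``.
    """
    if not expected:
        raise ValueError("no calibration frames to validate")
    frames = set(expected)
    accuracy: dict[str, float] = {}
    recode: list[str] = []
    for coder, labels in coded.items():
        if set(labels) != frames:
            missing = frames.symmetric_difference(labels)
            raise ValueError(
                f"coder {coder!r} frames do not align with expected frames "
                f"(mismatch on {sorted(missing)[:5]}...)")
        acc = sum(labels[f] == expected[f] for f in frames) / len(frames)
        accuracy[coder] = acc
        if acc < CODER_ACCURACY_THRESHOLD:
            recode.append(coder)
    return CalibrationReport(accuracy=accuracy, passed=not recode,
                             recode_required=sorted(recode))


@dataclass(frozen=True)
class GazeMap:
    """A 6-parameter affine map from raw gaze estimates to screen coordinates.

    ``screen = raw @ A + b`` with A the 2x2 linear part and b the offset.
    """

    A: np.ndarray  # (2, 2)
    b: np.ndarray  # (2,)
    residual_rms: float

    def apply(self, raw) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(raw, dtype=float))
        return pts @ self.A + self.b


def fit_gaze_map(raw, targets, *, max_residual: float | None = None) -> GazeMap:
    """Least-squares affine fit of raw gaze points onto known screen targets.

    Parameters
    ----------
    raw, targets:
        (n, 2) arrays of matched points: the subject's uncalibrated gaze
        estimates while dwelling on each waypoint, and the waypoint
        coordinates. n >= 3 non-collinear raw points are required.
    max_residual:
        Optional ceiling on the training residual RMS; exceeding it raises,
        signalling a calibration too poor to use.
    """
    raw = np.asarray(raw, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if raw.shape != targets.shape or raw.ndim != 2 or raw.shape[1] != 2:
        raise ValueError("raw and targets must be matched (n, 2) arrays")
    if raw.shape[0] < 3:
        raise ValueError("need at least 3 calibration points")
    design = np.hstack([raw, np.ones((raw.shape[0], 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("calibration points are collinear; affine fit is degenerate")
    coef, *_ = np.linalg.lstsq(design, targets, rcond=None)
    A, b = coef[:2], coef[2]
    fitted = design @ coef
    residual_rms = float(np.sqrt(np.mean(np.sum((fitted - targets) ** 2, axis=1))))
    if max_residual is not None and residual_rms > max_residual:
        raise ValueError(
            f"calibration residual RMS {residual_rms:.4f} exceeds {max_residual}")
    return GazeMap(A=A, b=b, residual_rms=residual_rms)
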