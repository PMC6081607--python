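"""Cognitive composite scores the VPC task is validated against.

Two composites are supported:

* PACC — the Preclinical Alzheimer Cognitive Composite: the unweighted mean
  of four z-transformed components (Logical Memory delayed recall, FCSRT
  total, Digit Symbol coding, MMSE), z-scored against normative means/SDs
  of clinically normal older adults. Higher is better on every component.
* NIHTB — a surrogate for the NIH Toolbox Cognition Battery summary: the
  mean of z-standardized component scores (Flanker, PCPST, DCCS, PSMT).
  The battery's own summary is an IRT theta score whose model is internal
  to the battery; the z-mean here is a documented stand-in, not a
  reimplementation of it.

Timed measures where lower raw scores mean better performance (e.g. Trail
Making A) carry ``reverse: true`` in the norm table and are sign-flipped at
z-transform, so that one sign convention covers every z-scored component.
Single measures such as Trails A can still be reported on their raw
(negative-correlation) scale by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

PACC_COMPONENTS = ("lm_dr", "fcsrt", "digit_symbol", "mmse")
NIHTB_COMPONENTS = ("flanker", "pcpst", "dccs", "psmt")


@dataclass(frozen=True)
class Norm:
    """Normative mean/SD for one component; ``reverse`` flips the z sign."""

    mean: float
    sd: float
    reverse: bool = False

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("normative SD must be positive")


def z_transform(score: float, norm: Norm) -> float:
    """Z-score a raw component score against its norm.

    ``(score - mean) / sd``, negated for reverse-scored (timed) measures so
    higher z always means better performance.
    """
    z = (score - norm.mean) / norm.sd
    return -z if norm.reverse else z


def pacc_composite(z_scores: dict[str, float], *,
                   available_case: bool = False) -> float:
    """PACC: unweighted mean of the four component z-scores.

    With ``available_case=False`` (default) a missing component makes the
    composite undefined (NaN); with ``available_case=True`` the mean is
    taken over the components present.
    """
    return _mean_composite(z_scores, PACC_COMPONENTS, available_case)


def nihtb_composite(z_scores: dict[str, float], *,
                    available_case: bool = False) -> float:
    """Surrogate NIHTB summary: mean of the four component z-scores."""
    return _mean_composite(z_scores, NIHTB_COMPONENTS, available_case)


def _mean_composite(z_scores: dict[str, float], components: tuple[str, ...],
                    available_case: bool) -> float:
    vals = [z_scores[c] for c in components
            if c in z_scores and not math.isnan(z_scores[c])]
    if len(vals) < len(components) and not available_case:
        return math.nan
    if not vals:
        return math.nan
    return sum(vals) / len(vals)


def compute_composites(cognition: pd.DataFrame, norms: dict[str, Norm],
                       *, available_case: bool = False) -> pd.DataFrame:
    """Z-transform every normed component and build both composites.

    ``cognition`` has one row per subject (column ``subject_id`` plus raw
    component columns). Returns a table of per-component z-scores (suffix
    ``_z``) plus ``pacc`` and ``nihtb`` columns.
    """
    out = {"subject_id": cognition["subject_id"]}
    zcols: dict[str, pd.Series] = {}
    for comp, norm in norms.items():
        if comp in cognition.columns:
            zcols[comp] = cognition[comp].map(lambda s, n=norm: z_transform(s, n))
            out[f"{comp}_z"] = zcols[comp]
    rows_pacc, rows_nihtb = [], []
    for i in cognition.index:
        z = {c: zcols[c].loc[i] for c in zcols}
        rows_pacc.append(pacc_composite(z, available_case=available_case))
        rows_nihtb.append(nihtb_composite(z, available_case=available_case))
    out["pacc"] = pd.Series(rows_pacc, index=cognition.index)
    out["nihtb"] = pd.Series(rows_nihtb, index=cognition.index)
    return pd.DataFrame(out)


def norms_from_mapping(raw: dict) -> dict[str, Norm]:
    """Build a norm table from a plain mapping (e.g. parsed norms.yaml)."""
    norms = {}
    for comp, spec in raw.items():
        norms[comp] = Norm(mean=float(spec["mean"]), sd=float(spec["sd"]),
                           reverse=bool(spec.get("reverse", False)))
    return norms
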