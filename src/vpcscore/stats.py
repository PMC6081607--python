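"""Reliability and validity statistics for the VPC pipeline.

Covers the four statistical operations the assessment rests on:

* :func:`krippendorff_nominal` — chance-corrected multi-rater agreement for
  nominal codes (any number of raters, missing codes allowed), via the
  coincidence-matrix formulation.
* :func:`spearman` — rank correlation with a two-tailed p-value; exact
  permutation p at small n, t-approximation otherwise.
* :func:`fisher_compare` — difference of two correlations through the
  variance-stabilizing atanh (Fisher z) transform, for independent samples
  or for overlapping (dependent) correlations.
* :func:`strength_category` — conventional strength bands for correlation
  and agreement coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps


class UndefinedStatisticError(ValueError):
    """Raised when a statistic has no defined value for the given input."""


# ---------------------------------------------------------------------------
# Krippendorff's alpha (nominal)
# ---------------------------------------------------------------------------

def krippendorff_nominal(matrix) -> float:
    """Krippendorff's agreement coefficient for nominal data.

    Parameters
    ----------
    matrix:
        Units-by-raters array of nominal codes. Missing entries may be
        ``None``, ``NaN`` or ``""``. Units with fewer than two codes are
        ignored (nothing is pairable within them).

    Returns
    -------
    float
        ``1 - Do/De`` where ``Do`` is the observed disagreement from the
        coincidence matrix and ``De`` the disagreement expected by chance.
        Perfect agreement returns exactly 1.0.

    Notes
    -----
    Sometimes reported in the applied literature under the name
    "Krippendorff's kappa"; the quantity computed here is the standard
    alpha coefficient for nominal-level data.
    """
    rows = _clean_matrix(matrix)
    # value counts per pairable unit
    totals: dict[object, float] = {}
    observed: dict[tuple[object, object], float] = {}
    n_pairable = 0.0
    for unit in rows:
        m_u = len(unit)
        if m_u < 2:
            continue
        n_pairable += m_u
        counts: dict[object, int] = {}
        for v in unit:
            counts[v] = counts.get(v, 0) + 1
        for c, n_c in counts.items():
            totals[c] = totals.get(c, 0.0) + n_c
            for k, n_k in counts.items():
                pairs = n_c * (n_k - (1 if c == k else 0))
                if pairs:
                    observed[(c, k)] = observed.get((c, k), 0.0) + pairs / (m_u - 1)
    if n_pairable < 2 or len(totals) == 0:
        raise UndefinedStatisticError("no pairable units: agreement undefined")
    if len(totals) == 1:
        return 1.0  # a single category used everywhere: perfect agreement
    d_o = sum(v for (c, k), v in observed.items() if c != k) / n_pairable
    n = n_pairable
    d_e = sum(n_c * n_k for c, n_c in totals.items()
              for k, n_k in totals.items() if c != k) / (n * (n - 1.0))
    if d_e == 0.0:
        return 1.0
    return 1.0 - d_o / d_e


def _clean_matrix(matrix) -> list[list[object]]:
    rows = []
    for raw in matrix:
        unit = []
        for v in raw:
            if v is None:
                continue
            if isinstance(v, float) and math.isnan(v):
                continue
            if isinstance(v, str) and v == "":
                continue
            unit.append(v)
        rows.append(unit)
    return rows


# ---------------------------------------------------------------------------
# Spearman's rho
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    """A rank correlation with its two-tailed significance."""

    rho: float
    n: int
    p: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho outside [-1, 1]")


#: largest n for which the exact permutation p-value is computed
EXACT_PERMUTATION_MAX_N = 7


def spearman(x, y, *, exact_max_n: int = EXACT_PERMUTATION_MAX_N) -> CorrelationResult:
    """Two-tailed Spearman rank correlation.

    Ties are handled with mid-ranks. For ``n <= exact_max_n`` the p-value is
    the exact two-tailed permutation probability (all n! orderings of y);
    otherwise the usual t-approximation is used.

    Raises
    ------
    UndefinedStatisticError
        if fewer than 3 pairs remain or either variable has zero rank
        variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise UndefinedStatisticError("need at least 3 complete pairs")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedStatisticError("zero rank variance: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _exact_permutation_p(rx, ry, rho)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return CorrelationResult(rho=rho, n=int(n), p=float(min(p, 1.0)))


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exhaustive two-tailed permutation p for the rank correlation."""
    rx = rx - rx.mean()
    denom_x = math.sqrt(float(rx @ rx))
    ryc = ry - ry.mean()
    denom_y = math.sqrt(float(ryc @ ryc))
    hits = 0
    total = 0
    thr = abs(rho_obs) - 1e-12
    for perm in permutations(ryc):
        r = float(rx @ np.asarray(perm)) / (denom_x * denom_y)
        if abs(r) >= thr:
            hits += 1
        total += 1
    return hits / total


# ---------------------------------------------------------------------------
# Comparing two correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationComparison:
    """Result of testing whether two correlations differ."""

    z: float
    p: float
    method: str  # "independent" or "dependent"


def fisher_compare(r1: float, n1: int, r2: float, n2: int,
                   r12: float | None = None) -> CorrelationComparison:
    """Test the difference between two correlation coefficients.

    With ``r12`` omitted, the correlations are treated as coming from
    independent samples:

        z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))

    With ``r12`` supplied (the correlation between the two measures, both
    observed on the same ``n1 == n2`` subjects), the dependent-overlapping
    test of Steiger (as popularized by Meng, Rosenthal & Rubin) is used.

    The p-value is two-tailed in both cases; the sign of ``z`` matches the
    sign of ``r1 - r2`` after transformation.
    """
    for r in (r1, r2) + (() if r12 is None else (r12,)):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if min(n1, n2) <= 3:
        raise ValueError("need n > 3 in both samples")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    if r12 is None:
        se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
        z = (z1 - z2) / se
        method = "independent"
    else:
        if n1 != n2:
            raise ValueError("dependent comparison requires n1 == n2")
        n = n1
        rm2 = (r1 * r1 + r2 * r2) / 2.0
        f = min((1.0 - r12) / (2.0 * (1.0 - rm2)), 1.0)
        h = (1.0 - f * rm2) / (1.0 - rm2)
        z = (z1 - z2) * math.sqrt((n - 3.0) / (2.0 * (1.0 - r12) * h))
        method = "dependent"
    p = 2.0 * sps.norm.sf(abs(z))
    return CorrelationComparison(z=float(z), p=float(min(p, 1.0)), method=method)


# ---------------------------------------------------------------------------
# Strength bands
# ---------------------------------------------------------------------------

#: Cohen bands on |r|: below .10 negligible, .10 weak, .30 moderate, .50+ strong
_COHEN_BANDS = ((0.50, "strong"), (0.30, "moderate"), (0.10, "weak"))
#: agreement bands: .40-.59 weak, .60-.79 moderate, .80+ strong
_KAPPA_BANDS = ((0.80, "strong"), (0.60, "moderate"), (0.40, "weak"))


def strength_category(value: float, scale: str = "cohen_r") -> str:
    """Label the strength of a correlation (``cohen_r``) or agreement (``kappa``).

    ``cohen_r`` uses the magnitude of the coefficient; ``kappa`` uses the
    signed value (negative agreement is simply below every band).
    """
    if not -1.0 - 1e-12 <= value <= 1.0 + 1e-12:
        raise ValueError("coefficient outside [-1, 1]")
    if scale == "cohen_r":
        v = abs(value)
        bands, floor_label = _COHEN_BANDS, "negligible"
    elif scale == "kappa":
        v = value
        bands, floor_label = _KAPPA_BANDS, "poor"
    else:
        raise ValueError(f"unknown scale: {scale!r}")
    for cutoff, label in bands:
        if v >= cutoff:
            return label
    return floor_label
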