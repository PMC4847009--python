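"""Replicate-homogeneity screening via coefficients of variation.

For each developmental stage, the coefficient of variation (sample SD over
mean) of every miRNA across the stage's biological replicates summarizes
how reproducible its expression is.  The *global CV* is the mean (with SEM)
of per-miRNA CVs; *sliding CVs* are window means over miRNAs ranked by
decreasing mean abundance, exposing the abundance-dependence of
measurement noise.  A stage whose global CV is high may hide a homogeneous
subset of replicates (a "sub-stage"): an exhaustive search over replicate
subsets finds the lowest-CV subset and accepts it when it is both
absolutely tight (global CV below an acceptance threshold) and materially
tighter than the full replicate set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EstimationError, InputError

__all__ = [
    "per_mirna_cv",
    "stage_cvs",
    "global_cv",
    "sliding_cvs",
    "find_homogeneous_substage",
    "SubstageResult",
    "HomogeneityReport",
    "stage_homogeneity_report",
]


def per_mirna_cv(values: Sequence[float] | np.ndarray) -> float:
    """Sample SD (n-1 denominator) divided by the mean; requires mean > 0."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InputError("CV needs at least two replicate values")
    mean = arr.mean()
    if mean <= 0:
        raise EstimationError("CV undefined for non-positive mean")
    return float(arr.std(ddof=1) / mean)


def stage_cvs(values: pd.DataFrame) -> pd.Series:
    """Per-miRNA CVs across the columns (replicates) of ``values``.

    miRNAs with non-positive mean are excluded with a warning.
    """
    if values.shape[1] < 2:
        raise InputError("need at least two replicates")
    mat = values.to_numpy(dtype=float)
    means = mat.mean(axis=1)
    ok = means > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} miRNAs with zero mean excluded from CV computation")
    cvs = mat[ok].std(axis=1, ddof=1) / means[ok]
    return pd.Series(cvs, index=values.index[ok], name="cv")


def global_cv(cvs: Sequence[float] | pd.Series) -> tuple[float, float]:
    """Mean and SEM of per-miRNA CVs (SEM 0 for a single value, by convention)."""
    arr = np.asarray(cvs, dtype=float)
    if arr.size == 0:
        raise InputError("global CV of an empty CV list is undefined")
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), sem


def sliding_cvs(
    cvs: Sequence[float] | pd.Series, window: int = 50, step: int = 1
) -> list[tuple[int, float]]:
    """Window means of CVs ordered by decreasing abundance.

    ``cvs`` must already be ordered by decreasing mean abundance.  Returns
    ``(1-based start rank, mean CV)`` per window; when fewer values than
    the window size exist, a single window covers them all.
    """
    arr = np.asarray(cvs, dtype=float)
    n = arr.size
    if n == 0:
        return []
    if n < window:
        return [(1, float(arr.mean()))]
    return [
        (start + 1, float(arr[start : start + window].mean()))
        for start in range(0, n - window + 1, step)
    ]


@dataclass
class SubstageResult:
    """Outcome of the homogeneous-sub-stage search within one stage."""

    members: tuple[str, ...] | None  # None: no subset beat the full replicate set
    cv: float  # global CV of the returned subset (or of the full set)
    full_cv: float
    litter_confounded: bool = False


def _subset_global_cv(mat: np.ndarray, cols: tuple[int, ...]) -> float:
    sub = mat[:, cols]
    means = sub.mean(axis=1)
    ok = means > 0
    if not ok.any():
        return math.inf
    return float((sub[ok].std(axis=1, ddof=1) / means[ok]).mean())


def find_homogeneous_substage(
    values: pd.DataFrame,
    min_size: int = 4,
    accept_cv: float = 0.35,
    improvement: float = 0.75,
    litters: Mapping[str, str] | None = None,
) -> SubstageResult:
    """Exhaustively search replicate subsets for a homogeneous sub-stage.

    Scores every proper subset of the stage's replicates of size at least
    ``min_size`` by its global CV (per-miRNA CVs recomputed within the
    subset).  The lowest-CV subset is returned when its global CV is at
    most ``accept_cv`` *and* at most ``improvement`` times the full-set
    global CV; otherwise ``members`` is None and the full replicate set
    stands.  ``litter_confounded`` flags a returned subset whose members
    all share one litter.
    """
    n = values.shape[1]
    if min_size > n:
        raise InputError(f"min_size={min_size} exceeds the {n} available replicates")
    if min_size < 2:
        raise InputError("min_size must be at least 2")
    mat = values.to_numpy(dtype=float)
    full = _subset_global_cv(mat, tuple(range(n)))
    best_cols: tuple[int, ...] | None = None
    best_cv = math.inf
    for size in range(min_size, n):
        for cols in combinations(range(n), size):
            cv = _subset_global_cv(mat, cols)
            if cv < best_cv:
                best_cv, best_cols = cv, cols
    if best_cols is None or best_cv > accept_cv or best_cv > improvement * full:
        return SubstageResult(members=None, cv=full, full_cv=full)
    members = tuple(values.columns[list(best_cols)])
    confounded = False
    if litters is not None:
        confounded = len({litters[m] for m in members}) == 1
    return SubstageResult(members=members, cv=best_cv, full_cv=full, litter_confounded=confounded)


@dataclass
class HomogeneityReport:
    """Per-stage homogeneity summary."""

    stage: str
    per_mirna_cv: pd.Series
    global_cv: tuple[float, float]
    sliding_cv: list[tuple[int, float]] = field(default_factory=list)
    substage: SubstageResult | None = None


def stage_homogeneity_report(
    values: pd.DataFrame,
    stage: str,
    window: int = 50,
    min_size: int = 4,
    accept_cv: float = 0.35,
    improvement: float = 0.75,
    litters: Mapping[str, str] | None = None,
) -> HomogeneityReport:
    """Full homogeneity screen of one stage's replicate columns.

    ``values`` must be restricted to the stage's libraries and to
    filter-passing miRNAs.  Sliding windows rank miRNAs by decreasing mean
    normalized expression across the stage's replicates.
    """
    cvs = stage_cvs(values)
    order = values.loc[cvs.index].mean(axis=1).sort_values(ascending=False).index
    ranked = cvs.loc[order]
    substage = None
    if values.shape[1] >= min_size:
        substage = find_homogeneous_substage(
            values, min_size=min_size, accept_cv=accept_cv,
            improvement=improvement, litters=litters,
        )
    return HomogeneityReport(
        stage=stage,
        per_mirna_cv=cvs,
        global_cv=global_cv(cvs),
        sliding_cv=sliding_cvs(ranked, window=window),
        substage=substage,
    )
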