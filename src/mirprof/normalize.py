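"""Median-of-ratios size-factor normalization and per-stage mean profiles.

The size factor of library *j* is the median, over miRNAs *i* with strictly
positive counts in every library, of ``k_ij / (prod_v k_iv)^(1/m)`` — the
ratio of the count to the across-library geometric mean.  Dividing each
column by its factor makes libraries comparable in sequencing depth and
composition.  Factors are computed on the full quantified profile, before
any expression filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError, InputError

__all__ = ["size_factors", "normalize", "stage_mean_profiles", "NormalizedProfile",
           "normalize_profile"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per library (column)."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise EstimationError(
            "size factors undefined: no miRNA has strictly positive counts in all libraries"
        )
    sub = mat[positive]
    log_ratios = np.log(sub) - np.log(sub).mean(axis=1, keepdims=True)
    # median taken on the log scale: for an even number of miRNAs the two
    # central ratios are averaged geometrically, the DESeq convention
    return pd.Series(
        np.exp(np.median(log_ratios, axis=0)), index=counts.columns, name="size_factor"
    )


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each library column by its size factor."""
    factors = factors.reindex(counts.columns)
    if factors.isna().any():
        raise InputError("a size factor is missing for some library")
    if (factors <= 0).any():
        raise InputError("size factors must be positive")
    return counts.div(factors, axis=1)


def stage_mean_profiles(values: pd.DataFrame, stages: pd.Series) -> pd.DataFrame:
    """Arithmetic mean expression per miRNA per stage.

    ``stages`` maps library id -> stage label; stages with zero libraries
    are simply absent from the output.
    """
    stages = stages.reindex(values.columns)
    if stages.isna().any():
        raise InputError("every library needs a stage label")
    return values.T.groupby(stages).mean().T


@dataclass
class NormalizedProfile:
    """Size-factor-scaled expression values plus per-stage mean profiles."""

    values: pd.DataFrame
    size_factors: pd.Series
    stage_means: pd.DataFrame


def normalize_profile(counts: pd.DataFrame, stages: pd.Series) -> NormalizedProfile:
    """Convenience wrapper: factors, scaled values and stage means in one go."""
    factors = size_factors(counts)
    values = normalize(counts, factors)
    return NormalizedProfile(
        values=values, size_factors=factors, stage_means=stage_mean_profiles(values, stages)
    )
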