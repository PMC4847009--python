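"""Nonparametric differential expression with FDR control.

Per-miRNA two-group comparisons use the Mann-Whitney U test: exact
two-sided p-values (full enumeration of rank arrangements) when the groups
are small (combined n <= 14) and tie-free, otherwise the normal
approximation with tie and continuity correction.  Raw p-values are
adjusted per comparison with the Benjamini-Yekutieli step-up procedure,
which controls the false discovery rate under arbitrary dependence by
inflating the Benjamini-Hochberg threshold by the harmonic sum
``c(m) = sum_{k=1..m} 1/k``.  Significant miRNAs (adjusted p < alpha) are
classified by fold change: beyond 3-fold (fold > 3 up, fold < 1/3 down) or
within 3-fold.

With small groups the exact test is discrete: for 6 vs 6 replicates the
smallest achievable two-sided p is 2/924, so with hundreds of tests an
isolated perfectly separated miRNA cannot survive BY adjustment — only a
sufficiently large block of co-regulated miRNAs can, rescued by the
step-up rank.  This is a property of the design, not a defect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "mann_whitney",
    "by_adjust",
    "fold_change_and_classify",
    "Comparison",
    "ComparisonPlan",
    "side_stage_plan",
    "each_stage_vs_reference_plan",
    "diet_plan",
    "run_comparisons",
]

EXACT_MAX_N = 14  # combined group size up to which the exact null is enumerated


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group a, p-value).

    Exact p by enumeration of all C(n_a+n_b, n_a) rank arrangements when
    the pooled sample is tie-free and of size at most 14; otherwise the
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # all values identical: no separation at all
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and pooled.size <= EXACT_MAX_N) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), min(float(res.pvalue), 1.0)


def by_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli adjusted p-values, in the input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_by")[1]


def fold_change_and_classify(
    mean_a: float,
    mean_b: float,
    p_adj: float,
    alpha: float = 0.05,
    fc_threshold: float = 3.0,
) -> tuple[float, str]:
    """Fold change (mean A over mean B) and its significance category.

    Categories: ``ns`` (adjusted p >= alpha), ``sig_small`` (significant,
    within the fold threshold), ``sig_up_large`` (fold strictly above the
    threshold) and ``sig_down_large`` (fold strictly below its
    reciprocal).  When mean B is zero a pseudocount of 0.5 is added to
    both means so the ratio stays defined.
    """
    if mean_a == 0 and mean_b == 0:
        raise InputError("fold change undefined when both group means are zero")
    if mean_b == 0:
        mean_a, mean_b = mean_a + 0.5, mean_b + 0.5
    fc = mean_a / mean_b
    if p_adj >= alpha:
        return fc, "ns"
    if fc > fc_threshold:
        return fc, "sig_up_large"
    if fc < 1.0 / fc_threshold:
        return fc, "sig_down_large"
    return fc, "sig_small"


@dataclass(frozen=True)
class Comparison:
    """One two-group comparison: label plus the two library sets."""

    label: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise InputError(f"groups of {self.label} overlap")
        if min(len(self.group_a), len(self.group_b)) < 3:
            raise InputError(f"each group of {self.label} needs at least 3 libraries")


@dataclass
class ComparisonPlan:
    comparisons: list[Comparison] = field(default_factory=list)

    def __iter__(self):
        return iter(self.comparisons)


def _stage_libs(
    metadata: pd.DataFrame,
    stage: str,
    diet: str,
    substages: Mapping[str, Sequence[str]] | None,
) -> tuple[str, ...]:
    """Libraries of a stage (or its homogeneous sub-stage, when discovered)."""
    if substages and stage in substages:
        return tuple(substages[stage])
    sel = (metadata["stage"] == stage) & (metadata["diet"] == diet)
    return tuple(metadata.index[sel])


def side_stage_plan(
    metadata: pd.DataFrame,
    stages: Sequence[str],
    diet: str = "C",
    substages: Mapping[str, Sequence[str]] | None = None,
) -> ComparisonPlan:
    """Adjacent-stage comparisons along the time course (e.g. P4-P8, P8-P14)."""
    comps = []
    for s_a, s_b in zip(stages, stages[1:]):
        comps.append(
            Comparison(
                label=f"{s_a}-vs-{s_b}",
                group_a=_stage_libs(metadata, s_a, diet, substages),
                group_b=_stage_libs(metadata, s_b, diet, substages),
            )
        )
    return ComparisonPlan(comps)


def each_stage_vs_reference_plan(
    metadata: pd.DataFrame,
    stages: Sequence[str],
    reference_stage: str,
    diet: str = "C",
    substages: Mapping[str, Sequence[str]] | None = None,
) -> ComparisonPlan:
    """Each earlier stage against the terminal reference stage."""
    ref_libs = _stage_libs(metadata, reference_stage, diet, substages)
    comps = [
        Comparison(
            label=f"{s}-vs-{reference_stage}",
            group_a=_stage_libs(metadata, s, diet, substages),
            group_b=ref_libs,
        )
        for s in stages
        if s != reference_stage
    ]
    return ComparisonPlan(comps)


def diet_plan(
    metadata: pd.DataFrame, stages: Sequence[str], diet_a: str = "C", diet_b: str = "HF"
) -> ComparisonPlan:
    """Control vs high-fat progeny within each stage."""
    comps = [
        Comparison(
            label=f"{s}-{diet_a}-vs-{diet_b}",
            group_a=_stage_libs(metadata, s, diet_a, None),
            group_b=_stage_libs(metadata, s, diet_b, None),
        )
        for s in stages
    ]
    return ComparisonPlan(comps)


def run_comparisons(
    values: pd.DataFrame,
    plan: ComparisonPlan,
    retained: Sequence[str] | pd.Index,
    alpha: float = 0.05,
    fc_threshold: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every planned comparison over the retained miRNAs.

    Returns a per-(miRNA, comparison) result table and a per-comparison
    summary with significant counts, percentages and beyond-threshold
    fold-change tallies.  BY adjustment is applied within each comparison
    across its tested miRNAs; miRNAs with both group means zero are
    excluded from the comparison (and from its multiple-testing family).
    """
    retained = pd.Index(retained)
    missing = retained.difference(values.index)
    if len(missing):
        raise InputError(f"retained miRNAs absent from the profile: {list(missing)[:5]}")
    rows = []
    summaries = []
    for comp in plan:
        absent = [lib for lib in (*comp.group_a, *comp.group_b) if lib not in values.columns]
        if absent:
            raise InputError(f"comparison {comp.label} references unknown libraries {absent}")
        sub_a = values.loc[retained, list(comp.group_a)]
        sub_b = values.loc[retained, list(comp.group_b)]
        tested = []
        for mirna in retained:
            va = sub_a.loc[mirna].to_numpy()
            vb = sub_b.loc[mirna].to_numpy()
            if va.mean() == 0 and vb.mean() == 0:
                continue
            u, p = mann_whitney(va, vb)
            tested.append((mirna, float(va.mean()), float(vb.mean()), u, p))
        if not tested:
            continue
        p_adj = by_adjust([t[4] for t in tested])
        comp_rows = []
        for (mirna, ma, mb, u, p), padj in zip(tested, p_adj):
            fc, category = fold_change_and_classify(
                ma, mb, padj, alpha=alpha, fc_threshold=fc_threshold
            )
            comp_rows.append(
                {
                    "mirna": mirna,
                    "comparison": comp.label,
                    "mean_a": ma,
                    "mean_b": mb,
                    "fold_change": fc,
                    "u_statistic": u,
                    "p_raw": p,
                    "p_adj": padj,
                    "category": category,
                }
            )
        rows.extend(comp_rows)
        cats = pd.Series([r["category"] for r in comp_rows])
        n = len(comp_rows)
        n_sig = int((cats != "ns").sum())
        n_large = int(cats.isin(["sig_up_large", "sig_down_large"]).sum())
        summaries.append(
            {
                "comparison": comp.label,
                "n_tested": n,
                "n_significant": n_sig,
                "pct_significant": 100.0 * n_sig / n,
                "n_large_fc": n_large,
                "pct_large_fc": 100.0 * n_large / n,
                "n_up_large": int((cats == "sig_up_large").sum()),
                "n_down_large": int((cats == "sig_down_large").sum()),
            }
        )
    columns = [
        "mirna", "comparison", "mean_a", "mean_b", "fold_change",
        "u_statistic", "p_raw", "p_adj", "category",
    ]
    return pd.DataFrame(rows, columns=columns), pd.DataFrame(summaries)
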