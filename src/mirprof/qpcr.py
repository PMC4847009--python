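"""Efficiency-corrected relative qPCR quantification and concordance checks.

Relative expression follows the efficiency-corrected ratio form of the
delta-delta-Ct method: for target assay T and reference assay R, sample s
and calibrator c,

    ratio = E_T ** (Ct_T(c) - Ct_T(s)) / E_R ** (Ct_R(c) - Ct_R(s))

with per-assay amplification efficiencies E in (1, 2] ascertained
experimentally (E = 2 recovers the textbook 2^-ddCt).  Two consumers:

* sample QC — POMC expression relative to GAPDH, calibrated against
  POMC-non-expressing PVN control punches, discards dissections that
  missed the arcuate nucleus;
* concordance — ratio-of-ratio tables from sequencing and from qPCR are
  compared cell by cell (log2 difference and direction agreement).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "CtTable",
    "relative_expression",
    "pomc_qc",
    "hts_ratio_table",
    "qpcr_ratio_table",
    "concordance",
]

#: qPCR reference assay used for miRNA quantification (U6 is size-excluded
#: from small-RNA fractions, so a stably expressed miRNA serves as reference)
DEFAULT_REFERENCE_ASSAY = "miR-124-3p"


@dataclass
class CtTable:
    """Long-form Ct measurements with per-assay efficiencies and sample metadata.

    ``data`` columns: sample, assay, ct.  ``efficiencies`` maps assay id to
    its amplification efficiency in (1, 2].  ``sample_meta`` (optional) is
    indexed by sample id with columns such as tissue, stage, diet.
    """

    data: pd.DataFrame
    efficiencies: Mapping[str, float]
    sample_meta: pd.DataFrame | None = None
    _lookup: dict[tuple[str, str], float] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        required = {"sample", "assay", "ct"}
        if not required.issubset(self.data.columns):
            raise InputError(f"Ct table needs columns {sorted(required)}")
        if (self.data["ct"] <= 0).any():
            raise InputError("Ct values must be positive")
        for assay in self.data["assay"].unique():
            eff = self.efficiencies.get(assay)
            if eff is None:
                raise ConfigurationError(f"no amplification efficiency for assay {assay}")
            if not 1.0 < eff <= 2.0:
                raise ConfigurationError(f"efficiency of {assay} must be in (1, 2]")
        self._lookup = {
            (r.sample, r.assay): float(r.ct) for r in self.data.itertuples(index=False)
        }

    def ct(self, sample: str, assay: str) -> float | None:
        return self._lookup.get((sample, assay))

    def samples(self) -> list[str]:
        return list(self.data["sample"].unique())


def relative_expression(
    ct: CtTable, target: str, reference: str, sample: str, calibrator: str
) -> float:
    """Efficiency-corrected relative expression of ``sample`` vs ``calibrator``."""
    values = {}
    for assay in (target, reference):
        for s in (sample, calibrator):
            v = ct.ct(s, assay)
            if v is None:
                raise InputError(f"missing Ct for sample {s}, assay {assay}")
            values[(s, assay)] = v
    e_t = ct.efficiencies[target]
    e_r = ct.efficiencies[reference]
    d_t = values[(calibrator, target)] - values[(sample, target)]
    d_r = values[(calibrator, reference)] - values[(sample, reference)]
    return float(e_t**d_t / e_r**d_r)


def _mean_pvn_calibrator(ct: CtTable, pvn_controls: Sequence[str], assays: Sequence[str]) -> dict:
    cal = {}
    for assay in assays:
        cts = [ct.ct(s, assay) for s in pvn_controls]
        cts = [c for c in cts if c is not None]
        if not cts:
            raise InputError(f"no PVN control carries a Ct for assay {assay}")
        cal[assay] = float(np.mean(cts))
    return cal


def pomc_qc(
    ct: CtTable,
    arc_samples: Sequence[str],
    pvn_controls: Sequence[str],
    target: str = "POMC",
    reference: str = "GAPDH",
    min_fold_over_pvn: float = 3.0,
    within_stage_outlier_fraction: float = 0.2,
) -> pd.DataFrame:
    """Keep/discard flags for dissected samples based on POMC enrichment.

    POMC expression relative to GAPDH is computed per sample with the mean
    of the PVN controls as calibrator.  Samples below ``min_fold_over_pvn``
    are discarded ("low POMC": the punch likely missed the arcuate
    nucleus); samples below ``within_stage_outlier_fraction`` times their
    stage median are additionally discarded as within-stage outliers.
    """
    if not pvn_controls:
        raise InputError("at least one PVN control is required")
    cal = _mean_pvn_calibrator(ct, pvn_controls, [target, reference])
    e_t, e_r = ct.efficiencies[target], ct.efficiencies[reference]
    rows = []
    for s in arc_samples:
        ct_t, ct_r = ct.ct(s, target), ct.ct(s, reference)
        if ct_t is None or ct_r is None:
            import warnings

            warnings.warn(f"sample {s} skipped: missing Ct")
            continue
        value = e_t ** (cal[target] - ct_t) / e_r ** (cal[reference] - ct_r)
        stage = None
        if ct.sample_meta is not None and s in ct.sample_meta.index:
            stage = ct.sample_meta.at[s, "stage"] if "stage" in ct.sample_meta else None
        rows.append({"sample": s, "pomc_rel": value, "stage": stage})
    flags = pd.DataFrame(rows).set_index("sample")
    flags["keep"] = flags["pomc_rel"] >= min_fold_over_pvn
    flags["reason"] = np.where(flags["keep"], "", "low POMC")
    if flags["stage"].notna().any():
        medians = flags.groupby("stage")["pomc_rel"].transform("median")
        outlier = flags["keep"] & (flags["pomc_rel"] < within_stage_outlier_fraction * medians)
        flags.loc[outlier, "keep"] = False
        flags.loc[outlier, "reason"] = "within-stage outlier"
    return flags[["pomc_rel", "stage", "keep", "reason"]]


def hts_ratio_table(
    stage_means: pd.DataFrame,
    mirnas: Sequence[str],
    reference_mirna: str = DEFAULT_REFERENCE_ASSAY,
    calibrator_stage: str = "P28",
) -> pd.DataFrame:
    """Sequencing-side ratio-of-ratios: (miR/ref) per stage over (miR/ref) at calibrator."""
    if reference_mirna not in stage_means.index:
        raise InputError(f"reference miRNA {reference_mirna} absent from stage means")
    rel = stage_means.loc[list(mirnas)].div(stage_means.loc[reference_mirna], axis=1)
    return rel.div(rel[calibrator_stage], axis=0)


def qpcr_ratio_table(
    ct: CtTable,
    mirnas: Sequence[str],
    samples_by_stage: Mapping[str, Sequence[str]],
    reference_assay: str = DEFAULT_REFERENCE_ASSAY,
    calibrator_stage: str = "P28",
) -> pd.DataFrame:
    """qPCR-side ratio table matching :func:`hts_ratio_table` in shape.

    Per (miRNA, stage): mean over the stage's samples of the relative
    expression against the mean-Ct virtual calibrator of the calibrator
    stage.
    """
    cal_samples = samples_by_stage[calibrator_stage]
    assays = list(mirnas) + [reference_assay]
    cal = _mean_pvn_calibrator(ct, cal_samples, assays)  # mean-Ct virtual sample
    e_r = ct.efficiencies[reference_assay]
    out = {}
    for stage, samples in samples_by_stage.items():
        col = {}
        for m in mirnas:
            e_t = ct.efficiencies[m]
            vals = []
            for s in samples:
                ct_t, ct_r = ct.ct(s, m), ct.ct(s, reference_assay)
                if ct_t is None or ct_r is None:
                    continue
                vals.append(e_t ** (cal[m] - ct_t) / e_r ** (cal[reference_assay] - ct_r))
            col[m] = float(np.mean(vals)) if vals else np.nan
        out[stage] = col
    return pd.DataFrame(out).loc[list(mirnas)]


def concordance(
    hts_ratios: pd.DataFrame, qpcr_ratios: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Cell-by-cell agreement between sequencing and qPCR ratio tables.

    Returns a long-form report (both ratios, their log2 difference, and a
    same-direction flag: both above or both below 1) plus a summary with
    concordant/discordant/missing counts.
    """
    rows = []
    missing = 0
    for mirna in hts_ratios.index:
        for stage in hts_ratios.columns:
            h = hts_ratios.at[mirna, stage]
            q = (
                qpcr_ratios.at[mirna, stage]
                if (mirna in qpcr_ratios.index and stage in qpcr_ratios.columns)
                else np.nan
            )
            if np.isnan(h) or np.isnan(q):
                missing += 1
                continue
            same = (h >= 1.0) == (q >= 1.0)
            rows.append(
                {
                    "mirna": mirna,
                    "stage": stage,
                    "hts_ratio": h,
                    "qpcr_ratio": q,
                    "log2_diff": float(np.log2(h) - np.log2(q)),
                    "same_direction": bool(same),
                }
            )
    report = pd.DataFrame(
        rows, columns=["mirna", "stage", "hts_ratio", "qpcr_ratio", "log2_diff", "same_direction"]
    )
    summary = {
        "n_cells": len(report),
        "n_concordant": int(report["same_direction"].sum()) if len(report) else 0,
        "n_discordant": int((~report["same_direction"]).sum()) if len(report) else 0,
        "n_missing": missing,
    }
    return report, summary
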