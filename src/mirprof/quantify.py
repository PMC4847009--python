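"""Alignment of inserts to the hairpin reference and isomiR-aware counting.

Inserts are aligned ungapped (substitutions only, at most two mismatches)
against every offset of every hairpin, keeping all hits in the best
(minimum-mismatch) stratum.  The reporting name follows the field's
convention for maturation variants: any 3'-end variant of a mature arm is
grouped under the canonical arm name, while a 5'-shifted variant — whose
seed region differs and which therefore targets different mRNAs — is
reported as a separate entity named ``<arm>-hairp``.  Counts of inserts
tied between several reporting names are split equally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InputError
from .readproc import InsertRecord
from .reference import MatureArm, MiRnaReference

__all__ = [
    "Alignment",
    "HairpinAligner",
    "align_to_reference",
    "classify_isomir",
    "build_count_profiles",
    "apply_efficiency_factors",
    "expression_filter",
]

_SEPARATOR = "NNN"  # longer than the mismatch allowance: windows can't span hairpins


@dataclass(frozen=True)
class Alignment:
    """An ungapped hit of an insert on a hairpin, annotated with arm shifts.

    ``shift_5p``/``shift_3p`` are signed offsets of the insert ends relative
    to the annotated mature-arm boundaries (negative = extension); they are
    None when the hit overlaps no annotated arm.
    """

    insert: str
    hairpin_id: str
    start: int
    mismatches: int
    arm: MatureArm | None
    shift_5p: int | None
    shift_3p: int | None


class HairpinAligner:
    """Reusable exhaustive Hamming aligner over a hairpin reference."""

    def __init__(self, ref: MiRnaReference, max_mismatches: int = 2):
        if max_mismatches >= len(_SEPARATOR):
            raise InputError("mismatch allowance must stay below the separator length")
        self.ref = ref
        self.max_mismatches = max_mismatches
        self._ids = list(ref.hairpins)
        concat_parts: list[str] = []
        self._starts = np.empty(len(self._ids), dtype=np.int64)
        self._ends = np.empty(len(self._ids), dtype=np.int64)
        off = 0
        for i, hid in enumerate(self._ids):
            seq = ref.hairpins[hid]
            self._starts[i] = off
            self._ends[i] = off + len(seq)
            concat_parts.append(seq)
            concat_parts.append(_SEPARATOR)
            off += len(seq) + len(_SEPARATOR)
        self._concat = "".join(concat_parts)
        self._arr = np.frombuffer(self._concat.encode("ascii"), dtype=np.uint8)
        # hairpin index owning each concat position (separators -> previous)
        self._owner = np.searchsorted(self._starts, np.arange(len(self._arr)), "right") - 1
        self._arms_by_hairpin = {hid: ref.arms_of(hid) for hid in self._ids}

    def _to_alignment(self, insert: str, pos: int, mm: int) -> Alignment:
        h = int(self._owner[pos])
        hid = self._ids[h]
        start = pos - int(self._starts[h])
        end = start + len(insert)
        arm = None
        best_overlap = 0
        for cand in self._arms_by_hairpin[hid]:
            overlap = min(end, cand.end) - max(start, cand.start)
            if overlap > best_overlap:
                best_overlap = overlap
                arm = cand
        # require the hit to cover at least half the insert with arm sequence
        if arm is None or best_overlap < math.ceil(len(insert) / 2):
            return Alignment(insert, hid, start, mm, None, None, None)
        return Alignment(insert, hid, start, mm, arm, start - arm.start, end - arm.end)

    def align(self, insert: str) -> list[Alignment]:
        """All hits in the best mismatch stratum (empty list if unmapped)."""
        L = len(insert)
        if L < 16:
            raise InputError("inserts shorter than 16 nt are not alignable")
        # exact stratum first, at C speed
        positions: list[int] = []
        start = 0
        while True:
            pos = self._concat.find(insert, start)
            if pos < 0:
                break
            positions.append(pos)
            start = pos + 1
        if positions:
            return [self._to_alignment(insert, p, 0) for p in positions]
        if self.max_mismatches == 0 or L > len(self._arr):
            return []
        ins = np.frombuffer(insert.encode("ascii"), dtype=np.uint8)
        windows = sliding_window_view(self._arr, L)
        mm = (windows != ins).sum(axis=1)
        starts = np.arange(len(mm))
        valid = (starts + L) <= self._ends[self._owner[starts]]
        mm = np.where(valid, mm, L)
        best = int(mm.min())
        if best > self.max_mismatches:
            return []
        return [self._to_alignment(insert, int(p), best) for p in np.flatnonzero(mm == best)]


def align_to_reference(
    insert: str, ref: MiRnaReference, max_mismatches: int = 2
) -> list[Alignment]:
    """One-shot alignment; builds a throwaway index (use HairpinAligner in loops)."""
    return HairpinAligner(ref, max_mismatches).align(insert)


def classify_isomir(alignment: Alignment) -> tuple[str | None, str]:
    """Reporting name and category of an aligned insert.

    5'-shift zero: canonical arm name, category ``canonical`` or
    ``isomir_3p`` (all 3' variants share the canonical name).  Any 5'-shift:
    name ``<arm>-hairp``, category ``isomir_5p``.  No overlapping arm:
    ``(None, "unknown")`` — excluded from profiles.
    """
    if alignment.arm is None:
        return None, "unknown"
    if alignment.shift_5p == 0:
        category = "canonical" if alignment.shift_3p == 0 else "isomir_3p"
        return alignment.arm.name, category
    return f"{alignment.arm.name}-hairp", "isomir_5p"


def build_count_profiles(
    records_by_library: Mapping[str, Iterable[InsertRecord]],
    ref: MiRnaReference,
    max_mismatches: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Per-library miRNA count profiles plus a mapping run report.

    Each insert's count is assigned to the reporting name of its best
    alignment(s), split equally across distinct tied names.  The report
    tallies mapped/unmapped/unknown-arm counts and isomiR category
    fractions per library.
    """
    aligner = HairpinAligner(ref, max_mismatches)
    cells: dict[str, dict[str, float]] = {}
    report: dict[str, dict] = {}
    align_cache: dict[str, list[Alignment]] = {}
    for lib, records in records_by_library.items():
        col: dict[str, float] = {}
        tally = {"mapped": 0, "unmapped": 0, "unknown_arm": 0}
        categories: dict[str, float] = {"canonical": 0.0, "isomir_3p": 0.0, "isomir_5p": 0.0}
        for rec in records:
            hits = align_cache.get(rec.sequence)
            if hits is None:
                hits = aligner.align(rec.sequence)
                align_cache[rec.sequence] = hits
            if not hits:
                tally["unmapped"] += rec.count
                continue
            named = {}
            for h in hits:
                name, category = classify_isomir(h)
                if name is not None:
                    named[name] = category
            if not named:
                tally["unknown_arm"] += rec.count
                continue
            tally["mapped"] += rec.count
            share = rec.count / len(named)
            for name, category in named.items():
                col[name] = col.get(name, 0.0) + share
                categories[category] += share
        cells[lib] = col
        total_mapped = max(tally["mapped"], 1)
        report[lib] = {
            **tally,
            "category_fractions": {k: v / total_mapped for k, v in categories.items()},
        }
    profile = pd.DataFrame(cells).fillna(0.0)
    profile = profile.loc[sorted(profile.index), list(records_by_library)]
    return profile, report


def apply_efficiency_factors(
    profile: pd.DataFrame,
    controls: pd.DataFrame,
    min_count: float = 20.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Correct per-miRNA protocol bias using a pair of control libraries.

    ``controls`` has two columns, (reference protocol, variant protocol),
    quantified from the same RNA.  The factor ``f = variant / reference`` is
    computed only where both counts are at least ``min_count``; elsewhere
    ``f = 1``.  Corrected counts are ``raw / f``.
    """
    if controls.shape[1] != 2:
        raise InputError("controls must have exactly two columns (reference, variant)")
    ref_col = controls.iloc[:, 0]
    var_col = controls.iloc[:, 1]
    defined = (ref_col >= min_count) & (var_col >= min_count)
    if not defined.any():
        warnings.warn("control libraries share no miRNA above min_count; all factors = 1")
    factors = pd.Series(1.0, index=controls.index)
    factors[defined] = var_col[defined] / ref_col[defined]
    factors = factors.reindex(profile.index).fillna(1.0)
    return profile.div(factors, axis=0), factors


def expression_filter(stage_means: pd.DataFrame, threshold: float = 10.0) -> pd.Index:
    """miRNAs strictly above ``threshold`` in at least one stage mean."""
    keep = (stage_means > threshold).any(axis=1)
    return stage_means.index[keep]
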