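"""Demultiplexing, adaptor trimming and unique-sequence collapsing.

Pooled reads carry their library identity as an 11-nt barcode forming the
first eleven bases of the 3' adaptor (the constant adaptor tail follows the
barcode).  Demultiplexing therefore looks for ``barcode + tail`` occurrences;
a candidate match is scored by its total mismatches over the barcode plus
the visible tail bases, and the best (fewest-mismatch, then leftmost) match
decides the library.  Reads matching no barcode within the allowance, or
with two barcodes tied at the same position, are routed to the unassigned
stream.

Trimming removes the leftmost best occurrence of the library's full adaptor
prefix (minimum overlap 8, mismatch rate <= 10%, terminal partial overlaps
allowed); collapsing groups identical inserts with counts after discarding
inserts shorter than 16 nt.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConfigurationError, InputError

__all__ = [
    "SequencedRead",
    "InsertRecord",
    "read_fastq",
    "write_fastq",
    "demultiplex",
    "trim_adaptor",
    "collapse_and_filter",
]

_ALPHABET = re.compile(r"^[ACGTN]*$")

BARCODE_LENGTH = 11
MIN_BARCODE_OVERLAP = 8  # terminal partial barcode matches need this many bases


@dataclass(frozen=True)
class SequencedRead:
    """A single read: id, sequence (ACGTN) and per-base quality string."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise InputError(f"sequence/quality length mismatch for read {self.id}")
        if not _ALPHABET.match(self.sequence):
            raise InputError(f"read {self.id} contains characters outside ACGTN")


@dataclass(frozen=True)
class InsertRecord:
    """A unique insert sequence with its read count within one library."""

    sequence: str
    count: int
    library: str | None = None


def read_fastq(path: str | Path) -> Iterator[SequencedRead]:
    """Stream reads from a 4-line-record FASTQ file."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield SequencedRead(id=title.split()[0], sequence=seq.upper(), quality=qual)


def write_fastq(reads: Iterable[SequencedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


# --------------------------------------------------------------------------
# matching primitives
# --------------------------------------------------------------------------

def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming mismatches between equal-length strings, early abort past limit.

    N never matches anything, including another N.
    """
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def _best_adaptor_match(
    seq: str, adaptor: str, min_overlap: int, max_mismatch_rate: float
) -> tuple[int, int] | None:
    """Best (mismatches, position) of an adaptor-prefix occurrence, or None.

    A candidate at position ``pos`` spans ``overlap = min(len(adaptor),
    len(seq) - pos)`` bases (terminal partial overlaps allowed) and
    qualifies when ``overlap >= min_overlap`` and its mismatch count is at
    most ``floor(max_mismatch_rate * overlap)``.  Among qualifying
    candidates the fewest mismatches win; ties break leftmost.
    """
    n = len(seq)
    # fast path: leftmost exact occurrence, found with C-speed str.find
    probe = adaptor[: min(min_overlap, len(adaptor))]
    start = 0
    while True:
        pos = seq.find(probe, start)
        if pos < 0:
            break
        overlap = min(len(adaptor), n - pos)
        if seq[pos : pos + overlap] == adaptor[:overlap]:
            return (0, pos)
        start = pos + 1
    best: tuple[int, int] | None = None
    for pos in range(0, n - min_overlap + 1):
        overlap = min(len(adaptor), n - pos)
        limit = int(max_mismatch_rate * overlap)
        mm = _mismatches(seq[pos : pos + overlap], adaptor[:overlap], limit)
        if mm <= limit and (best is None or mm < best[0]):
            best = (mm, pos)
            if mm == 0:
                break
    return best


# --------------------------------------------------------------------------
# demultiplexing
# --------------------------------------------------------------------------

def _validate_barcodes(barcode_table: dict[str, str], max_mismatch: int) -> None:
    for lib, bc in barcode_table.items():
        if len(bc) != BARCODE_LENGTH:
            raise ConfigurationError(f"barcode of {lib} is not {BARCODE_LENGTH} nt")
        if not _ALPHABET.match(bc) or "N" in bc:
            raise ConfigurationError(f"barcode of {lib} contains invalid characters")
    items = list(barcode_table.items())
    for i, (lib_a, a) in enumerate(items):
        for lib_b, b in items[i + 1 :]:
            dist = sum(x != y for x, y in zip(a, b))
            if dist <= 2 * max_mismatch:
                raise ConfigurationError(
                    f"barcodes {lib_a}/{lib_b} at Hamming distance {dist} <= "
                    f"2*max_mismatch={2 * max_mismatch}"
                )


def _barcode_candidates(
    seq: str,
    barcode_table: dict[str, str],
    anchor: str,
    max_mismatch: int,
    anchor_mismatch_rate: float,
    exact_only: bool,
) -> list[tuple[int, int, str]]:
    """(total mismatches, position, library) for qualifying barcode matches.

    The full barcode must be visible; visible anchor (tail) bases following
    it must match within ``anchor_mismatch_rate``.
    """
    n = len(seq)
    out: list[tuple[int, int, str]] = []
    for lib, bc in barcode_table.items():
        if exact_only:
            positions: list[tuple[int, int]] = []
            start = 0
            while True:
                pos = seq.find(bc, start)
                if pos < 0:
                    break
                positions.append((pos, 0))
                start = pos + 1
            # terminal partial occurrences (barcode running off the read end)
            for pos in range(max(0, n - BARCODE_LENGTH + 1), n - MIN_BARCODE_OVERLAP + 1):
                if seq[pos:] == bc[: n - pos]:
                    positions.append((pos, 0))
        else:
            positions = []
            for pos in range(0, n - MIN_BARCODE_OVERLAP + 1):
                visible_bc = min(BARCODE_LENGTH, n - pos)
                mm = _mismatches(seq[pos : pos + visible_bc], bc[:visible_bc], max_mismatch)
                if mm <= max_mismatch:
                    positions.append((pos, mm))
        for pos, bc_mm in positions:
            tail_start = pos + BARCODE_LENGTH
            visible = min(len(anchor), max(0, n - tail_start))
            limit = int(anchor_mismatch_rate * visible)
            a_mm = _mismatches(seq[tail_start : tail_start + visible], anchor[:visible], limit)
            if a_mm <= limit:
                out.append((bc_mm + a_mm, pos, lib))
    return out


def demultiplex(
    reads: Iterable[SequencedRead],
    barcode_table: dict[str, str],
    adaptor_anchor: str,
    max_mismatch: int = 1,
    anchor_mismatch_rate: float = 0.1,
) -> tuple[dict[str, list[SequencedRead]], list[SequencedRead]]:
    """Assign each read to the library whose barcode best matches its adaptor.

    Returns ``(per-library read lists, unassigned reads)``.  Assignment is a
    pure function of each read, hence order-independent.  Barcodes must be
    pairwise more than ``2 * max_mismatch`` apart (configuration error
    otherwise), so two barcodes can never tie at the same position on an
    error-free read.  A barcode truncated by the read end still matches
    when at least 8 of its bases are visible.
    """
    _validate_barcodes(barcode_table, max_mismatch)
    assigned: dict[str, list[SequencedRead]] = {lib: [] for lib in barcode_table}
    unassigned: list[SequencedRead] = []
    for read in reads:
        seq = read.sequence
        cands = _barcode_candidates(
            seq, barcode_table, adaptor_anchor, max_mismatch, anchor_mismatch_rate, True
        )
        if not any(c[0] == 0 for c in cands):
            cands = _barcode_candidates(
                seq, barcode_table, adaptor_anchor, max_mismatch, anchor_mismatch_rate, False
            )
        if not cands:
            unassigned.append(read)
            continue
        cands.sort(key=lambda c: (c[0], c[1], c[2]))
        total, pos, lib = cands[0]
        tied = {c[2] for c in cands if c[0] == total and c[1] == pos}
        if len(tied) > 1:
            unassigned.append(read)
        else:
            assigned[lib].append(read)
    return assigned, unassigned


# --------------------------------------------------------------------------
# trimming and collapsing
# --------------------------------------------------------------------------

def trim_adaptor(
    read: SequencedRead | str,
    adaptor: str,
    min_overlap: int = 8,
    max_mismatch_rate: float = 0.1,
) -> str | None:
    """Insert preceding the best adaptor-prefix occurrence, or None.

    Terminal partial overlaps (an adaptor prefix running off the read end)
    count when at least ``min_overlap`` bases are visible.  Returns the
    read prefix before the match; None when the adaptor is not found.
    """
    if len(adaptor) < min_overlap:
        raise ConfigurationError("adaptor shorter than min_overlap")
    seq = read.sequence if isinstance(read, SequencedRead) else read
    hit = _best_adaptor_match(seq, adaptor, min_overlap, max_mismatch_rate)
    if hit is None:
        return None
    return seq[: hit[1]]


def collapse_and_filter(
    inserts: Iterable[str], min_len: int = 16, library: str | None = None
) -> list[InsertRecord]:
    """Group inserts of one library into unique sequences with counts.

    Inserts shorter than ``min_len`` are discarded (a 16-nt insert is
    retained).  Output is ordered by descending count, then lexicographic
    sequence, so it is deterministic.
    """
    counter = Counter(s for s in inserts if len(s) >= min_len)
    records = [
        InsertRecord(sequence=s, count=c, library=library)
        for s, c in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return records


def write_insert_table(records: Iterable[InsertRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for r in records:
            fh.write(f"{r.sequence}\t{r.count}\n")
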