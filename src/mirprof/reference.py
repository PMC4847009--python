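"""miRBase-style reference: hairpin sequences with annotated mature arms.

A reference is the alignment target for insert sequences: a set of hairpin
(pre-miRNA) sequences, each carrying one or two annotated mature arms
(5p and/or 3p) given as 0-based half-open intervals on the hairpin
(+ strand only).  Arms may be grouped into families sharing the seed region
(bases 2-8 of the mature sequence).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

__all__ = ["MatureArm", "MiRnaReference"]


@dataclass(frozen=True)
class MatureArm:
    """An annotated mature miRNA on its hairpin (0-based half-open interval)."""

    name: str
    hairpin_id: str
    start: int
    end: int
    arm: str  # "5p" or "3p"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise InputError(f"invalid arm interval for {self.name}: [{self.start}, {self.end})")
        if self.arm not in ("5p", "3p"):
            raise InputError(f"arm must be '5p' or '3p', got {self.arm!r}")


@dataclass
class MiRnaReference:
    """Hairpin sequences plus mature-arm annotation and family structure."""

    hairpins: dict[str, str]
    arms: list[MatureArm]
    families: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a in self.arms:
            if a.hairpin_id not in self.hairpins:
                raise InputError(f"arm {a.name} references unknown hairpin {a.hairpin_id}")
            if a.end > len(self.hairpins[a.hairpin_id]):
                raise InputError(f"arm {a.name} extends past its hairpin")
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise InputError("duplicate mature-arm names in reference")

    @property
    def arm_names(self) -> list[str]:
        return [a.name for a in self.arms]

    def arm_sequence(self, arm: MatureArm) -> str:
        return self.hairpins[arm.hairpin_id][arm.start:arm.end]

    def arms_of(self, hairpin_id: str) -> list[MatureArm]:
        return [a for a in self.arms if a.hairpin_id == hairpin_id]

    # ------------------------------------------------------------------ IO
    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=hid, description="")
            for hid, seq in self.hairpins.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_arm_table(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["hairpin_id", "arm_name", "arm", "start", "end"])
            for a in self.arms:
                w.writerow([a.hairpin_id, a.name, a.arm, a.start, a.end])

    @classmethod
    def read(cls, fasta: str | Path, arm_table: str | Path) -> "MiRnaReference":
        hairpins = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        arms: list[MatureArm] = []
        with open(arm_table) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                arms.append(
                    MatureArm(
                        name=row["arm_name"],
                        hairpin_id=row["hairpin_id"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        arm=row["arm"],
                    )
                )
        return cls(hairpins=hairpins, arms=arms)
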