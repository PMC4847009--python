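"""Shared in-memory containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import InputError

__all__ = ["CountMatrix"]

#: metadata columns every library carries
METADATA_COLUMNS = ("stage", "diet", "litter")


@dataclass
class CountMatrix:
    """miRNA x library table of non-negative counts with per-library metadata.

    ``counts`` has miRNA reporting-names as the row index and library ids as
    columns; ``metadata`` is indexed by library id with columns
    ``stage``, ``diet`` and ``litter``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.metadata.index):
            raise InputError("count columns and metadata index must match in order")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("counts must be non-negative")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise InputError(f"metadata missing columns: {missing}")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def stage_of(self) -> pd.Series:
        return self.metadata["stage"]

    # ------------------------------------------------------------------ IO
    def write_tsv(self, counts_path: str | Path, metadata_path: str | Path) -> None:
        self.counts.rename_axis("mirna").to_csv(counts_path, sep="\t")
        self.metadata.rename_axis("library").to_csv(metadata_path, sep="\t")

    @classmethod
    def read_tsv(cls, counts_path: str | Path, metadata_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, comment="#")
        return cls(counts=counts, metadata=metadata.loc[counts.columns])
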