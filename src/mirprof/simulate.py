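"""Synthetic small RNA-seq data: reference, expression, reads and qPCR tables.

This module generates a toy miRBase-like hairpin reference, stage-structured
true expression with planted fold changes, barcoded FASTQ reads and qPCR Ct
tables, so every downstream pipeline stage can be exercised without any
external download.

The generative model
--------------------
Per-miRNA baseline abundance is lognormal (median 500, sigma 1.5 on the
natural-log scale), producing the heavy-tailed abundance spectrum typical of
small-RNA libraries.  Stage effects are multiplicative fold changes planted
on a configurable fraction of miRNAs between chosen stage pairs, with the
direction (up or down) drawn per miRNA.  Each miRNA additionally carries a
lognormal ligation-bias factor that is *identical in every library* —
adaptor-ligation bias is a property of the sequence, reproducible between
libraries, so it cancels from between-library comparisons.  Biological
between-replicate variability is a per-library lognormal factor
(``replicate_noise_sd``).  Library counts are a single multinomial draw of
``reads_per_library`` reads over the bias-weighted expected abundances, so
column sums are exact.

Reads are the (possibly end-shifted) mature sequence followed by the
library's 3' adaptor, whose first eleven bases are the library barcode,
truncated to the read length.  Sequencing errors are i.i.d. substitutions.

A "heterogeneous stage" flag mixes two expression regimes among the
replicates of one stage (e.g. 4 replicates from regime A and 2 from a
shifted regime B) to create a discoverable homogeneous sub-stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .errors import ConfigurationError, InputError
from .reference import MatureArm, MiRnaReference

__all__ = [
    "SimulationConfig",
    "TrueState",
    "PlantedEffect",
    "generate_reference",
    "generate_barcodes",
    "simulate_expression_matrix",
    "synthesize_reads",
    "pool_fastqs",
    "simulate_qpcr",
]

BASES = "ACGT"

#: constant part of the 3' adaptor following the 11-nt library barcode
DEFAULT_ADAPTOR_TAIL = "TGGAATTCTCGGGTGCCAAGG"

#: study design: replicates retained per postnatal stage
DEFAULT_REPLICATES = {"P4": 4, "P8": 6, "P14": 6, "P21": 7, "P28": 6}

BARCODE_LENGTH = 11


@dataclass(frozen=True)
class PlantedEffect:
    """A planted differential-expression effect between two stages."""

    stage_a: str
    stage_b: str
    fraction: float
    fold: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigurationError("planted fraction must be in [0, 1]")
        if self.fold <= 0:
            raise ConfigurationError("planted fold must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Defaults describe a desk-scale version of the study design: five
    postnatal stages with 4-7 replicates each, three litters per stage,
    5e4 reads per library (the depth is a scale knob, not a claim), and
    isomiR end-heterogeneity at canonical/3'-shift/5'-shift fractions
    0.60/0.25/0.15.
    """

    n_hairpins: int = 50
    family_sizes: tuple[int, ...] = ()
    mature_length_range: tuple[int, int] = (20, 24)
    two_arm_probability: float = 0.5
    stages: tuple[str, ...] = ("P4", "P8", "P14", "P21", "P28")
    replicates_per_stage: Mapping[str, int] | int = field(
        default_factory=lambda: dict(DEFAULT_REPLICATES)
    )
    litters_per_stage: int = 3
    diets: tuple[str, ...] = ("C",)
    planted_de: tuple[PlantedEffect, ...] = ()
    reads_per_library: int = 50_000
    isomir_fractions: tuple[float, float, float] = (0.60, 0.25, 0.15)
    shift_magnitude_probs: tuple[float, float] = (0.7, 0.3)  # P(|shift|=1), P(|shift|=2)
    per_base_error_rate: float = 0.002
    ligation_bias_sd: float = 1.0
    replicate_noise_sd: float = 0.30
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 1.5
    read_length: int = 36
    adaptor_tail: str = DEFAULT_ADAPTOR_TAIL
    barcode_table: Mapping[str, str] | None = None
    heterogeneous_stage: str | None = None
    heterogeneous_n_outliers: int = 2
    heterogeneous_fraction: float = 0.30
    heterogeneous_fold: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hairpins <= 0:
            raise ConfigurationError("n_hairpins must be positive")
        if sum(self.family_sizes) > self.n_hairpins:
            raise ConfigurationError("family sizes exceed n_hairpins")
        if any(s < 2 for s in self.family_sizes):
            raise ConfigurationError("family sizes must be >= 2")
        lo, hi = self.mature_length_range
        if not (16 <= lo <= hi):
            raise ConfigurationError("mature_length_range must satisfy 16 <= lo <= hi")
        if self.reads_per_library <= 0:
            raise ConfigurationError("reads_per_library must be positive")
        fr = self.isomir_fractions
        if any(not 0.0 <= p <= 1.0 for p in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ConfigurationError("isomir_fractions must be probabilities summing to 1")
        if abs(sum(self.shift_magnitude_probs) - 1.0) > 1e-9:
            raise ConfigurationError("shift_magnitude_probs must sum to 1")
        if not 0.0 <= self.two_arm_probability <= 1.0:
            raise ConfigurationError("two_arm_probability must be in [0, 1]")
        if not 0.0 <= self.per_base_error_rate <= 1.0:
            raise ConfigurationError("per_base_error_rate must be in [0, 1]")
        if hi + BARCODE_LENGTH > self.read_length:
            raise ConfigurationError(
                "mature length plus the 11-nt barcode must fit in the read length"
            )
        if self.heterogeneous_stage is not None and self.heterogeneous_stage not in self.stages:
            raise ConfigurationError("heterogeneous_stage must be one of the stages")
        for eff in self.planted_de:
            if eff.stage_a not in self.stages or eff.stage_b not in self.stages:
                raise ConfigurationError("planted effect references unknown stage")

    def replicates_for(self, stage: str) -> int:
        if isinstance(self.replicates_per_stage, int):
            return self.replicates_per_stage
        return self.replicates_per_stage[stage]


@dataclass
class TrueState:
    """Ground truth recorded by the generator for downstream evaluation."""

    baseline: pd.Series
    ligation_bias: pd.Series
    planted_fold_changes: dict[tuple[str, tuple[str, str]], float]
    expected_counts: pd.DataFrame
    homogeneous_members: list[str] | None = None

    def planted_mirnas(self, stage_a: str, stage_b: str) -> dict[str, float]:
        """Fold changes (stage_b relative to stage_a) of the planted miRNAs."""
        key = (stage_a, stage_b)
        return {m: f for (m, pair), f in self.planted_fold_changes.items() if pair == key}

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            {"mirna": m, "stage_a": a, "stage_b": b, "fold": f}
            for (m, (a, b)), f in sorted(self.planted_fold_changes.items())
        ]
        pd.DataFrame(rows, columns=["mirna", "stage_a", "stage_b", "fold"]).to_csv(
            path, sep="\t", index=False
        )


# --------------------------------------------------------------------------
# reference generation
# --------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def generate_reference(config: SimulationConfig) -> MiRnaReference:
    """Generate a toy miRBase-like reference, deterministic given the seed.

    Every hairpin carries an annotated 5p arm and, with probability 1/2, a
    3p arm as well.  Declared families share bases 2-8 (the seed region) of
    their 5p arm and differ at at least one downstream internal base.  All
    mature sequences are unique across the reference, and no mature
    sequence occurs anywhere else in any hairpin, so exact alignment is
    unambiguous by construction.
    """
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.mature_length_range
    self_p = config.two_arm_probability

    # map hairpin index -> family id (families fill the first hairpins)
    family_of: dict[int, int] = {}
    idx = 0
    for fam_id, size in enumerate(config.family_sizes):
        for _ in range(size):
            family_of[idx] = fam_id
            idx += 1
    family_seed: dict[int, str] = {
        fam_id: _random_seq(rng, 7) for fam_id in range(len(config.family_sizes))
    }

    hairpins: dict[str, str] = {}
    arms: list[MatureArm] = []
    families: dict[str, list[str]] = {
        f"fam-{j + 1}": [] for j in range(len(config.family_sizes))
    }
    seen_arms: set[str] = set()
    fam_downstream: dict[int, list[str]] = {j: [] for j in range(len(config.family_sizes))}

    for i in range(config.n_hairpins):
        hid = f"hp-{i + 1}"
        for _attempt in range(200):
            arm5_len = int(rng.integers(lo, hi + 1))
            arm5 = _random_seq(rng, arm5_len)
            fam = family_of.get(i)
            if fam is not None:
                arm5 = arm5[0] + family_seed[fam] + arm5[8:]
                downstream = arm5[8:]
                if downstream in fam_downstream[fam]:
                    continue  # must differ at >=1 internal base downstream of the seed
            has_3p = (rng.random() < self_p) if fam is None else False
            loop = _random_seq(rng, 10)
            flank5 = _random_seq(rng, 3)
            if has_3p:
                arm3_len = int(rng.integers(lo, hi + 1))
                arm3 = _random_seq(rng, arm3_len)
                seq = flank5 + arm5 + loop + arm3 + _random_seq(rng, 6)
            else:
                arm3 = None
                seq = flank5 + arm5 + loop + _random_seq(rng, 6)
            new_arms = [arm5] + ([arm3] if arm3 else [])
            if any(a in seen_arms for a in new_arms):
                continue
            # mature sequences must not occur anywhere else in the reference
            if any(a in other for a in new_arms for other in hairpins.values()):
                continue
            if any(prev in seq for prev in seen_arms):
                continue
            hairpins[hid] = seq
            start5 = len(flank5)
            arms.append(MatureArm(f"miR-{i + 1}-5p", hid, start5, start5 + len(arm5), "5p"))
            if arm3:
                start3 = start5 + len(arm5) + len(loop)
                arms.append(MatureArm(f"miR-{i + 1}-3p", hid, start3, start3 + len(arm3), "3p"))
            seen_arms.update(new_arms)
            if fam is not None:
                families[f"fam-{fam + 1}"].append(f"miR-{i + 1}-5p")
                fam_downstream[fam].append(arm5[8:])
            break
        else:  # pragma: no cover - astronomically unlikely
            raise ConfigurationError(f"could not generate a unique hairpin for {hid}")

    return MiRnaReference(hairpins=hairpins, arms=arms, families=families)


# --------------------------------------------------------------------------
# expression and counts
# --------------------------------------------------------------------------

def _library_design(config: SimulationConfig) -> pd.DataFrame:
    """Library ids with stage, diet and round-robin litter assignment."""
    rows = []
    for diet in config.diets:
        for stage in config.stages:
            for k in range(config.replicates_for(stage)):
                lib = f"{stage}-{diet}-r{k + 1}"
                litter = f"{stage}-{diet}-L{k % config.litters_per_stage + 1}"
                rows.append({"library": lib, "stage": stage, "diet": diet, "litter": litter})
    return pd.DataFrame(rows).set_index("library")


def simulate_expression_matrix(
    ref: MiRnaReference, config: SimulationConfig
) -> tuple[CountMatrix, TrueState]:
    """Draw per-library counts from the stage-structured generative model.

    Column sums equal ``reads_per_library`` exactly (one multinomial draw per
    library).  Planted fold changes are applied from ``stage_b`` onward in
    stage order, so adjacent-pair effects compose along the time course.
    """
    mirnas = ref.arm_names
    n = len(mirnas)
    meta = _library_design(config)

    rng = np.random.default_rng([config.seed, 10])
    baseline = pd.Series(
        rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n), index=mirnas
    )
    bias = pd.Series(rng.lognormal(0.0, config.ligation_bias_sd, n), index=mirnas)

    stage_mult = pd.DataFrame(1.0, index=mirnas, columns=list(config.stages))
    planted: dict[tuple[str, tuple[str, str]], float] = {}
    stage_order = list(config.stages)
    for eff in config.planted_de:
        k = int(round(eff.fraction * n))
        chosen = rng.choice(n, size=k, replace=False)
        direction = rng.choice([eff.fold, 1.0 / eff.fold], size=k)
        onset = stage_order.index(eff.stage_b)
        for ci, f in zip(chosen, direction):
            planted[(mirnas[ci], (eff.stage_a, eff.stage_b))] = float(f)
            for s in stage_order[onset:]:
                stage_mult.loc[mirnas[ci], s] *= f

    # heterogeneous-stage scenario: the last n_outliers replicates of one
    # stage follow a shifted regime B on a fraction of miRNAs
    outlier_mult = np.ones(n)
    if config.heterogeneous_stage is not None:
        k = int(round(config.heterogeneous_fraction * n))
        chosen = rng.choice(n, size=k, replace=False)
        direction = rng.choice([config.heterogeneous_fold, 1.0 / config.heterogeneous_fold], size=k)
        outlier_mult[chosen] = direction

    counts = {}
    expected = {}
    homogeneous: list[str] = []
    for j, (lib, row) in enumerate(meta.iterrows()):
        lib_rng = np.random.default_rng([config.seed, 11, j])
        expr = baseline.to_numpy() * stage_mult[row["stage"]].to_numpy()
        is_outlier = False
        if row["stage"] == config.heterogeneous_stage:
            n_rep = config.replicates_for(row["stage"])
            rep_idx = int(lib.rsplit("-r", 1)[1])
            is_outlier = rep_idx > n_rep - config.heterogeneous_n_outliers
            if is_outlier:
                expr = expr * outlier_mult
            else:
                homogeneous.append(lib)
        if config.replicate_noise_sd > 0:
            expr = expr * lib_rng.lognormal(0.0, config.replicate_noise_sd, n)
        weights = expr * bias.to_numpy()
        p = weights / weights.sum()
        counts[lib] = lib_rng.multinomial(config.reads_per_library, p)
        expected[lib] = config.reads_per_library * p

    counts_df = pd.DataFrame(counts, index=mirnas, columns=meta.index)
    truth = TrueState(
        baseline=baseline,
        ligation_bias=bias,
        planted_fold_changes=planted,
        expected_counts=pd.DataFrame(expected, index=mirnas, columns=meta.index),
        homogeneous_members=homogeneous or None,
    )
    return CountMatrix(counts=counts_df, metadata=meta), truth


# --------------------------------------------------------------------------
# read synthesis
# --------------------------------------------------------------------------

def generate_barcodes(
    n: int,
    rng: np.random.Generator,
    length: int = BARCODE_LENGTH,
    min_distance: int = 5,
) -> list[str]:
    """Random barcodes with pairwise Hamming distance >= ``min_distance``."""
    barcodes: list[str] = []
    for _ in range(10_000):
        cand = _random_seq(rng, length)
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_distance for bc in barcodes):
            barcodes.append(cand)
            if len(barcodes) == n:
                return barcodes
    raise ConfigurationError(f"could not generate {n} barcodes at distance {min_distance}")


def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    chars = list(seq)
    for pos in positions:
        old = chars[pos]
        alternatives = [b for b in BASES if b != old]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def synthesize_reads(
    counts: CountMatrix,
    ref: MiRnaReference,
    config: SimulationConfig,
    outdir: str | Path,
) -> tuple[dict[str, Path], dict[str, str]]:
    """Write one FASTQ per library; returns (paths, barcode table).

    Each read is the (possibly end-shifted) mature sequence followed by
    ``barcode + adaptor_tail``, truncated to ``read_length``; substitution
    errors are applied at ``per_base_error_rate``; quality is constant 'I'.
    Before error injection, per-miRNA read counts equal the count matrix.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    libs = counts.libraries
    if config.barcode_table is not None:
        missing = [lib for lib in libs if lib not in config.barcode_table]
        if missing:
            raise ConfigurationError(f"no barcode assigned to libraries: {missing}")
        barcode_table = {lib: config.barcode_table[lib] for lib in libs}
    else:
        bc_rng = np.random.default_rng([config.seed, 20])
        barcode_table = dict(zip(libs, generate_barcodes(len(libs), bc_rng)))

    arms = {a.name: a for a in ref.arms}
    p_can, p_3p, p_5p = config.isomir_fractions
    mag_p = config.shift_magnitude_probs
    paths: dict[str, Path] = {}

    for j, lib in enumerate(libs):
        rng = np.random.default_rng([config.seed, 12, j])
        adaptor = barcode_table[lib] + config.adaptor_tail
        path = outdir / f"{lib}.fastq"
        serial = 0
        with open(path, "w") as fh:
            for mirna, c in counts.counts[lib].items():
                c = int(c)
                if c == 0:
                    continue
                arm = arms[mirna]
                hp = ref.hairpins[arm.hairpin_id]
                n_can, n_3, n_5 = rng.multinomial(c, [p_can, p_3p, p_5p])
                for category, n_reads in (("can", n_can), ("3p", n_3), ("5p", n_5)):
                    for _ in range(n_reads):
                        start, end = arm.start, arm.end
                        if category != "can":
                            mag = 1 if rng.random() < mag_p[0] else 2
                            shift = mag if rng.random() < 0.5 else -mag
                            if category == "3p":
                                end = min(max(end + shift, start + 16), len(hp))
                            else:
                                start = max(min(start + shift, end - 16), 0)
                        insert = hp[start:end]
                        read = (insert + adaptor)[: config.read_length]
                        if config.per_base_error_rate > 0:
                            hits = np.flatnonzero(
                                rng.random(len(read)) < config.per_base_error_rate
                            )
                            if hits.size:
                                read = _mutate(read, hits, rng)
                        serial += 1
                        fh.write(f"@{lib}.{serial}\n{read}\n+\n{'I' * len(read)}\n")
        paths[lib] = path
    return paths, barcode_table


def pool_fastqs(paths: Sequence[str | Path], out: str | Path) -> Path:
    """Concatenate per-library FASTQ files into one pooled file."""
    out = Path(out)
    with open(out, "w") as dst:
        for p in paths:
            dst.write(Path(p).read_text())
    return out


# --------------------------------------------------------------------------
# qPCR simulation
# --------------------------------------------------------------------------

def simulate_qpcr(
    expressions: pd.DataFrame,
    efficiencies: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 35.0,
) -> pd.DataFrame:
    """Simulate Ct values: ``Ct = intercept - log_E(expression) + noise``.

    ``expressions`` is assay x sample (positive); returns a long-form table
    with columns (sample, assay, ct).
    """
    for assay in expressions.index:
        if assay not in efficiencies:
            raise ConfigurationError(f"no efficiency for assay {assay}")
        if not 1.0 < efficiencies[assay] <= 2.0:
            raise ConfigurationError(f"efficiency of {assay} must be in (1, 2]")
    if (expressions.to_numpy() <= 0).any():
        raise InputError("expressions must be positive")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for assay in expressions.index:
        log_e = math.log(efficiencies[assay])
        for sample in expressions.columns:
            ct = intercept - math.log(expressions.at[assay, sample]) / log_e
            if noise_sd > 0:
                ct += rng.normal(0.0, noise_sd)
            rows.append({"sample": sample, "assay": assay, "ct": ct})
    return pd.DataFrame(rows, columns=["sample", "assay", "ct"])
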