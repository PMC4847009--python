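"""End-to-end orchestration: simulate -> process -> quantify -> normalize ->
homogeneity -> differential expression, from one configuration mapping.

Every stage reads and writes plain-text artifacts inside a run directory,
so any stage can be skipped when its inputs are provided externally.  All
randomness flows from the single master seed in the configuration; every
output table carries a header comment recording the seed and a hash of the
configuration, and a manifest records parameters and file checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import diffexp, homogeneity, normalize, quantify, readproc, simulate
from .containers import CountMatrix
from .errors import MirprofError

__all__ = ["load_config", "run_pipeline", "summarize", "PipelineStageError"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulation": {},
    "read_processing": {"max_mismatch": 1, "min_overlap": 8, "max_mismatch_rate": 0.1,
                        "min_len": 16},
    "quantification": {"max_mismatches": 2},
    "filter": {"threshold": 10.0},
    "homogeneity": {"window": 50, "min_size": 4, "accept_cv": 0.35, "improvement": 0.75},
    "diffexp": {"alpha": 0.05, "fc_threshold": 3.0},
}


class PipelineStageError(MirprofError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _merged(config: Mapping[str, Any] | None) -> dict[str, Any]:
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in (config or {}).items():
        if isinstance(value, Mapping) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML run configuration, filling defaults per module block."""
    with open(path) as fh:
        return _merged(yaml.safe_load(fh) or {})


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> Path:
    """Execute all stages in dependency order; returns the run directory.

    Any stage failure is re-raised as :class:`PipelineStageError` naming
    the stage.
    """
    config = _merged(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"seed={config['seed']} config={_config_hash(config)}"
    stage = "configure"
    try:
        sim_block = dict(config["simulation"])
        if "planted_de" in sim_block:  # YAML carries plain mappings
            sim_block["planted_de"] = tuple(
                eff if isinstance(eff, simulate.PlantedEffect)
                else simulate.PlantedEffect(**eff)
                for eff in sim_block["planted_de"]
            )
        sim_cfg = simulate.SimulationConfig(seed=config["seed"], **sim_block)

        stage = "simulate"
        ref = simulate.generate_reference(sim_cfg)
        ref.write_fasta(outdir / "reference.fasta")
        ref.write_arm_table(outdir / "arms.tsv")
        counts, truth = simulate.simulate_expression_matrix(ref, sim_cfg)
        counts.write_tsv(outdir / "true_counts.tsv", outdir / "metadata.tsv")
        truth.write_tsv(outdir / "planted_effects.tsv")
        reads_dir = outdir / "reads"
        paths, barcodes = simulate.synthesize_reads(counts, ref, sim_cfg, reads_dir)
        pd.Series(barcodes, name="barcode").rename_axis("library").to_csv(
            outdir / "barcodes.tsv", sep="\t"
        )
        pooled = simulate.pool_fastqs(list(paths.values()), outdir / "pooled.fastq")

        stage = "demultiplex"
        rp = config["read_processing"]
        assigned, unassigned = readproc.demultiplex(
            readproc.read_fastq(pooled),
            barcodes,
            sim_cfg.adaptor_tail,
            max_mismatch=rp["max_mismatch"],
        )

        stage = "trim+collapse"
        records = {}
        for lib, lib_reads in assigned.items():
            adaptor = barcodes[lib] + sim_cfg.adaptor_tail
            inserts = []
            for r in lib_reads:
                ins = readproc.trim_adaptor(
                    r, adaptor, min_overlap=rp["min_overlap"],
                    max_mismatch_rate=rp["max_mismatch_rate"],
                )
                if ins is not None:
                    inserts.append(ins)
            records[lib] = readproc.collapse_and_filter(
                inserts, min_len=rp["min_len"], library=lib
            )

        stage = "quantify"
        profile, run_report = quantify.build_count_profiles(
            records, ref, max_mismatches=config["quantification"]["max_mismatches"]
        )
        run_report["unassigned_reads"] = len(unassigned)
        profile = profile.reindex(columns=counts.libraries, fill_value=0.0)
        _write_tsv(profile, outdir / "counts.tsv", tag, index_label="mirna")

        stage = "normalize"
        prof = normalize.normalize_profile(profile, counts.metadata["stage"])
        _write_tsv(prof.values, outdir / "normalized.tsv", tag, index_label="mirna")
        _write_tsv(prof.stage_means, outdir / "stage_means.tsv", tag, index_label="mirna")
        run_report["size_factors"] = prof.size_factors.round(6).to_dict()
        retained = quantify.expression_filter(
            prof.stage_means, threshold=config["filter"]["threshold"]
        )

        stage = "homogeneity"
        hom_cfg = config["homogeneity"]
        hom_dir = outdir / "homogeneity"
        hom_dir.mkdir(exist_ok=True)
        substages: dict[str, tuple[str, ...]] = {}
        hom_rows = []
        for stage_label in sim_cfg.stages:
            libs = counts.metadata.index[counts.metadata["stage"] == stage_label]
            if len(libs) < 2:
                continue
            sub_values = prof.values.loc[retained, libs]
            litters = counts.metadata.loc[libs, "litter"].to_dict()
            report = homogeneity.stage_homogeneity_report(
                sub_values, stage_label, window=hom_cfg["window"],
                min_size=min(hom_cfg["min_size"], len(libs)),
                accept_cv=hom_cfg["accept_cv"], improvement=hom_cfg["improvement"],
                litters=litters,
            )
            _write_tsv(
                report.per_mirna_cv.to_frame(), hom_dir / f"{stage_label}.tsv", tag,
                index_label="mirna",
            )
            sub = report.substage
            if sub is not None and sub.members is not None:
                substages[stage_label] = sub.members
            hom_rows.append(
                {
                    "stage": stage_label,
                    "global_cv": report.global_cv[0],
                    "global_cv_sem": report.global_cv[1],
                    "substage": ",".join(sub.members) if sub and sub.members else "",
                    "substage_cv": sub.cv if sub else float("nan"),
                    "litter_confounded": bool(sub.litter_confounded) if sub else False,
                }
            )
        hom_summary = pd.DataFrame(hom_rows).set_index("stage")
        _write_tsv(hom_summary, outdir / "homogeneity_summary.tsv", tag, index_label="stage")
        with open(outdir / "substages.json", "w") as fh:
            json.dump({k: list(v) for k, v in substages.items()}, fh, indent=1)

        stage = "diffexp"
        de_cfg = config["diffexp"]
        plan = diffexp.side_stage_plan(
            counts.metadata, list(sim_cfg.stages), diet=sim_cfg.diets[0], substages=substages
        )
        ref_stage = de_cfg.get("reference_stage", sim_cfg.stages[-1])
        seen = {c.label for c in plan.comparisons}
        plan.comparisons += [
            c
            for c in diffexp.each_stage_vs_reference_plan(
                counts.metadata, list(sim_cfg.stages), ref_stage,
                diet=sim_cfg.diets[0], substages=substages,
            )
            if c.label not in seen
        ]
        if len(sim_cfg.diets) == 2:
            plan.comparisons += diffexp.diet_plan(
                counts.metadata, list(sim_cfg.stages), *sim_cfg.diets
            ).comparisons
        results, de_summary = diffexp.run_comparisons(
            prof.values, plan, retained,
            alpha=de_cfg["alpha"], fc_threshold=de_cfg["fc_threshold"],
        )
        _write_tsv(results, outdir / "de_results.tsv", tag)
        _write_tsv(de_summary, outdir / "de_summary.tsv", tag)

        stage = "manifest"
        files = sorted(
            p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "seed": config["seed"],
            "config_hash": _config_hash(config),
            "parameters": {k: v for k, v in config.items()},
            "simulation": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(sim_cfg).items()
                if k != "barcode_table"
            },
            "run_report": run_report,
            "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    except Exception as exc:  # noqa: BLE001 - diagnostics must name the stage
        raise PipelineStageError(stage, exc) from exc
    return outdir


def summarize(run_dir: str | Path) -> str:
    """Human-readable report of a completed run (deterministic given inputs)."""
    run_dir = Path(run_dir)
    lines = ["run summary", "==========="]
    warnings = []
    hom_path = run_dir / "homogeneity_summary.tsv"
    if hom_path.exists():
        hom = pd.read_csv(hom_path, sep="\t", comment="#", index_col=0)
        lines.append("")
        lines.append("replicate homogeneity per stage:")
        for stage_label, row in hom.iterrows():
            sub = row["substage"] if isinstance(row["substage"], str) and row["substage"] else "none"
            lines.append(
                f"  {stage_label}: global CV {row['global_cv']:.3f} "
                f"+/- {row['global_cv_sem']:.3f}; substage: {sub}"
            )
    else:
        warnings.append("homogeneity summary missing")
    de_path = run_dir / "de_summary.tsv"
    if de_path.exists():
        de = pd.read_csv(de_path, sep="\t", comment="#")
        lines.append("")
        lines.append("differential expression per comparison:")
        for _, row in de.iterrows():
            lines.append(
                f"  {row['comparison']}: {row['n_significant']}/{row['n_tested']} significant "
                f"({row['pct_significant']:.1f}%), {row['n_large_fc']} beyond 3-fold "
                f"({row['pct_large_fc']:.1f}%)"
            )
    else:
        warnings.append("differential-expression summary missing")
    for w in warnings:
        lines.append(f"WARNING: {w}")
    return "\n".join(lines) + "\n"
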