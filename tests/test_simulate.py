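"""Generator contracts: reference structure, count conservation, determinism,
isomiR composition and the closed-form Ct model."""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from mirprof import simulate as sim
from mirprof.errors import ConfigurationError, InputError


class TestGenerateReference:
    def test_arms_are_substrings_of_their_hairpins(self, small_ref):
        for arm in small_ref.arms:
            seq = small_ref.arm_sequence(arm)
            assert seq in small_ref.hairpins[arm.hairpin_id]
            assert 16 <= len(seq) <= 24

    def test_deterministic_given_seed(self, small_config, small_ref, tmp_path):
        again = sim.generate_reference(small_config)
        assert again.hairpins == small_ref.hairpins
        assert again.arms == small_ref.arms
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        small_ref.write_fasta(p1)
        again.write_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_family_members_share_seed_and_differ_downstream(self):
        cfg = sim.SimulationConfig(n_hairpins=10, family_sizes=(3,), seed=3)
        ref = sim.generate_reference(cfg)
        members = ref.families["fam-1"]
        assert len(members) == 3
        arms = {a.name: ref.arm_sequence(a) for a in ref.arms if a.name in members}
        seqs = list(arms.values())
        seeds = {s[1:8] for s in seqs}
        assert len(seeds) == 1  # bases 2-8 shared exactly
        downstream = {s[8:] for s in seqs}
        assert len(downstream) == 3  # every member differs past the seed

    def test_mature_sequences_unique_across_reference(self, small_ref):
        seqs = [small_ref.arm_sequence(a) for a in small_ref.arms]
        assert len(set(seqs)) == len(seqs)

    def test_family_sizes_exceeding_hairpins_rejected(self):
        with pytest.raises(ConfigurationError):
            sim.SimulationConfig(n_hairpins=4, family_sizes=(3, 3))


class TestSimulateExpressionMatrix:
    def test_column_sums_equal_reads_per_library(self, small_run, small_config):
        cm, _ = small_run
        assert (cm.counts.sum(axis=0) == small_config.reads_per_library).all()

    def test_null_case_stage_ratios_near_one(self, small_run):
        # no planted effects: abundant miRNAs should show stage ratios near 1
        cm, truth = small_run
        assert truth.planted_fold_changes == {}
        stage = cm.metadata["stage"]
        means = cm.counts.T.groupby(stage).mean().T
        abundant = means.min(axis=1) > 200
        ratios = means.loc[abundant, "B"] / means.loc[abundant, "A"]
        assert np.all((ratios > 0.4) & (ratios < 2.5))

    def test_ligation_bias_identical_across_libraries(self, small_run):
        # the bias vector is a single per-miRNA series applied to every library
        _, truth = small_run
        assert isinstance(truth.ligation_bias, pd.Series)
        assert (truth.ligation_bias > 0).all()

    def test_planted_fold_within_resampling_oracle_interval(self):
        # one 4-fold effect at high depth: the realized stage-mean ratio must
        # fall inside the 99% interval of a brute-force multinomial resampling
        # of the generator's own expected proportions
        cfg = sim.SimulationConfig(
            n_hairpins=40, two_arm_probability=0.0, stages=("A", "B"),
            replicates_per_stage=4, reads_per_library=100_000,
            planted_de=(sim.PlantedEffect("A", "B", 0.05, 4.0),),
            replicate_noise_sd=0.0, seed=5,
        )
        ref = sim.generate_reference(cfg)
        cm, truth = sim.simulate_expression_matrix(ref, cfg)
        planted = truth.planted_mirnas("A", "B")
        assert len(planted) == 2
        mirna, fold = next(iter(planted.items()))
        stage = cm.metadata["stage"]
        libs_a = stage.index[stage == "A"]
        libs_b = stage.index[stage == "B"]
        observed = cm.counts.loc[mirna, libs_b].mean() / cm.counts.loc[mirna, libs_a].mean()

        rng = np.random.default_rng(12345)
        p = truth.expected_counts / cfg.reads_per_library
        draws = []
        for _ in range(500):
            res = {
                lib: rng.multinomial(cfg.reads_per_library, p[lib])[
                    cm.counts.index.get_loc(mirna)
                ]
                for lib in cm.counts.columns
            }
            s = pd.Series(res)
            draws.append(s[libs_b].mean() / s[libs_a].mean())
        lo, hi = np.quantile(draws, [0.005, 0.995])
        assert lo <= observed <= hi
        # raw-count ratios are fold modulated by the library composition
        # shift; at 5% planted miRNAs the ratio still sits near the fold
        assert 0.5 * min(fold, 1 / fold) < observed < 2.0 * max(fold, 1 / fold)

    def test_zero_reads_rejected(self):
        with pytest.raises(ConfigurationError):
            sim.SimulationConfig(reads_per_library=0)

    def test_litters_assigned_round_robin(self, small_run, small_config):
        cm, _ = small_run
        litters = cm.metadata.groupby("stage")["litter"].nunique()
        expected = min(small_config.litters_per_stage, 3)
        assert (litters == expected).all()


class TestSynthesizeReads:
    def test_read_counts_and_length_bound(self, small_run, small_ref, small_config, tmp_path):
        cm, _ = small_run
        paths, barcodes = sim.synthesize_reads(cm, small_ref, small_config, tmp_path)
        assert set(paths) == set(cm.libraries)
        for lib, path in paths.items():
            lines = Path(path).read_text().splitlines()
            assert len(lines) == 4 * small_config.reads_per_library  # conservation
            seqs = lines[1::4]
            assert all(len(s) <= small_config.read_length for s in seqs)

    def test_deterministic_fastq_bytes(self, small_run, small_ref, small_config, tmp_path):
        cm, _ = small_run
        p1, _ = sim.synthesize_reads(cm, small_ref, small_config, tmp_path / "x")
        p2, _ = sim.synthesize_reads(cm, small_ref, small_config, tmp_path / "y")
        lib = cm.libraries[0]
        assert Path(p1[lib]).read_bytes() == Path(p2[lib]).read_bytes()

    def test_isomir_category_fractions_match_multinomial_expectation(self, tmp_path):
        from mirprof.quantify import build_count_profiles
        from mirprof.readproc import collapse_and_filter, trim_adaptor, read_fastq

        fractions = (0.6, 0.25, 0.15)
        cfg = sim.SimulationConfig(
            n_hairpins=40, seed=9, reads_per_library=20_000, stages=("A",),
            replicates_per_stage=1, per_base_error_rate=0.0, isomir_fractions=fractions,
        )
        ref = sim.generate_reference(cfg)
        cm, _ = sim.simulate_expression_matrix(ref, cfg)
        paths, barcodes = sim.synthesize_reads(cm, ref, cfg, tmp_path)
        lib = cm.libraries[0]
        adaptor = barcodes[lib] + cfg.adaptor_tail
        inserts = [
            ins for r in read_fastq(paths[lib])
            if (ins := trim_adaptor(r, adaptor)) is not None
        ]
        records = {lib: collapse_and_filter(inserts, library=lib)}
        _, report = build_count_profiles(records, ref)
        got = report[lib]["category_fractions"]
        n = cfg.reads_per_library
        for key, p in zip(("canonical", "isomir_3p", "isomir_5p"), fractions):
            sd = math.sqrt(p * (1 - p) / n)
            assert abs(got[key] - p) < 3 * sd + 0.01

    def test_missing_barcode_assignment_rejected(self, small_run, small_ref, small_config,
                                                 tmp_path):
        cm, _ = small_run
        cfg = sim.SimulationConfig(
            **{**{f: getattr(small_config, f) for f in (
                "n_hairpins", "seed", "reads_per_library", "stages",
                "replicates_per_stage")},
               "barcode_table": {"only-one-lib": "ACGTACGTACG"}},
        )
        with pytest.raises(ConfigurationError):
            sim.synthesize_reads(cm, small_ref, cfg, tmp_path)


class TestSimulateQpcr:
    def test_fourfold_ratio_gives_two_cycles_at_full_efficiency(self):
        expr = pd.DataFrame({"s1": [1.0], "s2": [4.0]}, index=["T"])
        ct = sim.simulate_qpcr(expr, {"T": 2.0})
        pivot = ct.set_index("sample")["ct"]
        assert pivot["s1"] - pivot["s2"] == pytest.approx(2.0)

    def test_equal_expression_equal_ct(self):
        expr = pd.DataFrame({"s1": [7.0], "s2": [7.0]}, index=["T"])
        ct = sim.simulate_qpcr(expr, {"T": 1.8})
        assert ct["ct"].nunique() == 1

    def test_partial_efficiency_closed_form(self):
        # ten-fold ratio at E=1.9: delta-Ct = ln(10)/ln(1.9)
        expr = pd.DataFrame({"s1": [1.0], "s2": [10.0]}, index=["T"])
        ct = sim.simulate_qpcr(expr, {"T": 1.9})
        pivot = ct.set_index("sample")["ct"]
        assert pivot["s1"] - pivot["s2"] == pytest.approx(math.log(10) / math.log(1.9))

    def test_invalid_efficiency_rejected(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["T"])
        with pytest.raises(ConfigurationError):
            sim.simulate_qpcr(expr, {"T": 1.0})
        with pytest.raises(InputError):
            sim.simulate_qpcr(pd.DataFrame({"s1": [0.0]}, index=["T"]), {"T": 2.0})
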