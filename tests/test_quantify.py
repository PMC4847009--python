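"""Alignment, isomiR naming, count building, efficiency factors and filtering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirprof import quantify as qt
from mirprof.readproc import InsertRecord
from mirprof.reference import MatureArm, MiRnaReference


def _mutate(seq: str, *positions: int) -> str:
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    chars = list(seq)
    for p in positions:
        chars[p] = swap[chars[p]]
    return "".join(chars)


def _exhaustive_oracle(insert: str, ref: MiRnaReference, max_mm: int = 2):
    """Independent brute force: every offset of every hairpin, best stratum."""
    hits = []
    for hid, seq in ref.hairpins.items():
        for start in range(0, len(seq) - len(insert) + 1):
            mm = sum(a != b for a, b in zip(insert, seq[start : start + len(insert)]))
            hits.append((mm, hid, start))
    if not hits:
        return []
    best = min(h[0] for h in hits)
    if best > max_mm:
        return []
    return sorted((hid, start) for mm, hid, start in hits if mm == best)


class TestAlignToReference:
    def test_exact_arm_alignment(self, small_ref):
        arm = small_ref.arms[0]
        hits = qt.align_to_reference(small_ref.arm_sequence(arm), small_ref)
        assert len(hits) == 1
        h = hits[0]
        assert (h.hairpin_id, h.mismatches, h.shift_5p, h.shift_3p) == (
            arm.hairpin_id, 0, 0, 0,
        )

    def test_two_mismatches_tolerated_three_rejected(self, small_ref):
        arm = small_ref.arms[0]
        seq = small_ref.arm_sequence(arm)
        two = _mutate(seq, 3, 9)
        three = _mutate(seq, 3, 9, 15)
        assert qt.align_to_reference(two, small_ref)[0].mismatches == 2
        assert qt.align_to_reference(three, small_ref) == []

    def test_agrees_with_exhaustive_oracle(self, small_ref):
        rng = np.random.default_rng(4)
        aligner = qt.HairpinAligner(small_ref)
        arms = list(small_ref.arms)
        for _ in range(40):
            arm = arms[rng.integers(len(arms))]
            seq = small_ref.arm_sequence(arm)
            n_mut = int(rng.integers(0, 4))
            positions = rng.choice(len(seq), size=n_mut, replace=False)
            query = _mutate(seq, *positions.tolist())
            got = sorted((h.hairpin_id, h.start) for h in aligner.align(query))
            assert got == _exhaustive_oracle(query, small_ref)

    def test_family_tie_returns_both_and_splits_counts(self):
        # two arms differing at two internal bases; a query carrying exactly
        # one of the two differences is 1 mismatch from each arm
        a = "ACGTACGTACGTACGTACGT"
        b = _mutate(a, 10, 12)
        ref = MiRnaReference(
            hairpins={"h1": "TTT" + a + "GGGTTTGGG", "h2": "CCC" + b + "AAACCCAAA"},
            arms=[
                MatureArm("miR-1-5p", "h1", 3, 23, "5p"),
                MatureArm("miR-2-5p", "h2", 3, 23, "5p"),
            ],
        )
        query = _mutate(a, 10)  # shares b's base at 10, a's base at 12
        hits = qt.align_to_reference(query, ref)
        assert sorted(h.hairpin_id for h in hits) == ["h1", "h2"]
        assert {h.mismatches for h in hits} == {1}
        profile, _ = qt.build_count_profiles({"L": [InsertRecord(query, 10, "L")]}, ref)
        assert profile.loc["miR-1-5p", "L"] == pytest.approx(5.0)
        assert profile.loc["miR-2-5p", "L"] == pytest.approx(5.0)


class TestClassifyIsomir:
    @pytest.fixture()
    def aligned(self, small_ref):
        aligner = qt.HairpinAligner(small_ref)

        def make(shift5: int, shift3: int):
            arm = next(a for a in small_ref.arms if a.start >= 2)
            hp = small_ref.hairpins[arm.hairpin_id]
            query = hp[arm.start + shift5 : arm.end + shift3]
            hits = aligner.align(query)
            assert len(hits) == 1
            return hits[0], arm

        return make

    def test_three_prime_variant_keeps_canonical_name(self, aligned):
        hit, arm = aligned(0, 1)
        assert qt.classify_isomir(hit) == (arm.name, "isomir_3p")

    def test_five_prime_variant_gets_hairp_name(self, aligned):
        hit, arm = aligned(-1, 0)
        assert qt.classify_isomir(hit) == (f"{arm.name}-hairp", "isomir_5p")

    def test_canonical(self, aligned):
        hit, arm = aligned(0, 0)
        assert qt.classify_isomir(hit) == (arm.name, "canonical")


class TestBuildCountProfiles:
    def test_single_canonical_record(self, small_ref):
        arm = small_ref.arms[0]
        rec = InsertRecord(small_ref.arm_sequence(arm), 100, "L1")
        profile, report = qt.build_count_profiles({"L1": [rec]}, small_ref)
        assert profile.loc[arm.name, "L1"] == 100
        assert report["L1"]["mapped"] == 100

    def test_three_prime_isomir_counted_with_canonical(self, small_ref):
        arm = next(a for a in small_ref.arms if a.end + 1 <= len(small_ref.hairpins[a.hairpin_id]))
        hp = small_ref.hairpins[arm.hairpin_id]
        canonical = hp[arm.start : arm.end]
        threep = hp[arm.start : arm.end + 1]
        profile, _ = qt.build_count_profiles(
            {"L": [InsertRecord(canonical, 80, "L"), InsertRecord(threep, 20, "L")]},
            small_ref,
        )
        assert profile.loc[arm.name, "L"] == pytest.approx(100.0)

    def test_unmapped_inserts_tallied(self, small_ref):
        rec = InsertRecord("A" * 22, 7, "L")
        profile, report = qt.build_count_profiles({"L": [rec]}, small_ref)
        assert report["L"]["unmapped"] == 7
        assert profile.empty or "L" in profile.columns

    def test_mapped_plus_unmapped_conserves_totals(self, small_ref):
        arm = small_ref.arms[0]
        records = [
            InsertRecord(small_ref.arm_sequence(arm), 30, "L"),
            InsertRecord("T" * 25, 12, "L"),
        ]
        profile, report = qt.build_count_profiles({"L": records}, small_ref)
        total = report["L"]["mapped"] + report["L"]["unmapped"] + report["L"]["unknown_arm"]
        assert total == 42
        assert profile["L"].sum() == pytest.approx(report["L"]["mapped"])


class TestApplyEfficiencyFactors:
    def test_factor_halves_count(self):
        profile = pd.DataFrame({"L": [50.0]}, index=["miR-X"])
        controls = pd.DataFrame({"ref": [100.0], "var": [200.0]}, index=["miR-X"])
        corrected, factors = qt.apply_efficiency_factors(profile, controls)
        assert factors["miR-X"] == 2.0
        assert corrected.loc["miR-X", "L"] == 25.0

    def test_absent_mirna_keeps_count(self):
        profile = pd.DataFrame({"L": [50.0]}, index=["miR-Y"])
        controls = pd.DataFrame({"ref": [100.0], "var": [200.0]}, index=["miR-X"])
        corrected, factors = qt.apply_efficiency_factors(profile, controls)
        assert factors["miR-Y"] == 1.0
        assert corrected.loc["miR-Y", "L"] == 50.0

    def test_low_coverage_controls_excluded(self):
        profile = pd.DataFrame({"L": [50.0]}, index=["miR-X"])
        controls = pd.DataFrame({"ref": [10.0], "var": [200.0]}, index=["miR-X"])
        with pytest.warns(UserWarning):
            corrected, factors = qt.apply_efficiency_factors(profile, controls)
        assert factors["miR-X"] == 1.0

    def test_identical_controls_change_nothing(self):
        profile = pd.DataFrame({"L": [50.0, 30.0]}, index=["a", "b"])
        controls = pd.DataFrame({"ref": [100.0, 40.0], "var": [100.0, 40.0]},
                                index=["a", "b"])
        corrected, _ = qt.apply_efficiency_factors(profile, controls)
        pd.testing.assert_frame_equal(corrected, profile)


class TestExpressionFilter:
    def test_strict_threshold(self):
        means = pd.DataFrame(
            {"s1": [10.0, 3.0, 0.0], "s2": [8.2, 10.4, 0.0]},
            index=["at-threshold", "above-once", "all-zero"],
        )
        retained = qt.expression_filter(means, threshold=10.0)
        assert list(retained) == ["above-once"]
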