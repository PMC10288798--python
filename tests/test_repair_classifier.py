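"""Microhomology detection and repair-category rules."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mmejtools import (
    AlleleObservation,
    ClassifierParams,
    GuideRecord,
    IndelDescriptor,
    Locus,
    MalformedAlleleTableError,
    NonCanonicalIntervalError,
    ProgrammedEdit,
    RepairCategory,
    classify_embryo,
    classify_repair,
    detect_microhomology,
    normalize_deletion,
)
from conftest import oracle_placements, random_locus


def make_guide(locus, cut):
    return GuideRecord(
        locus_name=locus.name,
        protospacer="A" * 20,
        strand="+",
        pam_start=cut + 3,
        cut_site=cut,
    )


def obs(locus, cut, indel, frequency=10.0, embryo="e1"):
    return AlleleObservation(
        embryo_id=embryo, guide=make_guide(locus, cut), indel=indel, frequency=frequency
    )


class TestDetectMicrohomology:
    def test_tandem_repeat_junction(self, repeat_locus):
        evidence = detect_microhomology(repeat_locus, (3, 6))
        assert (evidence.length, evidence.sequence) == (3, "CAT")
        assert not evidence.capped

    def test_unique_placement_has_no_junction(self, plain_locus):
        evidence = detect_microhomology(plain_locus, (3, 5))
        assert (evidence.length, evidence.sequence) == (0, "")

    def test_long_repeat_capped_at_mh_max(self):
        # 30-nt repeat pair: ambiguity 30, reported capped at 25 and flagged
        unit = "ATCGGTACCTGATTACAGGCATCGAACGTT"  # 30 nt, non-periodic
        locus = Locus("tandem", "GGG" + unit + unit + "CCC")
        (start, end), span = normalize_deletion(locus, (3, 33))
        assert span == 30
        evidence = detect_microhomology(locus, (start, end))
        assert evidence.length == 25
        assert evidence.capped
        assert evidence.sequence == locus.sequence[start:start + 25]

    def test_non_canonical_interval_rejected(self, repeat_locus):
        with pytest.raises(NonCanonicalIntervalError):
            detect_microhomology(repeat_locus, (6, 9))

    @given(
        seq=st.text(alphabet="ACG", min_size=10, max_size=200),
        data=st.data(),
    )
    def test_equals_bruteforce_placement_oracle(self, seq, data):
        """Junction microhomology equals placement-count ambiguity."""
        start = data.draw(st.integers(0, len(seq) - 3))
        end = data.draw(st.integers(start + 1, len(seq) - 1))
        locus = Locus("h", seq)
        canonical, _ = normalize_deletion(locus, (start, end))
        evidence = detect_microhomology(locus, canonical)
        n_placements = len(oracle_placements(seq, start, end))
        assert evidence.length == min(n_placements - 1, 25)


class TestClassifyRepair:
    def test_insertion_at_cut_is_nhej(self, repeat_locus):
        indel = IndelDescriptor(kind="insertion", del_start=6, del_end=6, ins_sequence="A")
        call = classify_repair(obs(repeat_locus, 6, indel), repeat_locus)
        assert call.category == RepairCategory.NHEJ

    def test_single_base_deletion_in_homopolymer_is_nhej(self):
        locus = Locus("homo", "GGGAAAAAGGG")
        indel = IndelDescriptor(kind="deletion", del_start=5, del_end=6)
        call = classify_repair(obs(locus, 5, indel), locus)
        assert call.category == RepairCategory.NHEJ
        assert call.note == "single-base deletion"

    def test_repeat_flanked_deletion_is_mmej(self, repeat_locus):
        indel = IndelDescriptor(kind="deletion", del_start=3, del_end=6)
        call = classify_repair(obs(repeat_locus, 6, indel), repeat_locus)
        assert call.category == RepairCategory.MMEJ
        assert (call.mh_length, call.mh_sequence) == (3, "CAT")

    def test_microhomology_free_deletion_is_nhej(self, plain_locus):
        indel = IndelDescriptor(kind="deletion", del_start=3, del_end=5)
        call = classify_repair(obs(plain_locus, 4, indel), plain_locus)
        assert call.category == RepairCategory.NHEJ

    def test_delins_follows_the_insertion_rule(self, repeat_locus):
        indel = IndelDescriptor(kind="delins", del_start=3, del_end=6, ins_sequence="TT")
        call = classify_repair(obs(repeat_locus, 6, indel), repeat_locus)
        assert call.category == RepairCategory.NHEJ

    def test_programmed_substitution_is_hdr(self):
        seq = "ACGTACGTACGTCCATGGACGTACGTACGT"
        locus = Locus(
            "donor",
            seq,
            donor_edit=ProgrammedEdit(
                kind="substitution", start=12, end=18, replacement="GAATTC"
            ),
        )
        indel = IndelDescriptor(
            kind="substitution", del_start=12, del_end=18, ins_sequence="GAATTC"
        )
        call = classify_repair(obs(locus, 14, indel), locus)
        assert call.category == RepairCategory.HDR

    def test_imperfect_hdr_is_unattributable(self):
        seq = "ACGTACGTACGTCCATGGACGTACGTACGT"
        locus = Locus(
            "donor",
            seq,
            donor_edit=ProgrammedEdit(
                kind="substitution", start=12, end=18, replacement="GAATTC"
            ),
        )
        indel = IndelDescriptor(
            kind="substitution", del_start=12, del_end=18, ins_sequence="GAATTG"
        )
        call = classify_repair(obs(locus, 14, indel), locus)
        assert call.category == RepairCategory.UNATTRIBUTABLE

    def test_unedited_allele(self, repeat_locus):
        call = classify_repair(
            obs(repeat_locus, 6, IndelDescriptor(kind="none")), repeat_locus
        )
        assert call.category == RepairCategory.UNEDITED

    def test_distant_deletion_is_unattributable(self):
        locus = Locus("long", "ACGTACGA" * 50)
        params = ClassifierParams(repair_window=10)
        indel = IndelDescriptor(kind="deletion", del_start=300, del_end=310)
        call = classify_repair(obs(locus, 20, indel), locus, params)
        assert call.category == RepairCategory.UNATTRIBUTABLE

    def test_placement_invariance(self, rng):
        """Any reported placement of the same deletion gets the same call."""
        for _ in range(50):
            seq = random_locus(rng, 60, alphabet="AC")
            locus = Locus("p", seq)
            start = int(rng.integers(5, 40))
            end = int(rng.integers(start + 1, min(start + 15, 55)))
            cut = int(rng.integers(max(1, start - 5), min(len(seq) - 1, end + 5)))
            placements = oracle_placements(seq, start, end)
            length = end - start
            calls = {
                (
                    classify_repair(
                        obs(
                            locus,
                            cut,
                            IndelDescriptor(kind="deletion", del_start=i, del_end=i + length),
                        ),
                        locus,
                    ).category,
                    classify_repair(
                        obs(
                            locus,
                            cut,
                            IndelDescriptor(kind="deletion", del_start=i, del_end=i + length),
                        ),
                        locus,
                    ).mh_length,
                )
                for i in placements
            }
            assert len(calls) == 1

    def test_raising_mh_min_only_moves_mmej_to_nhej(self, rng):
        """Monotone threshold: MMEJ calls can only become NHEJ, never the reverse."""
        for _ in range(50):
            seq = random_locus(rng, 60, alphabet="ACG")
            locus = Locus("m", seq)
            start = int(rng.integers(5, 40))
            end = int(rng.integers(start + 2, min(start + 12, 55)))
            o = obs(locus, start, IndelDescriptor(kind="deletion", del_start=start, del_end=end))
            cat_by_min = [
                classify_repair(o, locus, ClassifierParams(mh_min=mh_min)).category
                for mh_min in (1, 2, 4, 8)
            ]
            seen_nhej = False
            for category in cat_by_min:
                if category == RepairCategory.NHEJ:
                    seen_nhej = True
                else:
                    assert not seen_nhej, "MMEJ reappeared after raising mh_min"


class TestClassifyEmbryo:
    def test_category_sums_and_efficiency(self, repeat_locus):
        observations = [
            obs(repeat_locus, 6, IndelDescriptor(kind="none"), 40.0),
            obs(
                repeat_locus,
                6,
                IndelDescriptor(kind="deletion", del_start=3, del_end=6),
                50.0,
            ),
            obs(
                repeat_locus,
                6,
                IndelDescriptor(kind="insertion", del_start=6, del_end=6, ins_sequence="T"),
                10.0,
            ),
        ]
        profile = classify_embryo(observations, repeat_locus)
        assert profile.f_mmej == pytest.approx(50.0)
        assert profile.f_nhej == pytest.approx(10.0)
        assert profile.f_unedited == pytest.approx(40.0)
        assert profile.efficiency == pytest.approx(60.0)

    def test_empty_observation_list_is_an_error(self, repeat_locus):
        with pytest.raises(ValueError):
            classify_embryo([], repeat_locus)

    def test_overfull_frequencies_rejected(self, repeat_locus):
        observations = [
            obs(repeat_locus, 6, IndelDescriptor(kind="none"), 60.0),
            obs(repeat_locus, 6, IndelDescriptor(kind="none"), 60.0),
        ]
        with pytest.raises(MalformedAlleleTableError):
            classify_embryo(observations, repeat_locus)

    def test_partition_property(self, rng):
        """Category frequencies always partition the reported allele mass."""
        from mmejtools.synthetic_data import SimulationConfig, simulate_cohort
        from mmejtools.repair_classifier import classify_cohort

        cohort = simulate_cohort(SimulationConfig(seed=11, n_guides=4, n_embryos=6))
        _, profiles = classify_cohort(
            cohort.alleles, cohort.loci, cohort.guides, cohort.classifier_params
        )
        for p in profiles:
            total = p.f_nhej + p.f_mmej + p.f_hdr + p.f_unedited + p.f_unattributable
            assert total == pytest.approx(100.0, abs=0.1)
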