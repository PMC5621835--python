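"""Allele calling: classification, alignment, naming, discovery, assignment."""

from collections import Counter

import numpy as np
import pytest

from indeltrace.calling import (Allele, AlleleCaller, AlleleError, Indel, INTACT,
                                ReadTooShortError, align_read, apply_indel,
                                assign_reads, build_allele, classify_non_mutant,
                                consolidate_alleles, extract_indel, left_align,
                                make_representative, name_allele)
from indeltrace.targets import TargetError, synthetic_target
from tests.conftest import TOY_REFERENCE


def all_single_deletion_placements(reference: str, read: str, length: int):
    """Independent enumeration oracle: every (start, end) whose deletion
    reproduces the read exactly."""
    hits = []
    for s in range(1, len(reference) - length + 2):
        e = s + length - 1
        if reference[:s - 1] + reference[e:] == read:
            hits.append((s, e))
    return hits


def all_single_insertion_placements(reference: str, read: str, length: int):
    """Every (after, inserted) whose insertion reproduces the read."""
    hits = []
    for p in range(0, len(reference) + 1):
        ins = read[p:p + length]
        if reference[:p] + ins + reference[p:] == read:
            hits.append((p, ins))
    return hits


class TestClassifyNonMutant:
    def test_reference_is_non_mutant(self, toy_target):
        assert classify_non_mutant(toy_target.reference, toy_target)

    def test_deletion_in_protospacer_is_mutant(self, toy_target):
        read = TOY_REFERENCE[:14] + TOY_REFERENCE[15:]
        assert not classify_non_mutant(read, toy_target)

    def test_substitution_outside_site_stays_non_mutant(self, toy_target):
        # rule is a perfect protospacer+PAM match, nothing more
        read = "T" + TOY_REFERENCE[1:]
        assert read != TOY_REFERENCE
        assert classify_non_mutant(read, toy_target)


class TestAlignExtract:
    def test_three_base_deletion_recovered_at_leftmost_placement(self, toy_target):
        read = TOY_REFERENCE[:27] + TOY_REFERENCE[30:]
        indel = extract_indel(align_read(read, toy_target), toy_target)
        placements = all_single_deletion_placements(TOY_REFERENCE, read, 3)
        assert (indel.del_start, indel.del_end) == min(placements)

    def test_gap_free_reference_alignment(self, toy_target):
        aln = align_read(TOY_REFERENCE, toy_target)
        assert extract_indel(aln, toy_target) is None

    def test_homopolymer_insertion_left_aligned(self, toy_target):
        # "TT" inserted after base 30 sits in a T-run; leftmost placement wins
        read = TOY_REFERENCE[:30] + "TT" + TOY_REFERENCE[30:]
        indel = extract_indel(align_read(read, toy_target), toy_target)
        placements = all_single_insertion_placements(TOY_REFERENCE, read, 2)
        assert indel.insertion_after == min(p for p, _ in placements)
        assert apply_indel(TOY_REFERENCE, indel) == read

    def test_substitution_only_yields_no_indel(self, toy_target):
        read = TOY_REFERENCE[:28] + "G" + TOY_REFERENCE[29:]
        assert read != TOY_REFERENCE
        aln = align_read(read, toy_target)
        assert extract_indel(aln, toy_target) is None

    def test_large_deletion_spanning_whole_site_qualifies(self, toy_target):
        read = TOY_REFERENCE[:10] + TOY_REFERENCE[40:]   # deletes 11..40 (30 bp)
        indel = extract_indel(align_read(read, toy_target), toy_target)
        assert indel is not None
        assert indel.del_start <= 11 and indel.del_end >= 33
        assert apply_indel(TOY_REFERENCE, indel) == read

    def test_indel_outside_window_returns_none(self, toy_target):
        read = TOY_REFERENCE[:45] + TOY_REFERENCE[48:]   # deletes 46..48
        aln = align_read(read, toy_target)
        assert extract_indel(aln, toy_target) is None

    def test_short_read_rejected(self, toy_target):
        with pytest.raises(ReadTooShortError):
            align_read("ACGTACGT", toy_target)


class TestNaming:
    @pytest.mark.parametrize("indel,expected", [
        (Indel(del_start=28, del_end=30), "D28-30"),
        (Indel(insertion="TTA", insertion_after=30), "I30+TTA"),
        (Indel(del_start=29, del_end=33, insertion="G"), "D29-33+G"),
    ])
    def test_canonical_names(self, indel, expected):
        assert name_allele(indel) == expected

    def test_empty_indel_rejected(self):
        with pytest.raises(AlleleError):
            Indel()

    def test_inverted_deletion_span_rejected(self):
        with pytest.raises(AlleleError):
            Indel(del_start=30, del_end=28)


class TestRepresentative:
    def test_deletion_representative_is_symmetric_flanks(self, toy_target):
        rep = make_representative(Indel(del_start=28, del_end=30), toy_target)
        assert rep == TOY_REFERENCE[12:27] + TOY_REFERENCE[30:45]  # 13-27 + 31-45
        assert len(rep) == 30

    def test_insertion_representative_centers_insertion(self, toy_target):
        ins = Indel(insertion="TTA", insertion_after=30)
        rep = make_representative(ins, toy_target)
        # flank total 27: 14 left, 13 right around the junction after base 30
        assert rep == TOY_REFERENCE[16:30] + "TTA" + TOY_REFERENCE[30:43]

    def test_end_proximal_deletion_compensates_flanks(self, toy_target):
        # deleting 2..31 leaves one base on the left; deficit goes right
        rep = make_representative(Indel(del_start=2, del_end=31), toy_target)
        assert len(rep) == 30
        assert rep == TOY_REFERENCE[0] + TOY_REFERENCE[31:60]

    def test_unrepresentable_deletion_raises(self, toy_target):
        with pytest.raises(AlleleError):
            make_representative(Indel(del_start=2, del_end=55), toy_target)


class TestLeftAlignProperty:
    def test_all_equivalent_homopolymer_placements_share_a_name(self, toy_target):
        # single-T deletion anywhere in the TTT run at 28..30+inserted context
        reads = {TOY_REFERENCE[:p - 1] + TOY_REFERENCE[p:] for p in (29, 30)}
        assert len(reads) == 1  # placements are literally the same string
        names = set()
        for p in (29, 30):
            names.add(name_allele(left_align(Indel(del_start=p, del_end=p),
                                             TOY_REFERENCE)))
        assert len(names) == 1


class TestDiscoveryAssignment:
    def _reads_for(self, target, spec):
        """spec: list of (Indel|None, count); None = intact."""
        reads = []
        for indel, n in spec:
            seq = target.reference if indel is None else apply_indel(target.reference, indel)
            reads.extend([seq] * n)
        return reads

    def test_three_alleles_recovered_with_exact_counts(self, toy_target):
        indels = [Indel(del_start=28, del_end=30),
                  Indel(del_start=24, del_end=32, insertion="A"),
                  Indel(insertion="CAA", insertion_after=27)]
        reads = self._reads_for(toy_target, [(None, 50), (indels[0], 30),
                                             (indels[1], 15), (indels[2], 5)])
        caller = AlleleCaller(toy_target)
        alleles = caller.discover(reads)
        assert {a.name for a in alleles} == {name_allele(i) for i in indels}
        result = caller.assign(reads, alleles)
        assert result.counts[INTACT] == 50
        assert result.counts[name_allele(indels[0])] == 30
        assert result.counts[name_allele(indels[1])] == 15
        assert result.counts[name_allele(indels[2])] == 5
        assert result.n_error == 0

    def test_all_non_mutant_reads_yield_no_alleles(self, toy_target):
        caller = AlleleCaller(toy_target)
        assert caller.discover([toy_target.reference] * 100) == []

    def test_near_site_substitutions_are_error_reads(self, toy_target):
        # substitutions near but not in the cut window: no alleles, residue is error
        read = TOY_REFERENCE[:24] + "A" + TOY_REFERENCE[25:]
        assert read != TOY_REFERENCE
        caller = AlleleCaller(toy_target)
        alleles = caller.discover([read] * 10)
        assert alleles == []
        result = caller.assign([read] * 10, alleles)
        assert result.n_error == 10

    def test_conservation_of_reads(self, toy_target):
        rng = np.random.default_rng(0)
        pool = [toy_target.reference,
                apply_indel(TOY_REFERENCE, Indel(del_start=28, del_end=30)),
                "ACGT" * 3,                                     # unalignably short
                TOY_REFERENCE[:24] + "A" + TOY_REFERENCE[25:]]  # error read
        reads = [pool[i] for i in rng.integers(0, 4, size=500)]
        caller = AlleleCaller(toy_target)
        alleles = caller.discover(reads)
        result = caller.assign(reads, alleles)
        assert result.total == 500

    def test_assignment_is_idempotent(self, toy_target):
        reads = self._reads_for(toy_target,
                                [(None, 20), (Indel(del_start=28, del_end=30), 10)])
        caller = AlleleCaller(toy_target)
        alleles = caller.discover(reads)
        r1 = caller.assign(reads, alleles)
        r2 = caller.assign(reads, alleles)
        assert r1.counts == r2.counts and r1.n_error == r2.n_error

    def test_multi_representative_read_goes_to_longest_footprint(self, toy_target):
        short = build_allele(Indel(del_start=28, del_end=30), toy_target)
        long = build_allele(Indel(del_start=24, del_end=33), toy_target)
        chimera = short.representative + long.representative
        result = assign_reads([chimera], [short, long], toy_target)
        assert result.counts[long.name] == 1
        assert result.counts[short.name] == 0


class TestConsolidation:
    def test_shared_allele_merges(self, toy_target):
        a = build_allele(Indel(del_start=28, del_end=30), toy_target)
        master = consolidate_alleles([[a], [a]])
        assert len(master) == 1

    def test_disjoint_sets_union(self, toy_target):
        def mk(s):
            return build_allele(Indel(del_start=s, del_end=s + 2), toy_target)
        animal1 = [mk(s) for s in (26, 27, 28)]
        animal2 = [build_allele(Indel(insertion=b * 2, insertion_after=27), toy_target)
                   for b in "ACGT"]
        master = consolidate_alleles([animal1, animal2])
        assert len(master) == 7

    def test_equivalent_placements_merge_after_left_alignment(self, toy_target):
        # the same physical single-T deletion, provisionally named at two
        # equivalent homopolymer placements
        provisional = [Indel(del_start=29, del_end=29), Indel(del_start=30, del_end=30)]
        canonical = [left_align(i, TOY_REFERENCE) for i in provisional]
        alleles = [build_allele(i, toy_target) for i in canonical]
        master = consolidate_alleles([[alleles[0]], [alleles[1]]])
        assert len(master) == 1

    def test_representative_length_mismatch_rejected(self, toy_target):
        other = synthetic_target(seed=5, name="other", representative_length=34)
        a = build_allele(Indel(del_start=28, del_end=30), toy_target)
        b = build_allele(Indel(del_start=79, del_end=81), other)
        with pytest.raises(TargetError):
            consolidate_alleles([[a], [b]])
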