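"""Two-caller consensus: SNV/CNA set operations and trinucleotide profiles."""

import numpy as np
import pytest

from cloneconcord.consensus import (
    TRINUC_CLASSES,
    collapse_substitution,
    filter_min_length,
    genome_context_counts,
    partition_cnas,
    partition_snvs,
    trinuc_profile,
)
from cloneconcord.core import CNASegment, GenomicInterval, SNVRecord

from oracles import partition_to_base_arrays, per_base_cna_oracle


def snv(chrom, pos, ref, alt):
    return SNVRecord(chrom, pos, ref, alt, ref_count=30, alt_count=10)


def seg(start, end, maj, mnr, label="unspecified", chrom="1", frac=None):
    return CNASegment(
        GenomicInterval(chrom, start, end), maj, mnr,
        clonal_fraction=frac, clonality_label=label,
    )


class TestSnvPartition:
    def test_basic_partition(self):
        a = [snv("1", 1, "A", "C"), snv("1", 2, "A", "C")]
        b = [snv("1", 2, "A", "C"), snv("1", 3, "A", "C")]
        part = partition_snvs(a, b)
        assert part.intersect == {("1", 2, "A", "C")}
        assert part.a_unique == {("1", 1, "A", "C")}
        assert part.b_unique == {("1", 3, "A", "C")}
        assert part.union == part.intersect | part.a_unique | part.b_unique

    def test_identical_callers(self):
        a = [snv("1", 1, "A", "C")]
        part = partition_snvs(a, a)
        assert part.a_unique == set() and part.b_unique == set()

    def test_alt_allele_is_part_of_identity(self):
        part = partition_snvs([snv("1", 5, "A", "C")], [snv("1", 5, "A", "G")])
        assert part.intersect == set()

    def test_duplicates_deduplicated(self):
        part = partition_snvs([snv("1", 1, "A", "C"), snv("1", 1, "A", "C")], [])
        assert part.a_unique == {("1", 1, "A", "C")}


class TestCnaPartition:
    def test_identical_aberration_is_intersect(self):
        part = partition_cnas([seg(0, 10_000, 2, 1)], [seg(0, 10_000, 2, 1)])
        assert len(part.intersect) == 1
        assert part.covered_bp("intersect") == 10_000
        assert part.covered_bp("union") == 10_000

    def test_aberrant_vs_neutral_is_tool_unique(self):
        part = partition_cnas([seg(0, 10_000, 2, 1)], [seg(0, 10_000, 1, 1)])
        assert part.covered_bp("a_unique") == 10_000
        assert part.covered_bp("intersect") == 0
        assert part.union[0].major_cn == 2

    def test_conflicting_aberrations_excluded_from_union(self):
        part = partition_cnas([seg(0, 10_000, 3, 1)], [seg(0, 10_000, 2, 0)])
        assert part.covered_bp("disagreement") == 10_000
        assert part.union == []

    def test_partial_overlap_resolved_per_base(self):
        part = partition_cnas(
            [seg(0, 6_000, 2, 1)], [seg(4_000, 10_000, 2, 1)]
        )
        assert part.covered_bp("intersect") == 2_000
        assert part.covered_bp("a_unique") == 4_000
        assert part.covered_bp("b_unique") == 4_000

    def test_dual_entry_region_is_unique_but_other_caller_fills_union(self):
        # caller B delineates a subclonal aberration as a clonal+subclonal
        # pair; the region is B-unique, yet A's aberration enters the union
        b = [seg(0, 10_000, 1, 1, "clonal"), seg(0, 10_000, 3, 1, "subclonal", frac=0.4)]
        a = [seg(0, 10_000, 2, 0)]
        part = partition_cnas(a, b)
        assert part.covered_bp("b_unique") == 10_000
        assert part.covered_bp("a_unique") == 0
        assert len(part.union) == 1
        assert (part.union[0].major_cn, part.union[0].minor_cn) == (2, 0)

    def test_dual_entry_against_neutral_leaves_union_empty(self):
        b = [seg(0, 10_000, 1, 1, "clonal"), seg(0, 10_000, 3, 1, "subclonal", frac=0.4)]
        part = partition_cnas([seg(0, 10_000, 1, 1)], b)
        assert part.covered_bp("b_unique") == 10_000
        assert part.union == []

    def test_overlapping_same_clonality_rejected(self):
        with pytest.raises(ValueError):
            partition_cnas(
                [seg(0, 10_000, 2, 1, "clonal"), seg(5_000, 15_000, 3, 1, "clonal")],
                [seg(0, 10_000, 2, 1)],
            )

    def test_matches_per_base_oracle_on_small_cases(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            a, b, length = _random_segmentations(rng)
            part = partition_cnas(a, b)
            got = partition_to_base_arrays(part, length)
            expected = per_base_cna_oracle(a, b, length)
            for g, e in zip(got, expected):
                assert np.array_equal(g, e)


def _random_segmentations(rng, length=50_000, max_segs=6):
    """Random valid per-caller segmentations on one toy chromosome."""

    def one_caller(dual_allowed):
        n = int(rng.integers(0, max_segs + 1))
        if n == 0:
            return []
        pts = np.sort(rng.choice(length, size=2 * n, replace=False))
        segs = []
        states = [(1, 1), (2, 1), (3, 1), (1, 0), (2, 0), (2, 2)]
        for i in range(n):
            start, end = int(pts[2 * i]), int(pts[2 * i + 1])
            if end <= start:
                continue
            maj, mnr = states[int(rng.integers(len(states)))]
            if dual_allowed and rng.random() < 0.3:
                segs.append(seg(start, end, 1, 1, "clonal"))
                segs.append(
                    seg(start, end, max(maj, 2), mnr, "subclonal", frac=0.5)
                )
            else:
                segs.append(seg(start, end, maj, mnr))
        return segs

    return one_caller(False), one_caller(True), length


class TestLengthFilter:
    def test_boundary(self):
        short = seg(0, 9_999, 2, 1)
        exact = seg(0, 10_000, 2, 1)
        assert filter_min_length([short, exact]) == [exact]

    def test_empty(self):
        assert filter_min_length([]) == []


class TestTrinucProfile:
    def test_single_pyrimidine_substitution(self):
        genome = {"1": "AACAA"}
        prof = trinuc_profile([snv("1", 3, "C", "T")], genome)
        assert prof.total == 1
        assert prof.counts[TRINUC_CLASSES.index("A[C>T]A")] == 1

    def test_purine_reference_strand_collapsed(self):
        # G>A on the forward strand in TGC context records as the
        # reverse-complement class G[C>T]A
        genome = {"1": "ATGCA"}
        prof = trinuc_profile([snv("1", 3, "G", "A")], genome)
        assert prof.counts[TRINUC_CLASSES.index("G[C>T]A")] == 1

    def test_reference_mismatch_listed_not_counted(self):
        genome = {"1": "AACAA"}
        prof = trinuc_profile([snv("1", 3, "G", "A")], genome)
        assert prof.total == 0
        assert len(prof.errors) == 1

    def test_counts_sum_to_contextualized_records(self, small_genome):
        rng = np.random.default_rng(3)
        records = []
        chrom = "1"
        for pos0 in rng.choice(len(small_genome[chrom]) - 4, 500, replace=False) + 2:
            ref = small_genome[chrom][pos0]
            alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
            records.append(snv(chrom, int(pos0) + 1, ref, alt))
        prof = trinuc_profile(records, small_genome)
        assert prof.total == 500 - len(prof.errors)
        assert len(prof.errors) == 0

    def test_all_purine_substitutions_collapse_to_pyrimidine_classes(self):
        for ref in "AG":
            for alt in "ACGT".replace(ref, ""):
                for five in "ACGT":
                    for three in "ACGT":
                        cls, ctx = collapse_substitution(five, ref, alt, three)
                        assert cls[2] in "CT"
                        assert cls in TRINUC_CLASSES

    def test_genome_context_counts_double_stranded(self):
        # "ACAT": interior trinucs ACA (C centre) and CAT (A centre ->
        # reverse complement ATG, T centre)
        counts = genome_context_counts({"1": "ACAT"})
        from cloneconcord.consensus import CONTEXT_TYPES

        assert counts[CONTEXT_TYPES.index("ACA")] == 1
        assert counts[CONTEXT_TYPES.index("ATG")] == 1
        assert counts.sum() == 2
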