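"""Transformation semantics and relation verdicts for the nine MRs."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrtest import (
    AlignmentRecord,
    AlignmentResult,
    ReadRecord,
    ReadSet,
    Reference,
    TransformMetadata,
    Verdict,
    check_relation,
    mr1_permute,
    mr2_revcomp,
    mr3_duplicate,
    mr4_halve,
    mr5_extend,
    mr6_select_unmapped,
    mr7_select_mapped,
    mr8_boost_quality,
    mr9_correct_mismatches,
)
from mrtest.metamorphic_relations import DUPLICATE_SUFFIX, TransformError
from mrtest.toy_aligners import HarnessError

from conftest import read_records


def _single_set(*seqs: str, qual: str | None = None) -> ReadSet:
    return ReadSet.single(
        ReadRecord(f"r{i}", s, qual or "I" * len(s)) for i, s in enumerate(seqs)
    )


def _paired_set(n: int) -> ReadSet:
    r1 = tuple(ReadRecord(f"p{i}", "ACGT", "IIII", role="read1") for i in range(n))
    r2 = tuple(ReadRecord(f"p{i}", "TTTT", "JJJJ", role="read2") for i in range(n))
    return ReadSet(reads1=r1, reads2=r2, paired=True)


def _mapped(name, role="single", pos=1, strand="+", length=4, **kw):
    return AlignmentRecord(read_name=name, role=role, mapped=True,
                           contig="c", pos=pos, strand=strand,
                           cigar=f"{length}M", **kw)


def _unmapped(name, role="single"):
    return AlignmentRecord(read_name=name, role=role, mapped=False)


class TestMR1Permute:
    def test_single_read_is_fixed_point(self):
        rs = _single_set("ACGT")
        out, _ = mr1_permute(rs, seed=0)
        assert out == rs

    def test_permutation_preserves_multiset_and_is_nontrivial(self):
        rs = _single_set("AAAA", "CCCC", "GGGG", "TTTT")
        out, meta = mr1_permute(rs, seed=3)
        assert sorted(r.name for r in out.reads1) == [r.name for r in rs.reads1]
        assert sorted(out.reads1, key=lambda r: r.name) == list(rs.reads1)
        assert meta.params["permutation"] != [0, 1, 2, 3]

    def test_mates_stay_at_equal_indices(self):
        rs = _paired_set(6)
        out, _ = mr1_permute(rs, seed=7)
        for r1, r2 in zip(out.reads1, out.reads2):
            assert r1.name == r2.name


class TestMR2Revcomp:
    def test_palindromic_sequence_keeps_bases_reverses_quality(self):
        rs = _single_set("ACGT", qual="IIHH")
        out, _ = mr2_revcomp(rs)
        assert out.reads1[0].sequence == "ACGT"
        assert out.reads1[0].quality == "HHII"

    def test_complement_rules(self):
        out, _ = mr2_revcomp(_single_set("AAAC"))
        assert out.reads1[0].sequence == "GTTT"

    def test_file_order_reversed(self):
        rs = _single_set("AAAA", "CCCC")
        out, _ = mr2_revcomp(rs)
        assert [r.name for r in out.reads1] == ["r1", "r0"]

    @settings(max_examples=40, derandomize=True)
    @given(reads=st.lists(read_records(), min_size=1, max_size=6))
    def test_involution(self, reads):
        rs = ReadSet.single(reads)
        twice, _ = mr2_revcomp(mr2_revcomp(rs)[0])
        assert twice == rs


class TestMR3Duplicate:
    def test_doubles_and_preserves_originals(self):
        rs = _single_set("AAAA", "CCCC", "GGGG")
        out, meta = mr3_duplicate(rs)
        assert len(out) == 6
        assert out.reads1[:3] == rs.reads1
        assert meta.name_map[f"r1{DUPLICATE_SUFFIX}"] == "r1"
        seqs = sorted(r.sequence for r in out.reads1)
        assert seqs == sorted(["AAAA", "CCCC", "GGGG"] * 2)

    def test_reserved_suffix_collision_rejected(self):
        rs = ReadSet.single([ReadRecord("x" + DUPLICATE_SUFFIX, "AC", "II")])
        with pytest.raises(TransformError):
            mr3_duplicate(rs)


class TestMR4Halve:
    def test_even_index_retention(self):
        rs = _single_set("AAAA", "CCCC", "GGGG", "TTTT")
        out, _ = mr4_halve(rs)
        assert [r.name for r in out.reads1] == ["r0", "r2"]
        assert out.reads1[0] == rs.reads1[0]

    @pytest.mark.parametrize("n,expected", [(2, 1), (5, 3), (6, 3)])
    def test_ceil_half_retained(self, n, expected):
        out, _ = mr4_halve(_paired_set(n))
        assert len(out) == expected

    def test_single_read_rejected(self):
        with pytest.raises(TransformError):
            mr4_halve(_single_set("ACGT"))


class TestMR5Extend:
    def test_plus_strand_extension_from_reference(self, small_reference):
        seq = small_reference["chr_t"]
        read = ReadRecord("r0", seq[:10], "I" * 10)
        src = AlignmentResult.from_records(
            [AlignmentRecord(read_name="r0", role="single", mapped=True,
                             contig="chr_t", pos=1, strand="+", cigar="10M")]
        )
        out, _ = mr5_extend(ReadSet.single([read]), src, small_reference)
        ext = out.reads1[0]
        assert len(ext) == 30
        assert ext.sequence == seq[:30]
        assert ext.quality[10:] == "J" * 20

    def test_minus_strand_appends_revcomp_of_upstream(self, small_reference):
        from mrtest import reverse_complement
        seq = small_reference["chr_t"]
        read_seq = reverse_complement(seq[30:40])
        read = ReadRecord("r0", read_seq, "I" * 10)
        src = AlignmentResult.from_records(
            [AlignmentRecord(read_name="r0", role="single", mapped=True,
                             contig="chr_t", pos=31, strand="-", cigar="10M")]
        )
        out, _ = mr5_extend(ReadSet.single([read]), src, small_reference)
        ext = out.reads1[0]
        assert ext.sequence == read_seq + reverse_complement(seq[10:30])

    def test_unmapped_read_unchanged_and_boundary_truncation(self,
                                                             small_reference):
        seq = small_reference["chr_t"]
        reads = ReadSet.single([
            ReadRecord("u", "ACGT", "IIII"),
            ReadRecord("e", seq[50:60], "I" * 10),  # 10 bp from contig end
        ])
        src = AlignmentResult.from_records([
            _unmapped("u"),
            AlignmentRecord(read_name="e", role="single", mapped=True,
                            contig="chr_t", pos=51, strand="+", cigar="10M"),
        ])
        out, _ = mr5_extend(reads, src, small_reference)
        assert out.reads1[0] == reads.reads1[0]
        assert len(out.reads1[1]) == 10  # nothing beyond the contig end

    def test_missing_record_is_harness_error(self, small_reference):
        with pytest.raises(HarnessError):
            mr5_extend(_single_set("ACGT"), AlignmentResult(), small_reference)


class TestMR6MR7Selection:
    def _source(self):
        return AlignmentResult.from_records([
            _mapped("r0"), _unmapped("r1"), _mapped("r2"), _mapped("r3"),
            _unmapped("r4"),
        ])

    def test_mr6_keeps_only_unmapped(self):
        rs = _single_set(*["ACGT"] * 5)
        out, _ = mr6_select_unmapped(rs, self._source())
        assert [r.name for r in out.reads1] == ["r1", "r4"]

    def test_mr6_all_mapped_gives_empty_set(self):
        rs = _single_set("ACGT", "ACGT")
        src = AlignmentResult.from_records([_mapped("r0"), _mapped("r1")])
        out, _ = mr6_select_unmapped(rs, src)
        assert len(out) == 0

    def test_mr6_paired_excludes_half_unmapped_pairs(self):
        rs = _paired_set(2)
        src = AlignmentResult.from_records([
            _mapped("p0", "read1"), _unmapped("p0", "read2"),
            _unmapped("p1", "read1"), _unmapped("p1", "read2"),
        ])
        out, _ = mr6_select_unmapped(rs, src)
        assert [r.name for r in out.reads1] == ["p1"]

    def test_mr7_single_end_includes_mapq0_mapped_reads(self):
        rs = _single_set("ACGT", "ACGT")
        src = AlignmentResult.from_records(
            [_mapped("r0", mapq=0), _unmapped("r1")]
        )
        out, _ = mr7_select_mapped(rs, src)
        assert [r.name for r in out.reads1] == ["r0"]

    def test_mr7_paired_requires_proper_pairing(self):
        rs = _paired_set(2)
        src = AlignmentResult.from_records([
            _mapped("p0", "read1"), _mapped("p0", "read2"),  # mapped, improper
            _mapped("p1", "read1", properly_paired=True),
            _mapped("p1", "read2", properly_paired=True),
        ])
        out, _ = mr7_select_mapped(rs, src)
        assert [r.name for r in out.reads1] == ["p1"]


class TestMR8BoostQuality:
    def test_phred_arithmetic(self):
        rs = ReadSet.single([ReadRecord("r0", "AC", "!!")])
        src = AlignmentResult.from_records([_mapped("r0", length=2)])
        out, _ = mr8_boost_quality(rs, src, delta=10)
        assert out.reads1[0].quality == "++"  # Phred 0 -> 10

    def test_cap_at_q41_and_unmapped_untouched(self):
        rs = ReadSet.single([ReadRecord("r0", "AC", "JJ"),
                             ReadRecord("r1", "AC", "!!")])
        src = AlignmentResult.from_records(
            [_mapped("r0", length=2), _unmapped("r1")]
        )
        out, _ = mr8_boost_quality(rs, src, delta=30)
        assert out.reads1[0].quality == "JJ"
        assert out.reads1[1].quality == "!!"


class TestMR9Correct:
    def test_identical_read_unchanged(self, small_reference):
        seq = small_reference["chr_t"]
        rs = ReadSet.single([ReadRecord("r0", seq[10:20], "I" * 10)])
        src = AlignmentResult.from_records(
            [AlignmentRecord(read_name="r0", role="single", mapped=True,
                             contig="chr_t", pos=11, strand="+", cigar="10M")]
        )
        out, _ = mr9_correct_mismatches(rs, src, small_reference)
        assert out.reads1[0].sequence == seq[10:20]

    def test_mismatch_replaced_by_reference_base(self, small_reference):
        seq = small_reference["chr_t"]
        bad = list(seq[10:20])
        bad[3] = "ACGT"[("ACGT".index(bad[3]) + 1) % 4]
        rs = ReadSet.single([ReadRecord("r0", "".join(bad), "I" * 10)])
        src = AlignmentResult.from_records(
            [AlignmentRecord(read_name="r0", role="single", mapped=True,
                             contig="chr_t", pos=11, strand="+", cigar="10M")]
        )
        out, _ = mr9_correct_mismatches(rs, src, small_reference)
        assert out.reads1[0].sequence == seq[10:20]
        assert out.reads1[0].quality == "I" * 10  # untouched

    def test_minus_strand_correction_is_complement(self, small_reference):
        from mrtest import reverse_complement
        seq = small_reference["chr_t"]
        true_read = reverse_complement(seq[20:30])
        bad = list(true_read)
        bad[2] = "ACGT"[("ACGT".index(bad[2]) + 1) % 4]
        rs = ReadSet.single([ReadRecord("r0", "".join(bad), "I" * 10)])
        src = AlignmentResult.from_records(
            [AlignmentRecord(read_name="r0", role="single", mapped=True,
                             contig="chr_t", pos=21, strand="-", cigar="10M")]
        )
        out, _ = mr9_correct_mismatches(rs, src, small_reference)
        assert out.reads1[0].sequence == true_read

    def test_unsupported_cigar_names_read(self, small_reference):
        from mrtest.metamorphic_relations import UnsupportedCigarError
        rs = _single_set("ACGTACGTAC")
        src = AlignmentResult.from_records(
            [AlignmentRecord(read_name="r0", role="single", mapped=True,
                             contig="chr_t", pos=1, strand="+",
                             cigar="5M2I3M")]
        )
        with pytest.raises(UnsupportedCigarError, match="r0"):
            mr9_correct_mismatches(rs, src, small_reference)


class TestCheckRelation:
    def _meta(self, mr_id, names):
        return TransformMetadata(mr_id, {n: n for n in names})

    def test_identical_results_pass(self):
        res = AlignmentResult.from_records([_mapped("r0"), _unmapped("r1")])
        rep = check_relation("MR1", res, res, self._meta("MR1", ["r0", "r1"]))
        assert rep.verdict is Verdict.PASS and rep.n_discordant == 0

    def test_single_moved_read_fails(self):
        src = AlignmentResult.from_records([_mapped("r0"), _mapped("r1")])
        fu = AlignmentResult.from_records([_mapped("r0"),
                                           _mapped("r1", pos=250)])
        rep = check_relation("MR1", src, fu, self._meta("MR1", ["r0", "r1"]))
        assert rep.verdict is Verdict.FAIL
        assert rep.n_discordant == 1
        assert rep.diffs[0].key == ("r1", "single")
        assert "pos" in rep.diffs[0].fields

    def test_mr6_any_mapped_read_fails(self):
        src = AlignmentResult.from_records([_unmapped("r0")])
        fu = AlignmentResult.from_records([_mapped("r0")])
        rep = check_relation("MR6", src, fu, self._meta("MR6", ["r0"]))
        assert rep.verdict is Verdict.FAIL

    def test_mr7_moved_multimapper_fails(self):
        src = AlignmentResult.from_records([_mapped("r0", mapq=0)])
        fu = AlignmentResult.from_records([_mapped("r0", pos=77, mapq=0)])
        rep = check_relation("MR7", src, fu, self._meta("MR7", ["r0"]))
        assert rep.verdict is Verdict.FAIL

    def test_mr7_unmapped_followup_fails(self):
        src = AlignmentResult.from_records([_mapped("r0")])
        fu = AlignmentResult.from_records([_unmapped("r0")])
        rep = check_relation("MR7", src, fu, self._meta("MR7", ["r0"]))
        assert rep.verdict is Verdict.FAIL
        assert rep.diffs[0].fields == ("mapped",)

    def test_mr3_duplicate_checked_against_original(self):
        src = AlignmentResult.from_records([_mapped("r0", pos=5)])
        fu = AlignmentResult.from_records([
            _mapped("r0", pos=5),
            _mapped(f"r0{DUPLICATE_SUFFIX}", pos=9),
        ])
        meta = TransformMetadata(
            "MR3", {"r0": "r0", f"r0{DUPLICATE_SUFFIX}": "r0"}
        )
        rep = check_relation("MR3", src, fu, meta)
        assert rep.verdict is Verdict.FAIL
        assert rep.diffs[0].key == (f"r0{DUPLICATE_SUFFIX}", "single")

    def test_name_not_in_map_is_harness_error(self):
        src = AlignmentResult.from_records([_mapped("r0")])
        fu = AlignmentResult.from_records([_mapped("mystery")])
        with pytest.raises(HarnessError):
            check_relation("MR1", src, fu, self._meta("MR1", ["r0"]))

    def test_mr4_reports_coverage_ratio(self):
        ref = Reference(sequences={"c": "A" * 1000})
        src = AlignmentResult.from_records(
            [_mapped(f"r{i}", pos=1 + 10 * i, length=50) for i in range(4)]
        )
        fu = AlignmentResult.from_records(
            [_mapped(f"r{i}", pos=1 + 10 * i, length=50) for i in (0, 2)]
        )
        rep = check_relation("MR4", src, fu,
                             self._meta("MR4", ["r0", "r2"]), reference=ref)
        assert rep.verdict is Verdict.PASS
        assert rep.coverage_ratio == pytest.approx(0.5)
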