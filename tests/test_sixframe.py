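import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ampmine.seqio import SequenceRecord
from ampmine.sixframe import (
    FRAMES,
    find_orfs,
    map_protein_span_to_nt,
    merge_overlapping_contigs,
    reverse_complement,
    six_frame_translate,
    translate_frame,
)

from oracles import oracle_orfs, oracle_translate_frame

nt_seqs = st.text(alphabet="ACGTN", min_size=1, max_size=300)


def _record(seq, identifier="contig1"):
    return SequenceRecord(identifier, "", seq, "nucleotide")


class TestReverseComplement:
    def test_examples(self):
        assert reverse_complement("ATGC") == "GCAT"
        assert reverse_complement("NNN") == "NNN"

    @given(seq=nt_seqs)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_rejects_other_characters(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")


class TestTranslation:
    def test_standard_code_examples(self):
        assert translate_frame("ATGAAA", 1) == "MK"
        assert translate_frame("TTTCAT", -1) == "MK"

    def test_short_sequence_gives_empty_protein(self):
        assert translate_frame("AT", 1) == ""
        assert translate_frame("ATGA", 3) == ""

    def test_agrees_with_codon_oracle_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=300, p=[0.24] * 4 + [0.04]))
        for frame in FRAMES:
            assert translate_frame(seq, frame) == oracle_translate_frame(seq, frame)

    def test_six_frames_of_a_9mer_have_lengths_322322(self):
        fts = six_frame_translate(_record("ATGAAATTT"))
        assert [ft.frame for ft in fts] == list(FRAMES)
        assert [len(ft.protein) for ft in fts] == [3, 2, 2, 3, 2, 2]

    def test_each_mapped_codon_retranslates_to_its_residue(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100))
        contig = _record(seq)
        for ft in six_frame_translate(contig):
            for i in range(1, len(ft.protein) + 1):
                start = ft.codon_first_base(i)
                if ft.frame > 0:
                    codon = seq[start - 1 : start + 2]
                else:
                    codon = reverse_complement(seq[start - 3 : start])
                assert translate_frame(codon, 1) == ft.protein[i - 1]

    def test_plus_frames_of_reverse_complement_equal_minus_frames(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=99))
        fwd = six_frame_translate(_record(seq))
        rev = six_frame_translate(_record(reverse_complement(seq)))
        for f in (1, 2, 3):
            assert fwd[f - 1].protein == rev[f + 2].protein


class TestMapProteinSpan:
    def test_plus_frame_examples(self):
        ft = six_frame_translate(_record("ATGAAATTT"))[0]
        assert map_protein_span_to_nt(ft, 1, 2) == (1, 6, "+")
        ft2 = six_frame_translate(_record("ATGAAATTT"))[1]
        assert map_protein_span_to_nt(ft2, 1, 1) == (2, 4, "+")

    def test_out_of_range_raises(self):
        ft = six_frame_translate(_record("ATGAAATTT"))[0]
        with pytest.raises(IndexError):
            map_protein_span_to_nt(ft, 1, 4)

    def test_random_spans_retranslate_to_protein_slice(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=120))
        contig = _record(seq)
        for ft in six_frame_translate(contig):
            n = len(ft.protein)
            for _ in range(10):
                a, b = sorted(rng.integers(1, n + 1, size=2))
                start, end, strand = map_protein_span_to_nt(ft, a, b)
                assert end - start + 1 == 3 * (b - a + 1)
                sub = seq[start - 1 : end]
                if strand == "-":
                    sub = reverse_complement(sub)
                assert translate_frame(sub, 1) == ft.protein[a - 1 : b]


class TestFindOrfs:
    def test_smallest_complete_case(self):
        orfs = find_orfs(_record("ATGAAATAA"), min_aa=1)
        complete = [o for o in orfs if o.completeness == "complete"]
        assert len(complete) == 1
        orf = complete[0]
        assert (orf.start_nt, orf.end_nt, orf.protein) == (1, 6, "MK")

    def test_matches_enumeration_oracle_on_random_contigs(self, rng):
        for _ in range(60):
            length = int(rng.integers(30, 400))
            seq = "".join(rng.choice(list("ACGTN"), size=length, p=[0.24] * 4 + [0.04]))
            got = {
                (o.strand, o.start_nt, o.end_nt, o.protein, o.completeness)
                for o in find_orfs(_record(seq), min_aa=5)
            }
            assert got == oracle_orfs(seq, 5)

    def test_reported_orfs_satisfy_invariants(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=600))
        for orf in find_orfs(_record(seq), min_aa=10):
            assert orf.end_nt - orf.start_nt + 1 == 3 * len(orf.protein)
            assert "*" not in orf.protein
            if orf.completeness == "complete":
                assert orf.protein.startswith("M")
                if orf.strand == "+":
                    stop = seq[orf.end_nt : orf.end_nt + 3]
                else:
                    stop = reverse_complement(seq[orf.start_nt - 4 : orf.start_nt - 1])
                assert stop in ("TAA", "TAG", "TGA")


class TestMerge:
    def test_simple_overlap(self):
        a = _record("AAACCC", "A")
        b = _record("CCCGGG", "B")
        join = merge_overlapping_contigs(a, b, min_overlap=3)
        assert join is not None
        assert join.merged.residues == "AAACCCGGG"
        assert join.merged.identifier == "A+B"
        assert join.overlap_len == 3

    def test_no_shared_30mer_gives_none(self, rng):
        a = _record("".join(rng.choice(list("AC"), size=100)), "A")
        b = _record("".join(rng.choice(list("GT"), size=100)), "B")
        assert merge_overlapping_contigs(a, b, min_overlap=30) is None

    def test_reverse_orientation_is_tried(self):
        a = _record("TTGAACGCATGC", "A")
        b_forward = "ACGCATGCTTAG"  # shares the 8-mer ACGCATGC with a's tail
        b = _record(reverse_complement(b_forward), "B")
        join = merge_overlapping_contigs(a, b, min_overlap=8)
        assert join is not None
        assert join.merged.residues == "TTGAACGCATGCTTAG"
        assert join.b_reversed

    def test_inputs_are_substrings_of_merge(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=200))
        a = _record(core[:120], "A")
        b = _record(core[80:], "B")
        join = merge_overlapping_contigs(a, b, min_overlap=30)
        assert join is not None and join.merged.residues == core
        assert a.residues in join.merged.residues
        assert b.residues in join.merged.residues
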