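import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from ampmine.align import (
    ScoringScheme,
    search_amps_vs_proteins,
    search_amps_vs_sixframe,
    smith_waterman,
)
from ampmine.seqio import AMPReferenceEntry, SequenceRecord
from ampmine.sixframe import reverse_complement

from oracles import naive_sw_score

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_peptide(rng, max_len=30, min_len=3):
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(AA), size=n))


class TestSmithWaterman:
    def test_cysteine_decamer_scores_ninety(self):
        result = smith_waterman("C" * 10, "C" * 10)
        assert result.score == 90  # 10 x BLOSUM62 C/C = 9
        assert result.a_span == (1, 10) and result.b_span == (1, 10)

    def test_disjoint_residues_score_zero(self):
        result = smith_waterman("MKVL", "WWWW")
        assert result.score <= 11  # nothing near a mining threshold
        assert smith_waterman("KKKK", "DDDD").score == 0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACD")

    def test_self_alignment_equals_diagonal_sum(self, rng):
        scheme = ScoringScheme()
        for _ in range(20):
            pep = _random_peptide(rng)
            expected = sum(scheme.score_pair(c, c) for c in pep)
            assert smith_waterman(pep, pep, scheme).score == expected

    def test_score_symmetric_in_arguments(self, rng):
        for _ in range(30):
            a, b = _random_peptide(rng), _random_peptide(rng)
            assert smith_waterman(a, b).score == smith_waterman(b, a).score

    def test_matches_naive_gotoh_oracle(self, rng):
        for _ in range(60):
            a, b = _random_peptide(rng), _random_peptide(rng)
            assert smith_waterman(a, b).score == naive_sw_score(a, b)

    def test_matches_biopython_pairwise_aligner(self, rng):
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        for _ in range(40):
            a, b = _random_peptide(rng), _random_peptide(rng)
            ours = smith_waterman(a, b).score
            theirs = int(aligner.score(a, b))
            assert ours == max(theirs, 0)

    def test_identity_never_exceeds_positives(self, rng):
        for _ in range(20):
            a, b = _random_peptide(rng), _random_peptide(rng)
            result = smith_waterman(a, b)
            assert result.identity <= result.positive + 1e-9


class TestSearches:
    def test_planted_substring_yields_single_hit_with_span(self):
        amp = AMPReferenceEntry("AP00001", "planted", "CKRWCNACRKWC")
        protein = SequenceRecord(
            "prot1", "", "MGGG" + "CKRWCNACRKWC" + "GGGL", "protein"
        )
        hits = search_amps_vs_proteins([amp], [protein], min_score=50)
        assert len(hits) == 1
        assert hits[0].subject_protein_span == (5, 16)
        assert hits[0].percent_identity == 100.0

    def test_empty_protein_list_gives_no_hits(self):
        amp = AMPReferenceEntry("AP00001", "planted", "CKRWCNACRKWC")
        assert search_amps_vs_proteins([amp], []) == []

    def test_no_emitted_hit_below_min_score(self, rng):
        amps = [
            AMPReferenceEntry(f"AP0000{i}", "r", _random_peptide(rng, 25, 10))
            for i in range(1, 4)
        ]
        proteins = [
            SequenceRecord(f"p{i}", "", _random_peptide(rng, 80, 40), "protein")
            for i in range(5)
        ]
        for min_score in (10, 25):
            for hit in search_amps_vs_proteins(amps, proteins, min_score=min_score):
                assert hit.score >= min_score

    def test_minus_strand_hit_maps_to_forward_span(self, rng):
        from ampmine.synthdata import _reverse_translate

        peptide = "MCKRWCNACRKWCAARNDC"
        cds = _reverse_translate(rng, peptide)
        flank5 = "".join(rng.choice(list("ACGT"), size=33))
        flank3 = "".join(rng.choice(list("ACGT"), size=21))
        contig_fwd = flank5 + cds + flank3
        contig = SequenceRecord(
            "ctg", "", reverse_complement(contig_fwd), "nucleotide"
        )
        amp = AMPReferenceEntry("AP00002", "planted", peptide)
        hits = search_amps_vs_sixframe([amp], [contig], min_score=60)
        assert hits, "planted minus-strand peptide not found"
        hit = hits[0]
        assert hit.frame < 0
        lo, hi = hit.subject_nt_span
        sub = reverse_complement(contig.residues[lo - 1 : hi])
        # re-translating the reported forward-strand span recovers the peptide
        from ampmine.sixframe import translate_frame

        q_lo, q_hi = hit.query_span
        assert translate_frame(sub, 1) == peptide[q_lo - 1 : q_hi]

    def test_percent_positive_threshold_mode(self):
        amp = AMPReferenceEntry("AP00004", "r", "CKRWCNACRKWC")
        subject = SequenceRecord("s", "", "GG" + amp.mature_sequence + "GG", "protein")
        hits = search_amps_vs_proteins(
            [amp], [subject], min_score=90, threshold_on="percent_positive"
        )
        assert len(hits) == 1 and hits[0].percent_positive == 100.0
        with pytest.raises(ValueError, match="threshold mode"):
            search_amps_vs_proteins([amp], [subject], threshold_on="evalue")

    def test_hits_sorted_by_score_then_subject(self, rng):
        amp = AMPReferenceEntry("AP00003", "r", "CKRWCNACRKWCAA")
        exact = SequenceRecord("b_exact", "", "G" + amp.mature_sequence + "G", "protein")
        partial = SequenceRecord(
            "a_partial", "", "G" + amp.mature_sequence[:10] + "GGGG", "protein"
        )
        hits = search_amps_vs_proteins([amp], [exact, partial], min_score=20)
        assert [h.subject_id for h in hits] == ["b_exact", "a_partial"]
        assert hits[0].score > hits[1].score
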