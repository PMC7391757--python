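import dataclasses
import json

import numpy as np
import pytest

from ampmine.align import ScoringScheme, search_amps_vs_sixframe
from ampmine.annotate import (
    detect_alf_loop,
    detect_kazal,
    detect_wap,
    physchem_profile,
    predict_signal_peptide,
)
from ampmine.expression import tier
from ampmine.seqio import SequenceRecord
from ampmine.sixframe import find_orfs, merge_overlapping_contigs
from ampmine.synthdata import (
    TABLE2_LIBRARIES,
    generate_counts,
    generate_dataset,
    generate_precursor,
    generate_transcriptome,
    load_truth,
    write_truth,
)

DETECTOR = {
    "paralithocin": lambda m: m.count("C") == 8,
    "crustin": lambda m: detect_wap(m) is not None,
    "alf": lambda m: detect_alf_loop(m) is not None,
    "kazal": lambda m: detect_kazal(m) is not None,
    "buforin_like": lambda m: m.startswith("M"),
}


class TestPrecursors:
    @pytest.mark.parametrize("family", list(DETECTOR))
    def test_constructive_guarantees(self, family):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            sp, mature = generate_precursor(rng, family)
            assert DETECTOR[family](mature), f"{family} pattern failed at seed {seed}"
            assert physchem_profile(mature).passes_amp_screen
            if family == "buforin_like":
                assert sp == ""
                # histone-derived: no signal peptide may be called
                assert predict_signal_peptide(mature) is None
            else:
                call = predict_signal_peptide(sp + mature)
                assert call is not None
                assert call.cleavage_after == len(sp)

    def test_unsupported_family_raises(self):
        with pytest.raises(ValueError):
            generate_precursor(np.random.default_rng(0), "defensin")

    def test_same_seed_same_precursor(self):
        a = generate_precursor(np.random.default_rng(42), "crustin")
        b = generate_precursor(np.random.default_rng(42), "crustin")
        assert a == b


class TestTranscriptome:
    def test_same_seed_reproduces_dataset_exactly(self):
        c1, r1, k1, t1 = generate_dataset(5, n_planted=6, n_decoys=10)
        c2, r2, k2, t2 = generate_dataset(5, n_planted=6, n_decoys=10)
        assert [(c.identifier, c.residues) for c in c1] == [
            (c.identifier, c.residues) for c in c2
        ]
        assert [dataclasses.asdict(g) for g in t1.genes] == [
            dataclasses.asdict(g) for g in t2.genes
        ]
        assert k1.counts == k2.counts

    def test_planted_orf_coordinates_are_found_verbatim(self, small_dataset):
        contigs, _refs, _counts, truth = small_dataset
        by_id = {c.identifier: c for c in contigs}
        for gene in truth.genes:
            if gene.contig_layout != "single":
                continue
            orfs = find_orfs(by_id[gene.contig_ids[0]], min_aa=25)
            spans = {
                (o.start_nt, o.end_nt, o.completeness, o.protein) for o in orfs
            }
            assert (
                gene.orf_start_nt,
                gene.orf_end_nt,
                "complete",
                gene.precursor,
            ) in spans

    def test_split_pair_reassembles_the_planted_transcript(self, small_dataset):
        contigs, _refs, _counts, truth = small_dataset
        by_id = {c.identifier: c for c in contigs}
        split_genes = [g for g in truth.genes if g.contig_layout == "split_pair"]
        assert split_genes, "dataset should contain a split gene"
        for gene in split_genes:
            a, b = (by_id[i] for i in gene.contig_ids)
            join = merge_overlapping_contigs(a, b, min_overlap=30)
            assert join is not None
            merged_orfs = find_orfs(join.merged, min_aa=25)
            assert any(
                (o.start_nt, o.end_nt, o.protein)
                == (gene.orf_start_nt, gene.orf_end_nt, gene.precursor)
                for o in merged_orfs
            )

    def test_truncated_layouts_carry_fragment_completeness(self, small_dataset):
        contigs, _refs, _counts, truth = small_dataset
        by_id = {c.identifier: c for c in contigs}
        for gene in truth.genes:
            if gene.contig_layout not in (
                "five_prime_truncated",
                "three_prime_truncated",
            ):
                continue
            orfs = find_orfs(by_id[gene.contig_ids[0]], min_aa=25)
            assert any(
                (o.start_nt, o.end_nt, o.completeness)
                == (gene.orf_start_nt, gene.orf_end_nt, gene.completeness)
                for o in orfs
            )

    def test_no_decoy_reaches_the_mining_threshold(self):
        rng = np.random.default_rng(11)
        contigs, truth = generate_transcriptome(rng, n_planted=4, n_decoys=15)
        decoys = [c for c in contigs if c.identifier in set(truth.decoy_ids)]
        from ampmine.synthdata import generate_reference

        refs = generate_reference(truth)
        hits = search_amps_vs_sixframe(refs, decoys, ScoringScheme(), min_score=90)
        assert hits == []

    def test_decoy_free_dataset(self):
        rng = np.random.default_rng(3)
        contigs, truth = generate_transcriptome(rng, n_planted=0, n_decoys=5)
        assert truth.genes == []
        assert len(contigs) == 5


class TestCounts:
    def test_high_tier_exceeds_3000_in_at_least_95_percent_of_seeds(self):
        _contigs, _refs, _counts, truth = generate_dataset(2, n_planted=6, n_decoys=0)
        high_ids = [g.contig_ids[0] for g in truth.genes if g.tier == "high"]
        assert high_ids
        successes = 0
        trials = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            counts = generate_counts(rng, truth)
            for gid in high_ids:
                trials += 1
                total = sum(counts.get(gid, lib) for lib in counts.library_ids)
                if total > 3000:
                    successes += 1
        assert successes / trials >= 0.95

    def test_low_tier_genes_tier_low(self, default_dataset):
        _contigs, _refs, counts, truth = default_dataset
        for gene in truth.genes:
            if gene.tier == "low":
                total = sum(
                    counts.get(gene.contig_ids[0], lib) for lib in counts.library_ids
                )
                assert tier(total) == "low"

    def test_libraries_default_to_study_names(self, default_dataset):
        _contigs, _refs, counts, _truth = default_dataset
        assert counts.library_ids == TABLE2_LIBRARIES

    def test_totals_cover_column_sums(self, default_dataset):
        _contigs, _refs, counts, _truth = default_dataset
        for lib in counts.library_ids:
            assert counts.library_totals[lib] >= counts.column_sum(lib)

    def test_same_seed_same_counts(self, default_dataset):
        _contigs, _refs, _counts, truth = default_dataset
        a = generate_counts(np.random.default_rng(9), truth)
        b = generate_counts(np.random.default_rng(9), truth)
        assert a.counts == b.counts


class TestTruthSerialization:
    def test_round_trip(self, tmp_path, small_dataset):
        _contigs, _refs, _counts, truth = small_dataset
        path = tmp_path / "truth.json"
        write_truth(truth, path)
        back = load_truth(path)
        assert [dataclasses.asdict(g) for g in back.genes] == [
            dataclasses.asdict(g) for g in truth.genes
        ]
        assert back.decoy_ids == truth.decoy_ids

    def test_truth_invariants(self, small_dataset):
        contigs, _refs, _counts, truth = small_dataset
        contig_ids = {c.identifier for c in contigs}
        gene_contigs = {cid for g in truth.genes for cid in g.contig_ids}
        assert set(truth.decoy_ids).isdisjoint(gene_contigs)
        assert gene_contigs <= contig_ids
        for gene in truth.genes:
            assert (
                gene.orf_end_nt - gene.orf_start_nt + 1
                == 3 * len(gene.orf_protein)
            )
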