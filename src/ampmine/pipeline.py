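"""End-to-end candidate mining: search, delineation, joining, reporting.

``mine`` runs both search approaches — ORF proteins against the reference
peptides (blastp-style) and references against all six frame translations of
every contig (tblastn-style) — unions the hits, delineates the containing
ORF for each, joins split gene models across overlapping contigs, annotates
(signal peptide, domains, physicochemistry, family), deduplicates loci, and
assigns family-wise gene identifiers (PcPar1, PcCrs1, ...).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .align import (
    AlignmentHit,
    ScoringScheme,
    search_amps_vs_proteins,
    search_amps_vs_sixframe,
)
from .annotate import (
    DomainHit,
    PhysChemProfile,
    SignalPeptideCall,
    classify_family,
    detect_alf_loop,
    detect_kazal,
    detect_wap,
    flag_embedded,
    physchem_profile,
    predict_signal_peptide,
)
from .seqio import (
    AMPReferenceEntry,
    SequenceRecord,
    write_candidate_table,
)
from .sixframe import OpenReadingFrame, find_orfs, merge_overlapping_contigs

logger = logging.getLogger(__name__)

#: a hit counts as "at a contig edge" when its nucleotide span ends within
#: this many bases of the contig boundary (ten codons)
JOIN_EDGE_NT = 30


@dataclass
class PipelineConfig:
    """Tunable knobs of a mining run."""

    min_score: int = 90
    min_orf_aa: int = 25
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    join_min_overlap: int = 30
    max_mature_len: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_score", "min_orf_aa", "join_min_overlap", "max_mature_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AMPCandidate:
    """One reported candidate: ORF + best hit + annotation."""

    gene_id: str
    contig_ids: list[str]
    orf: OpenReadingFrame
    best_hit: AlignmentHit
    best_hit_name: str
    signal_peptide: SignalPeptideCall | None
    domains: list[DomainHit]
    physchem: PhysChemProfile
    family: str
    embedded: bool

    @property
    def mature_protein(self) -> str:
        if self.signal_peptide is None:
            return self.orf.protein
        return self.orf.protein[self.signal_peptide.cleavage_after :]


def _orf_key(orf: OpenReadingFrame) -> tuple:
    return (orf.contig_id, orf.frame, orf.protein_start, orf.protein_end)


def _hit_better(a: AlignmentHit, b: AlignmentHit) -> bool:
    """True when a outranks b (higher score, then lexicographic accession)."""
    return (-a.score, a.query_id) < (-b.score, b.query_id)


def _containing_orf(
    hit: AlignmentHit, orfs: list[OpenReadingFrame]
) -> OpenReadingFrame | None:
    lo, hi = hit.subject_protein_span
    for orf in orfs:
        if (
            orf.contig_id == hit.subject_id
            and orf.frame == hit.frame
            and orf.protein_start <= lo
            and hi <= orf.protein_end
        ):
            return orf
    return None


def _orf_relative(hit: AlignmentHit, orf: OpenReadingFrame) -> AlignmentHit:
    """Re-express a six-frame hit's subject span relative to the ORF protein."""
    lo, hi = hit.subject_protein_span
    shift = orf.protein_start - 1
    return dataclasses.replace(hit, subject_protein_span=(lo - shift, hi - shift))


def _collect_candidates(
    contigs: list[SequenceRecord],
    amps: list[AMPReferenceEntry],
    config: PipelineConfig,
    orfs_by_contig: dict[str, list[OpenReadingFrame]],
) -> dict[tuple, tuple[OpenReadingFrame, AlignmentHit]]:
    """Run both search approaches and key the best hit per ORF."""
    best: dict[tuple, tuple[OpenReadingFrame, AlignmentHit]] = {}

    def _offer(orf: OpenReadingFrame, hit: AlignmentHit) -> None:
        key = _orf_key(orf)
        if key not in best or _hit_better(hit, best[key][1]):
            best[key] = (orf, hit)

    # approach A: references vs ORF proteins
    protein_records = []
    orf_by_record_id: dict[str, OpenReadingFrame] = {}
    for contig_id in sorted(orfs_by_contig):
        for i, orf in enumerate(orfs_by_contig[contig_id]):
            rec_id = f"{contig_id}::orf{i}"
            orf_by_record_id[rec_id] = orf
            protein_records.append(
                SequenceRecord(rec_id, "", orf.protein, "protein")
            )
    if protein_records:
        for hit in search_amps_vs_proteins(
            amps, protein_records, config.scheme, config.min_score
        ):
            orf = orf_by_record_id[hit.subject_id]
            _offer(orf, dataclasses.replace(hit, subject_id=orf.contig_id))

    # approach B: references vs six-frame translations
    for hit in search_amps_vs_sixframe(amps, contigs, config.scheme, config.min_score):
        orf = _containing_orf(hit, orfs_by_contig.get(hit.subject_id, []))
        if orf is None:
            logger.warning(
                "hit %s vs %s (frame %s) spans no single ORF; dropped",
                hit.query_id, hit.subject_id, hit.frame,
            )
            continue
        _offer(orf, _orf_relative(hit, orf))
    return best


def _near_edge(hit: AlignmentHit, contig_len: int) -> bool:
    if hit.subject_nt_span is None:
        return False
    lo, hi = hit.subject_nt_span
    return lo <= JOIN_EDGE_NT or contig_len - hi <= JOIN_EDGE_NT


def _attempt_joins(
    contigs: list[SequenceRecord],
    amps: list[AMPReferenceEntry],
    config: PipelineConfig,
) -> list[tuple[SequenceRecord, list[str]]]:
    """Find split gene models: one reference hitting two contigs at edges.

    Returns merged pseudo-contigs along with their source contig ids.
    """
    by_id = {c.identifier: c for c in contigs}
    sixframe_hits = search_amps_vs_sixframe(
        amps, contigs, config.scheme, config.min_score
    )
    per_query: dict[str, list[AlignmentHit]] = {}
    for hit in sixframe_hits:
        per_query.setdefault(hit.query_id, []).append(hit)
    merged: list[tuple[SequenceRecord, list[str]]] = []
    seen_pairs: set[frozenset] = set()
    for query_id in sorted(per_query):
        hits = per_query[query_id]
        contig_ids = sorted({h.subject_id for h in hits})
        if len(contig_ids) != 2:
            continue
        pair = frozenset(contig_ids)
        if pair in seen_pairs:
            continue
        edge_ok = all(
            any(
                _near_edge(h, len(by_id[cid].residues))
                for h in hits
                if h.subject_id == cid
            )
            for cid in contig_ids
        )
        if not edge_ok:
            continue
        a, b = by_id[contig_ids[0]], by_id[contig_ids[1]]
        join = merge_overlapping_contigs(a, b, config.join_min_overlap)
        if join is None:
            continue
        seen_pairs.add(pair)
        merged.append((join.merged, [a.identifier, b.identifier]))
    return merged


def _annotate(
    orf: OpenReadingFrame,
    hit: AlignmentHit,
    contig_ids: list[str],
    names: dict[str, str],
) -> AMPCandidate:
    protein = orf.protein
    signal = None
    if orf.completeness in ("complete", "three_prime_fragment"):
        signal = predict_signal_peptide(protein)
    domains = [
        d
        for d in (detect_wap(protein), detect_kazal(protein), detect_alf_loop(protein))
        if d is not None
    ]
    mature = protein[signal.cleavage_after :] if signal else protein
    family, _prefix = classify_family(hit.query_id, domains)
    return AMPCandidate(
        gene_id="",
        contig_ids=contig_ids,
        orf=orf,
        best_hit=hit,
        best_hit_name=names.get(hit.query_id, ""),
        signal_peptide=signal,
        domains=domains,
        physchem=physchem_profile(mature) if mature else physchem_profile(protein),
        family=family,
        embedded=flag_embedded(len(protein), hit.subject_protein_span),
    )


def mine(
    contigs: list[SequenceRecord],
    amps: list[AMPReferenceEntry],
    config: PipelineConfig | None = None,
) -> list[AMPCandidate]:
    """Mine AMP candidates from assembled contigs against reference peptides."""
    if not contigs or not amps:
        raise ValueError("need non-empty contigs and references")
    if config is None:
        config = PipelineConfig()
    names = {a.accession: a.name for a in amps}

    orfs_by_contig = {
        c.identifier: find_orfs(c, config.min_orf_aa) for c in contigs
    }
    best = _collect_candidates(contigs, amps, config, orfs_by_contig)

    # join split gene models and replace their per-piece candidates
    joined_sources: set[str] = set()
    joined_candidates: dict[tuple, tuple[OpenReadingFrame, AlignmentHit, list[str]]] = {}
    for merged_contig, sources in _attempt_joins(contigs, amps, config):
        merged_orfs = {merged_contig.identifier: find_orfs(merged_contig, config.min_orf_aa)}
        merged_best = _collect_candidates([merged_contig], amps, config, merged_orfs)
        if not merged_best:
            continue
        joined_sources.update(sources)
        for key, (orf, hit) in merged_best.items():
            joined_candidates[key] = (orf, hit, sources)

    candidates: list[AMPCandidate] = []
    for key in sorted(best):
        orf, hit = best[key]
        if orf.contig_id in joined_sources:
            continue
        candidates.append(_annotate(orf, hit, [orf.contig_id], names))
    for key in sorted(joined_candidates):
        orf, hit, sources = joined_candidates[key]
        candidates.append(_annotate(orf, hit, sources, names))

    if not candidates:
        logger.info("no hits above score %d anywhere", config.min_score)
        return []
    candidates = deduplicate(candidates)
    candidates = assign_gene_ids(candidates)
    candidates.sort(key=lambda c: (c.family, -c.best_hit.score, c.gene_id))
    return candidates


def deduplicate(candidates: list[AMPCandidate]) -> list[AMPCandidate]:
    """Collapse candidates whose ORFs overlap on the same contig and strand.

    Within each overlap group only the best survives: highest score, then
    longer ORF, then lexicographically smallest accession.
    """
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if candidates[i].orf.overlaps(candidates[j].orf):
                parent[find(i)] = find(j)
    groups: dict[int, list[AMPCandidate]] = {}
    for i, cand in enumerate(candidates):
        groups.setdefault(find(i), []).append(cand)
    survivors = []
    for members in groups.values():
        members.sort(
            key=lambda c: (
                -c.best_hit.score,
                -len(c.orf.protein),
                c.best_hit.query_id,
            )
        )
        survivors.append(members[0])
    survivors.sort(key=lambda c: (c.orf.contig_id, c.orf.start_nt))
    return survivors


def assign_gene_ids(candidates: list[AMPCandidate]) -> list[AMPCandidate]:
    """Family-wise ordinals by descending score: PcPar1, PcPar2, ..."""
    from .annotate import FAMILY_PREFIX

    by_family: dict[str, list[AMPCandidate]] = {}
    for cand in candidates:
        by_family.setdefault(cand.family, []).append(cand)
    for family, members in sorted(by_family.items()):
        members.sort(
            key=lambda c: (
                -c.best_hit.score,
                c.best_hit.query_id,
                c.orf.contig_id,
            )
        )
        prefix = FAMILY_PREFIX.get(family, "PcAMP")
        for ordinal, cand in enumerate(members, start=1):
            cand.gene_id = f"{prefix}{ordinal}"
    return candidates


def report(
    candidates: list[AMPCandidate],
    table_path: str | Path,
    summary_path: str | Path | None = None,
) -> dict:
    """Write the candidate TSV and a JSON summary; returns the summary."""
    table_path = Path(table_path)
    write_candidate_table(candidates, table_path)
    per_family: dict[str, int] = {}
    per_completeness: dict[str, int] = {}
    for cand in candidates:
        per_family[cand.family] = per_family.get(cand.family, 0) + 1
        key = cand.orf.completeness
        per_completeness[key] = per_completeness.get(key, 0) + 1
    summary = {
        "n_candidates": len(candidates),
        "per_family": dict(sorted(per_family.items())),
        "per_completeness": dict(sorted(per_completeness.items())),
    }
    if summary_path is None:
        summary_path = table_path.with_suffix(".summary.json")
    with open(summary_path, "w", encoding="utf-8") as handle:
        json.dump(summary, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return summary
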