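"""Nucleotide-level machinery: six-frame translation, ORF calling, joining.

Coordinates are 1-based and inclusive, always reported on the forward strand
with a strand flag.  An ORF span excludes its stop codon, so span length is
exactly three times the protein length; the printed convention of the crab
paralithocin gene models (e.g. a 72-aa protein at positions 148-363) follows
from this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .seqio import SequenceRecord

FRAMES = (1, 2, 3, -1, -2, -3)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> residue under the standard genetic code, stops as "*"
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; the complement of N is N."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """One codon to one residue; codons containing N translate to X."""
    if "N" in codon:
        return "X"
    return CODON_TO_AA[codon]


@dataclass
class FrameTranslation:
    """A translation of one contig in one of the six frames.

    ``protein`` may contain ``*`` for stops.  ``codon_first_base(i)`` maps the
    1-based protein position to the forward-strand coordinate of the first
    base of its codon *as read on the coding strand*: strictly increasing for
    + frames, strictly decreasing for - frames.
    """

    contig_id: str
    frame: int
    protein: str
    contig_length: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    def codon_first_base(self, i: int) -> int:
        if not 1 <= i <= len(self.protein):
            raise IndexError(f"protein position {i} out of range")
        offset = abs(self.frame) - 1
        if self.frame > 0:
            return offset + 3 * (i - 1) + 1
        return self.contig_length - offset - 3 * (i - 1)

    @property
    def nt_offset_of_codon(self) -> dict[int, int]:
        return {i: self.codon_first_base(i) for i in range(1, len(self.protein) + 1)}


def translate_frame(seq: str, frame: int) -> str:
    """Translate one frame; trailing partial codon dropped; stops as ``*``."""
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    s = seq if frame > 0 else reverse_complement(seq)
    offset = abs(frame) - 1
    aas = []
    for start in range(offset, len(s) - 2, 3):
        aas.append(translate_codon(s[start : start + 3]))
    return "".join(aas)


def six_frame_translate(contig: SequenceRecord) -> list[FrameTranslation]:
    """Translate a contig in the fixed frame order +1,+2,+3,-1,-2,-3."""
    if contig.alphabet != "nucleotide":
        raise ValueError(f"{contig.identifier}: not a nucleotide record")
    return [
        FrameTranslation(
            contig_id=contig.identifier,
            frame=f,
            protein=translate_frame(contig.residues, f),
            contig_length=len(contig.residues),
        )
        for f in FRAMES
    ]


COMPLETENESS_CLASSES = (
    "complete",
    "five_prime_fragment",
    "three_prime_fragment",
    "internal_fragment",
)


@dataclass
class OpenReadingFrame:
    """A delineated coding span.

    ``start_nt``/``end_nt`` are forward-strand, 1-based, inclusive, and
    exclude the stop codon; ``protein`` carries no ``*``.  ``completeness``
    records whether the span has both a start codon and a downstream stop
    (``complete``) or is truncated by the contig boundary at its 5' or 3'
    end, or spans a whole frame with neither (``internal_fragment``).
    ``frame`` and the protein-coordinate span within that frame's
    translation are kept for hit delineation.
    """

    contig_id: str
    strand: str
    start_nt: int
    end_nt: int
    protein: str
    completeness: str
    frame: int
    protein_start: int  # 1-based position in the FrameTranslation protein
    protein_end: int

    def __post_init__(self) -> None:
        if self.end_nt - self.start_nt + 1 != 3 * len(self.protein):
            raise ValueError(
                f"{self.contig_id}: ORF span {self.start_nt}-{self.end_nt} "
                f"inconsistent with protein length {len(self.protein)}"
            )
        if "*" in self.protein:
            raise ValueError(f"{self.contig_id}: internal stop in ORF protein")
        if self.completeness not in COMPLETENESS_CLASSES:
            raise ValueError(f"unknown completeness {self.completeness!r}")

    def overlaps(self, other: "OpenReadingFrame") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.strand == other.strand
            and self.start_nt <= other.end_nt
            and other.start_nt <= self.end_nt
        )


def _orf_from_span(ft: FrameTranslation, p_start: int, p_end: int, completeness: str):
    start_nt, end_nt, strand = map_protein_span_to_nt(ft, p_start, p_end)
    return OpenReadingFrame(
        contig_id=ft.contig_id,
        strand=strand,
        start_nt=start_nt,
        end_nt=end_nt,
        protein=ft.protein[p_start - 1 : p_end],
        completeness=completeness,
        frame=ft.frame,
        protein_start=p_start,
        protein_end=p_end,
    )


def find_orfs(contig: SequenceRecord, min_aa: int = 25) -> list[OpenReadingFrame]:
    """Scan all six frames for ORFs and classify their completeness.

    Within each frame the maximal stop-free stretches are examined:

    * a stretch with an ATG and a following in-frame stop yields a
      ``complete`` ORF from its first ATG to the codon before the stop;
    * a stretch with a following stop but no ATG whose open end abuts the
      contig boundary is a ``five_prime_fragment`` from its first codon;
    * a stretch reaching the contig end without a stop is a
      ``three_prime_fragment`` (from its first ATG when present);
    * a stretch spanning the whole frame with neither ATG nor stop is an
      ``internal_fragment``.

    On the minus strand the classification refers to the coding sequence
    (its 5'/3' ends), then coordinates are mapped to the forward strand.
    ORFs shorter than ``min_aa`` are discarded.  N-containing codons
    translate to X and can serve as neither start nor stop.
    """
    orfs: list[OpenReadingFrame] = []
    for ft in six_frame_translate(contig):
        protein = ft.protein
        n = len(protein)
        if n == 0:
            continue
        pos = 0
        while pos < n:
            if protein[pos] == "*":
                pos += 1
                continue
            end = pos
            while end < n and protein[end] != "*":
                end += 1
            # stretch occupies protein positions pos+1 .. end (1-based)
            s1, e1 = pos + 1, end
            stop_follows = end < n
            at_start = pos == 0
            m_idx = protein.find("M", pos, end)
            first_m = m_idx + 1 if m_idx != -1 else None
            span = None
            if stop_follows:
                if first_m is not None:
                    span = (first_m, e1, "complete")
                elif at_start:
                    span = (s1, e1, "five_prime_fragment")
            else:
                if first_m is not None:
                    span = (first_m, e1, "three_prime_fragment")
                elif at_start:
                    span = (s1, e1, "internal_fragment")
                else:
                    span = (s1, e1, "three_prime_fragment")
            if span is not None and span[1] - span[0] + 1 >= min_aa:
                orfs.append(_orf_from_span(ft, *span))
            pos = end
    return orfs


def map_protein_span_to_nt(
    ft: FrameTranslation, p_start: int, p_end: int
) -> tuple[int, int, str]:
    """Map a 1-based protein interval to its forward-strand nucleotide span."""
    if not 1 <= p_start <= p_end <= len(ft.protein):
        raise IndexError(
            f"protein span {p_start}-{p_end} out of range for "
            f"{len(ft.protein)}-aa frame translation"
        )
    if ft.frame > 0:
        start = ft.codon_first_base(p_start)
        end = ft.codon_first_base(p_end) + 2
    else:
        start = ft.codon_first_base(p_end) - 2
        end = ft.codon_first_base(p_start)
    return start, end, ft.strand


@dataclass
class JoinResult:
    """Two contigs merged across an exact overlap."""

    merged: SequenceRecord
    left_id: str
    right_id: str
    overlap_len: int
    b_reversed: bool = False


def _longest_overlap(left: str, right: str, min_overlap: int) -> int:
    """Longest k >= min_overlap with suffix(left, k) == prefix(right, k)."""
    for k in range(min(len(left), len(right)), min_overlap - 1, -1):
        if left[-k:] == right[:k]:
            return k
    return 0


def merge_overlapping_contigs(
    a: SequenceRecord, b: SequenceRecord, min_overlap: int = 30
) -> JoinResult | None:
    """Merge two contigs across their longest exact overlap, if any.

    Both orientations of ``b`` are tried, in both orders (a-then-b and
    b-then-a).  The longest overlap wins; ties prefer the orientation that
    keeps ``b`` forward, then the a-first order.  The merged identifier is
    always ``a.id + "+" + b.id``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be positive")
    candidates: list[tuple[int, int, str]] = []  # (overlap, priority, merged_seq)
    for rev, b_seq in ((False, b.residues), (True, reverse_complement(b.residues))):
        k = _longest_overlap(a.residues, b_seq, min_overlap)
        if k:
            candidates.append((k, 0 if not rev else 2, a.residues + b_seq[k:], rev))
        k = _longest_overlap(b_seq, a.residues, min_overlap)
        if k:
            candidates.append((k, 1 if not rev else 3, b_seq + a.residues[k:], rev))
    if not candidates:
        return None
    overlap, _, merged_seq, rev = max(candidates, key=lambda c: (c[0], -c[1]))
    merged = SequenceRecord(
        identifier=f"{a.identifier}+{b.identifier}",
        description="merged",
        residues=merged_seq,
        alphabet="nucleotide",
    )
    return JoinResult(
        merged=merged,
        left_id=a.identifier,
        right_id=b.identifier,
        overlap_len=overlap,
        b_reversed=rev,
    )
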