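"""Exact affine-gap Smith-Waterman local alignment and the two search modes.

The search reproduces a BLAST-style protein screen with exhaustive exact
alignment instead of seeded heuristics: every reference peptide is aligned
against every subject (protein-vs-protein, or protein-vs-all-six-frame
translations of nucleotide contigs) and hits are kept when the raw alignment
score reaches the configured threshold (default 90, the published filter).

Scoring: BLOSUM62 by default, gap of length k costs
``gap_open + (k - 1) * gap_extend`` (defaults 11/1).  The unknown residue X
scores -1 against everything.  Traceback is deterministic with tie order
diagonal > up > left, and the start cell is the first maximum in row-major
order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .seqio import AMPReferenceEntry, SequenceRecord
from .sixframe import FrameTranslation, map_protein_span_to_nt, six_frame_translate

#: residue order used for encoding; everything unknown maps to X
ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_INDEX = {ch: i for i, ch in enumerate(ALPHABET)}
_X = _INDEX["X"]

NEG_INF = np.int64(-(10**9))


def _matrix_to_array(matrix) -> np.ndarray:
    """Substitution matrix -> dense int array over :data:`ALPHABET`.

    The X row/column is forced to -1 against everything.
    """
    arr = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            try:
                arr[i, j] = int(matrix[a, b])
            except (KeyError, IndexError):
                arr[i, j] = -1
    arr[_X, :] = -1
    arr[:, _X] = -1
    return arr


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap costs."""

    matrix_name: str = "BLOSUM62"
    substitution: np.ndarray | None = None
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.substitution is None:
            self.substitution = _matrix_to_array(
                substitution_matrices.load(self.matrix_name)
            )
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")

    @classmethod
    def from_file(cls, path: str | Path, gap_open: int = 11, gap_extend: int = 1):
        """Load an NCBI-format substitution matrix text file."""
        with open(path) as handle:
            matrix = substitution_matrices.read(handle)
        scheme = cls(
            matrix_name=Path(path).stem,
            substitution=_matrix_to_array(matrix),
            gap_open=gap_open,
            gap_extend=gap_extend,
        )
        return scheme

    def score_pair(self, a: str, b: str) -> int:
        return int(self.substitution[_INDEX.get(a, _X), _INDEX.get(b, _X)])


def encode(seq: str) -> np.ndarray:
    """Encode residues as int8 indices into :data:`ALPHABET` (unknown -> X)."""
    return np.array([_INDEX.get(ch, _X) for ch in seq], dtype=np.int8)


@njit(cache=True)
def _sw_score_kernel(a, b, sub, go, ge):  # pragma: no cover - jitted
    n = a.shape[0]
    m = b.shape[0]
    h_prev = np.zeros(m + 1, dtype=np.int64)
    e_prev = np.full(m + 1, NEG_INF, dtype=np.int64)
    best = np.int64(0)
    for i in range(1, n + 1):
        h_cur = np.zeros(m + 1, dtype=np.int64)
        e_cur = np.full(m + 1, NEG_INF, dtype=np.int64)
        f = NEG_INF
        for j in range(1, m + 1):
            e = h_cur[j - 1] - go
            if e_cur[j - 1] - ge > e:
                e = e_cur[j - 1] - ge
            e_cur[j] = e
            fo = h_prev[j] - go
            if f - ge > fo:
                f = f - ge
            else:
                f = fo
            h = h_prev[j - 1] + sub[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_cur[j] = h
            if h > best:
                best = h
        h_prev = h_cur
        e_prev = e_cur
    return best


@njit(cache=True)
def _sw_fill_kernel(a, b, sub, go, ge):  # pragma: no cover - jitted
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - go
            if E[i, j - 1] - ge > e:
                e = E[i, j - 1] - ge
            E[i, j] = e
            f = H[i - 1, j] - go
            if F[i - 1, j] - ge > f:
                f = F[i - 1, j] - ge
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@dataclass
class LocalAlignment:
    """Best local alignment of a (query) against b (subject).

    Spans are 1-based inclusive; ``pairs`` lists aligned index pairs with
    ``None`` marking a gap.  ``score == 0`` means "no alignment".
    """

    score: int
    a_span: tuple[int, int] | None
    b_span: tuple[int, int] | None
    pairs: list[tuple[int | None, int | None]]
    identity: float = 0.0
    positive: float = 0.0


def _percentages(
    a: str, b: str, pairs: Sequence[tuple[int | None, int | None]], scheme: ScoringScheme
) -> tuple[float, float]:
    if not pairs:
        return 0.0, 0.0
    ident = 0
    pos = 0
    for i, j in pairs:
        if i is not None and j is not None:
            same = a[i - 1] == b[j - 1]
            if same:
                ident += 1
            if same or scheme.score_pair(a[i - 1], b[j - 1]) > 0:
                pos += 1
    n = len(pairs)
    return 100.0 * ident / n, 100.0 * pos / n


def smith_waterman(a: str, b: str, scheme: ScoringScheme | None = None) -> LocalAlignment:
    """Best-scoring affine-gap local alignment with deterministic traceback."""
    if not a or not b:
        raise ValueError("empty sequence")
    if scheme is None:
        scheme = ScoringScheme()
    ea, eb = encode(a), encode(b)
    sub = scheme.substitution
    go, ge = np.int64(scheme.gap_open), np.int64(scheme.gap_extend)
    H, E, F = _sw_fill_kernel(ea, eb, sub, go, ge)
    score = int(H.max())
    if score == 0:
        return LocalAlignment(score=0, a_span=None, b_span=None, pairs=[])
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)  # first max, row-major
    i, j = int(i), int(j)
    end_a, end_b = i, j
    pairs: list[tuple[int | None, int | None]] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + sub[ea[i - 1], eb[j - 1]]
            if H[i, j] == diag:
                pairs.append((i, j))
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in b: consume a residue (up)
            pairs.append((i, None))
            if F[i, j] == H[i - 1, j] - go:
                state = "H"
            i -= 1
        else:  # state == "E", gap in a: consume b residue (left)
            pairs.append((None, j))
            if E[i, j] == H[i, j - 1] - go:
                state = "H"
            j -= 1
    pairs.reverse()
    a_idx = [p[0] for p in pairs if p[0] is not None]
    b_idx = [p[1] for p in pairs if p[1] is not None]
    result = LocalAlignment(
        score=score,
        a_span=(min(a_idx), end_a),
        b_span=(min(b_idx), end_b),
        pairs=pairs,
    )
    result.identity, result.positive = _percentages(a, b, pairs, scheme)
    return result


@dataclass
class AlignmentHit:
    """A thresholded local alignment of a reference AMP against a subject."""

    query_id: str
    subject_id: str
    frame: int | None
    score: int
    percent_identity: float
    percent_positive: float
    query_span: tuple[int, int]
    subject_protein_span: tuple[int, int]
    subject_nt_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.percent_identity > self.percent_positive + 1e-9:
            raise ValueError("identity cannot exceed positives")


def _sorted_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    return sorted(hits, key=lambda h: (-h.score, h.subject_id, h.query_id))


def search_amps_vs_proteins(
    amps: Iterable[AMPReferenceEntry],
    proteins: Iterable[SequenceRecord],
    scheme: ScoringScheme | None = None,
    min_score: int = 90,
    threshold_on: str = "score",
) -> list[AlignmentHit]:
    """Align every reference AMP against every protein record (blastp-style).

    ``threshold_on`` selects the filter semantics: ``"score"`` keeps hits
    with raw alignment score >= ``min_score`` (default); ``"percent_positive"``
    keeps hits whose percentage of positive-scoring aligned columns reaches
    ``min_score`` (any positive-scoring alignment is then examined).
    """
    if scheme is None:
        scheme = ScoringScheme()
    if threshold_on not in ("score", "percent_positive"):
        raise ValueError(f"unknown threshold mode {threshold_on!r}")
    sub = scheme.substitution
    go, ge = np.int64(scheme.gap_open), np.int64(scheme.gap_extend)
    hits: list[AlignmentHit] = []
    proteins = list(proteins)
    encoded = [(p, encode(p.residues)) for p in proteins]
    for amp in amps:
        ea = encode(amp.mature_sequence)
        for prot, ep in encoded:
            if ep.shape[0] == 0:
                continue
            score = int(_sw_score_kernel(ea, ep, sub, go, ge))
            if threshold_on == "score":
                if score < min_score:
                    continue
            elif score <= 0:
                continue
            aln = smith_waterman(amp.mature_sequence, prot.residues, scheme)
            if threshold_on == "percent_positive" and aln.positive < min_score:
                continue
            hits.append(
                AlignmentHit(
                    query_id=amp.accession,
                    subject_id=prot.identifier,
                    frame=None,
                    score=aln.score,
                    percent_identity=aln.identity,
                    percent_positive=aln.positive,
                    query_span=aln.a_span,
                    subject_protein_span=aln.b_span,
                )
            )
    return _sorted_hits(hits)


def search_amps_vs_sixframe(
    amps: Iterable[AMPReferenceEntry],
    contigs: Iterable[SequenceRecord],
    scheme: ScoringScheme | None = None,
    min_score: int = 90,
    threshold_on: str = "score",
) -> list[AlignmentHit]:
    """Align every reference AMP against all six frame translations
    of every contig (tblastn-style); hits carry frame and forward-strand
    nucleotide span.  ``threshold_on`` as in :func:`search_amps_vs_proteins`."""
    if scheme is None:
        scheme = ScoringScheme()
    if threshold_on not in ("score", "percent_positive"):
        raise ValueError(f"unknown threshold mode {threshold_on!r}")
    sub = scheme.substitution
    go, ge = np.int64(scheme.gap_open), np.int64(scheme.gap_extend)
    hits: list[AlignmentHit] = []
    frames: list[tuple[FrameTranslation, np.ndarray]] = []
    for contig in contigs:
        for ft in six_frame_translate(contig):
            if ft.protein:
                frames.append((ft, encode(ft.protein)))
    for amp in amps:
        ea = encode(amp.mature_sequence)
        for ft, ep in frames:
            score = int(_sw_score_kernel(ea, ep, sub, go, ge))
            if threshold_on == "score":
                if score < min_score:
                    continue
            elif score <= 0:
                continue
            aln = smith_waterman(amp.mature_sequence, ft.protein, scheme)
            if threshold_on == "percent_positive" and aln.positive < min_score:
                continue
            nt_start, nt_end, _ = map_protein_span_to_nt(ft, *aln.b_span)
            hits.append(
                AlignmentHit(
                    query_id=amp.accession,
                    subject_id=ft.contig_id,
                    frame=ft.frame,
                    score=aln.score,
                    percent_identity=aln.identity,
                    percent_positive=aln.positive,
                    query_span=aln.a_span,
                    subject_protein_span=aln.b_span,
                    subject_nt_span=(nt_start, nt_end),
                )
            )
    return _sorted_hits(hits)
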