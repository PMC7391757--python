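"""Deterministic synthetic transcriptomes with a machine-readable truth table.

The generator emulates the structure of a Trinity de novo assembly that
carries antimicrobial-peptide precursor genes: contigs with planted
precursor ORFs (signal peptide + cysteine-patterned mature peptide) flanked
by UTRs, genes split across two overlapping contigs, 5'/3'-truncated
fragments, composition-matched decoy contigs, and tiered read counts across
the seven tissue libraries.  Every planted precursor is constructed so the
annotation rules provably fire: the signal peptide satisfies the documented
cleavage heuristic at its planted site, the mature peptide matches its
family's domain pattern and the physicochemical screen.

All randomness flows through one ``numpy.random.Generator``; a fixed seed
reproduces every sequence, identifier and count byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import AMPReferenceEntry, CountsTable, SequenceRecord
from .sixframe import CODON_TO_AA, reverse_complement

#: the seven tissue libraries of the study design
TABLE2_LIBRARIES = ["B-top", "C-top", "A-belly", "A-legm", "C-legm", "A-legs", "C-legs"]

SUPPORTED_FAMILIES = (
    "paralithocin",
    "crustin",
    "alf",
    "kazal",
    "buforin_like",
    "decoy_like",
)

LAYOUTS = ("single", "split_pair", "five_prime_truncated", "three_prime_truncated")

DEFAULT_LAYOUT_MIX = {
    "single": 0.6,
    "split_pair": 0.2,
    "five_prime_truncated": 0.1,
    "three_prime_truncated": 0.1,
}

#: per-family accession pools (must exist in the shipped family map);
#: real APD accessions first, synthetic AP9xxxx fillers after
ACCESSION_POOLS = {
    "paralithocin": ["AP02959", "AP02960", "AP02961"]
    + [f"AP9010{i}" for i in range(1, 9)],
    "crustin": ["AP02625", "AP01555", "AP02752", "AP02753"]
    + [f"AP9020{i}" for i in range(1, 9)],
    "alf": ["AP02147"] + [f"AP9030{i}" for i in range(1, 9)],
    "kazal": ["AP03038"] + [f"AP9040{i}" for i in range(1, 9)],
    "buforin_like": ["AP00308", "AP00489"] + [f"AP9050{i}" for i in range(1, 9)],
}

FAMILY_OF_REFERENCE = {
    "paralithocin": "paralithocin",
    "crustin": "crustin",
    "alf": "alf",
    "kazal": "kazal",
    "buforin_like": "buforin",
}

#: tier anchors echoing the printed expression classes
TIER_MEANS = {"high": 8000, "medium": 1000, "low": 50}
#: negative-binomial shape per tier (overdispersion)
TIER_SHAPES = {"high": 20.0, "medium": 15.0, "low": 10.0}
TIER_WEIGHTS = {"high": 0.7, "medium": 0.2, "low": 0.1}

# residue pools: no C, M, Y, P and no strong hydrophobics, so planted
# cysteine patterns and signal-peptide calls stay unambiguous
_FILLER = "GSANQTEDKR"
_BASIC_FILLER = "KRGSQTEDN"  # no A: keeps histone-like precursors below the
# h-region hydropathy floor, so no signal peptide is ever called on them
_LOOP_NEUTRAL = "GSQTAN"
_MATURE_START = "QRSW"

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
_STOP_CODONS = _AA_TO_CODONS.pop("*")


@dataclass
class PlantedGene:
    """Ground truth for one planted AMP gene."""

    truth_id: str
    family: str
    signal_peptide: str
    mature: str
    strand: str
    contig_layout: str
    contig_ids: list[str]
    orf_start_nt: int
    orf_end_nt: int
    tier: str
    completeness: str
    orf_protein: str
    accession: str = ""

    @property
    def precursor(self) -> str:
        return self.signal_peptide + self.mature


@dataclass
class TruthTable:
    """Everything a test needs to judge a pipeline run."""

    genes: list[PlantedGene]
    decoy_ids: list[str]
    seed: int
    parameters: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# precursor construction


def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=int(n)))


def _signal_peptide(rng: np.random.Generator, length: int | None = None) -> str:
    """A signal peptide the cleavage heuristic provably calls at its end.

    Scaffold: charged n-region MGPMK, a hydrophobic V/L core, then the tail
    MVAAPHIADA whose internal small residues are each protected (by an
    upstream M or H at -3, or a following proline) so the only valid
    cleavage candidate is the final alanine.
    """
    if length is None:
        length = int(rng.integers(21, 27))
    if not 21 <= length <= 28:
        raise ValueError("signal peptide length must be in 21..28")
    core = _draw(rng, "VL", length - 15)
    return "MGPMK" + core + "MVAAPHIADA"


def _paralithocin_mature(rng: np.random.Generator, min_len: int = 40) -> str:
    """Cysteine-rich mature peptide with exactly eight cysteines (4 S-S)."""
    length = int(rng.integers(max(min_len, 44), 58))
    body = list(_MATURE_START[int(rng.integers(0, 4))] + _draw(rng, _FILLER, length - 1))
    # eight cysteines at spaced interior positions
    positions = 2 + np.cumsum(rng.integers(3, (length - 4) // 8, size=8))
    for pos in positions:
        body[min(int(pos), length - 2)] = "C"
    mature = "".join(body)
    if mature.count("C") != 8:  # collision guard; respaced deterministically
        body = list(_MATURE_START[0] + _draw(rng, _FILLER, length - 1))
        step = (length - 6) // 8
        for k in range(8):
            body[3 + k * step] = "C"
        mature = "".join(body)
    return mature


def _crustin_mature(rng: np.random.Generator, min_len: int = 40) -> str:
    """Pro-region plus a WAP four-disulfide-core eight-cysteine domain."""
    gaps = [
        int(rng.integers(3, 11)),
        int(rng.integers(4, 9)),
        int(rng.integers(4, 9)),
        int(rng.integers(4, 13)),
        int(rng.integers(4, 11)),
        int(rng.integers(3, 7)),
    ]
    wap = (
        "C" + _draw(rng, _FILLER, gaps[0])
        + "C" + _draw(rng, _FILLER, gaps[1])
        + "C" + _draw(rng, _FILLER, gaps[2])
        + "C" + _draw(rng, _FILLER, gaps[3])
        + "C" + _draw(rng, _FILLER, gaps[4])
        + "CC" + _draw(rng, _FILLER, gaps[5])
        + "C"
    )
    pro_len = max(6, min_len - len(wap) - 3)
    pro = _MATURE_START[int(rng.integers(0, 4))] + _draw(rng, _FILLER, pro_len - 1)
    return pro + wap + _draw(rng, _FILLER, 3)


def _alf_mature(rng: np.random.Generator, min_len: int = 40) -> str:
    """Two-cysteine disulfide loop enclosing a positively charged cluster."""
    loop_interior = int(rng.integers(16, 31))
    n_basic = int(rng.integers(6, 9))
    loop = list(_draw(rng, _LOOP_NEUTRAL, loop_interior))
    basic_pos = rng.permutation(loop_interior)[:n_basic]
    for pos in basic_pos:
        loop[int(pos)] = "KR"[int(rng.integers(0, 2))]
    head_len = max(7, min_len - loop_interior - 12)
    head = _MATURE_START[int(rng.integers(0, 4))] + _draw(rng, _FILLER, head_len - 1)
    tail = _draw(rng, _FILLER, int(rng.integers(8, 15)))
    return head + "C" + "".join(loop) + "C" + tail


def _kazal_mature(rng: np.random.Generator, min_len: int = 40) -> str:
    """Kazal-type protease-inhibitor cysteine/tyrosine spacing."""
    core = (
        "C" + _draw(rng, _FILLER, 7)
        + "C" + _draw(rng, _FILLER, 6)
        + "Y" + _draw(rng, _FILLER, 3)
        + "C" + _draw(rng, _FILLER, int(rng.integers(2, 4)))
        + "C"
    )
    head_len = max(6, min_len - len(core) - 6)
    head = _MATURE_START[int(rng.integers(0, 4))] + _draw(rng, _FILLER, head_len - 1)
    return head + core + _draw(rng, _FILLER, 6)


def _buforin_mature(rng: np.random.Generator, min_len: int = 40) -> str:
    """Histone-H2A-like basic peptide; starts with M, no signal peptide."""
    length = int(rng.integers(max(min_len, 44), 56))
    return "M" + _draw(rng, _BASIC_FILLER, length - 1)


def generate_precursor(
    rng: np.random.Generator, family: str, min_mature_len: int = 40
) -> tuple[str, str]:
    """Signal peptide and mature peptide for one planted family.

    ``buforin_like`` precursors carry no signal peptide (histone-derived);
    ``decoy_like`` yields an innocuous polar peptide matching no detector.
    """
    if family not in SUPPORTED_FAMILIES:
        raise ValueError(f"unsupported family {family!r}")
    if family == "buforin_like":
        return "", _buforin_mature(rng, min_mature_len)
    if family == "decoy_like":
        return "", "M" + _draw(rng, "GSANQTED", 39)
    sp = _signal_peptide(rng)
    mature = {
        "paralithocin": _paralithocin_mature,
        "crustin": _crustin_mature,
        "alf": _alf_mature,
        "kazal": _kazal_mature,
    }[family](rng, min_mature_len)
    return sp, mature


# --------------------------------------------------------------------------
# transcript assembly


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = []
    for aa in protein:
        options = _AA_TO_CODONS[aa]
        codons.append(options[int(rng.integers(0, len(options)))])
    return "".join(codons)


def _random_utr(rng: np.random.Generator, n: int) -> str:
    s = _draw(rng, "ACGT", n)
    # scrub start codons so the planted ATG is the first in its stretch
    while "ATG" in s:
        s = s.replace("ATG", "ATC")
    return s


def _trinity_id(dn: int, rng: np.random.Generator) -> str:
    c = int(rng.integers(0, 3))
    g = int(rng.integers(1, 4))
    i = int(rng.integers(1, 6))
    return f"TRINITY_DN{dn}_c{c}_g{g}_i{i}"


def _flip(span: tuple[int, int], length: int) -> tuple[int, int]:
    s, e = span
    return length - e + 1, length - s + 1


def generate_transcriptome(
    rng: np.random.Generator,
    n_planted: int = 20,
    n_decoys: int = 80,
    layout_mix: dict[str, float] | None = None,
    decoy_reject_score: int = 60,
) -> tuple[list[SequenceRecord], TruthTable]:
    """Generate Trinity-style contigs plus the matching truth table.

    Planted genes are reverse-translated with seeded codon choice, embedded
    in ATG-free UTRs, optionally reverse-complemented, split across two
    overlapping contigs, or truncated across a contig edge.  Decoys are
    composition-matched random contigs re-drawn until no planted reference
    peptide aligns at ``decoy_reject_score`` or above.
    """
    from .align import ScoringScheme, search_amps_vs_sixframe  # local: avoids cycle

    if layout_mix is None:
        layout_mix = DEFAULT_LAYOUT_MIX
    layouts = _layout_assignment(n_planted, layout_mix, rng)
    families = [
        ("paralithocin", "crustin", "alf", "kazal", "buforin_like")[i % 5]
        for i in range(n_planted)
    ]
    tiers = _tier_assignment(n_planted, rng)
    pool_cursor = {fam: 0 for fam in ACCESSION_POOLS}

    dn_numbers = rng.permutation(np.arange(10, 200000))[: n_planted * 2 + n_decoys]
    dn_iter = iter(int(x) for x in dn_numbers)

    contigs: list[SequenceRecord] = []
    genes: list[PlantedGene] = []
    for idx in range(n_planted):
        family = families[idx]
        layout = layouts[idx]
        min_mature = 48 if layout != "single" else 40
        sp, mature = generate_precursor(rng, family, min_mature_len=min_mature)
        precursor = sp + mature
        cds = _reverse_translate(rng, precursor)
        stop = _STOP_CODONS[int(rng.integers(0, 3))]
        utr5 = _random_utr(rng, int(rng.integers(45, 150)))
        utr3 = _random_utr(rng, int(rng.integers(30, 120)))
        transcript = utr5 + cds + stop + utr3
        cds_start = len(utr5) + 1  # 1-based
        cds_end = len(utr5) + len(cds)  # excludes stop codon
        accession = _next_accession(family, pool_cursor)
        gene = _place_gene(
            rng,
            idx,
            family,
            layout,
            sp,
            mature,
            transcript,
            cds_start,
            cds_end,
            tiers[idx],
            accession,
            dn_iter,
            contigs,
        )
        genes.append(gene)

    refs = [
        AMPReferenceEntry(
            accession=g.accession,
            name=f"synthetic {g.family} {i + 1}",
            mature_sequence=g.mature if g.signal_peptide else g.precursor,
            family_hint=g.family,
        )
        for i, g in enumerate(genes)
    ]
    scheme = ScoringScheme()
    decoy_ids: list[str] = []
    gene_lengths = np.array([len(c.residues) for c in contigs])
    for _ in range(n_decoys):
        dn = next(dn_iter)
        decoy_id = _trinity_id(dn, rng)
        for _attempt in range(50):
            length = int(rng.integers(250, 900))
            seq = _draw(rng, "ACGTACGTGC", length)  # mild GC skew
            record = SequenceRecord(decoy_id, f"len={length}", seq, "nucleotide")
            hits = search_amps_vs_sixframe(
                refs, [record], scheme, min_score=decoy_reject_score
            )
            if not hits:
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not draw a clean decoy in 50 attempts")
        contigs.append(record)
        decoy_ids.append(decoy_id)

    truth = TruthTable(
        genes=genes,
        decoy_ids=decoy_ids,
        seed=-1,
        parameters={
            "n_planted": n_planted,
            "n_decoys": n_decoys,
            "layout_mix": dict(layout_mix),
            "decoy_reject_score": decoy_reject_score,
        },
    )
    return contigs, truth


def _next_accession(family: str, cursor: dict[str, int]) -> str:
    pool = ACCESSION_POOLS[family]
    i = cursor[family]
    if i >= len(pool):
        raise ValueError(f"accession pool for {family} exhausted")
    cursor[family] = i + 1
    return pool[i]


def _layout_assignment(
    n: int, mix: dict[str, float], rng: np.random.Generator
) -> list[str]:
    """Largest-remainder apportionment of layouts, then a seeded shuffle."""
    total = sum(mix.values())
    quotas = {k: n * v / total for k, v in mix.items()}
    counts = {k: int(q) for k, q in quotas.items()}
    leftover = n - sum(counts.values())
    by_frac = sorted(quotas, key=lambda k: (quotas[k] - counts[k], k), reverse=True)
    for k in by_frac[:leftover]:
        counts[k] += 1
    assignment = [k for k in LAYOUTS for _ in range(counts.get(k, 0))]
    rng.shuffle(assignment)
    return assignment


def _tier_assignment(n: int, rng: np.random.Generator) -> list[str]:
    tiers = list(TIER_WEIGHTS)
    weights = np.array([TIER_WEIGHTS[t] for t in tiers])
    draws = rng.choice(len(tiers), size=n, p=weights / weights.sum())
    out = [tiers[int(d)] for d in draws]
    # guarantee every tier appears so tier-ordering checks are meaningful
    for i, tier in enumerate(tiers):
        if tier not in out and n > i:
            out[i] = tier
    return out


def _place_gene(
    rng,
    idx,
    family,
    layout,
    sp,
    mature,
    transcript,
    cds_start,
    cds_end,
    tier,
    accession,
    dn_iter,
    contigs,
) -> PlantedGene:
    truth_id = f"gene{idx + 1:03d}"
    sp_len = len(sp)
    mature_len = len(mature)
    mature_cds_start = cds_start + 3 * sp_len  # first nt of mature codons

    if layout == "single":
        contig_id = _trinity_id(next(dn_iter), rng)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        seq = transcript
        span = (cds_start, cds_end)
        if strand == "-":
            seq = reverse_complement(seq)
            span = _flip(span, len(seq))
        contigs.append(
            SequenceRecord(contig_id, f"len={len(seq)}", seq, "nucleotide")
        )
        return PlantedGene(
            truth_id, family, sp, mature, strand, layout, [contig_id],
            span[0], span[1], tier, "complete", sp + mature, accession,
        )

    if layout == "split_pair":
        k1 = mature_len // 2
        cut = mature_cds_start - 1 + 3 * k1  # 0-based split point
        # keep the stop codon out of the left contig so neither piece is a
        # complete gene model on its own
        max_overlap = min(81, 3 * (mature_len - k1) - 6)
        overlap = int(rng.integers(40, max_overlap))
        left = transcript[: cut + overlap]
        right = transcript[cut:]
        id_left = _trinity_id(next(dn_iter), rng)
        id_right = _trinity_id(next(dn_iter), rng)
        flip_right = bool(rng.integers(0, 2))
        right_seq = reverse_complement(right) if flip_right else right
        contigs.append(
            SequenceRecord(id_left, f"len={len(left)}", left, "nucleotide")
        )
        contigs.append(
            SequenceRecord(id_right, f"len={len(right_seq)}", right_seq, "nucleotide")
        )
        return PlantedGene(
            truth_id, family, sp, mature, "+", layout, [id_left, id_right],
            cds_start, cds_end, tier, "complete", sp + mature, accession,
        )

    if layout == "five_prime_truncated":
        drop = sp_len + max(1, mature_len // 4)
        cut = cds_start - 1 + 3 * drop  # codon-aligned 0-based cut
        seq = transcript[cut:]
        remainder = mature[drop - sp_len :]
        span = (1, 3 * len(remainder))
        contig_id = _trinity_id(next(dn_iter), rng)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if strand == "-":
            seq = reverse_complement(seq)
            span = _flip(span, len(seq))
        contigs.append(
            SequenceRecord(contig_id, f"len={len(seq)}", seq, "nucleotide")
        )
        return PlantedGene(
            truth_id, family, sp, mature, strand, layout, [contig_id],
            span[0], span[1], tier, "five_prime_fragment", remainder, accession,
        )

    if layout == "three_prime_truncated":
        keep = sp_len + max(25 - sp_len, (3 * mature_len) // 4)
        end = cds_start - 1 + 3 * keep
        seq = transcript[:end]
        kept_protein = (sp + mature)[:keep]
        span = (cds_start, end)
        contig_id = _trinity_id(next(dn_iter), rng)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if strand == "-":
            seq = reverse_complement(seq)
            span = _flip(span, len(seq))
        contigs.append(
            SequenceRecord(contig_id, f"len={len(seq)}", seq, "nucleotide")
        )
        return PlantedGene(
            truth_id, family, sp, mature, strand, layout, [contig_id],
            span[0], span[1], tier, "three_prime_fragment", kept_protein, accession,
        )

    raise ValueError(f"unknown layout {layout!r}")


def generate_reference(truth: TruthTable) -> list[AMPReferenceEntry]:
    """The reference-peptide 'database' matching a generated truth table."""
    return [
        AMPReferenceEntry(
            accession=g.accession,
            name=f"synthetic {g.family} {i + 1}",
            mature_sequence=g.mature if g.signal_peptide else g.precursor,
            family_hint=g.family,
        )
        for i, g in enumerate(truth.genes)
    ]


# --------------------------------------------------------------------------
# counts


def generate_counts(
    rng: np.random.Generator,
    truth: TruthTable,
    libraries: list[str] | None = None,
) -> CountsTable:
    """Tiered read counts per contig across the tissue libraries.

    Planted genes draw a negative-binomial total around their tier mean
    (high ~8000, medium ~1000, low ~50) split across libraries with a
    Dirichlet-multinomial; decoys get background totals below 100 reads.
    Library totals include a constant transcriptome-wide background so RPKM
    denominators resemble real library sizes.
    """
    if libraries is None:
        libraries = list(TABLE2_LIBRARIES)
    counts: dict[tuple[str, str], int] = {}
    gene_ids: list[str] = []

    def _spread(total: int) -> list[int]:
        weights = rng.dirichlet(np.full(len(libraries), 5.0))
        return [int(x) for x in rng.multinomial(total, weights)]

    for gene in truth.genes:
        mean = TIER_MEANS[gene.tier]
        shape = TIER_SHAPES[gene.tier]
        p = shape / (shape + mean)
        total = int(rng.negative_binomial(shape, p))
        row_id = gene.contig_ids[0]
        gene_ids.append(row_id)
        for lib, c in zip(libraries, _spread(total)):
            counts[(row_id, lib)] = c
    for decoy_id in truth.decoy_ids:
        total = min(99, int(rng.poisson(25)))
        gene_ids.append(decoy_id)
        for lib, c in zip(libraries, _spread(total)):
            counts[(decoy_id, lib)] = c

    column_sums = {
        lib: sum(counts.get((g, lib), 0) for g in gene_ids) for lib in libraries
    }
    totals = {lib: column_sums[lib] + 1_500_000 for lib in libraries}
    return CountsTable(
        library_ids=libraries, gene_ids=gene_ids, counts=counts, library_totals=totals
    )


# --------------------------------------------------------------------------
# truth serialization


def write_truth(truth: TruthTable, path: str | Path) -> None:
    """Dump the truth table as JSON."""
    payload = {
        "genes": [dataclasses.asdict(g) for g in truth.genes],
        "decoy_ids": truth.decoy_ids,
        "seed": truth.seed,
        "parameters": truth.parameters,
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=1, sort_keys=True)
        handle.write("\n")


def load_truth(path: str | Path) -> TruthTable:
    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    return TruthTable(
        genes=[PlantedGene(**g) for g in payload["genes"]],
        decoy_ids=payload["decoy_ids"],
        seed=payload["seed"],
        parameters=payload["parameters"],
    )


def generate_dataset(
    seed: int,
    n_planted: int = 20,
    n_decoys: int = 80,
    layout_mix: dict[str, float] | None = None,
    libraries: list[str] | None = None,
):
    """One-call dataset: contigs, references, counts, truth (all seeded)."""
    rng = np.random.default_rng(seed)
    contigs, truth = generate_transcriptome(
        rng, n_planted=n_planted, n_decoys=n_decoys, layout_mix=layout_mix
    )
    truth.seed = seed
    refs = generate_reference(truth)
    counts = generate_counts(rng, truth, libraries=libraries)
    return contigs, refs, counts, truth
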