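# Methods

This note documents the models, conventions and design choices behind
`ampmine`, and what the synthetic-data tests do and do not demonstrate.

## Mining model

A candidate AMP gene is an open reading frame in an assembled contig whose
translation aligns to a curated reference peptide at or above a raw
Smith–Waterman score of 90. Two search routes feed the candidate set and
are unioned: references against ORF proteins (useful when the gene model is
already complete) and references against all six frame translations (which
also finds frame-confined matches in fragments). A hit must fall entirely
inside one ORF of its frame; hits spanning a frameshift are dropped with a
warning, since resolving them requires manual curation.

### Alignment scoring

BLOSUM62 with affine gaps, open 11 and extend 1; a gap of length k costs
`11 + (k−1)`. Scores are raw (no E-values or composition adjustment): the
screening filter is a single score threshold, and raw score is the
conservative, scale-free reading of a "similarity score ≥ 90" filter whose
original tool-specific semantics are not recoverable. The unknown residue X
scores −1 against everything. Traceback is deterministic (diagonal > up >
left; first maximum in row-major order), so identical inputs yield
byte-identical reports. The alignment is exhaustive rather than seeded:
at desk scale (hundreds of contigs, tens of references) exactness is
affordable and directly testable against a naive dynamic-programming oracle.
A substitution matrix in NCBI text format can be supplied to replace
BLOSUM62.

### ORF conventions

Coordinates are 1-based, inclusive, forward-strand, with a strand flag; the
span excludes the stop codon (span = 3 × protein length — this is the
convention under which a 72-aa protein occupies positions 148–363). Only ATG
opens a complete ORF; N-containing codons translate to X and can serve as
neither start nor stop. Stretch classification: a stop-free stretch with an
ATG and a following stop is `complete` (from its first ATG); with a stop but
no ATG, abutting the contig start, `five_prime_fragment`; reaching the
contig end without a stop, `three_prime_fragment` (from its first ATG when
present, else from the stretch start); spanning a whole frame with neither,
`internal_fragment`. Interior no-ATG stretches between two stops are not
reported. The default minimum ORF length is 25 aa — below the shortest
mature AMPs worth reporting but high enough to bound random-ORF noise.

### Contig joining

Two contigs are merged only by exact overlap (default ≥30 nt; the generator
plants ≥40 nt), testing both orientations of the second contig and both
orders; the longest overlap wins and ties prefer the orientation preserving
the first contig's strand. Joining is attempted only when one reference hits
exactly two contigs and each hit ends within 30 nt (ten codons) of a contig
edge — the signature of one gene model split across assembly isoforms. This
deliberately under-joins: unrelated contigs sharing a motif do not trigger
a merge.

### Deduplication and naming

Candidates whose ORFs overlap by ≥1 nt on the same contig and strand are one
locus; the highest score survives (ties: longer ORF, then lexicographically
smallest accession). Within each family, gene identifiers are ordinals by
descending score (`PcPar1`, `PcPar2`, …) with fixed prefixes per family; the
beta-thymosin prefix is transliterated to ASCII (`PcBThm`) for portability.

## Signal-peptide caller

A deterministic heuristic in the von Heijne tradition, fully specified so
behavior is reproducible without a trained model. Candidate cleavage
positions p ∈ 15..35 are valid when (i) the n-region (positions
1..max(2, p−15)) contains K/R, or the protein opens with M followed by K/R
within five residues; (ii) some window of ≥7 consecutive residues within
3..p−3 has mean Kyte–Doolittle hydropathy ≥1.5 (the h-region; all window
lengths are scanned because a longer window can beat every 7-residue
sub-window); (iii) residue p ∈ {A,G,S,C,T,Q} and residue p−2 ∈
{A,G,S,C,T,V,L,I} (the −3/−1 rule); and (iv) the residue after the site is
not proline — signal peptidase does not cleave before P, and without this
exclusion internal Ala-x-Ala motifs upstream of prolines produce spurious
early sites. Among valid candidates the score is the h-region mean
hydropathy plus 0.5 when residue p is alanine; ties resolve to the smallest
p, which prevents the caller from sliding past the true site onto small
residues at the start of the mature peptide (e.g. an R-S mature N-terminus
whose serine would otherwise tie). Calling is skipped for ORFs lacking
their 5′ end, which cannot contain an N-terminal signal.

## Domain detectors and physicochemistry

The WAP, Kazal and ALF detectors are bounded-gap cysteine-spacing patterns,
not profile HMMs: WAP
`C x(3,10) C x(4,8) C x(4,8) C x(4,12) C x(4,10) CC x(3,6) C` (gaps exclude
C, so a match carries exactly eight cysteines), Kazal
`C x(7) C x(6) Y x(3) C x(2,3) C`, and for ALF a cysteine pair 15–35
residues apart whose enclosed loop has net charge ≥ +3 (K/R = +1, H = +0.5,
D/E = −1; the highest-charge pair is reported). They are substring-monotone
and validated on constructed fixtures; recall on real proteomes is out of
scope. The physicochemical screen is exactly the published size window for
natural AMPs — length ≤ 150 aa and mass 2–9 kDa (average residue masses plus
18.02 Da water; X counts 110 Da and is flagged) — with the hydrophobic
fraction reported but not thresholded, since no cutoff is published.
Candidates failing the screen are still reported (the screen is a column,
not a filter). A match is flagged `embedded` when the protein exceeds
150 aa and the hit covers less than half of it: an AMP-like region inside a
large coding gene.

## Expression

RPKM = `1e9 · C / (L · N)` with N the total counted reads of the library
(from the counts table's TOTAL row when present, else column sums; no
mapping-rate correction, as no mapping statistics are assumed). Tiering uses
summed raw reads across libraries because the printed anchors are read
counts: >3,000 high, <100 low, and the "around 1,000" middle class is
formalized as [100, 3000]. Mean RPKM is the arithmetic mean across all
libraries.

## Synthetic data: what it emulates and what it does not

The generator plants precursor genes — signal peptide plus family-patterned
mature peptide for paralithocin (eight cysteines), crustin (WAP), ALF
(charged loop), Kazal, and histone-derived buforin-like genes without a
signal peptide — reverse-translated with uniform synonymous-codon choice,
embedded in ATG-free UTRs, on either strand, as intact contigs, split pairs
sharing an exact ≥40 nt overlap, or 5′/3′ boundary truncations. Decoys are
random contigs re-drawn until no reference aligns at score ≥60, leaving a
safety margin below the mining threshold of 90. Counts are
negative-binomial totals around tier means 8,000 / 1,000 / 50 (shapes
20/15/10), split across the seven tissue libraries by a
Dirichlet-multinomial; library totals add a constant 1.5 M background so
RPKM denominators resemble real library sizes. Default conditions: 20
planted genes, 80 decoys, layout mix 60% single / 20% split / 10% + 10%
truncated, tier weights 0.7/0.2/0.1.

The construction is adversarial only in structure, not in sequence: planted
matures are exact copies of the reference peptides, there is no codon bias,
no sequencing error, no polymorphism, and decoys are composition-matched
random sequence rather than real paralogs. Passing the recovery tests
therefore shows the machinery (translation, coordinates, thresholding,
joining, classification) is correct — it does not estimate sensitivity on
real transcriptomes, where divergence from database peptides dominates.
Signal peptides use one scaffold family (charged MGPMK n-region, V/L core,
MVAAPHIADA-style c-region) built to satisfy the caller by construction.

## Numerical and degenerate-input choices

Empty FASTA files, negative counts, duplicate ids, and out-of-range spans
raise errors naming the offending record; contigs shorter than one codon
translate to six empty frames; proteins shorter than 30 aa return "no
signal peptide" rather than an error; an all-decoy run yields an empty
report (header-only TSV, zero-count summary) rather than an error. All
orderings (hits, candidates, gene ordinals, report rows) have explicit sort
keys, and every stochastic component draws from one seeded generator, so a
fixed seed reproduces reports byte for byte.

Test problem sizes: oracle equivalence uses 200 random peptide pairs
(≤30 aa) for the aligner and 500 random contigs (≤1 kb) for the ORF
scanner; end-to-end recovery runs the default 20-gene / 80-decoy dataset at
seed 1. These sizes make the exhaustive oracles exact and keep the full
suite fast on a single CPU.

## Known limitations

The score threshold defaults to a raw-score reading of the published
filter; a percent-positive reading is selectable (`threshold_on=
"percent_positive"` in the search functions) but the original tool's exact
normalization is not recoverable. The signal-peptide caller and domain patterns are
deterministic approximations, suitable for precursor-shaped synthetic data
and for triage, not substitutes for SignalP- or Pfam-class models on real
proteomes. Joining is exact-overlap only and will not bridge contigs with
assembly errors inside the overlap. Candidate counts from any real
transcriptome depend on the reference database snapshot and assembly depth
and are not a target of this package.
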