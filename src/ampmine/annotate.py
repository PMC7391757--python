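"""Candidate characterization: signal peptides, domains, physicochemistry.

The signal-peptide caller is a deterministic heuristic in the von Heijne
tradition (charged n-region, >=7-residue hydrophobic h-region, small residues
at the -3/-1 positions of the cleavage site), specified in full so behavior
is reproducible without a trained model.  The domain detectors are
bounded-gap cysteine-spacing patterns for the WAP (whey acidic protein)
four-disulfide core of crustins, the Kazal protease-inhibitor fold, and the
positively charged disulfide loop of anti-lipopolysaccharide factors (ALF).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# signal peptides

#: residues accepted at the -1 position of a cleavage site
_MINUS1 = set("AGSCTQ")
#: residues accepted at the -3 position
_MINUS3 = set("AGSCTVLI")
#: minimum mean Kyte-Doolittle hydropathy of the h-region
_H_MEAN_MIN = 1.5
_H_MIN_LEN = 7


@dataclass
class SignalPeptideCall:
    """A predicted signal peptide with its n/h/c regions.

    ``cleavage_after`` is the 1-based index of the last signal-peptide
    residue (the printed crab paralithocins all cleave after residue 23).
    The three regions tile 1..cleavage_after in order.
    """

    cleavage_after: int
    n_region: tuple[int, int]
    h_region: tuple[int, int]
    c_region: tuple[int, int]
    score: float

    def __post_init__(self) -> None:
        if not 15 <= self.cleavage_after <= 35:
            raise ValueError("cleavage site must fall in 15..35")
        n, h, c = self.n_region, self.h_region, self.c_region
        if not (n[0] == 1 and n[1] + 1 == h[0] and h[1] + 1 == c[0] and c[1] == self.cleavage_after):
            raise ValueError("n/h/c regions must tile 1..cleavage_after in order")


def _best_h_window(protein: str, lo: int, hi: int) -> tuple[float, tuple[int, int]] | None:
    """Max mean hydropathy over windows of length >= 7 within [lo, hi] (1-based).

    Longer windows can beat every length-7 sub-window, so all lengths are
    scanned (the range is at most ~30 residues).  Ties prefer the earliest
    then the longest window.
    """
    if hi - lo + 1 < _H_MIN_LEN:
        return None
    values = [KYTE_DOOLITTLE.get(ch, -4.5) for ch in protein]
    best: tuple[float, tuple[int, int]] | None = None
    for s in range(lo, hi - _H_MIN_LEN + 2):
        total = sum(values[s - 1 : s + _H_MIN_LEN - 2])
        for e in range(s + _H_MIN_LEN - 1, hi + 1):
            total += values[e - 1]
            mean = total / (e - s + 1)
            if best is None or mean > best[0]:
                best = (mean, (s, e))
    return best


def predict_signal_peptide(protein: str) -> SignalPeptideCall | None:
    """Call a signal-peptide cleavage site, or ``None``.

    Candidate cleavage points p run over 15..35.  A candidate is valid when

    1. the n-region (positions 1..max(2, p-15)) contains K or R, or the
       protein starts with M followed by K/R within the next five residues;
    2. some window of >= 7 consecutive residues inside positions 3..p-3 has
       mean Kyte-Doolittle hydropathy >= 1.5 (the h-region);
    3. the (-3,-1) rule holds: residue p is one of {A,G,S,C,T,Q} and residue
       p-2 one of {A,G,S,C,T,V,L,I};
    4. the residue following the site is not proline (signal peptidase
       does not cleave before P).

    Among valid candidates the one maximizing (h-region mean hydropathy
    + 0.5 if residue p is A) wins; score ties resolve to the smallest p.
    Proteins shorter than 30 residues return ``None``.
    """
    if len(protein) < 30:
        return None
    best: tuple[float, int, tuple[int, int]] | None = None
    for p in range(15, min(35, len(protein) - 1) + 1):
        # rule (iii) first: cheapest
        if protein[p - 1] not in _MINUS1 or protein[p - 3] not in _MINUS3:
            continue
        # rule (iv): no proline immediately after the site
        if protein[p] == "P":
            continue
        # rule (i): charged n-region
        n_end = max(2, p - 15)
        n_region = protein[:n_end]
        charged = ("K" in n_region) or ("R" in n_region)
        m_start = protein[0] == "M" and any(ch in "KR" for ch in protein[1:6])
        if not (charged or m_start):
            continue
        # rule (ii): hydrophobic h-region
        window = _best_h_window(protein, 3, p - 3)
        if window is None or window[0] < _H_MEAN_MIN:
            continue
        h_mean, h_span = window
        score = h_mean + (0.5 if protein[p - 1] == "A" else 0.0)
        if best is None or score > best[0] + 1e-12:
            best = (score, p, h_span)
    if best is None:
        return None
    score, p, h_span = best
    return SignalPeptideCall(
        cleavage_after=p,
        n_region=(1, h_span[0] - 1),
        h_region=h_span,
        c_region=(h_span[1] + 1, p),
        score=score,
    )


# --------------------------------------------------------------------------
# domains

@dataclass
class DomainHit:
    """A matched cysteine-spacing domain pattern."""

    kind: str
    span: tuple[int, int]
    cysteine_count: int
    detail: str = ""


#: eight-cysteine four-disulfide core of the WAP domain; gaps exclude C so
#: the matched region carries exactly eight cysteines
_WAP_RE = re.compile(
    "C[^C]{3,10}C[^C]{4,8}C[^C]{4,8}C[^C]{4,12}C[^C]{4,10}CC[^C]{3,6}C"
)
_KAZAL_RE = re.compile("C[^C]{7}C[^C]{6}Y[^C]{3}C[^C]{2,3}C")

_CHARGE = {"K": 1.0, "R": 1.0, "H": 0.5, "D": -1.0, "E": -1.0}


def net_charge(peptide: str) -> float:
    """Net charge with K/R = +1, H = +0.5, D/E = -1."""
    return sum(_CHARGE.get(ch, 0.0) for ch in peptide)


def _regex_domain(protein: str, pattern: re.Pattern, kind: str) -> DomainHit | None:
    m = pattern.search(protein)
    if not m:
        return None
    span = (m.start() + 1, m.end())
    return DomainHit(
        kind=kind,
        span=span,
        cysteine_count=m.group(0).count("C"),
    )


def detect_wap(protein: str) -> DomainHit | None:
    """First region matching the WAP eight-cysteine spacing pattern."""
    return _regex_domain(protein, _WAP_RE, "WAP")


def detect_kazal(protein: str) -> DomainHit | None:
    """First region matching the Kazal C/Y spacing pattern."""
    return _regex_domain(protein, _KAZAL_RE, "Kazal")


def detect_alf_loop(protein: str) -> DomainHit | None:
    """Positively charged disulfide loop between two cysteines.

    Scans cysteine pairs 15-35 positions apart and reports the pair whose
    enclosed segment has the highest net charge, provided it is >= +3.
    """
    cys = [i for i, ch in enumerate(protein, start=1) if ch == "C"]
    best: tuple[float, tuple[int, int]] | None = None
    for ai, i in enumerate(cys):
        for j in cys[ai + 1 :]:
            if not 15 <= j - i <= 35:
                continue
            charge = net_charge(protein[i : j - 1])
            if charge < 3.0:
                continue
            if best is None or charge > best[0]:
                best = (charge, (i, j))
    if best is None:
        return None
    charge, (i, j) = best
    return DomainHit(
        kind="ALF_loop",
        span=(i, j),
        cysteine_count=protein[i - 1 : j].count("C"),
        detail=f"loop net charge {charge:+.1f}",
    )


# --------------------------------------------------------------------------
# physicochemical screen

#: average residue masses (Da) of the 20 amino acids in a peptide chain
AVERAGE_RESIDUE_MASS = {
    "G": 57.05, "A": 71.08, "S": 87.08, "P": 97.12, "V": 99.13,
    "T": 101.10, "C": 103.14, "L": 113.16, "I": 113.16, "N": 114.10,
    "D": 115.09, "Q": 128.13, "K": 128.17, "E": 129.12, "M": 131.19,
    "H": 137.14, "F": 147.18, "R": 156.19, "Y": 163.18, "W": 186.21,
}
_WATER_MASS = 18.02
_X_MASS = 110.0

HYDROPHOBIC_RESIDUES = set("AILMFVWC")


@dataclass
class PhysChemProfile:
    """Length, mass, charge and hydrophobicity of a peptide.

    ``passes_amp_screen`` is exactly the published size window for natural
    antimicrobial peptides: at most 150 residues and 2-9 kDa.  The
    hydrophobic fraction is reported but not thresholded.
    """

    length_aa: int
    mass_kDa: float
    net_charge: float
    hydrophobic_fraction: float
    passes_amp_screen: bool
    detail: str = ""


def physchem_profile(peptide: str) -> PhysChemProfile:
    """Profile a peptide; unknown residue X contributes 110 Da, flagged."""
    if not peptide or "*" in peptide:
        raise ValueError("need a non-empty peptide without stops")
    mass = _WATER_MASS
    n_x = 0
    for ch in peptide:
        if ch in AVERAGE_RESIDUE_MASS:
            mass += AVERAGE_RESIDUE_MASS[ch]
        else:
            mass += _X_MASS
            n_x += 1
    mass_kda = mass / 1000.0
    length = len(peptide)
    return PhysChemProfile(
        length_aa=length,
        mass_kDa=mass_kda,
        net_charge=net_charge(peptide),
        hydrophobic_fraction=sum(ch in HYDROPHOBIC_RESIDUES for ch in peptide) / length,
        passes_amp_screen=(length <= 150 and 2.0 <= mass_kda <= 9.0),
        detail=f"{n_x} unknown residue(s) at 110 Da" if n_x else "",
    )


# --------------------------------------------------------------------------
# family classification

FAMILY_PREFIX = {
    "buforin": "PcBuf",
    "acipensin": "PcAcp",
    "ubiquicidin": "PcUbi",
    "lysozyme": "PcLys",
    "beta_thymosin": "PcBThm",
    "crustin": "PcCrs",
    "paralithocin": "PcPar",
    "kazal": "PcKaz",
    "alf": "PcALF",
    "other": "PcAMP",
}

#: domain evidence that can upgrade an unknown-accession candidate
_DOMAIN_FAMILY = {"WAP": "crustin", "Kazal": "kazal", "ALF_loop": "alf"}

_FAMILY_MAP_CACHE: dict[str, str] | None = None


def load_family_map(path: str | Path | None = None) -> dict[str, str]:
    """Accession -> family map from the shipped (editable) TSV."""
    global _FAMILY_MAP_CACHE
    if path is None and _FAMILY_MAP_CACHE is not None:
        return _FAMILY_MAP_CACHE
    if path is None:
        source = resources.files("ampmine.data").joinpath("family_map.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            continue
        accession, family = fields[0], fields[1]
        if family not in FAMILY_PREFIX:
            raise ValueError(f"unknown family {family!r} in map")
        mapping[accession] = family
    if path is None:
        _FAMILY_MAP_CACHE = mapping
    return mapping


def classify_family(
    best_hit_accession: str,
    domains: list[DomainHit],
    name: str = "",
    family_map: dict[str, str] | None = None,
) -> tuple[str, str]:
    """Map a best-hit accession (plus domain evidence) to (family, prefix).

    Unknown accessions default to family ``other``; a detected WAP, Kazal or
    ALF-loop domain upgrades them to crustin / kazal / alf respectively.
    """
    if family_map is None:
        family_map = load_family_map()
    family = family_map.get(best_hit_accession, "other")
    if family == "other":
        for hit in domains:
            upgraded = _DOMAIN_FAMILY.get(hit.kind)
            if upgraded:
                family = upgraded
                break
    return family, FAMILY_PREFIX[family]


def flag_embedded(orf_protein_length: int, subject_span: tuple[int, int]) -> bool:
    """True when a short AMP match sits inside a large (>150 aa) protein.

    The hit must cover less than half of the protein; such candidates
    correspond to AMP-like regions embedded in long coding genes.
    """
    if orf_protein_length <= 150:
        return False
    covered = subject_span[1] - subject_span[0] + 1
    return covered < 0.5 * orf_protein_length
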