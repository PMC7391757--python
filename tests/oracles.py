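"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written without reusing the package's alignment or
ORF-scanning code paths: the alignment oracle is a plain three-matrix Gotoh
dynamic program over a dict-based matrix lookup, and the ORF oracle
enumerates every (strand, frame) combination codon by codon.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62_pair(x: str, y: str) -> int:
    if x == "X" or y == "X":
        return -1
    return int(_BLOSUM62[x, y])


def naive_sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Affine-gap local alignment score by a plain O(nm) Gotoh recursion.

    Gap of length k costs gap_open + (k - 1) * gap_extend.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]
    F = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0,
                H[i - 1][j - 1] + blosum62_pair(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            if H[i][j] > best:
                best = H[i][j]
    return best


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_CODON = {}
_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODON[_b1 + _b2 + _b3] = _AMINO[16 * _i + 4 * _j + _k]


def oracle_translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    return _CODON[codon]


def oracle_translate_frame(seq: str, frame: int) -> str:
    s = seq if frame > 0 else "".join(_COMP[c] for c in reversed(seq))
    off = abs(frame) - 1
    return "".join(
        oracle_translate_codon(s[i : i + 3]) for i in range(off, len(s) - 2, 3)
    )


def oracle_orfs(seq: str, min_aa: int) -> set[tuple]:
    """Exhaustive (strand, frame, stretch) enumeration of reportable ORFs.

    Returns tuples (strand, start_nt, end_nt, protein, completeness) with
    forward-strand 1-based inclusive coordinates excluding the stop codon.
    """
    L = len(seq)
    out: set[tuple] = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else "".join(_COMP[c] for c in reversed(seq))
        for off in range(3):
            aas = [
                oracle_translate_codon(s[i : i + 3])
                for i in range(off, L - 2, 3)
            ]
            n = len(aas)
            i = 0
            while i < n:
                if aas[i] == "*":
                    i += 1
                    continue
                j = i
                while j < n and aas[j] != "*":
                    j += 1
                # stretch of codon indices [i, j)
                stop_follows = j < n
                at_start = i == 0
                first_m = next((k for k in range(i, j) if aas[k] == "M"), None)
                span = None
                if stop_follows:
                    if first_m is not None:
                        span = (first_m, "complete")
                    elif at_start:
                        span = (i, "five_prime_fragment")
                else:
                    if first_m is not None:
                        span = (first_m, "three_prime_fragment")
                    elif at_start:
                        span = (i, "internal_fragment")
                    else:
                        span = (i, "three_prime_fragment")
                if span is not None and j - span[0] >= min_aa:
                    cm, completeness = span
                    protein = "".join(aas[cm:j])
                    if strand == "+":
                        start_nt = off + 3 * cm + 1
                        end_nt = off + 3 * j
                    else:
                        start_nt = L - off - 3 * j + 1
                        end_nt = L - off - 3 * cm
                    out.add((strand, start_nt, end_nt, protein, completeness))
                i = j
    return out
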