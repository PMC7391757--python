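"""RPKM expression quantification and tiering for candidate genes.

RPKM (reads per kilobase of transcript per million mapped reads) is
``1e9 * C / (L * N)`` for C mapped reads on a transcript of L nucleotides in
a library of N total reads.  Genes are tiered on their summed raw reads
across libraries with the printed anchors: more than 3,000 reads is high,
fewer than 100 is low, anything between is medium.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .seqio import CountsTable

TIERS = ("high", "medium", "low")


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene per-library expression."""

    gene_id: str
    library_id: str
    reads: int
    transcript_length: int
    library_total: int
    rpkm: float
    tier: str


def rpkm(reads: int, length_nt: int, library_total: int) -> float:
    """``1e9 * C / (L * N)``; scale-free in (C, N) jointly."""
    if length_nt <= 0 or library_total <= 0:
        raise ValueError("transcript length and library total must be positive")
    if reads < 0:
        raise ValueError("reads must be non-negative")
    return 1e9 * reads / (length_nt * library_total)


def tier(total_reads: int) -> str:
    """Expression tier from summed raw reads: >3000 high, <100 low."""
    if total_reads < 0:
        raise ValueError("reads must be non-negative")
    if total_reads > 3000:
        return "high"
    if total_reads < 100:
        return "low"
    return "medium"


def expression_table(
    counts: CountsTable, lengths: dict[str, int], gene_ids: list[str] | None = None
) -> list[ExpressionRecord]:
    """Expression records for the given genes (default: all with a length)."""
    if gene_ids is None:
        gene_ids = [g for g in counts.gene_ids if g in lengths]
    records: list[ExpressionRecord] = []
    for gene_id in gene_ids:
        if gene_id not in lengths:
            raise KeyError(f"no transcript length for {gene_id!r}")
        total = sum(counts.get(gene_id, lib) for lib in counts.library_ids)
        gene_tier = tier(total)
        for lib in counts.library_ids:
            reads = counts.get(gene_id, lib)
            n = counts.library_totals[lib]
            records.append(
                ExpressionRecord(
                    gene_id=gene_id,
                    library_id=lib,
                    reads=reads,
                    transcript_length=lengths[gene_id],
                    library_total=n,
                    rpkm=rpkm(reads, lengths[gene_id], n),
                    tier=gene_tier,
                )
            )
    return records


def summarize_mean_rpkm(records: list[ExpressionRecord]) -> pd.DataFrame:
    """Per-gene mean RPKM across libraries, sorted by descending mean."""
    if not records:
        return pd.DataFrame(columns=["gene_id", "mean_rpkm", "tier"])
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "rpkm": [r.rpkm for r in records],
            "tier": [r.tier for r in records],
        }
    )
    out = (
        df.groupby("gene_id", sort=False)
        .agg(mean_rpkm=("rpkm", "mean"), tier=("tier", "first"))
        .reset_index()
        .sort_values(["mean_rpkm", "gene_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return out


def records_to_frame(records: list[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "library_id": [r.library_id for r in records],
            "reads": [r.reads for r in records],
            "transcript_length": [r.transcript_length for r in records],
            "library_total": [r.library_total for r in records],
            "rpkm": [r.rpkm for r in records],
            "tier": [r.tier for r in records],
        }
    )
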