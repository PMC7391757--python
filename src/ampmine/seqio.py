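"""Readers and writers for the external formats the mining pipeline touches.

FASTA sequences (nucleotide contigs and protein references), APD-style
antimicrobial-peptide reference headers, tab-separated per-library read-count
tables, and the tab-separated candidate report.  All files are UTF-8 with
Unix line endings.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio.SeqIO.FastaIO import FastaWriter

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_APD_ACCESSION_RE = re.compile(r"^AP\d+$")


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: identifier, free-text description, residues.

    ``alphabet`` is either ``"nucleotide"`` or ``"protein"``; residues are
    upper-case and validated against the corresponding alphabet.
    """

    identifier: str
    description: str
    residues: str
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.identifier or any(c.isspace() for c in self.identifier):
            raise ValueError(f"bad identifier: {self.identifier!r}")
        if not self.residues:
            raise ValueError(f"record {self.identifier}: empty sequence")
        allowed = (
            NUCLEOTIDE_ALPHABET if self.alphabet == "nucleotide" else PROTEIN_ALPHABET
        )
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"record {self.identifier}: illegal {self.alphabet} "
                    f"residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AMPReferenceEntry:
    """A reference antimicrobial peptide with an APD-style accession."""

    accession: str
    name: str
    mature_sequence: str
    family_hint: str | None = None

    def __post_init__(self) -> None:
        if not _APD_ACCESSION_RE.match(self.accession):
            raise ValueError(f"accession {self.accession!r} is not APD-style")
        if len(self.mature_sequence) < 5:
            raise ValueError(f"{self.accession}: mature sequence shorter than 5 aa")


@dataclass
class CountsTable:
    """Per-library mapped-read counts with library totals.

    ``counts`` maps ``(gene_or_contig_id, library_id)`` to a non-negative
    integer; ids absent for a library count as zero.  ``library_totals`` come
    from an explicit TOTAL row when present, else from the column sums, and
    are never below the column sums.
    """

    library_ids: list[str]
    gene_ids: list[str]
    counts: dict[tuple[str, str], int]
    library_totals: dict[str, int]

    def get(self, gene_id: str, library_id: str) -> int:
        return self.counts.get((gene_id, library_id), 0)

    def column_sum(self, library_id: str) -> int:
        return sum(self.counts.get((g, library_id), 0) for g in self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        data = {
            lib: [self.get(g, lib) for g in self.gene_ids] for lib in self.library_ids
        }
        return pd.DataFrame(data, index=self.gene_ids)


def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Residues are upper-cased; headers split at the first whitespace into
    identifier and description; blank lines are ignored; record order is
    preserved.  An empty file raises ``ValueError("no records")``; residues
    outside the declared alphabet raise with the record name and position.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            SequenceRecord(
                identifier=rec.id,
                description=desc,
                residues=str(rec.seq).upper(),
                alphabet=alphabet,
            )
        )
    if not records:
        raise ValueError("no records")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    if width < 1:
        raise ValueError("width must be >= 1")
    bio_records = [
        _BioSeqRecord(Seq(r.residues), id=r.identifier, description=r.description)
        for r in records
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        writer = FastaWriter(handle, wrap=width)
        writer.write_file(bio_records)


def parse_amp_reference(
    records: Iterable[SequenceRecord],
) -> tuple[list[AMPReferenceEntry], int]:
    """Split APD-style headers ``APnnnnn_Name`` into reference entries.

    Headers whose identifier does not start with an ``AP``+digits token
    followed by ``_`` are skipped with a logged warning; the number of skips
    is returned alongside the parsed entries.
    """
    entries: list[AMPReferenceEntry] = []
    skipped = 0
    for rec in records:
        header = rec.identifier
        if rec.description:
            header = f"{header} {rec.description}"
        accession, _, name = header.partition("_")
        if not _APD_ACCESSION_RE.match(accession) or not name:
            logger.warning("skipping non-APD reference header %r", header)
            skipped += 1
            continue
        entries.append(
            AMPReferenceEntry(
                accession=accession, name=name, mature_sequence=rec.residues
            )
        )
    return entries, skipped


def read_counts_table(path: str | Path) -> CountsTable:
    """Read a tab-separated counts table.

    First column holds gene/contig ids, remaining columns one library each.
    An optional final row named ``TOTAL`` gives per-library totals (e.g. all
    mapped reads, not only the tabulated genes); otherwise totals are the
    column sums.  Duplicate ids and negative or non-integer cells are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate ids in counts table: {dupes}")
    library_ids = [str(c) for c in df.columns]
    parsed: dict[tuple[str, str], int] = {}
    totals_row: dict[str, int] | None = None
    gene_ids: list[str] = []
    for gene_id, row in df.iterrows():
        values: dict[str, int] = {}
        for lib in library_ids:
            cell = row[lib]
            try:
                value = int(str(cell))
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer count {cell!r} at row {gene_id!r}, column {lib!r}"
                ) from None
            if value < 0:
                raise ValueError(
                    f"negative count {value} at row {gene_id!r}, column {lib!r}"
                )
            values[lib] = value
        if str(gene_id) == "TOTAL":
            totals_row = values
            continue
        gene_ids.append(str(gene_id))
        for lib, value in values.items():
            parsed[(str(gene_id), lib)] = value
    column_sums = {
        lib: sum(parsed.get((g, lib), 0) for g in gene_ids) for lib in library_ids
    }
    if totals_row is not None:
        for lib in library_ids:
            if totals_row[lib] < column_sums[lib]:
                raise ValueError(
                    f"TOTAL for library {lib!r} ({totals_row[lib]}) is below "
                    f"the column sum ({column_sums[lib]})"
                )
        totals = totals_row
    else:
        totals = column_sums
    return CountsTable(
        library_ids=library_ids,
        gene_ids=gene_ids,
        counts=parsed,
        library_totals=totals,
    )


def write_counts_table(table: CountsTable, path: str | Path) -> None:
    """Write a counts table with a trailing TOTAL row."""
    df = table.to_frame()
    df.loc["TOTAL"] = [table.library_totals[lib] for lib in table.library_ids]
    df.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


CANDIDATE_COLUMNS = [
    "gene_id",
    "contig_ids",
    "best_hit_accession",
    "best_hit_name",
    "peptide_length_aa",
    "completeness",
    "signal_peptide_flag",
    "domain_list",
    "family",
    "embedded_flag",
    "score",
]


def write_candidate_table(candidates, path: str | Path) -> None:
    """Write the candidate report as TSV with a fixed column order.

    An empty candidate list yields a header-only file.
    """
    rows = []
    for c in candidates:
        rows.append(
            {
                "gene_id": c.gene_id,
                "contig_ids": "+".join(c.contig_ids),
                "best_hit_accession": c.best_hit.query_id,
                "best_hit_name": c.best_hit_name,
                "peptide_length_aa": len(c.orf.protein),
                "completeness": c.orf.completeness,
                "signal_peptide_flag": c.signal_peptide is not None,
                "domain_list": ";".join(d.kind for d in c.domains),
                "family": c.family,
                "embedded_flag": c.embedded,
                "score": c.best_hit.score,
            }
        )
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
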