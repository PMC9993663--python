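"""Readers and writers for the external formats the classifier touches.

FASTA/FASTQ parsing is delegated to Biopython; the lineage map, the
Kraken-style per-read table and the assignment table are small TSV
dialects owned by this package.

All coordinates anywhere in the package are 0-based, half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from Bio import SeqIO

#: Taxonomic ranks, most to least inclusive. Fixed order everywhere.
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")

#: Sentinel for a rank with no taxonomic label.
UNKNOWN: str = "NA"


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence: id is the first whitespace-delimited word of the header."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Lineage:
    """Six-rank lineage, phylum through species; unknown ranks hold ``NA``."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(
                f"lineage needs exactly {len(RANKS)} ranks, got {len(self.names)}"
            )

    def at(self, rank: str) -> str:
        return self.names[RANKS.index(rank)]

    def known(self, rank: str) -> bool:
        return self.at(rank) != UNKNOWN


@dataclass
class LineageMap:
    """genome_id -> Lineage; ids unique, every scored genome must be present."""

    lineages: dict[str, Lineage] = field(default_factory=dict)

    def __getitem__(self, genome_id: str) -> Lineage:
        return self.lineages[genome_id]

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)


@dataclass(frozen=True)
class KrakenRecord:
    """One line of Kraken2-style per-read output (columns 1-4 only)."""

    status: str  # "C" or "U"
    read_id: str
    taxon: str
    read_length: int


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Residues are uppercased; record ids are truncated at the first
    whitespace. Sequence data before the first header is an error.
    """
    records: list[SequenceRecord] = []
    with open(path) as handle:
        # Biopython silently skips junk before the first '>'; reject it instead.
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(f"{path}: sequence data before first FASTA header")
                break
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            records.append(
                SequenceRecord(
                    id=rec.id, residues=str(rec.seq).upper(), description=rec.description
                )
            )
    return records


def write_fasta(path: str | os.PathLike, records: Sequence[SequenceRecord], width: int = 70) -> None:
    with open(path, "w") as out:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            out.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


def _sniff_format(path: str | os.PathLike) -> str:
    with open(path) as handle:
        first = handle.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"{path}: cannot sniff format from first byte {first!r}")


def read_reads(path: str | os.PathLike, format: str = "auto") -> Iterator[SequenceRecord]:
    """Stream reads from FASTA or FASTQ (quality discarded), in file order.

    ``format='auto'`` sniffs the dialect from the first byte ('>' FASTA,
    '@' FASTQ). A FASTQ file whose line count is not a multiple of 4
    raises with the offending line number.
    """
    if format == "auto":
        format = _sniff_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown read format {format!r}")
    if format == "fasta":
        yield from read_fasta(path)
        return
    # FASTQ: validate 4-line record structure ourselves to report truncation.
    with open(path) as handle:
        lineno = 0
        while True:
            block = [handle.readline() for _ in range(4)]
            if block[0] == "":
                break
            if "" in block:
                raise ValueError(
                    f"{path}: truncated FASTQ record starting at line {lineno + 1}"
                )
            header, seq, plus, _qual = (s.rstrip("\n") for s in block)
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record at line {lineno + 1}")
            read_id = header[1:].split()[0]
            yield SequenceRecord(id=read_id, residues=seq.upper(), description=header[1:])
            lineno += 4


def write_fastq(path: str | os.PathLike, records: Sequence[SequenceRecord], quality_char: str = "I") -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f"@{rec.id}\n{rec.residues}\n+\n{quality_char * len(rec.residues)}\n")


def read_lineage_map(path: str | os.PathLike) -> LineageMap:
    """Read a 2-column TSV: genome_id, semicolon-joined 6-rank lineage."""
    lineages: dict[str, Lineage] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            genome_id, joined = cols
            names = tuple(joined.split(";"))
            if len(names) != len(RANKS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(RANKS)} ranks, got {len(names)}"
                )
            if genome_id in lineages:
                raise ValueError(f"{path}:{lineno}: duplicate genome_id {genome_id!r}")
            lineages[genome_id] = Lineage(names)
    return LineageMap(lineages)


def write_lineage_map(path: str | os.PathLike, lineage_map: LineageMap) -> None:
    with open(path, "w") as out:
        for genome_id, lineage in lineage_map.lineages.items():
            out.write(f"{genome_id}\t{';'.join(lineage.names)}\n")


def parse_kraken_output(path: str | os.PathLike) -> list[KrakenRecord]:
    """Parse Kraken2-style per-read output; only columns 1-4 are consumed."""
    records: list[KrakenRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns, got {len(cols)}")
            status, read_id, taxon, length = cols[:4]
            if status not in ("C", "U"):
                raise ValueError(f"{path}:{lineno}: status {status!r} not in {{C,U}}")
            records.append(KrakenRecord(status, read_id, taxon, int(length)))
    return records


def write_assignments(path: str | os.PathLike, assignments) -> None:
    """Write the per-read, per-rank assignment table.

    Columns: read_id, rank, taxon, probability (6 decimals), assigned in {0,1}.
    """
    with open(path, "w") as out:
        out.write("read_id\trank\ttaxon\tprobability\tassigned\n")
        for a in assignments:
            for rank in RANKS:
                taxon, prob, flag = a.at(rank)
                out.write(f"{a.read_id}\t{rank}\t{taxon}\t{prob:.6f}\t{int(flag)}\n")
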