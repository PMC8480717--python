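"""Reading and writing the plain-text formats the pipeline speaks.

FASTA/FASTQ parsing is delegated to Bio.SeqIO; gzip-compressed inputs are
detected by extension. Reference sequences are normalised on load: upper-cased
and U->T (miRBase mature sequences are RNA, the pipeline works in DNA space).
"""

from __future__ import annotations

import csv
import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

VALID_ROLES = ("host_ncrna", "host_genome", "microbiome", "plant_mirna")

_ALPHABET = frozenset("ACGTN")
_COLLAPSED_ID_RE = re.compile(r"^(?P<tag>.+)_x(?P<count>\d+)$")


def normalize_sequence(seq: str) -> str:
    """Upper-case and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class ReferenceRecord:
    """A single reference sequence (ncRNA, chromosome, microbial contig or mature miRNA)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"reference {self.id!r} contains invalid characters {sorted(bad)}"
            )


@dataclass
class ReferenceSet:
    """Role-tagged collection of reference records with unique ids."""

    role: str
    records: list[ReferenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown reference role {self.role!r}")
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate record ids in {self.role} reference set")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_fasta(cls, path: str | Path, role: str) -> "ReferenceSet":
        records = [
            ReferenceRecord(rec.id, normalize_sequence(str(rec.seq)))
            for rec in SeqIO.parse(_open_text(path), "fasta")
        ]
        return cls(role=role, records=records)


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def sniff_format(path: str | Path) -> str:
    """Decide fastq vs fasta from the first non-empty line."""
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    return "fasta"


def read_reads(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTA or FASTQ file, possibly gzipped.

    Sequences are normalised (upper-case, U->T); qualities are discarded —
    nothing downstream is quality-aware.
    """
    fmt = sniff_format(path)
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, normalize_sequence(str(rec.seq))


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write reads with flat placeholder qualities (phred 40)."""
    with open(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def parse_collapsed_id(read_id: str) -> tuple[str, int]:
    """Split a collapsed-read id ``<tag>_x<count>`` into (tag, count)."""
    m = _COLLAPSED_ID_RE.match(read_id)
    if m is None:
        raise ValueError(f"not a collapsed-read id (missing _x<count>): {read_id!r}")
    return m.group("tag"), int(m.group("count"))


def load_species_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: miRBase species prefix -> species name."""
    table: dict[str, str] = {}
    with open(path, "rt") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"species map row needs 2 columns: {row!r}")
            table[row[0].strip()] = row[1].strip()
    return table


def write_species_map(table: dict[str, str], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for prefix in sorted(table):
            fh.write(f"{prefix}\t{table[prefix]}\n")
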