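"""Layered host/microbiome read subtraction.

Reads are matched against references as contiguous substrings with a bounded
number of substitutions (no indels), bowtie ``-v``-style. The matcher uses the
pigeonhole principle: a query partitioned into ``max_mm + 1`` contiguous pieces
must have at least one piece occurring exactly in the reference whenever the
whole query matches with <= max_mm mismatches; exact piece hits seed candidate
sites that are then verified by full Hamming comparison. N never matches any
base (always a mismatch), so a piece containing N cannot be the exact piece —
the guarantee is unaffected.

Subtraction order is fixed: host ncRNA (<=2 mismatches, forward strand only —
mature ncRNAs are single-stranded), then host genome (<=1 mismatch, both
strands), then an optional microbiome layer (<=1 mismatch, both strands).
A read removed at one layer never reaches the next. R_i (total clean reads)
is never altered by subtraction.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

from .preprocess import CollapsedRead, CollapsedReadSet
from .io import ReferenceSet

LAYER_SPECS = (
    ("ncrna", 2, "forward"),
    ("genome", 1, "both"),
    ("microbiome", 1, "both"),
)

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Hit:
    """A verified match site, in forward-reference coordinates (0-based,
    half-open start; '-' means the read matches the reverse strand)."""

    ref_id: str
    start: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class RemovalLog:
    read_id: str
    layer: str
    ref_id: str
    mismatches: int


def _hamming_bounded(a: str, b: str, max_mm: int) -> int | None:
    """Mismatch count if <= max_mm else None; N is always a mismatch."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > max_mm:
                return None
    return mm


def _partition_offsets(length: int, pieces: int) -> list[tuple[int, int]]:
    """Split [0, length) into ``pieces`` near-equal contiguous intervals."""
    base, rem = divmod(length, pieces)
    out, pos = [], 0
    for i in range(pieces):
        size = base + (1 if i < rem else 0)
        out.append((pos, pos + size))
        pos += size
    return out


class PartitionIndex:
    """Substring index over a reference set supporting pigeonhole lookup."""

    def __init__(self, refset: ReferenceSet, max_mismatches: int):
        if max_mismatches not in (0, 1, 2):
            raise ValueError("max_mismatches must be 0, 1 or 2")
        self.refset = refset
        self.max_mm = max_mismatches
        # records concatenated with a separator so piece hits never straddle
        self._starts: list[int] = []
        parts = []
        pos = 0
        for rec in refset.records:
            self._starts.append(pos)
            parts.append(rec.sequence)
            pos += len(rec.sequence) + 1
        self.text = "\x00".join(parts)

    def _locate(self, start: int, length: int):
        """Map a concatenated-text window to (record, local_start), or None if
        it falls outside a single record."""
        if start < 0:
            return None
        i = bisect_right(self._starts, start) - 1
        rec = self.refset.records[i]
        local = start - self._starts[i]
        if local + length > len(rec.sequence):
            return None
        return rec, local

    def _find_oriented(self, query: str, strand: str, hits: dict) -> None:
        n_pieces = self.max_mm + 1
        for lo, hi in _partition_offsets(len(query), n_pieces):
            piece = query[lo:hi]
            at = self.text.find(piece)
            while at != -1:
                located = self._locate(at - lo, len(query))
                if located is not None:
                    rec, local = located
                    key = (rec.id, local, strand)
                    if key not in hits:
                        window = rec.sequence[local : local + len(query)]
                        mm = _hamming_bounded(query, window, self.max_mm)
                        if mm is not None:
                            hits[key] = mm
                at = self.text.find(piece, at + 1)

    def find(self, query: str, strands: str = "forward") -> list[Hit]:
        """All verified hit sites of the query (and, for strands='both', of
        its reverse complement) at <= max_mm substitutions."""
        if strands not in ("forward", "both"):
            raise ValueError("strands must be 'forward' or 'both'")
        if len(query) < self.max_mm + 1:
            raise ValueError("query shorter than the pigeonhole piece count")
        found: dict[tuple[str, int, str], int] = {}
        self._find_oriented(query, "+", found)
        if strands == "both":
            self._find_oriented(reverse_complement(query), "-", found)
        hits = [Hit(rid, start, strand, mm) for (rid, start, strand), mm in found.items()]
        hits.sort(key=lambda h: (h.mismatches, h.ref_id, h.start, h.strand))
        return hits


def build_partition_index(refset: ReferenceSet, max_mismatches: int) -> PartitionIndex:
    return PartitionIndex(refset, max_mismatches)


def matches_reference(
    read: CollapsedRead | str,
    refset: ReferenceSet | PartitionIndex,
    max_mm: int,
    strands: str = "forward",
) -> tuple[bool, list[Hit]]:
    """Does the read occur in some reference with <= max_mm substitutions?"""
    seq = read if isinstance(read, str) else read.sequence
    index = (
        refset
        if isinstance(refset, PartitionIndex)
        else PartitionIndex(refset, max_mm)
    )
    hits = index.find(seq, strands)
    return bool(hits), hits


def subtract_host(
    readset: CollapsedReadSet,
    ncrna: ReferenceSet,
    genome: ReferenceSet,
    microbiome: ReferenceSet | None = None,
) -> tuple[CollapsedReadSet, list[RemovalLog]]:
    """Remove host-attributable reads layer by layer; survivors keep the
    original total_clean_reads (R_i is defined on clean reads)."""
    if ncrna is None or genome is None:
        raise ValueError("ncRNA and genome reference sets are mandatory")
    layer_sets = {"ncrna": ncrna, "genome": genome, "microbiome": microbiome}
    layers = []
    for name, max_mm, strands in LAYER_SPECS:
        refset = layer_sets[name]
        if refset is None:
            continue
        layers.append((name, PartitionIndex(refset, max_mm), strands))

    survivors: list[CollapsedRead] = []
    removed: list[RemovalLog] = []
    for read in readset.reads:
        for name, index, strands in layers:
            hits = index.find(read.sequence, strands)
            if hits:
                best = hits[0]  # find() sorts by (mismatches, ref, pos, strand)
                removed.append(RemovalLog(read.id, name, best.ref_id, best.mismatches))
                break
        else:
            survivors.append(read)
    surviving = CollapsedReadSet(
        sample_id=readset.sample_id,
        reads=survivors,
        total_clean_reads=readset.total_clean_reads,
    )
    return surviving, removed


def write_removal_log(logs: list[RemovalLog], path) -> None:
    with open(path, "wt") as fh:
        fh.write("read_id\tlayer\tref_id\tmismatches\n")
        for log in logs:
            fh.write(f"{log.read_id}\t{log.layer}\t{log.ref_id}\t{log.mismatches}\n")
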