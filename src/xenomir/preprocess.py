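"""Raw-read preprocessing: 3' adapter/polyA trimming, length filtering,
read collapsing and the sample QC/eligibility report.

Small RNA libraries read through the insert into the 3' sequencing adapter,
so trimming removes the best-matching adapter occurrence and everything after
it. Clean reads (18-30 nt survivors) are collapsed to unique sequences with an
abundance suffix ``_x<count>``; the clean-read total R_i collected here is the
RPM denominator used by the quantify stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30
DEFAULT_MIN_CLEAN_READS = 100_000
DEFAULT_MIN_CONCENTRATION = 0.5
# "concentrated" length window for the QC criterion
CONCENTRATION_RANGE = (20, 26)


@dataclass(frozen=True)
class RawRead:
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality string length differs from sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence with its multiplicity, id ``<tag>_x<count>``."""

    id: str
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("collapsed-read count must be >= 1")
        if not self.id.endswith(f"_x{self.count}"):
            raise ValueError(f"id {self.id!r} does not carry suffix _x{self.count}")


@dataclass
class CollapsedReadSet:
    """A sample's unique reads plus the clean-read total R_i.

    After host subtraction the surviving subset still carries the original
    R_i (RPM is defined on clean reads, not on survivors), so the
    counts-sum-to-total invariant is asserted via :meth:`validate`, not on
    construction.
    """

    sample_id: str
    reads: list[CollapsedRead]
    total_clean_reads: int

    def validate(self) -> None:
        total = sum(r.count for r in self.reads)
        if total != self.total_clean_reads:
            raise ValueError(
                f"counts sum to {total}, expected total_clean_reads={self.total_clean_reads}"
            )
        seqs = [r.sequence for r in self.reads]
        if len(seqs) != len(set(seqs)):
            raise ValueError("duplicate sequences in collapsed read set")


@dataclass
class QCReport:
    clean_read_count: int
    length_histogram: dict[int, int]
    concentration_fraction: float
    eligible: bool
    reasons: list[str] = field(default_factory=list)


def _hamming(a: str, b: str) -> int:
    # N never matches anything, including another N
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def trim_read(
    read: RawRead,
    adapter: str,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
    polya_min_run: int = 10,
) -> RawRead:
    """Remove the best-matching 3' adapter occurrence (and all bases after it),
    then any trailing polyA run of length >= ``polya_min_run``.

    Candidate occurrences are every alignment of the adapter's prefix against
    a suffix-anchored window of the read with overlap >= ``min_overlap`` and
    substitution error rate <= ``max_error_rate``. The occurrence maximising
    the number of matching bases wins (ties: fewer errors, then leftmost), so
    a full-length adapter hit beats any spurious short overlap.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not (0 <= max_error_rate < 0.5):
        raise ValueError("max_error_rate must be in [0, 0.5)")

    seq = read.sequence
    best: tuple[int, int, int] | None = None  # (-matches, errors, pos)
    for pos in range(len(seq)):
        overlap = min(len(adapter), len(seq) - pos)
        if overlap < min_overlap:
            break
        errors = _hamming(seq[pos : pos + overlap], adapter[:overlap])
        if errors <= max_error_rate * overlap:
            key = (-(overlap - errors), errors, pos)
            if best is None or key < best:
                best = key
    cut = len(seq) if best is None else best[2]
    seq = seq[:cut]

    # trailing polyA
    run = len(seq) - len(seq.rstrip("A"))
    if run >= polya_min_run:
        seq = seq[: len(seq) - run]

    qual = read.quality[: len(seq)] if read.quality is not None else None
    return RawRead(seq, qual)


def filter_by_length(
    reads: Iterable[RawRead],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[RawRead]:
    """Keep reads with min_len <= length <= max_len, order preserved."""
    if not (0 < min_len <= max_len):
        raise ValueError("require 0 < min_len <= max_len")
    return [r for r in reads if min_len <= len(r) <= max_len]


def collapse_reads(reads: Sequence[RawRead], sample_id: str) -> CollapsedReadSet:
    """Collapse identical sequences into unique records with multiplicities.

    Deterministic ordering: count descending, then sequence ascending; ids are
    ``seq<k>_x<count>`` with k starting at 1 so output is byte-stable.
    """
    counts: dict[str, int] = {}
    for r in reads:
        counts[r.sequence] = counts.get(r.sequence, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    collapsed = [
        CollapsedRead(id=f"seq{k}_x{n}", sequence=seq, count=n)
        for k, (seq, n) in enumerate(ordered, start=1)
    ]
    return CollapsedReadSet(
        sample_id=sample_id, reads=collapsed, total_clean_reads=len(reads)
    )


def qc_report(
    readset: CollapsedReadSet,
    min_clean_reads: int = DEFAULT_MIN_CLEAN_READS,
    min_concentration: float = DEFAULT_MIN_CONCENTRATION,
) -> QCReport:
    """Sample eligibility: clean reads strictly above ``min_clean_reads`` and
    the 20-26 nt fraction at least ``min_concentration``."""
    hist: dict[int, int] = {}
    for r in readset.reads:
        hist[len(r.sequence)] = hist.get(len(r.sequence), 0) + r.count
    total = readset.total_clean_reads
    lo, hi = CONCENTRATION_RANGE
    in_window = sum(n for length, n in hist.items() if lo <= length <= hi)
    frac = in_window / total if total else 0.0

    reasons = []
    if not total > min_clean_reads:
        reasons.append("clean_reads")
    if not frac >= min_concentration:
        reasons.append("length_concentration")
    return QCReport(
        clean_read_count=total,
        length_histogram=dict(sorted(hist.items())),
        concentration_fraction=frac,
        eligible=not reasons,
        reasons=reasons,
    )


def preprocess_reads(
    raw: Sequence[RawRead],
    sample_id: str,
    adapter: str | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    **trim_kwargs,
) -> tuple[CollapsedReadSet, QCReport]:
    """Convenience: trim (if an adapter is given), length-filter, collapse, QC."""
    trimmed = (
        [trim_read(r, adapter, **trim_kwargs) for r in raw] if adapter else list(raw)
    )
    kept = filter_by_length(trimmed, min_len, max_len)
    readset = collapse_reads(kept, sample_id)
    return readset, qc_report(readset)


def write_collapsed_fasta(readset: CollapsedReadSet, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for r in readset.reads:
            fh.write(f">{r.id}\n{r.sequence}\n")


def read_collapsed_fasta(
    path: str | Path, sample_id: str, total_clean_reads: int | None = None
) -> CollapsedReadSet:
    """Load a collapsed FASTA; R_i defaults to the sum of ``_x`` counts."""
    from .io import parse_collapsed_id, read_reads

    reads = []
    for rid, seq in read_reads(path):
        _, count = parse_collapsed_id(rid)
        reads.append(CollapsedRead(id=rid, sequence=seq, count=count))
    total = (
        total_clean_reads
        if total_clean_reads is not None
        else sum(r.count for r in reads)
    )
    return CollapsedReadSet(sample_id=sample_id, reads=reads, total_clean_reads=total)


def write_qc_tsv(report: QCReport, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("criterion\tvalue\tpassed\n")
        fh.write(
            f"clean_reads\t{report.clean_read_count}\t{'clean_reads' not in report.reasons}\n"
        )
        fh.write(
            "length_concentration\t"
            f"{report.concentration_fraction:.4f}\t"
            f"{'length_concentration' not in report.reasons}\n"
        )
        fh.write(f"eligible\t{report.eligible}\t{report.eligible}\n")
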