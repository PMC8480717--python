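"""Penalty-scored annotation of candidate reads against plant mature miRNAs.

Each candidate read is globally aligned to every plant mature miRNA reference
under a penalty scheme: match 0, mismatch 4, extra base on either side
(i.e. a gap) 3. The minimum-penalty alignment is found by banded dynamic
programming — given the retention rules, only alignments within a narrow band
around the main diagonal can ever be retained, so a band half-width of 2 is
sufficient and is the default.

An annotation is retained only when all of these hold simultaneously:
total score < 7, at most one mismatch, and at most one nucleotide of length
difference between read and reference. The retainable alignment patterns are
therefore exactly: identity (0), one extra base on one side (3), one mismatch
(4), and one insertion plus one deletion (6). A score-6 alignment made of two
same-direction extra bases implies a 2-nt length difference and is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .preprocess import CollapsedRead, CollapsedReadSet
from .io import ReferenceSet

MISMATCH_PENALTY = 4
EXTRA_BASE_PENALTY = 3
RETENTION_SCORE_LIMIT = 7  # retained iff score strictly below this
MAX_MISMATCHES = 1
MAX_LENGTH_DIFF = 1
MAX_SEQ_LEN = 50
_BIG = 1 << 30


@dataclass(frozen=True)
class AlignmentScore:
    """Penalty decomposition of the optimal global alignment."""

    score: int
    n_mismatch: int
    n_extra_query: int
    n_extra_ref: int

    @property
    def length_diff(self) -> int:
        return abs(self.n_extra_query - self.n_extra_ref)

    def __post_init__(self) -> None:
        expected = MISMATCH_PENALTY * self.n_mismatch + EXTRA_BASE_PENALTY * (
            self.n_extra_query + self.n_extra_ref
        )
        if self.score != expected:
            raise ValueError(
                f"score {self.score} inconsistent with decomposition (expected {expected})"
            )


@dataclass
class Annotation:
    query_sequence: str
    query_count: int
    best_refs: list[str]
    score: AlignmentScore
    retained: bool
    ambiguous: bool = field(default=False)  # set later by classify.assign_counts


def score_pair(query: str, ref: str, band: int = 2) -> AlignmentScore:
    """Minimum-penalty global alignment of two short sequences.

    The DP is restricted to cells within ``max(band, |len diff|)`` of the main
    diagonal. Cell values are (score, mismatches, extra_query, extra_ref)
    tuples minimised lexicographically, so among equal-score alignments the one
    with fewest mismatches is reported (scores below 7 have a unique
    decomposition anyway). N never matches any base.
    """
    if not query or not ref:
        raise ValueError("sequences must be non-empty")
    if len(query) > MAX_SEQ_LEN or len(ref) > MAX_SEQ_LEN:
        raise ValueError(f"sequences longer than {MAX_SEQ_LEN} nt are unsupported")
    m, n = len(query), len(ref)
    # A path that leaves the band |i-j| <= h spends at least 2(h+1) - |m-n|
    # gaps, i.e. >= 3*(2(h+1) - |m-n|) penalty. Double the band until the
    # in-band optimum beats that bound, so the reported score is the true
    # global optimum; retainable alignments (score < 7) never trigger an
    # expansion beyond the default half-width of 2.
    half = max(band, abs(m - n))
    while True:
        s, mm, xq, xr = _banded_dp(query, ref, half)
        off_band_floor = EXTRA_BASE_PENALTY * (2 * (half + 1) - abs(m - n))
        if s < off_band_floor or half >= max(m, n):
            return AlignmentScore(score=s, n_mismatch=mm, n_extra_query=xq, n_extra_ref=xr)
        half *= 2


def _banded_dp(query: str, ref: str, half: int) -> tuple[int, int, int, int]:
    m, n = len(query), len(ref)

    INF = (_BIG, 0, 0, 0)
    prev: list[tuple[int, int, int, int]] = [INF] * (n + 1)
    prev[0] = (0, 0, 0, 0)
    for j in range(1, min(n, half) + 1):
        s, mm, xq, xr = prev[j - 1]
        prev[j] = (s + EXTRA_BASE_PENALTY, mm, xq, xr + 1)

    for i in range(1, m + 1):
        cur: list[tuple[int, int, int, int]] = [INF] * (n + 1)
        lo, hi = max(0, i - half), min(n, i + half)
        for j in range(lo, hi + 1):
            best = INF
            if j >= 1 and prev[j - 1][0] < _BIG:
                s, mm, xq, xr = prev[j - 1]
                a, b = query[i - 1], ref[j - 1]
                if a == b and a != "N":
                    cand = (s, mm, xq, xr)
                else:
                    cand = (s + MISMATCH_PENALTY, mm + 1, xq, xr)
                if cand < best:
                    best = cand
            if prev[j][0] < _BIG:  # consume a query base: extra base in query
                s, mm, xq, xr = prev[j]
                cand = (s + EXTRA_BASE_PENALTY, mm, xq + 1, xr)
                if cand < best:
                    best = cand
            if j >= 1 and cur[j - 1][0] < _BIG:  # consume a ref base
                s, mm, xq, xr = cur[j - 1]
                cand = (s + EXTRA_BASE_PENALTY, mm, xq, xr + 1)
                if cand < best:
                    best = cand
            cur[j] = best
        prev = cur

    if prev[n][0] >= _BIG:
        raise RuntimeError("band does not reach the final cell")  # unreachable
    return prev[n]


def is_retainable(score: AlignmentScore) -> bool:
    return (
        score.score < RETENTION_SCORE_LIMIT
        and score.n_mismatch <= MAX_MISMATCHES
        and score.length_diff <= MAX_LENGTH_DIFF
    )


def annotate_read(
    query: CollapsedRead, plant_refs: ReferenceSet
) -> Annotation | None:
    """Best-scoring annotation of one read, or None if nothing is retainable.

    All references are scanned (references differing by more than 1 nt in
    length are skipped — they can never satisfy the length constraint) and
    every reference tied at the minimal score is listed, sorted
    lexicographically. The scan order never affects the result.
    """
    if plant_refs.role != "plant_mirna":
        raise ValueError("annotate_read requires a plant_mirna reference set")
    best_score: AlignmentScore | None = None
    best_ids: list[str] = []
    for rec in plant_refs.records:
        if abs(len(rec.sequence) - len(query.sequence)) > MAX_LENGTH_DIFF:
            continue
        s = score_pair(query.sequence, rec.sequence)
        if best_score is None or s.score < best_score.score:
            best_score, best_ids = s, [rec.id]
        elif s.score == best_score.score:
            best_ids.append(rec.id)
    if best_score is None:
        return None
    annotation = Annotation(
        query_sequence=query.sequence,
        query_count=query.count,
        best_refs=sorted(best_ids),
        score=best_score,
        retained=is_retainable(best_score),
    )
    return annotation if annotation.retained else None


def annotate_all(
    survivors: CollapsedReadSet, plant_refs: ReferenceSet
) -> tuple[list[Annotation], list[Annotation]]:
    """Annotate every surviving read.

    Returns (retained, rejected); rejected annotations carry their best
    (rejected) score for diagnostics. Reads with no length-compatible
    reference at all are omitted from both lists.
    """
    retained: list[Annotation] = []
    rejected: list[Annotation] = []
    for read in survivors.reads:
        ann = annotate_read(read, plant_refs)
        if ann is not None:
            retained.append(ann)
            continue
        # recompute best score without the retention gate, for diagnostics
        best: AlignmentScore | None = None
        best_ids: list[str] = []
        for rec in plant_refs.records:
            if abs(len(rec.sequence) - len(read.sequence)) > MAX_LENGTH_DIFF:
                continue
            s = score_pair(read.sequence, rec.sequence)
            if best is None or s.score < best.score:
                best, best_ids = s, [rec.id]
            elif s.score == best.score:
                best_ids.append(rec.id)
        if best is not None:
            rejected.append(
                Annotation(
                    query_sequence=read.sequence,
                    query_count=read.count,
                    best_refs=sorted(best_ids),
                    score=best,
                    retained=False,
                )
            )
    return retained, rejected


def write_annotations_tsv(
    retained: list[Annotation], rejected: list[Annotation], path
) -> None:
    with open(path, "wt") as fh:
        fh.write(
            "query_sequence\tcount\tscore\tn_mismatch\tn_extra_query\t"
            "n_extra_ref\tbest_refs\tretained\n"
        )
        for ann in list(retained) + list(rejected):
            s = ann.score
            fh.write(
                f"{ann.query_sequence}\t{ann.query_count}\t{s.score}\t"
                f"{s.n_mismatch}\t{s.n_extra_query}\t{s.n_extra_ref}\t"
                f"{';'.join(ann.best_refs)}\t{ann.retained}\n"
            )


def read_annotations_tsv(path) -> tuple[list[Annotation], list[Annotation]]:
    retained: list[Annotation] = []
    rejected: list[Annotation] = []
    with open(path, "rt") as fh:
        header = fh.readline()
        if not header.startswith("query_sequence"):
            raise ValueError("not an annotation TSV")
        for line in fh:
            seq, count, score, mm, xq, xr, refs, kept = line.rstrip("\n").split("\t")
            ann = Annotation(
                query_sequence=seq,
                query_count=int(count),
                best_refs=refs.split(";") if refs else [],
                score=AlignmentScore(int(score), int(mm), int(xq), int(xr)),
                retained=kept == "True",
            )
            (retained if ann.retained else rejected).append(ann)
    return retained, rejected
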