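"""Independent reference implementations used only to check the package.

Each oracle takes the dumbest correct route: full-matrix DP with plain ints,
exhaustive per-offset Hamming scans via numpy, textbook closed-form
statistics. None of them share code with the package internals they verify.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def full_dp_score(a: str, b: str, mismatch: int = 4, gap: int = 3) -> int:
    """Unbanded full-matrix global alignment penalty (ints only)."""
    m, n = len(a), len(b)
    prev = [j * gap for j in range(n + 1)]
    for i in range(1, m + 1):
        cur = [i * gap] + [0] * n
        ai = a[i - 1]
        for j in range(1, n + 1):
            sub = prev[j - 1] + (0 if ai == b[j - 1] and ai != "N" else mismatch)
            cur[j] = min(sub, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[n]


def exhaustive_hits(
    query: str, references: list[tuple[str, str]], max_mm: int, strands: str
) -> set[tuple[str, int, str, int]]:
    """Every (ref_id, start, strand, mismatches) site with <= max_mm
    substitutions, by scanning all offsets with numpy. No N handling —
    fixtures using this oracle are N-free."""
    out: set[tuple[str, int, str, int]] = set()
    oriented = [(query, "+")]
    if strands == "both":
        oriented.append((revcomp(query), "-"))
    for q, strand in oriented:
        q_arr = np.frombuffer(q.encode(), dtype=np.uint8)
        for ref_id, ref_seq in references:
            if len(ref_seq) < len(q):
                continue
            arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
            windows = sliding_window_view(arr, len(q))
            mm = (windows != q_arr).sum(axis=1)
            for start in np.nonzero(mm <= max_mm)[0]:
                out.add((ref_id, int(start), strand, int(mm[start])))
    return out


def min_hamming_scan(query: str, ref_seq: str, both_strands: bool = True) -> int:
    """Minimum Hamming distance of the query to any same-length window,
    plain Python loops."""
    best = len(query)
    targets = [query, revcomp(query)] if both_strands else [query]
    for q in targets:
        for start in range(len(ref_seq) - len(q) + 1):
            window = ref_seq[start : start + len(q)]
            best = min(best, sum(1 for x, y in zip(q, window) if x != y))
    return best


def brute_trim_cut(
    seq: str, adapter: str, min_overlap: int = 3, max_error_rate: float = 0.1
) -> int:
    """Cut position chosen by scanning every 3' suffix / adapter-prefix
    overlap and scoring Hamming errors; most matching bases wins, ties by
    fewer errors then leftmost."""
    best = None
    for pos in range(len(seq)):
        overlap = min(len(adapter), len(seq) - pos)
        if overlap < min_overlap:
            continue
        errors = sum(1 for x, y in zip(seq[pos : pos + overlap], adapter) if x != y)
        if errors <= max_error_rate * overlap:
            key = (-(overlap - errors), errors, pos)
            if best is None or key < best:
                best = key
    return len(seq) if best is None else best[2]


def pooled_ttest(x: list[float], y: list[float]) -> tuple[float, float, float]:
    """Textbook pooled-variance two-sample two-sided t-test: (t, df, p)."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    sx2 = sum((v - mx) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - my) ** 2 for v in y) / (ny - 1)
    df = nx + ny - 2
    sp = (((nx - 1) * sx2 + (ny - 1) * sy2) / df) ** 0.5
    t = (mx - my) / (sp * (1 / nx + 1 / ny) ** 0.5)
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, float(df), p


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute exactly n_subs distinct positions to different bases."""
    chars = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        chars[pos] = rng.choice([b for b in "ACGT" if b != chars[pos]])
    return "".join(chars)
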