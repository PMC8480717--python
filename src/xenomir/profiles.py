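"""Cross-sample comparison: sample x group matrices, presence/overlap among
sample classes (body fluids, tissues, species), per-species source tallies and
unpaired Student's t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from scipy import stats

from .classify import MiRNAGroup
from .quantify import SampleProfile, log_transform

DEFAULT_ALPHA = 0.05


@dataclass
class ProfileMatrix:
    """RPM values as a samples x groups DataFrame plus a sample->class map."""

    data: pd.DataFrame
    classes: dict[str, str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def group_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    degenerate: bool = False


def build_matrix(
    profiles: list[SampleProfile], class_map: dict[str, str]
) -> ProfileMatrix:
    """Assemble per-sample profiles into one rectangular RPM matrix.

    Columns are the union of all group ids; missing cells are 0. Rows and
    columns are sorted so the result is independent of input order.
    """
    ids = [p.sample_id for p in profiles]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample ids")
    cells = {
        p.sample_id: {r.group_id: r.rpm for r in p.records} for p in profiles
    }
    df = pd.DataFrame.from_dict(cells, orient="index").fillna(0.0)
    df = df.sort_index(axis=0).sort_index(axis=1)
    missing = [sid for sid in ids if sid not in class_map]
    if missing:
        raise ValueError(f"samples missing from class map: {missing}")
    return ProfileMatrix(data=df, classes={sid: class_map[sid] for sid in ids})


def presence_overlap(
    matrix: ProfileMatrix,
    classes: list[str] | None = None,
    min_rpm: float = 0.0,
) -> tuple[dict[tuple[str, ...], int], dict[str, float]]:
    """Venn-region counts of group presence across sample classes.

    A group is present in a class iff its RPM exceeds ``min_rpm`` (default:
    any detection) in at least one sample of that class. Returns
    (region counts keyed by the sorted tuple of classes a group is present in,
    over every non-empty subset; per-class fraction of its present groups that
    are unique to it).
    """
    if classes is None:
        classes = sorted(set(matrix.classes.values()))
    if not classes:
        raise ValueError("at least one class required")
    present: dict[str, set[str]] = {c: set() for c in classes}
    for c in classes:
        samples = [s for s, cls in matrix.classes.items() if cls == c]
        sub = matrix.data.loc[samples]
        for gid in matrix.group_ids:
            if (sub[gid] > min_rpm).any():
                present[c].add(gid)

    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(classes) + 1):
        for subset in combinations(classes, k):
            regions[subset] = 0
    all_present = set().union(*present.values())
    for gid in all_present:
        membership = tuple(c for c in classes if gid in present[c])
        regions[membership] += 1

    unique_fraction = {}
    for c in classes:
        n_present = len(present[c])
        n_unique = regions[(c,)]
        unique_fraction[c] = n_unique / n_present if n_present else 0.0
    return regions, unique_fraction


def species_source_counts(groups: list[MiRNAGroup]) -> dict[str, int]:
    """Per species (prefix code), the number of distinct miRNA families among
    groups tracing to that species. Family conservation means one sequence can
    credit many species; all are counted."""
    families: dict[str, set[str]] = {}
    for g in groups:
        for prefix in g.species:
            families.setdefault(prefix, set()).add(g.family)
    return {sp: len(fams) for sp, fams in sorted(families.items())}


def ttest_unpaired(
    x: list[float],
    y: list[float],
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
) -> TTestResult:
    """Two-sided unpaired Student's t-test (pooled variance; Welch optional).

    Degenerate zero-variance inputs: identical means give t=0, p=1; unequal
    means give p=0 with the degenerate flag set.
    """
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    if vx == 0.0 and vy == 0.0:
        df = float(nx + ny - 2)
        if mx == my:
            return TTestResult(0.0, df, 1.0, significant=1.0 < alpha)
        t = math.copysign(math.inf, mx - my)
        return TTestResult(t, df, 0.0, significant=0.0 < alpha, degenerate=True)
    res = stats.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df)
    p = float(res.pvalue)
    return TTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=df,
        p_value=p,
        significant=p < alpha,
    )


def adjust_pvalues(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (off by default everywhere)."""
    return list(stats.false_discovery_control(pvalues, method="bh"))


def class_abundance_tests(
    matrix: ProfileMatrix,
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
) -> pd.DataFrame:
    """Pairwise class comparisons of per-sample total abundance.

    Each sample is summarised as log10(total RPM + 1); classes with >= 2
    samples are compared pairwise by the unpaired t-test.
    """
    totals = matrix.data.sum(axis=1).map(log_transform)
    by_class: dict[str, list[float]] = {}
    for sid, cls in matrix.classes.items():
        by_class.setdefault(cls, []).append(float(totals[sid]))
    rows = []
    for a, b in combinations(sorted(by_class), 2):
        if len(by_class[a]) < 2 or len(by_class[b]) < 2:
            continue
        res = ttest_unpaired(by_class[a], by_class[b], alpha=alpha, welch=welch)
        rows.append(
            {
                "comparison": f"{a}_vs_{b}",
                "t": res.t_statistic,
                "df": res.degrees_of_freedom,
                "p": res.p_value,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows, columns=["comparison", "t", "df", "p", "significant"])


def write_overlap_tsv(regions: dict[tuple[str, ...], int], path) -> None:
    with open(path, "wt") as fh:
        fh.write("classes\tcount\n")
        for subset in sorted(regions, key=lambda s: (len(s), s)):
            fh.write(f"{'+'.join(subset)}\t{regions[subset]}\n")
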