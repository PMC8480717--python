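"""Per-group abundance: RPM and its log transform.

N_i = C_i x 10^6 / R_i, where C_i is a group's raw read count in sample i and
R_i the sample's clean-read total (after trimming and length filtering, before
host subtraction). For display and cross-sample comparison the RPM is
log-transformed as log10(N_i + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .classify import MiRNAGroup
from .preprocess import CollapsedReadSet

RPM_SCALE = 1_000_000


@dataclass(frozen=True)
class AbundanceRecord:
    group_id: str
    raw_count: int
    rpm: float
    log_rpm: float


@dataclass
class SampleProfile:
    sample_id: str
    total_clean_reads: int
    records: list[AbundanceRecord]


def rpm(raw_count: int, clean_reads: int, sample_id: str = "?") -> float:
    """Reads per million: raw_count x 10^6 / clean_reads."""
    if clean_reads <= 0:
        raise ZeroDivisionError(
            f"sample {sample_id}: clean-read total must be positive, got {clean_reads}"
        )
    if raw_count < 0:
        raise ValueError("raw_count must be non-negative")
    return raw_count * RPM_SCALE / clean_reads


def log_transform(rpm_value: float) -> float:
    """log10(rpm + 1); defined (and 0) at rpm = 0."""
    if rpm_value < 0:
        raise ValueError(f"rpm must be non-negative, got {rpm_value}")
    return math.log10(rpm_value + 1.0)


def build_profile(
    groups: list[MiRNAGroup],
    readset: CollapsedReadSet,
    dense: bool = False,
) -> SampleProfile:
    """One abundance record per group; zero-count groups are omitted unless
    ``dense`` is set. R_i is taken from the read set's clean-read total."""
    records = []
    for g in groups:
        if g.raw_count == 0 and not dense:
            continue
        value = rpm(g.raw_count, readset.total_clean_reads, readset.sample_id)
        records.append(
            AbundanceRecord(
                group_id=g.group_id,
                raw_count=g.raw_count,
                rpm=value,
                log_rpm=log_transform(value),
            )
        )
    return SampleProfile(
        sample_id=readset.sample_id,
        total_clean_reads=readset.total_clean_reads,
        records=records,
    )


def write_profile_tsv(profile: SampleProfile, path) -> None:
    with open(path, "wt") as fh:
        fh.write("sample_id\ttotal_clean_reads\tgroup_id\traw_count\trpm\tlog_rpm\n")
        for r in profile.records:
            fh.write(
                f"{profile.sample_id}\t{profile.total_clean_reads}\t"
                f"{r.group_id}\t{r.raw_count}\t{r.rpm:.6f}\t{r.log_rpm:.6f}\n"
            )


def read_profile_tsv(path) -> SampleProfile:
    sample_id = None
    total = None
    records = []
    with open(path, "rt") as fh:
        fh.readline()
        for line in fh:
            sid, tot, gid, count, rpm_v, log_v = line.rstrip("\n").split("\t")
            if sample_id is None:
                sample_id, total = sid, int(tot)
            elif sid != sample_id:
                raise ValueError("profile TSV mixes sample ids")
            records.append(
                AbundanceRecord(gid, int(count), float(rpm_v), float(log_v))
            )
    if sample_id is None:
        raise ValueError("empty profile TSV")
    return SampleProfile(sample_id=sample_id, total_clean_reads=total, records=records)
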