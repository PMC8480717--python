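"""End-to-end orchestration of a single sample: preprocess -> host filter ->
annotate -> classify -> quantify."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .annotate import Annotation, annotate_all
from .classify import MiRNAGroup, assign_counts, group_identical_sequences
from .hostfilter import RemovalLog, subtract_host
from .io import ReferenceSet
from .preprocess import (
    CollapsedReadSet,
    QCReport,
    RawRead,
    preprocess_reads,
)
from .quantify import SampleProfile, build_profile


@dataclass
class SampleResult:
    readset: CollapsedReadSet
    qc: QCReport
    survivors: CollapsedReadSet
    removal_log: list[RemovalLog]
    annotations: list[Annotation]
    rejected: list[Annotation]
    groups: list[MiRNAGroup]
    profile: SampleProfile


def run_sample(
    raw_reads: Sequence[RawRead],
    sample_id: str,
    ncrna: ReferenceSet,
    genome: ReferenceSet,
    plant: ReferenceSet,
    microbiome: ReferenceSet | None = None,
    adapter: str | None = None,
    dense: bool = False,
    **preprocess_kwargs,
) -> SampleResult:
    """Run the full pipeline on raw reads and return every intermediate."""
    readset, qc = preprocess_reads(
        raw_reads, sample_id, adapter=adapter, **preprocess_kwargs
    )
    survivors, removal_log = subtract_host(readset, ncrna, genome, microbiome)
    annotations, rejected = annotate_all(survivors, plant)
    groups = assign_counts(annotations, group_identical_sequences(plant))
    profile = build_profile(groups, readset, dense=dense)
    return SampleResult(
        readset=readset,
        qc=qc,
        survivors=survivors,
        removal_log=removal_log,
        annotations=annotations,
        rejected=rejected,
        groups=groups,
        profile=profile,
    )
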