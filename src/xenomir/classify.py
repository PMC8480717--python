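"""Sequence-identity grouping of plant miRNA references and species tracing.

Plant mature miRNA families are deeply conserved: the same mature sequence is
often deposited under many species in miRBase (osa-miR168a-5p, zma-miR168a-5p,
...). References with identical sequence are merged into one group named
``<family>_<N>`` where N is the number of merged reference entries, read
counts are assigned at group level — so a read matching five identical
deposits is counted once, not five times — and each group's candidate source
species is the union of its members' miRBase species prefixes.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .annotate import Annotation
from .io import ReferenceSet

# miRBase mature id grammar: <3-4 letter species prefix>-miR<digits><variant>
_ID_RE = re.compile(r"^([A-Za-z]{3,4})-(mir|miR|MIR)(\d+)(.*)$")


@dataclass(frozen=True)
class MirnaId:
    raw: str
    species_prefix: str
    family: str  # canonical, e.g. "miR168"
    variant: str  # residual suffix, e.g. "a-5p"


def parse_mirbase_id(raw: str) -> MirnaId:
    """Parse a miRBase-style mature miRNA id.

    ``osa-miR168a-5p`` -> prefix ``osa``, family ``miR168``, variant ``a-5p``.
    The family token is case-normalised to ``miR<digits>``.
    """
    if not raw:
        raise ValueError("empty miRNA id")
    m = _ID_RE.match(raw)
    if m is None:
        raise ValueError(f"unparseable miRBase id: {raw!r}")
    prefix, _mir, digits, rest = m.groups()
    return MirnaId(
        raw=raw, species_prefix=prefix.lower(), family=f"miR{digits}", variant=rest
    )


@dataclass
class MiRNAGroup:
    """References sharing one mature sequence, with group-level counts.

    ``raw_count`` (C_i) sums every contributing read's multiplicity, including
    reads whose best references straddle several groups; the ambiguous share
    is tracked separately in ``ambiguous_count`` so summaries can exclude it.
    """

    group_id: str
    family: str
    member_ids: list[MirnaId]
    sequence: str
    raw_count: int = 0
    ambiguous_count: int = 0
    species: set[str] = field(default_factory=set)
    multi_family: bool = False

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def group_identical_sequences(plant_refs: ReferenceSet) -> list[MiRNAGroup]:
    """One group per distinct mature sequence, named ``<family>_<N>``.

    The family is the modal family among members (lexicographically smallest
    on ties; such groups are flagged multi-family). When two distinct
    sequences would produce the same name, later groups (in sequence order)
    get a deterministic ordinal suffix ``.2``, ``.3``, ...
    """
    if plant_refs.role != "plant_mirna":
        raise ValueError("grouping requires a plant_mirna reference set")
    by_seq: dict[str, list[MirnaId]] = {}
    for rec in plant_refs.records:
        by_seq.setdefault(rec.sequence, []).append(parse_mirbase_id(rec.id))

    groups: list[MiRNAGroup] = []
    name_uses: Counter[str] = Counter()
    for seq in sorted(by_seq):
        members = by_seq[seq]
        fam_counts = Counter(m.family for m in members)
        top = max(fam_counts.values())
        family = min(f for f, c in fam_counts.items() if c == top)
        base = f"{family}_{len(members)}"
        name_uses[base] += 1
        group_id = base if name_uses[base] == 1 else f"{base}.{name_uses[base]}"
        groups.append(
            MiRNAGroup(
                group_id=group_id,
                family=family,
                member_ids=sorted(members, key=lambda m: m.raw),
                sequence=seq,
                species={m.species_prefix for m in members},
                multi_family=len(fam_counts) > 1,
            )
        )
    return groups


def assign_counts(
    annotations: list[Annotation], groups: list[MiRNAGroup]
) -> list[MiRNAGroup]:
    """Add each annotation's read count to every distinct group its best
    references belong to.

    Best references sharing one sequence land in one group and are counted
    once. An annotation whose ties span more than one group is marked
    ambiguous and its count is additionally recorded in each group's
    ``ambiguous_count``. Counts are reset before assignment, so the call is
    idempotent.
    """
    ref_to_group: dict[str, MiRNAGroup] = {}
    for g in groups:
        g.raw_count = 0
        g.ambiguous_count = 0
        for m in g.member_ids:
            ref_to_group[m.raw] = g
    for ann in annotations:
        hit_groups: dict[str, MiRNAGroup] = {}
        for ref_id in ann.best_refs:
            g = ref_to_group.get(ref_id)
            if g is None:
                raise ValueError(f"annotation references unknown id {ref_id!r}")
            hit_groups[g.group_id] = g
        ann.ambiguous = len(hit_groups) > 1
        for g in hit_groups.values():
            g.raw_count += ann.query_count
            if ann.ambiguous:
                g.ambiguous_count += ann.query_count
    return groups


def trace_species(
    group: MiRNAGroup, species_table: dict[str, str]
) -> list[str]:
    """Sorted unique source species names for a group's member prefixes;
    prefixes missing from the table are reported as ``unknown:<prefix>``."""
    names = {
        species_table.get(prefix, f"unknown:{prefix}") for prefix in group.species
    }
    return sorted(names)


def write_groups_tsv(
    groups: list[MiRNAGroup], path, species_table: dict[str, str] | None = None
) -> None:
    with open(path, "wt") as fh:
        fh.write(
            "group_id\tsequence\tmember_ids\traw_count\tambiguous_count\t"
            "multi_family\tspecies\n"
        )
        for g in groups:
            species = (
                ";".join(trace_species(g, species_table))
                if species_table is not None
                else ";".join(sorted(g.species))
            )
            fh.write(
                f"{g.group_id}\t{g.sequence}\t"
                f"{';'.join(m.raw for m in g.member_ids)}\t{g.raw_count}\t"
                f"{g.ambiguous_count}\t{g.multi_family}\t{species}\n"
            )
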