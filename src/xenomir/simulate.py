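"""Seeded synthetic references and samples with known ground truth.

The generator stands in for the real inputs of a dietary-miRNA screen: a host
genome, host ncRNA records (cut from that genome so the ncRNA and genome
filter layers overlap realistically), an optional microbiome, and a plant
mature miRNA reference whose families are deposited under several species
prefixes with identical sequence — exactly the situation that makes
sequence-identity grouping necessary.

Every plant miRNA sequence is rejection-sampled to lie at least
``min_host_distance`` substitutions (default 3, strictly above both filter
allowances) from every same-length window of the host references on both
strands, so error-free spike-ins are guaranteed to survive host subtraction
and error-free host background is guaranteed to be removed. This is what
makes exact end-to-end recovery (precision = recall = 1, RPM equal to the
truth table) a provable property of the generator rather than a tuning
outcome.

Reads carry only substitution errors by default, matching the
substitution-only filter semantics; ``indel_errors`` exists for stress-testing
the annotator's extra-base allowance. Seeds are mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .annotate import score_pair
from .hostfilter import reverse_complement
from .io import ReferenceRecord, ReferenceSet, write_fasta, write_fastq, write_species_map
from .preprocess import RawRead

BASES = "ACGT"

# miRBase-style species prefixes used for synthetic plant deposits
SPECIES_POOL: list[tuple[str, str]] = [
    ("osa", "Oryza sativa"),
    ("ath", "Arabidopsis thaliana"),
    ("zma", "Zea mays"),
    ("gma", "Glycine max"),
    ("mdm", "Malus domestica"),
    ("sly", "Solanum lycopersicum"),
    ("tae", "Triticum aestivum"),
    ("vvi", "Vitis vinifera"),
]

# minimum pairwise penalty score between distinct plant families, so a read
# one edit away from its source can never be closer to another family
_MIN_PLANT_SEPARATION = 9
_MAX_REJECTION_ATTEMPTS = 500


@dataclass
class SimConfig:
    seed: int
    genome_length: int = 20_000
    n_ncrna: int = 30
    ncrna_length: tuple[int, int] = (60, 120)
    microbiome_length: int = 5_000
    # (family name, number of species variants sharing the sequence, length)
    plant_families: list[tuple[str, int, int]] = field(
        default_factory=lambda: [
            ("miR168", 2, 21),
            ("miR166", 3, 21),
            ("miR156", 2, 22),
            ("miR159", 2, 21),
            ("miR396", 2, 20),
        ]
    )
    spike_counts: dict[str, int] = field(
        default_factory=lambda: {"miR168": 50, "miR166": 30, "miR156": 20, "miR159": 10}
    )
    host_background: int = 2_000
    error_rate: float = 0.0
    indel_errors: bool = False
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    read_length: int = 40
    min_host_distance: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not (0.0 <= self.error_rate <= 0.2):
            raise ValueError("error_rate must be in [0, 0.2]")
        if self.min_host_distance < 3:
            raise ValueError(
                "min_host_distance must be >= 3 (strictly above the filter allowances)"
            )
        if self.host_background < 0 or any(c < 0 for c in self.spike_counts.values()):
            raise ValueError("counts must be non-negative")
        known = {fam for fam, _, _ in self.plant_families}
        unknown = set(self.spike_counts) - known
        if unknown:
            raise ValueError(f"spike_counts for unknown families: {sorted(unknown)}")


@dataclass
class SimReferences:
    genome: ReferenceSet
    ncrna: ReferenceSet
    microbiome: ReferenceSet
    plant: ReferenceSet
    species_map: dict[str, str]
    # family -> (group_id expected after merging, shared sequence)
    family_truth: dict[str, tuple[str, str]]


@dataclass
class TruthRow:
    group_id: str
    sequence: str
    true_count: int
    expected_count: int
    expected_rpm: float


@dataclass
class TruthTable:
    total_clean_reads: int
    rows: list[TruthRow]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            fh.write(f"# total_clean_reads={self.total_clean_reads}\n")
            fh.write("group_id\tsequence\ttrue_count\texpected_count\texpected_rpm\n")
            for r in self.rows:
                fh.write(
                    f"{r.group_id}\t{r.sequence}\t{r.true_count}\t"
                    f"{r.expected_count}\t{r.expected_rpm:.6f}\n"
                )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _min_hamming_to_hosts(cand: str, host_arrays: list[np.ndarray]) -> int:
    """Minimum Hamming distance from the candidate to any same-length window
    of the host sequences (arrays already include both strands)."""
    q = _encode(cand)
    best = len(cand)
    for arr in host_arrays:
        if len(arr) < len(q):
            continue
        windows = sliding_window_view(arr, len(q))
        best = min(best, int((windows != q).sum(axis=1).min()))
    return best


def gen_references(config: SimConfig) -> SimReferences:
    """Deterministic synthetic reference bundle for a given seed."""
    rng = np.random.default_rng(config.seed)

    genome_seq = _random_seq(rng, config.genome_length)
    genome = ReferenceSet(
        role="host_genome", records=[ReferenceRecord("chr1", genome_seq)]
    )

    lo, hi = config.ncrna_length
    ncrna_records = []
    for i in range(config.n_ncrna):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, config.genome_length - length + 1))
        ncrna_records.append(
            ReferenceRecord(f"ncrna{i + 1}", genome_seq[start : start + length])
        )
    ncrna = ReferenceSet(role="host_ncrna", records=ncrna_records)

    microbiome_seq = _random_seq(rng, config.microbiome_length)
    microbiome = ReferenceSet(
        role="microbiome", records=[ReferenceRecord("mb_contig1", microbiome_seq)]
    )

    host_arrays = [
        _encode(genome_seq),
        _encode(reverse_complement(genome_seq)),
        _encode(microbiome_seq),
        _encode(reverse_complement(microbiome_seq)),
    ]

    plant_records: list[ReferenceRecord] = []
    family_truth: dict[str, tuple[str, str]] = {}
    existing: list[str] = []
    for fam_idx, (family, n_variants, length) in enumerate(config.plant_families):
        if n_variants > len(SPECIES_POOL):
            raise ValueError("more species variants requested than prefixes available")
        seq = None
        for _ in range(_MAX_REJECTION_ATTEMPTS):
            cand = _random_seq(rng, length)
            if _min_hamming_to_hosts(cand, host_arrays) < config.min_host_distance:
                continue
            if any(
                score_pair(cand, other).score < _MIN_PLANT_SEPARATION
                for other in existing
            ):
                continue
            seq = cand
            break
        if seq is None:
            raise RuntimeError(
                f"could not place family {family} at distance "
                f">= {config.min_host_distance} from the host; use longer references"
            )
        existing.append(seq)
        for v in range(n_variants):
            prefix, _name = SPECIES_POOL[(fam_idx + v) % len(SPECIES_POOL)]
            plant_records.append(ReferenceRecord(f"{prefix}-{family}a", seq))
        family_truth[family] = (f"{family}_{n_variants}", seq)

    plant = ReferenceSet(role="plant_mirna", records=plant_records)
    species_map = dict(SPECIES_POOL)
    return SimReferences(
        genome=genome,
        ncrna=ncrna,
        microbiome=microbiome,
        plant=plant,
        species_map=species_map,
        family_truth=family_truth,
    )


def _apply_errors(seq: str, rng: np.random.Generator, config: SimConfig) -> str:
    if config.error_rate == 0.0:
        return seq
    chars = list(seq)
    for i, c in enumerate(chars):
        if rng.random() < config.error_rate:
            if config.indel_errors and rng.random() < 0.2:
                # rare indel stressor: drop or duplicate the base
                chars[i] = "" if rng.random() < 0.5 else c + rng.choice(list(BASES))
            else:
                chars[i] = rng.choice([b for b in BASES if b != c])
    return "".join(chars)


def _finish_read(insert: str, config: SimConfig) -> str:
    if not config.adapter:
        return insert
    return (insert + config.adapter)[: config.read_length]


def gen_sample(
    refs: SimReferences, config: SimConfig, sample_id: str = "sim"
) -> tuple[list[RawRead], TruthTable]:
    """Emit a shuffled synthetic read set plus its ground-truth table.

    Host background reads are 18-30 nt windows of the genome (either strand)
    or of ncRNA records (forward); spike-ins are copies of the plant family
    sequences at the configured counts. Errors and the 3' adapter are applied
    per read; the truth table holds expected per-group counts and RPM under
    the error-free contract.
    """
    rng = np.random.default_rng(config.seed + 1)
    genome_seq = refs.genome.records[0].sequence
    inserts: list[str] = []

    for _ in range(config.host_background):
        length = int(rng.integers(18, 31))
        if rng.random() < 0.5 and refs.ncrna.records:
            rec = refs.ncrna.records[int(rng.integers(0, len(refs.ncrna.records)))]
            src = rec.sequence
            if len(src) < length:
                src = genome_seq
        else:
            src = genome_seq
        start = int(rng.integers(0, len(src) - length + 1))
        window = src[start : start + length]
        if rng.random() < 0.5:
            window = reverse_complement(window)
        inserts.append(window)

    rows: list[TruthRow] = []
    total_spikes = 0
    for family, _n, _len in config.plant_families:
        count = config.spike_counts.get(family, 0)
        if count == 0:
            continue
        group_id, seq = refs.family_truth[family]
        inserts.extend([seq] * count)
        total_spikes += count
        rows.append(TruthRow(group_id, seq, count, count, 0.0))

    total_clean = config.host_background + total_spikes
    for r in rows:
        r.expected_rpm = r.expected_count * 1_000_000 / total_clean

    reads = [
        RawRead(_finish_read(_apply_errors(ins, rng, config), config))
        for ins in inserts
    ]
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return reads, TruthTable(total_clean_reads=total_clean, rows=rows)


def write_references(refs: SimReferences, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(((r.id, r.sequence) for r in refs.genome.records), out / "genome.fa")
    write_fasta(((r.id, r.sequence) for r in refs.ncrna.records), out / "ncrna.fa")
    write_fasta(
        ((r.id, r.sequence) for r in refs.microbiome.records), out / "microbiome.fa"
    )
    write_fasta(
        ((r.id, r.sequence) for r in refs.plant.records), out / "plant_mirna.fa"
    )
    write_species_map(refs.species_map, out / "species_map.tsv")


def write_sample(
    reads: list[RawRead], truth: TruthTable, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fastq(
        ((f"read{i + 1}", r.sequence) for i, r in enumerate(reads)),
        out / "reads.fastq",
    )
    truth.to_tsv(out / "truth.tsv")
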