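# Methods

## Problem and model

`xenomir` screens non-plant small RNA sequencing samples for miRNAs of
dietary plant origin. The core difficulty is asymmetry of evidence: a read
identical to a plant mature miRNA is only meaningful if it could not have come
from the host, its microbiome, or sequencing noise. The pipeline therefore
subtracts first and annotates second, with every threshold chosen to be
conservative toward the host.

### Host subtraction

Matching is substitution-only (no indels) against contiguous reference
windows, the natural model for 18–30 nt reads. Layers run in a fixed order
and a read removed at one layer never reaches the next:

| layer | allowance | strands | rationale |
|---|---|---|---|
| host ncRNA | ≤ 2 mismatches | forward | mature ncRNAs are single-stranded RNA |
| host genome | ≤ 1 mismatch | both | genomic DNA is double-stranded |
| microbiome (optional) | ≤ 1 mismatch | both | same as genome; optional because curated microbiome sets exist only for some hosts |

The matcher is a pigeonhole partition index: a query split into
`max_mm + 1` contiguous pieces must have at least one piece occurring exactly
in the reference if the whole query matches within the allowance; exact piece
occurrences seed candidate sites verified by full Hamming comparison.
`N` never matches any base, including `N` — a conservative choice that
prevents ambiguous bases from letting host reads survive. Coordinates are
0-based half-open; reverse-strand hits are reported as the forward-strand
interval plus a strand flag. Allowances above 2 are rejected: the pipeline's
semantics are defined only for 0–2 mismatches.

### Annotation scoring

A surviving read is globally aligned to every plant mature miRNA (skipping
references whose length differs by more than 1 nt, which can never be
retained). Penalties: match 0, mismatch 4, extra base in either sequence
(a gap) 3. The annotation is retained iff

    score < 7   AND   mismatches ≤ 1   AND   |length difference| ≤ 1,

a conjunction under which the retainable alignment patterns are exactly:
identity (0), one extra base (3), one mismatch (4), and one insertion plus
one deletion (6). Two same-direction extra bases also cost 6 but imply a 2-nt
length difference and are rejected; one mismatch plus one extra base costs 7
and is rejected by the strict inequality. Enforcing the score rule and the
mismatch/length rule jointly was a genuine design choice: either rule alone
admits patterns the other forbids, and the conjunction is the only reading
that satisfies both simultaneously. The test suite pins this down by
exhaustively enumerating all ≤ 2-edit variants of a 21-mer.

The DP is banded with half-width 2 by default. Because any alignment path
leaving the band `|i−j| ≤ h` must spend at least `3·(2(h+1) − |Δlen|)` in gap
penalties, the implementation doubles the band until the in-band optimum is
below that floor, so the reported score is always the true global optimum —
retainable alignments (score < 7) never trigger an expansion. Among
equal-score alignments the decomposition with fewer mismatches is reported
(unique anyway for scores below 7). All references tied at the minimal score
are listed, sorted lexicographically; the scan order never affects the
result.

### Grouping, species tracing, quantification

References with identical mature sequence merge into one group named
`<family>_<N>` (N = merged reference entries; the alternative reading —
merged *read* sequences — was rejected because grouping happens before any
reads are seen). The family is the modal family among members,
lexicographically smallest on ties, with a `multi_family` flag. Because two
distinct sequences of one family can merge the same number of deposits, name
collisions get a deterministic ordinal suffix (`miR166_2`, `miR166_2.2` in
sequence-sorted order) so group ids stay unique.

A read's count is added once per distinct *group* its best references fall
in, never once per reference — identical deposits cannot double-count. Reads
whose score ties span several groups are counted in each but flagged
ambiguous, and each group carries the ambiguous share in a separate column so
summaries can exclude it.

Abundance is `N_i = C_i × 10^6 / R_i` with `R_i` the clean-read total after
trimming and length filtering but **before** host subtraction ("clean reads"
is the operative definition; normalising to endogenous miRNA counts would
change the denominator and is not what the formula states). Display values
use `log10(N_i + 1)`.

### Cross-sample statistics

Presence of a group in a sample class means RPM strictly above a threshold
(default 0 — any detection) in at least one sample of the class; overlap is
reported as exact Venn regions over all non-empty class subsets. Comparisons
use the classic pooled-variance unpaired Student's t-test, two-sided,
α = 0.05 (Welch behind a flag; no multiple-testing correction by default,
Benjamini–Hochberg available). Zero-variance degenerate inputs return t = 0,
p = 1 for equal means and p = 0 with a degenerate flag otherwise.

## Preprocessing parameters

Trimming implements the effect, not any particular trimmer: the 3' adapter
occurrence maximising matching bases (ties: fewer errors, then leftmost) with
overlap ≥ 3 nt and error rate ≤ 0.1 is removed together with everything
after it, followed by removal of a trailing polyA run of ≥ 10 A's. These are
declared defaults — no published value exists for them — and a
`--pre-trimmed` flag skips trimming entirely. "Concentrated at 20–26 nt" is
operationalised as ≥ 50% of clean reads in [20, 26] (configurable); sample
eligibility additionally requires strictly more than 100,000 clean reads.
Cohort-level acquisition rules (source file size, samples per project) are
metadata concerns and are not enforced on single-sample runs.

## Synthetic data

The generator emulates the screen's real inputs at desk scale: a 20 kb random
host genome, 30 ncRNA records cut from it (so the ncRNA and genome layers
overlap, as they do in reality), a 5 kb microbiome contig, and five plant
families (miR168, miR166, miR156, miR159, miR396) of 20–22 nt deposited under
2–3 species prefixes with identical sequence. Default spike-ins are 50/30/20/
10 copies of four families over 2,000 host background reads, error-free, with
a 21-nt 3' adapter appended and reads cut to 40 nt — sizes chosen so the full
suite runs in seconds while every code path (both filter layers, reverse
strands, merging, tracing, RPM) is exercised.

Two constructive guarantees make end-to-end assertions exact rather than
statistical: every plant sequence is rejection-sampled to lie ≥ 3
substitutions (`min_host_distance`, strictly above both filter allowances)
from every same-length host window on both strands, and distinct families are
kept at pairwise penalty ≥ 9 so a read one edit from its source can never be
attributed elsewhere. Consequently error-free spike-ins are recovered with
precision = recall = 1 and RPM equal to the truth table, and error-free
background is removed completely. The error model is substitution-only
(matching the filter semantics) with an `indel_errors` stress flag; at a 1%
per-base rate a spiked read is recovered iff it carries ≤ 1 error, giving a
closed-form binomial band that the tests check. Seeds are mandatory;
identical configurations produce byte-identical outputs.

What the generator does **not** emulate: realistic expression distributions,
quality scores, PCR duplicates, chimeric reads, or genuine miRBase sequence
families — so passing tests demonstrate the pipeline's logic is correct under
its stated matching model, not that any particular biological sample contains
plant miRNAs.

## Numerical and degenerate-input choices

- Collapsed read ordering is count-descending then sequence-ascending, ids
  `seq<k>_x<count>`, so outputs are byte-stable across runs.
- Trimming an entire read to zero length is not an error; the length filter
  removes it, and the conservation identity (raw = trimmed-to-zero +
  length-removed + clean) holds.
- RPM with `R_i = 0` raises, naming the sample; `log10(N+1)` round-trips
  within 1e-9.
- The t-test requires ≥ 2 observations per group.

## Known limitations

- Host matching is substitution-only; a host read with an indel relative to
  its source locus can survive to annotation (mitigated by the annotator's
  own strictness, not eliminated).
- Group naming is grammar-based (`miR<digits>`); non-standard ids fail
  parsing rather than being clustered by similarity.
- The microbiome layer accepts any FASTA; it cannot distinguish curated
  microbial small RNAs from arbitrary contigs.
- Tissue-specificity testing beyond pairwise t-tests (e.g. MANOVA designs)
  is out of scope.
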