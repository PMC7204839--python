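# Methods

## Problem setting

Microsatellite (SSR) loci are 1–6 nt motifs repeated in tandem. When
genotyped by amplicon sequencing, each locus is read through completely, so
an allele can be defined by its sequence (a haplotype) rather than by its
fragment length. Two noise processes dominate: PCR stutter — slippage
during amplification that adds or removes whole motif copies, producing a
coverage ladder around each true allele — and per-base sequencing error,
which scatters reads into many low-coverage unique sequences. The pipeline
recovers diploid genotypes from this mixture and validates every locus
with blind-replicate samples.

## Locus model and anchors

A locus is `forward_primer · left_flank · motif×k · right_flank ·
rc(reverse_primer)`. Panels are TSV files; motifs must be primitive (a
motif that is itself a tandem of a shorter unit, e.g. `ACAC`, is rejected,
because stutter-offset arithmetic needs a unique repeat unit), and flanks
may not begin/end with a full motif copy, which pins a canonical boundary
for the repeat tract. IUPAC ambiguity codes are allowed in primers only
and are expanded during matching.

Two analysis strategies differ only in their anchors. *FullLength* anchors
on the primer pair and keeps everything between the primers, so linked
flank polymorphism distinguishes alleles. *RepeatFocused* concatenates the
flanks onto the anchors (`primer+left_flank`, `right_flank+rc(primer)`);
the longer anchors absorb flank polymorphism within the mismatch allowance
and only the repeat-tract region defines the allele.

## Anchor matching and extraction

Anchors are located by infix (semi-global) unit-cost Levenshtein alignment
(edlib); a hit is accepted when its edit count is at most
`floor(0.08 × anchor length)` — the floor keeps the threshold integral —
with ties broken by the leftmost start. Both read orientations are
searched, the left anchor must precede the right anchor, and the
orientation with the smaller summed edit count wins (forward on ties).
Within the cohort pipeline, reads are deduplicated per sample, shortlisted
by an exact forward-primer hit in either orientation, and assigned to the
locus whose FullLength anchors match with the fewest summed edits (panel
order breaks ties); an ambiguous or anchorless read is counted as
unassigned, never genotyped twice.

## Stutter flagging and allele calling

Unique target sequences per individual × locus are processed in descending
coverage (ties: longer sequence first, then lexicographic — full
determinism). The most abundant sequence is a potential allele. A later
sequence is flagged as stutter when some already-flagged allele or stutter
with strictly greater coverage differs from it only by insertion or
deletion of whole motif copies inside the parent's maximal motif run, and
its coverage does not exceed the parent's coverage times the product of
per-offset threshold fractions along the best decomposition of the offset
into single steps (found by a shortest-path search over offsets; with the
default map a −2 product is allowed at `t(−1)²`). Chained, multiplicative
thresholds mirror how slippage compounds over PCR cycles. Unexplained
sequences are potential alleles when their coverage reaches the
per-allele floor `m`, otherwise low-coverage noise.

Genotypes are called from the potential-allele pool: missing when total
locus coverage is below `n` or the top candidate is below `m`; a second
allele is called when it reaches `m` reads and the heterozygote-balance
fraction (default 25%) of the top allele's coverage, otherwise the call is
homozygous. The two default parameter sets are
`PS1 = {−1: 50%, +1: 10%, m = 15, n = 20}` and
`PS2 = {−1: 70%, +1: 10%, m = 10, n = 20}`; the balance rule is exposed as
a parameter because the `m`/`n` floors alone do not decide near-balanced
heterozygotes, and every run logs its effective configuration.

## Replicate QC, reliability and combination

The allelic error rate of a locus × combo pools all unordered
within-replicate-group pairs: genotypes are compared as 2-allele multisets
(a homozygote counts doubled, making "alleles compared = 2 per pair"
well-defined), mismatches are `2 − |intersection|`, and pairs with a
missing member are excluded; groups larger than two contribute every pair.
With no evaluable pair the rate is undefined and the locus fails — the
validation rests entirely on blind repeats. Reliability is strict: a combo
fails only on *more than* 6% error or *more than* 50% missing data, so
boundary values pass. Sequencing success (≥ 20 reads in ≥ 50% of
individuals) is reported per locus but does not gate reliability, which
depends only on the error/missing thresholds. Per locus the best reliable
combo minimizes error rate, then missing rate, then maximizes allele
count, with a fixed preference order (FullLength·PS1, FullLength·PS2,
RepeatFocused·PS1, RepeatFocused·PS2) breaking full ties; its genotypes
are copied verbatim into the Combined dataset. Dataset-level missing and
error rates are pooled over counts, not averaged over loci, and the
overall success rate is reliable loci over multiplexed loci, rounded half
up to an integer percent.

## Allele catalog, homoplasy and polymorphism types

Within each locus alleles are coded `001`, `002`, … in order of
occurrence count (descending), then length (ascending), then
lexicographic. Size homoplasy compares `H` sequence-distinct with `S`
length-distinct alleles: `pct_homoplasy = 100(H−S)/H`,
`pct_increase = 100(H−S)/S`. Lengths are measured on the extracted target:
primers add a per-locus constant, so distinct-length counts are
unchanged. Homoplasy and increase percentages are rounded half-up to
integers, type shares to one decimal — the precision conventional for
these summaries.

Each allele is aligned to its locus reference (the most frequent allele;
ties prefer the longer, then lexicographically smaller — a frequency-based
choice keeps the reference stable across runs). The aligner is a
three-state unit-cost Needleman–Wunsch minimizing `(edits, gap openings)`
lexicographically, so an inserted or deleted stretch surfaces as one
contiguous event instead of equal-cost fragments; each indel is then
re-placed among its cost-equivalent positions to sit on a motif-copy
boundary inside the reference's maximal motif run when possible (bounded
so it cannot slide across a neighbouring event). Events are classified
against the run: an in-run indel of whole motif copies (up to rotation) is
repeat-number variation; other in-run indels/substitutions are motif
indels/SNPs; everything outside the run is flanking, including indels that
straddle the run boundary (they touch flanking bases). An allele counts
once per type it exhibits, so per-type totals may exceed the allele count.
Note that classification describes the *optimal alignment*: a flank edit
immediately adjacent to the run can merge with a repeat-count change into
a cheaper alignment with a different (but cost-minimal) interpretation.

## Simulator

The generator emulates a panel-validation cohort: random primitive-motif
loci with 20–25 nt primers and 8–16 nt flanks; per-locus allele pools of
3–6 repeat-count variants (Dirichlet-distributed frequencies), roughly a
third of loci also carrying one same-length flank-SNP allele that creates
known size homoplasy; 50 diploid individuals with a fifth blind-replicated;
negative-binomial coverage (mean 200, shape 8, matching the strong
between-locus dispersion of multiplexed PCR); per-read stutter with
geometric chaining (loss probability 0.15 per step, gain 0.02, so −2
products are rarer than −1); per-base substitution error 0.001; half the
reads reverse-complemented. All draws flow from one integer seed.

What the simulator does **not** model: platform-specific indel error
(e.g. homopolymer noise), chimeric reads, allele-specific amplification
bias, contamination, and flank indel variants. Passing end-to-end tests
therefore demonstrates correct recovery under idealized stutter/error
noise, not performance on degraded DNA or problematic loci; the
replicate-QC machinery is exercised mostly in its all-pass regime, with
unreliable-locus paths covered by unit tests.

## Numerical and degenerate-input choices

- Threshold comparisons use a small epsilon (1e−9 on coverage products,
  1e−12 on rates) so exact boundary cases are not lost to float noise.
- Empty tallies yield missing genotypes; a missing genotype carries no
  alleles; an empty replicate-pair set yields an undefined (not zero)
  error rate.
- Reads of exactly the 70 bp minimum are kept; exactly 50% of individuals
  at 20 reads passes sequencing success; error exactly 6% and missing
  exactly 50% pass reliability.
- Ordering is pinned everywhere (sample, locus, combo, coverage/length/
  lexicographic), so identical inputs give byte-identical outputs.

## Problem sizes used in checks

The end-to-end recovery check runs 20 seeded cohorts at the default study
conditions (10 loci × 50 individuals + 10 replicates × coverage 200 ≈
120 000 reads per cohort); the acceptance script runs 10 such cohorts,
sizes chosen as representative validation cohorts for a new panel.
Exhaustive-oracle equivalences use 1 000 random tallies (≤ 6 unique
sequences) and 1 000 random QC quadruples.
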