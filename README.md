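# strhap — sequence-based microsatellite haplotype genotyping

`strhap` turns multiplexed microsatellite (SSR) amplicon sequencing reads
into validated haplotype genotypes. It is aimed at molecular ecology and
population genetics groups that genotype panels of 10–60 short tandem
repeat loci by high-throughput amplicon sequencing instead of
capillary-electrophoresis fragment sizing, and that validate new panels
with blind-replicate samples.

## What it computes

For each locus an amplicon read decomposes as

```
forward_primer · left_flank · motif × k · right_flank · rc(reverse_primer)
```

The pipeline:

1. **Read preparation** — drops reads shorter than 70 bp and (optionally)
   sorts pooled reads among species panels by forward-primer match with one
   mismatch.
2. **Allele calling** — locates each locus in a read by approximate anchor
   matching (unit-cost edit distance, up to ⌊0.08·|anchor|⌋ edits), counts
   each unique extracted target per individual, flags every unique sequence
   as potential allele, PCR **stutter** (a product differing from a more
   abundant parent by whole motif copies, tolerated up to per-offset
   coverage thresholds that multiply along chained slippage steps, e.g.
   threshold(−1)² for a −2 product), or low-coverage noise, and calls 0–2
   alleles per individual × locus. Two strategies are run: *FullLength*
   (the whole inter-primer sequence is the allele, so linked flank SNPs
   and indels distinguish same-length alleles) and *RepeatFocused* (flanks
   are folded into the anchors; only the repeat tract defines the allele).
3. **Replicate QC and combination** — the allelic error rate of a locus is
   the number of allele mismatches between blind-replicate genotypes
   divided by the number of alleles compared; a locus × combo fails when
   error > 6% or missing data > 50%. Per locus the best of the four
   strategy × parameter-set combinations (ranked by error, then missing
   rate, then allele count) feeds a final *Combined* dataset, and the
   overall success rate is reliable loci over multiplexed loci.
4. **Haplotype reports** — a per-locus allele catalog with three-digit
   codes; **size homoplasy** `100·(H−S)/H` and the allele gain
   `100·(H−S)/S`, where `H` counts sequence-distinct and `S`
   length-distinct alleles; and a classification of every allele's
   differences from the locus reference into repeat-number variation,
   SNPs/indels in the motif, and SNPs/indels in the flanks.
5. **Simulation** — a seeded generator produces panels, diploid truth
   genotypes with blind replicates, and reads with geometric-chained
   stutter, substitution errors and negative-binomial coverage, so the
   whole pipeline is testable end to end without external data.

## Worked example

```sh
strhap simulate --out demo/sim --seed 7 --n-loci 6 --n-individuals 24 --coverage-mean 150
strhap all --panel demo/sim/panel.tsv --samples demo/sim/samples.tsv --out demo/run
```

prints

```
simulated 6 loci, 29 samples -> demo/sim
6 reliable loci of 6; overall success rate 100%; missing 0.0%; allelic error 0.00%; 34 alleles
```

29 samples are 24 individuals plus 5 blind replicates. All six loci pass
the 6%-error/50%-missing reliability rule, so the overall success rate is
6/6 = 100%; the Combined dataset holds 34 distinct alleles with no missing
genotypes and zero replicate mismatches. `demo/run/homoplasy.tsv` then
shows the gain from sequence-level alleles:

```
scope	n_haplotypes	n_sizes	pct_homoplasy	pct_increase
L004	7	6	14	17
pooled	34	33	3	3
```

Locus L004 carries 7 sequence-distinct alleles in only 6 distinct lengths:
one allele pair differs by a flank SNP at identical length, invisible to
fragment sizing (14% size homoplasy at that locus). The polymorphism-type
table attributes 81.8% of allele differences to repeat-number variation and
18.2% to flanking SNPs. Per-combo genotype and tally tables, locus QC,
combo selection and the coded Combined genotype table are written
alongside.

The same stages are available as library functions (`strhap.pipeline.
genotype_samples`, `run_qc`, `run_report`, `strhap.simulate.simulate_run`,
`truth_compare`) for scripted use.

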