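"""Synthetic SSR amplicon data: panels, truth genotypes and noisy reads.

The simulator emulates the data a multiplexed microsatellite amplicon
sequencing run produces: a panel of loci (primer pair, flanks, repeat
motif), diploid truth genotypes for a cohort with blind replicate samples,
and per-sample merged reads carrying the two dominant noise processes of
the assay — PCR stutter (whole-motif slippage, chained geometrically so a
-2 product is rarer than -1) and uniform per-base substitution error.
Coverage per locus x individual follows a negative-binomial law to mimic
the strong between-locus amplification heterogeneity of multiplexed PCR.

Every draw flows from a single integer seed, so a run is exactly
reproducible.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .panel import (
    LocusDefinition,
    Strategy,
    reverse_complement,
    is_primitive_motif,
    write_panel,
)
from .qc import CombinedDataset
from .reads import SampleEntry, SampleSheet

__all__ = [
    "SimConfig",
    "SimAllele",
    "SimTruth",
    "SimRun",
    "ConcordanceReport",
    "simulate_panel",
    "simulate_truth",
    "simulate_reads",
    "simulate_run",
    "truth_compare",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of a simulated run.

    Defaults describe a typical validation cohort for a new panel: 10 loci,
    50 individuals of which a fifth are blind-replicated, mean coverage 200
    reads per locus per sample, downward stutter probability 0.15 per read,
    upward 0.02, and per-base substitution error 0.001.
    """

    seed: int
    n_loci: int = 10
    n_individuals: int = 50
    replicate_fraction: float = 0.2
    coverage_mean: float = 200.0
    coverage_dispersion: float = 8.0   # negative-binomial shape; larger = tighter
    p_stutter_down: float = 0.15       # per read, chained geometrically
    p_stutter_up: float = 0.02
    error_rate: float = 0.001          # per base substitution probability
    motif_lengths: tuple[int, ...] = (2, 3, 4)
    flank_len_range: tuple[int, int] = (8, 16)
    primer_len_range: tuple[int, int] = (20, 25)
    ref_repeat_range: tuple[int, int] = (8, 13)
    pool_size_range: tuple[int, int] = (3, 6)
    homoplasy_snp_prob: float = 0.3    # chance a locus gains a same-length flank-SNP allele
    reverse_orient_frac: float = 0.5
    gzip_fastq: bool = False

    def __post_init__(self) -> None:
        for name in ("replicate_fraction", "p_stutter_down", "p_stutter_up",
                     "error_rate", "homoplasy_snp_prob", "reverse_orient_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.n_loci < 1 or self.n_individuals < 1:
            raise ValueError("n_loci and n_individuals must be >= 1")


@dataclass(frozen=True)
class SimAllele:
    """A true allele: effective flanks (possibly variant) around a repeat tract."""

    left_flank: str
    motif: str
    repeat_count: int
    right_flank: str

    @property
    def tract(self) -> str:
        return self.motif * self.repeat_count

    @property
    def full(self) -> str:
        """Inter-primer target sequence."""
        return self.left_flank + self.tract + self.right_flank


@dataclass
class SimTruth:
    """True genotypes per sample, with blind-replicate structure."""

    genotypes: dict[str, dict[str, tuple[SimAllele, SimAllele]]]  # sample -> locus -> pair
    replicate_groups: dict[str, list[str]]  # group id -> sample ids
    sample_sheet: SampleSheet

    @property
    def samples(self) -> list[str]:
        return list(self.genotypes)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _random_motif(rng: np.random.Generator, lengths: Sequence[int]) -> str:
    while True:
        motif = _random_seq(rng, int(rng.choice(lengths)))
        if is_primitive_motif(motif):
            return motif


def _trim_flank(flank: str, motif: str, side: str) -> str:
    # enforce the canonical tract boundary by mutating the offending base
    if side == "left":
        while flank.endswith(motif):
            repl = "A" if flank[-1] != "A" else "C"
            flank = flank[:-1] + repl
    else:
        while flank.startswith(motif):
            repl = "A" if flank[0] != "A" else "C"
            flank = repl + flank[1:]
    return flank


def simulate_panel(config: SimConfig,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[list[LocusDefinition], dict[str, list[SimAllele]]]:
    """Draw a random locus panel and a pool of true alleles per locus.

    Pools contain alleles differing in repeat count and, for a configurable
    share of loci, one same-length flank-SNP variant creating known size
    homoplasy.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    loci: list[LocusDefinition] = []
    pools: dict[str, list[SimAllele]] = {}
    for i in range(config.n_loci):
        locus_id = f"L{i + 1:03d}"
        motif = _random_motif(rng, config.motif_lengths)
        lf = _trim_flank(_random_seq(rng, int(rng.integers(*config.flank_len_range,
                                                           endpoint=True))), motif, "left")
        rf = _trim_flank(_random_seq(rng, int(rng.integers(*config.flank_len_range,
                                                           endpoint=True))), motif, "right")
        fwd = _random_seq(rng, int(rng.integers(*config.primer_len_range, endpoint=True)))
        rev = _random_seq(rng, int(rng.integers(*config.primer_len_range, endpoint=True)))
        ref_count = int(rng.integers(*config.ref_repeat_range, endpoint=True))

        pool_size = int(rng.integers(*config.pool_size_range, endpoint=True))
        lo = max(3, ref_count - 3)
        candidates = list(range(lo, lo + 8))
        counts = sorted(rng.choice(candidates, size=min(pool_size, len(candidates)),
                                   replace=False).tolist())
        if ref_count not in counts:
            counts[0] = ref_count
            counts = sorted(set(counts))
        pool = [SimAllele(lf, motif, int(c), rf) for c in counts]
        if len(lf) >= 4 and rng.random() < config.homoplasy_snp_prob:
            # same-length variant: one SNP in the left flank interior
            pos = len(lf) // 2
            base = lf[pos]
            alt = "ACGT"[("ACGT".index(base) + 1) % 4]
            var_lf = _trim_flank(lf[:pos] + alt + lf[pos + 1:], motif, "left")
            twin = pool[int(rng.integers(0, len(pool)))]
            variant = SimAllele(var_lf, motif, twin.repeat_count, rf)
            if variant.full != twin.full and len(variant.full) == len(twin.full):
                pool.append(variant)

        lengths = [len(a.full) for a in pool]
        span = (max(1, min(lengths) - 4 * len(motif)), max(lengths) + 4 * len(motif))
        loci.append(LocusDefinition(
            locus_id=locus_id, forward_primer=fwd, reverse_primer=rev,
            left_flank=lf, right_flank=rf, motif=motif,
            ref_repeat_count=ref_count, target_len_range=span,
        ))
        pools[locus_id] = pool
    return loci, pools


def simulate_truth(loci: Sequence[LocusDefinition], pools: Mapping[str, list[SimAllele]],
                   config: SimConfig, rng: np.random.Generator,
                   fastq_suffix: str = ".fastq") -> SimTruth:
    """Draw diploid genotypes and the blind-replicate sample layout.

    The first ``round(n_individuals * replicate_fraction)`` individuals get
    a second, blind sample sharing their replicate group and genotype.
    """
    freqs = {loc.locus_id: rng.dirichlet(np.full(len(pools[loc.locus_id]), 2.0))
             for loc in loci}
    individuals = [f"ind{i + 1:03d}" for i in range(config.n_individuals)]
    n_rep = int(round(config.n_individuals * config.replicate_fraction))

    genotypes: dict[str, dict[str, tuple[SimAllele, SimAllele]]] = {}
    replicate_groups: dict[str, list[str]] = {}
    entries: list[SampleEntry] = []
    for idx, ind in enumerate(individuals):
        geno: dict[str, tuple[SimAllele, SimAllele]] = {}
        for loc in loci:
            pool = pools[loc.locus_id]
            pair = rng.choice(len(pool), size=2, p=freqs[loc.locus_id])
            geno[loc.locus_id] = (pool[int(pair[0])], pool[int(pair[1])])
        samples = [ind] + ([f"{ind}r"] if idx < n_rep else [])
        replicate_groups[ind] = samples
        for s in samples:
            genotypes[s] = geno
            entries.append(SampleEntry(f"{s}{fastq_suffix}", s, ind))
    return SimTruth(genotypes=genotypes, replicate_groups=replicate_groups,
                    sample_sheet=SampleSheet(entries))


def _apply_stutter(count: int, rng: np.random.Generator,
                   p_down: float, p_up: float) -> int:
    while p_down > 0 and count > 1 and rng.random() < p_down:
        count -= 1
    while p_up > 0 and rng.random() < p_up:
        count += 1
    return count


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in pos:
        cur = chars[p]
        alts = [b for b in "ACGT" if b != cur]
        chars[p] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_reads(loci: Sequence[LocusDefinition], truth: SimTruth,
                   config: SimConfig, outdir: str | Path,
                   rng: np.random.Generator) -> dict[str, Path]:
    """Write per-sample FASTQ files with stutter and substitution noise.

    Each read is ``forward_primer + left_flank + tract + right_flank +
    revcomp(reverse_primer)``, with the tract's repeat count perturbed by
    chained stutter draws, per-base substitution errors applied over the
    whole read, and a fraction of reads emitted reverse-complemented.
    Returns sample id -> FASTQ path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nb_n = config.coverage_dispersion
    nb_p = nb_n / (nb_n + config.coverage_mean)
    paths: dict[str, Path] = {}
    for entry in truth.sample_sheet.entries:
        sample = entry.individual_id
        path = outdir / entry.fastq_path
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            for loc in loci:
                a1, a2 = truth.genotypes[sample][loc.locus_id]
                coverage = int(rng.negative_binomial(nb_n, nb_p))
                for ridx in range(coverage):
                    allele = a1 if rng.random() < 0.5 else a2
                    count = _apply_stutter(allele.repeat_count, rng,
                                           config.p_stutter_down, config.p_stutter_up)
                    target = allele.left_flank + allele.motif * count + allele.right_flank
                    read = (loc.forward_primer + target
                            + reverse_complement(loc.reverse_primer))
                    read = _mutate(read, rng, config.error_rate)
                    if rng.random() < config.reverse_orient_frac:
                        read = reverse_complement(read)
                    fh.write(f"@{sample}:{loc.locus_id}:{ridx}\n{read}\n+\n"
                             f"{'I' * len(read)}\n")
        paths[sample] = path
    return paths


@dataclass
class SimRun:
    """All artifacts of one simulated study."""

    config: SimConfig
    loci: list[LocusDefinition]
    pools: dict[str, list[SimAllele]]
    truth: SimTruth
    fastq_paths: dict[str, Path]
    outdir: Path


def simulate_run(config: SimConfig, outdir: str | Path) -> SimRun:
    """End-to-end simulation: panel, truth, reads, sheet and manifest on disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    loci, pools = simulate_panel(config, rng)
    suffix = ".fastq.gz" if config.gzip_fastq else ".fastq"
    truth = simulate_truth(loci, pools, config, rng, fastq_suffix=suffix)
    paths = simulate_reads(loci, truth, config, outdir, rng)

    write_panel(loci, outdir / "panel.tsv")
    truth.sample_sheet.write(outdir / "samples.tsv")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("sample\tlocus\tallele1_full\tallele2_full\tallele1_tract\tallele2_tract\n")
        for sample, geno in truth.genotypes.items():
            for locus_id, (a1, a2) in geno.items():
                fh.write(f"{sample}\t{locus_id}\t{a1.full}\t{a2.full}\t"
                         f"{a1.tract}\t{a2.tract}\n")
    manifest = {"seed": config.seed, "config": asdict(config),
                "n_samples": len(truth.samples), "n_loci": len(loci)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return SimRun(config=config, loci=loci, pools=pools, truth=truth,
                  fastq_paths=paths, outdir=outdir)


@dataclass
class ConcordanceReport:
    """Agreement between called genotypes and simulated truth."""

    per_locus: dict[str, float]
    n_compared: int
    n_concordant: int
    estimated_error_rate: float

    @property
    def overall(self) -> float:
        return self.n_concordant / self.n_compared if self.n_compared else 1.0


def truth_compare(combined: CombinedDataset, truth: SimTruth) -> ConcordanceReport:
    """Genotype concordance of a Combined dataset against simulated truth.

    For each retained locus, genotypes are compared as allele multisets
    against the truth projected into the chosen combo's allele space (full
    inter-primer target for FullLength, repeat tract for RepeatFocused).
    Missing calls are excluded from the comparison.
    """
    known = set(truth.genotypes)
    per_locus_hits: dict[str, list[int]] = {}
    for call in combined.calls:
        if call.is_missing:
            continue
        if call.individual_id not in known:
            raise ValueError(f"called sample {call.individual_id!r} absent from truth")
        strategy = call.combo.split(".")[0]
        a1, a2 = truth.genotypes[call.individual_id][call.locus_id]
        if strategy == Strategy.REPEAT_FOCUSED.value:
            true_pair = sorted((a1.tract, a2.tract))
        else:
            true_pair = sorted((a1.full, a2.full))
        hit = int(sorted(call.allele_pair()) == true_pair)
        per_locus_hits.setdefault(call.locus_id, []).append(hit)
    per_locus = {loc: sum(h) / len(h) for loc, h in sorted(per_locus_hits.items())}
    n_cmp = sum(len(h) for h in per_locus_hits.values())
    n_ok = sum(sum(h) for h in per_locus_hits.values())
    return ConcordanceReport(per_locus=per_locus, n_compared=n_cmp, n_concordant=n_ok,
                             estimated_error_rate=float(
                                 combined.summary.get("allelic_error_rate", 0.0)))
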