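"""Pipeline orchestration: reads -> per-combo genotype tables -> QC -> reports.

Ties the stage modules together for whole-cohort runs and owns the on-disk
TSV formats.  All outputs are deterministically ordered so identical inputs
produce byte-identical files.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .calling import (
    GenotypeCall,
    UniqueSeqTally,
    call_genotype,
    extract_target,
    extract_target_with_edits,
    flag_sequences,
)
from .panel import (
    AnalysisCombo,
    LocusDefinition,
    ParameterSet,
    Strategy,
    default_combos,
    reverse_complement,
)
from .qc import (
    CombinedDataset,
    LocusQC,
    combine_genotypes,
    compute_locus_qc,
    overall_success_rate,
)
from .reads import DEFAULT_MIN_READ_LEN, SampleSheet, filter_reads, read_fastq
from .report import (
    AlleleRecord,
    HomoplasyMetrics,
    build_catalog,
    collapse_by_size,
    homoplasy_metrics,
    polymorphism_counts,
    type_proportions,
)

__all__ = [
    "ReadAccounting",
    "GenotypeResult",
    "QCResult",
    "ReportResult",
    "genotype_samples",
    "run_qc",
    "run_report",
    "write_genotype_tables",
    "write_tally_tables",
    "write_qc_tables",
    "write_report_tables",
    "load_genotype_tables",
    "load_tally_totals",
]


@dataclass
class ReadAccounting:
    """Per-sample read bookkeeping; input = short + unassigned + assigned."""

    n_input: int = 0
    n_short: int = 0
    n_unassigned: int = 0
    per_locus: Counter = field(default_factory=Counter)

    @property
    def n_assigned(self) -> int:
        return sum(self.per_locus.values())

    def conserved(self) -> bool:
        return self.n_input == self.n_short + self.n_unassigned + self.n_assigned


@dataclass
class GenotypeResult:
    """Per-combo tallies and genotype tables plus read accounting."""

    combos: list[AnalysisCombo]
    tallies: dict[str, dict[tuple[str, str], UniqueSeqTally]]  # combo -> (locus, sample)
    tables: dict[str, list[GenotypeCall]]                      # combo -> calls
    accounting: dict[str, ReadAccounting]                      # sample -> accounting


def _assign_and_extract(seq: str, loci: Sequence[LocusDefinition],
                        anchor_mismatch: float,
                        ) -> tuple[LocusDefinition | None, dict[Strategy, str | None]]:
    """Assign one read to its best-matching locus and extract both targets.

    Exact forward-primer hits (either orientation) shortlist candidate
    loci; the read goes to the candidate whose FullLength anchors match
    with the fewest summed edits (panel order breaks ties).  Falls back to
    scanning the whole panel when the shortlist fails.
    """
    rc = reverse_complement(seq)
    shortlist = [loc for loc in loci
                 if loc.forward_primer in seq or loc.forward_primer in rc]
    for candidates in ([shortlist, list(loci)] if shortlist else [list(loci)]):
        best: tuple[int, int, LocusDefinition, str] | None = None
        for order, loc in enumerate(candidates):
            hit = extract_target_with_edits(seq, loc, Strategy.FULL_LENGTH, anchor_mismatch)
            if hit is None:
                continue
            target, edits = hit
            if best is None or (edits, order) < (best[0], best[1]):
                best = (edits, order, loc, target)
        if best is not None:
            loc = best[2]
            targets: dict[Strategy, str | None] = {Strategy.FULL_LENGTH: best[3]}
            targets[Strategy.REPEAT_FOCUSED] = extract_target(
                seq, loc, Strategy.REPEAT_FOCUSED, anchor_mismatch)
            return loc, targets
        if candidates is not shortlist:
            break
    return None, {}


def genotype_samples(loci: Sequence[LocusDefinition],
                     sample_reads: Mapping[str, str | Path | Iterable],
                     combos: Sequence[AnalysisCombo] | None = None,
                     min_read_len: int = DEFAULT_MIN_READ_LEN,
                     anchor_mismatch: float = 0.08) -> GenotypeResult:
    """Genotype every sample under every analysis combo.

    *sample_reads* maps sample id to a FASTQ path or an iterable of
    :class:`~strhap.reads.ReadRecord`.  Length filtering, locus assignment
    and target extraction run once per strategy; stutter flagging and
    allele calling run once per combo.  Every sample x locus x combo gets a
    genotype record (missing when nothing was callable).
    """
    combos = list(combos) if combos is not None else default_combos()
    strategies = sorted({c.strategy for c in combos}, key=lambda s: s.value)
    by_locus = {loc.locus_id: loc for loc in loci}

    # per strategy -> (locus, sample) -> Counter of targets
    target_counts: dict[Strategy, dict[tuple[str, str], Counter]] = {
        s: {} for s in strategies}
    accounting: dict[str, ReadAccounting] = {}

    for sample in sorted(sample_reads):
        src = sample_reads[sample]
        reads = read_fastq(src) if isinstance(src, (str, Path)) else iter(src)
        acc = ReadAccounting()
        all_reads = list(reads)
        acc.n_input = len(all_reads)
        kept, acc.n_short = filter_reads(all_reads, min_read_len)
        # deduplicate before the (expensive) anchor search
        uniq = Counter(r.sequence for r in kept)
        for seq, mult in uniq.items():
            loc, targets = _assign_and_extract(seq, loci, anchor_mismatch)
            if loc is None:
                acc.n_unassigned += mult
                continue
            acc.per_locus[loc.locus_id] += mult
            for strat in strategies:
                target = targets.get(strat)
                if target is None:
                    continue
                key = (loc.locus_id, sample)
                target_counts[strat].setdefault(key, Counter())[target] += mult
        accounting[sample] = acc

    samples = sorted(sample_reads)
    tallies: dict[str, dict[tuple[str, str], UniqueSeqTally]] = {}
    tables: dict[str, list[GenotypeCall]] = {}
    for combo in combos:
        combo_tallies: dict[tuple[str, str], UniqueSeqTally] = {}
        calls: list[GenotypeCall] = []
        for locus_id in sorted(by_locus):
            motif = by_locus[locus_id].motif
            for sample in samples:
                counts = target_counts[combo.strategy].get((locus_id, sample))
                entries = sorted(counts.items(), key=lambda kv: (-kv[1], -len(kv[0]), kv[0])) \
                    if counts else []
                tally = UniqueSeqTally(locus_id=locus_id, individual_id=sample,
                                       combo=combo.name, entries=entries)
                combo_tallies[(locus_id, sample)] = tally
                if not entries:
                    calls.append(GenotypeCall(sample, locus_id, combo.name, "missing"))
                    continue
                flagged = flag_sequences(tally, combo.parameter_set, motif)
                calls.append(call_genotype(flagged, combo.parameter_set,
                                           individual_id=sample, locus_id=locus_id,
                                           combo=combo.name))
        tallies[combo.name] = combo_tallies
        tables[combo.name] = calls
    return GenotypeResult(combos=combos, tallies=tallies, tables=tables,
                          accounting=accounting)


@dataclass
class QCResult:
    qcs: dict[str, list[LocusQC]]     # locus -> QC per combo
    combined: CombinedDataset
    success_rate_pct: int


def run_qc(result: GenotypeResult, sheet: SampleSheet,
           loci: Sequence[LocusDefinition],
           max_error: float = 0.06, max_missing: float = 0.50) -> QCResult:
    """QC every locus x combo, select best combos and build the Combined set."""
    individuals = sheet.individuals
    groups = sheet.replicate_groups()
    qcs: dict[str, list[LocusQC]] = {}
    for loc in loci:
        per_combo: list[LocusQC] = []
        for combo in result.combos:
            calls = [c for c in result.tables[combo.name] if c.locus_id == loc.locus_id]
            combo_tallies = [t for (lid, _), t in result.tallies[combo.name].items()
                             if lid == loc.locus_id]
            per_combo.append(compute_locus_qc(
                loc.locus_id, combo.name, calls, individuals, groups,
                tallies=combo_tallies, max_error=max_error, max_missing=max_missing))
        qcs[loc.locus_id] = per_combo
    combined = combine_genotypes(result.tables, qcs, individuals, groups)
    rate = overall_success_rate(len(combined.selections), len(loci))
    return QCResult(qcs=qcs, combined=combined, success_rate_pct=rate)


@dataclass
class ReportResult:
    catalog: list[AlleleRecord]
    homoplasy: dict[str, HomoplasyMetrics]   # per locus plus "pooled"
    polymorphism: dict[str, tuple[int, int]]  # type -> (n_alleles, n_loci)
    proportions: dict[str, float]             # type -> percent share


def run_report(combined: CombinedDataset,
               loci: Sequence[LocusDefinition]) -> ReportResult:
    """Allele catalog, homoplasy metrics and polymorphism-type breakdown."""
    by_locus_def = {loc.locus_id: loc for loc in loci}
    catalog = build_catalog(combined)
    per_locus: dict[str, list[AlleleRecord]] = {}
    for rec in catalog:
        per_locus.setdefault(rec.locus_id, []).append(rec)
    homoplasy: dict[str, HomoplasyMetrics] = {}
    tot_h = tot_s = 0
    for locus_id, records in sorted(per_locus.items()):
        h, s = len(records), collapse_by_size(records)
        tot_h += h
        tot_s += s
        homoplasy[locus_id] = homoplasy_metrics(h, s, scope=locus_id)
    if tot_h:
        homoplasy["pooled"] = homoplasy_metrics(tot_h, tot_s, scope="pooled")
    poly = polymorphism_counts(catalog, by_locus_def)
    counts = {t: n for t, (n, _) in poly.items()}
    props = type_proportions(counts) if sum(counts.values()) else {}
    return ReportResult(catalog=catalog, homoplasy=homoplasy,
                        polymorphism=poly, proportions=props)


# ---------------------------------------------------------------------------
# on-disk TSV formats


def write_genotype_tables(result: GenotypeResult, outdir: str | Path) -> Path:
    """One TSV with all per-combo genotype calls."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "genotypes.tsv"
    with open(path, "w") as fh:
        fh.write("combo\tindividual\tlocus\tstatus\tallele1\tallele2\tcount1\tcount2\n")
        for combo in result.combos:
            for c in result.tables[combo.name]:
                a = list(c.alleles) + ["", ""]
                n = [str(x) for x in c.counts] + ["", ""]
                fh.write(f"{c.combo}\t{c.individual_id}\t{c.locus_id}\t{c.status}\t"
                         f"{a[0]}\t{a[1]}\t{n[0]}\t{n[1]}\n")
    return path


def load_genotype_tables(path: str | Path) -> dict[str, list[GenotypeCall]]:
    tables: dict[str, list[GenotypeCall]] = {}
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("combo\t"), f"unexpected genotype table header: {header!r}"
        for line in fh:
            combo, ind, locus, status, a1, a2, n1, n2 = line.rstrip("\n").split("\t")
            alleles = tuple(a for a in (a1, a2) if a)
            counts = tuple(int(x) for x in (n1, n2) if x)
            tables.setdefault(combo, []).append(
                GenotypeCall(ind, locus, combo, status, alleles, counts))
    return tables


def write_tally_tables(result: GenotypeResult, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "tallies.tsv"
    with open(path, "w") as fh:
        fh.write("combo\tlocus\tindividual\tsequence\tcount\n")
        for combo in result.combos:
            for (locus_id, sample) in sorted(result.tallies[combo.name]):
                tally = result.tallies[combo.name][(locus_id, sample)]
                for seq, count in tally.entries:
                    fh.write(f"{combo.name}\t{locus_id}\t{sample}\t{seq}\t{count}\n")
    return path


def load_tally_totals(path: str | Path) -> dict[str, dict[tuple[str, str], int]]:
    """combo -> (locus, individual) -> total reads."""
    totals: dict[str, dict[tuple[str, str], int]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            combo, locus, ind, _seq, count = line.rstrip("\n").split("\t")
            key = (locus, ind)
            totals.setdefault(combo, {})[key] = totals.get(combo, {}).get(key, 0) + int(count)
    return totals


def write_qc_tables(qc: QCResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "locus_qc.tsv", "w") as fh:
        fh.write("locus\tcombo\tmissing_rate\tallelic_error_rate\tn_alleles\t"
                 "seq_success\treliable\n")
        for locus_id in sorted(qc.qcs):
            for rec in qc.qcs[locus_id]:
                err = "NA" if rec.allelic_error_rate is None else f"{rec.allelic_error_rate:.6f}"
                fh.write(f"{rec.locus_id}\t{rec.combo}\t{rec.missing_rate:.6f}\t{err}\t"
                         f"{rec.n_alleles}\t{int(rec.seq_success)}\t{int(rec.reliable)}\n")
    with open(outdir / "selection.tsv", "w") as fh:
        fh.write("locus\tchosen_combo\treason\n")
        for locus_id in sorted(set(qc.combined.selections) | set(qc.combined.exclusions)):
            if locus_id in qc.combined.selections:
                fh.write(f"{locus_id}\t{qc.combined.selections[locus_id]}\t"
                         "selected by error, missing, allele count\n")
            else:
                fh.write(f"{locus_id}\t-\t{qc.combined.exclusions[locus_id]}\n")
    with open(outdir / "combined_summary.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in qc.combined.summary.items():
            fh.write(f"{k}\t{v}\n")
        fh.write(f"overall_success_rate_pct\t{qc.success_rate_pct}\n")


def write_report_tables(report: ReportResult, combined: CombinedDataset,
                        outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    code_of = {(r.locus_id, r.sequence): r.code for r in report.catalog}
    with open(outdir / "allele_catalog.tsv", "w") as fh:
        fh.write("locus\tcode\tsequence\tlength_bp\toccurrences\n")
        for r in report.catalog:
            fh.write(f"{r.locus_id}\t{r.code}\t{r.sequence}\t{r.length_bp}\t"
                     f"{r.occurrences}\n")
    with open(outdir / "combined_genotypes.tsv", "w") as fh:
        fh.write("individual\tlocus\tcombo\tstatus\tallele1_code\tallele2_code\n")
        for c in sorted(combined.calls, key=lambda c: (c.locus_id, c.individual_id)):
            if c.is_missing:
                fh.write(f"{c.individual_id}\t{c.locus_id}\t{c.combo}\tmissing\t000\t000\n")
            else:
                pair = c.allele_pair()
                codes = sorted(code_of[(c.locus_id, a)] for a in pair)
                fh.write(f"{c.individual_id}\t{c.locus_id}\t{c.combo}\tcalled\t"
                         f"{codes[0]}\t{codes[1]}\n")
    with open(outdir / "homoplasy.tsv", "w") as fh:
        fh.write("scope\tn_haplotypes\tn_sizes\tpct_homoplasy\tpct_increase\n")
        for scope in sorted(report.homoplasy):
            m = report.homoplasy[scope]
            fh.write(f"{scope}\t{m.n_haplotypes}\t{m.n_sizes}\t"
                     f"{m.pct_homoplasy_rounded}\t{m.pct_increase_rounded}\n")
    with open(outdir / "polymorphism_types.tsv", "w") as fh:
        fh.write("type\tn_alleles\tn_loci\tpct_share\n")
        for t, (na, nl) in report.polymorphism.items():
            share = report.proportions.get(t, 0.0)
            fh.write(f"{t}\t{na}\t{nl}\t{share:.1f}\n")
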