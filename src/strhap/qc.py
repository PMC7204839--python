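"""Replicate-based locus QC, best-strategy selection and the Combined dataset.

Locus validation rests on blind repeats: the same biological individual is
genotyped from independently amplified samples, and the allelic error rate
is the number of allele mismatches between replicated genotypes divided by
the number of alleles compared.  A locus x combo passes QC when its error
rate is at most 6% and its missing rate at most 50% (strictly-greater
values fail); the best combo per locus is then chosen by error rate, then
missing rate, then allele count, and the per-locus winners are stitched
into a single Combined genotype dataset.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .calling import GenotypeCall, UniqueSeqTally

__all__ = [
    "LocusQC",
    "CombinedDataset",
    "DEFAULT_MAX_ERROR",
    "DEFAULT_MAX_MISSING",
    "DEFAULT_COMBO_ORDER",
    "missing_rate",
    "allelic_error_rate",
    "replicate_pairs",
    "sequencing_success",
    "is_reliable",
    "compute_locus_qc",
    "select_best_combo",
    "combine_genotypes",
    "overall_success_rate",
]

DEFAULT_MAX_ERROR = 0.06
DEFAULT_MAX_MISSING = 0.50
SEQ_SUCCESS_MIN_READS = 20
SEQ_SUCCESS_MIN_FRAC = 0.50

# Fixed tie-break preference when two combos are equivalent on all criteria.
DEFAULT_COMBO_ORDER = (
    "FullLength.PS1", "FullLength.PS2", "RepeatFocused.PS1", "RepeatFocused.PS2",
)

_EPS = 1e-12


@dataclass
class LocusQC:
    """Per locus x combo quality summary."""

    locus_id: str
    combo: str
    missing_rate: float
    allelic_error_rate: float | None  # None when no evaluable replicate pair
    n_alleles: int
    seq_success: bool
    reliable: bool = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate outside [0,1]")
        if self.allelic_error_rate is not None and not 0.0 <= self.allelic_error_rate <= 1.0:
            raise ValueError("allelic_error_rate outside [0,1]")
        self.reliable = is_reliable(self.allelic_error_rate, self.missing_rate)


def missing_rate(calls: Iterable[GenotypeCall], individuals: Sequence[str]) -> float:
    """Fraction of individual-samples without a called genotype.

    Every sample in *individuals* counts once (blind replicates are distinct
    samples); a sample with no call record at all counts as missing.
    """
    if not individuals:
        raise ValueError("individuals must be non-empty")
    called = {c.individual_id for c in calls if not c.is_missing}
    return sum(1 for ind in individuals if ind not in called) / len(individuals)


def _pair_mismatches(a: GenotypeCall, b: GenotypeCall) -> int:
    """Allele mismatches between two called genotypes (0, 1 or 2).

    Genotypes are compared as 2-allele multisets, a homozygote counting as
    two copies; mismatches = 2 - |multiset intersection|.
    """
    ca, cb = Counter(a.allele_pair()), Counter(b.allele_pair())
    shared = sum((ca & cb).values())
    return 2 - shared


def replicate_pairs(calls: Iterable[GenotypeCall],
                    replicate_groups: Mapping[str, Sequence[str]],
                    ) -> list[tuple[GenotypeCall, GenotypeCall]]:
    """All unordered within-group genotype pairs for one locus x combo.

    Groups with more than two members contribute every pairwise comparison.
    Pairs where either member is missing (or absent) are excluded here.
    """
    by_ind = {c.individual_id: c for c in calls}
    pairs = []
    for members in replicate_groups.values():
        for ia, ib in itertools.combinations(members, 2):
            a, b = by_ind.get(ia), by_ind.get(ib)
            if a is None or b is None or a.is_missing or b.is_missing:
                continue
            pairs.append((a, b))
    return pairs


def allelic_error_rate(pairs: Sequence[tuple[GenotypeCall, GenotypeCall]]) -> float | None:
    """Allele mismatches over alleles compared, pooled across pairs.

    Each evaluable pair compares two alleles.  Returns ``None`` (undefined)
    when there is no evaluable pair.
    """
    evaluable = [(a, b) for a, b in pairs if not a.is_missing and not b.is_missing]
    if not evaluable:
        return None
    mismatches = sum(_pair_mismatches(a, b) for a, b in evaluable)
    return mismatches / (2 * len(evaluable))


def sequencing_success(tallies: Iterable[UniqueSeqTally], individuals: Sequence[str],
                       min_reads: int = SEQ_SUCCESS_MIN_READS,
                       min_frac: float = SEQ_SUCCESS_MIN_FRAC) -> bool:
    """True when enough individuals reach minimum locus coverage.

    Default rule: at least 20 reads in at least 50% of the individuals
    (exactly 50% passes).  Individuals without a tally count as zero reads.
    """
    if not individuals:
        raise ValueError("individuals must be non-empty")
    totals = {t.individual_id: t.total_reads for t in tallies}
    n_ok = sum(1 for ind in individuals if totals.get(ind, 0) >= min_reads)
    return n_ok / len(individuals) >= min_frac - _EPS


def is_reliable(error_rate: float | None, miss_rate: float,
                max_error: float = DEFAULT_MAX_ERROR,
                max_missing: float = DEFAULT_MAX_MISSING) -> bool:
    """Reliability rule: fail on MORE THAN 6% error or 50% missing.

    Boundary values pass (the thresholds are strict "more than").  An
    undefined error rate (no replicate evidence) fails: without blind
    repeats the locus cannot be validated.
    """
    if error_rate is None:
        return False
    return error_rate <= max_error + _EPS and miss_rate <= max_missing + _EPS


def compute_locus_qc(locus_id: str, combo: str, calls: Sequence[GenotypeCall],
                     individuals: Sequence[str],
                     replicate_groups: Mapping[str, Sequence[str]],
                     tallies: Iterable[UniqueSeqTally] = (),
                     max_error: float = DEFAULT_MAX_ERROR,
                     max_missing: float = DEFAULT_MAX_MISSING) -> LocusQC:
    """Assemble the QC record for one locus under one combo."""
    miss = missing_rate(calls, individuals)
    err = allelic_error_rate(replicate_pairs(calls, replicate_groups))
    alleles = {a for c in calls if not c.is_missing for a in c.alleles}
    qc = LocusQC(locus_id=locus_id, combo=combo, missing_rate=miss,
                 allelic_error_rate=err, n_alleles=len(alleles),
                 seq_success=sequencing_success(tallies, individuals) if tallies else False)
    qc.reliable = is_reliable(err, miss, max_error, max_missing)
    return qc


def select_best_combo(qcs: Sequence[LocusQC],
                      combo_order: Sequence[str] = DEFAULT_COMBO_ORDER,
                      ) -> tuple[str | None, str]:
    """Choose the best combo for one locus, or exclude it.

    Reliable combos are ranked by allelic error rate, then missing rate,
    then (descending) allele count; a full tie falls back to the fixed
    preference order.  Returns ``(combo_name, reason)``; the combo is
    ``None`` when no combo is reliable.
    """
    if not qcs:
        raise ValueError("no QC records supplied")
    if len({q.locus_id for q in qcs}) != 1:
        raise ValueError("select_best_combo expects QC records of one locus")
    reliable = [q for q in qcs if q.reliable]
    if not reliable:
        return None, "no reliable analysis combination"

    def pref(combo: str) -> int:
        try:
            return combo_order.index(combo)
        except ValueError:
            return len(combo_order)

    best = min(reliable, key=lambda q: (q.allelic_error_rate, q.missing_rate,
                                        -q.n_alleles, pref(q.combo)))
    return best.combo, "selected by error, missing, allele count"


@dataclass
class CombinedDataset:
    """Final genotype table, each locus genotyped under its chosen combo."""

    selections: dict[str, str]            # locus_id -> combo name
    exclusions: dict[str, str]            # locus_id -> reason
    calls: list[GenotypeCall]             # only retained loci
    qc: dict[str, LocusQC]                # locus_id -> QC of the chosen combo
    summary: dict[str, float | int] = field(default_factory=dict)

    @property
    def loci(self) -> list[str]:
        return sorted(self.selections)


def combine_genotypes(tables: Mapping[str, Sequence[GenotypeCall]],
                      qcs: Mapping[str, Sequence[LocusQC]],
                      individuals: Sequence[str],
                      replicate_groups: Mapping[str, Sequence[str]],
                      combo_order: Sequence[str] = DEFAULT_COMBO_ORDER,
                      ) -> CombinedDataset:
    """Build the Combined dataset from per-combo genotype tables.

    *tables* maps combo name -> genotype calls (all loci); *qcs* maps
    locus_id -> QC records across combos.  Each retained locus's genotypes
    are copied verbatim from its selected combo; the dataset summary
    (missing and error rates pooled over counts, total alleles) is
    recomputed from the combined table.
    """
    selections: dict[str, str] = {}
    exclusions: dict[str, str] = {}
    chosen_qc: dict[str, LocusQC] = {}
    calls: list[GenotypeCall] = []
    for locus_id in sorted(qcs):
        combo, reason = select_best_combo(list(qcs[locus_id]), combo_order)
        if combo is None:
            exclusions[locus_id] = reason
            continue
        selections[locus_id] = combo
        chosen_qc[locus_id] = next(q for q in qcs[locus_id] if q.combo == combo)
        calls.extend(c for c in tables[combo] if c.locus_id == locus_id)

    n_cells = len(selections) * len(individuals)
    n_missing = sum(1 for c in calls if c.is_missing)
    # recompute replicate-missing separately per locus for the pooled error
    tot_mm = tot_cmp = 0
    for locus_id in selections:
        locus_calls = [c for c in calls if c.locus_id == locus_id]
        pairs = replicate_pairs(locus_calls, replicate_groups)
        tot_mm += sum(_pair_mismatches(a, b) for a, b in pairs)
        tot_cmp += 2 * len(pairs)
    total_alleles = len({(c.locus_id, a) for c in calls if not c.is_missing
                         for a in c.alleles})
    summary = {
        "n_loci": len(selections),
        "n_excluded": len(exclusions),
        "missing_rate": (n_missing / n_cells) if n_cells else 0.0,
        "allelic_error_rate": (tot_mm / tot_cmp) if tot_cmp else 0.0,
        "total_alleles": total_alleles,
    }
    return CombinedDataset(selections=selections, exclusions=exclusions, calls=calls,
                           qc=chosen_qc, summary=summary)


def overall_success_rate(n_reliable: int, n_multiplexed: int) -> int:
    """Percent of multiplexed loci that ended up reliable, rounded to integer."""
    if n_multiplexed < 1:
        raise ValueError("n_multiplexed must be >= 1")
    if n_reliable > n_multiplexed:
        raise ValueError("n_reliable cannot exceed n_multiplexed")
    return int(math.floor(100.0 * n_reliable / n_multiplexed + 0.5))
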