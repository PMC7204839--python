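"""Allele catalog, size-homoplasy metrics and polymorphism-type reports.

Sequence-defined alleles carry more information than fragment lengths: two
haplotypes of identical length may differ by SNPs or indels that capillary
electrophoresis cannot see (size homoplasy).  This module catalogs the
alleles of a combined genotype dataset with stable three-digit codes,
quantifies how many alleles collapse when only length is observed, and
classifies each allele's differences from the locus reference into repeat
number variation, SNPs/indels in the motif, and SNPs/indels in the flanks.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .calling import maximal_motif_run
from .panel import LocusDefinition
from .qc import CombinedDataset

__all__ = [
    "AlleleRecord",
    "HomoplasyMetrics",
    "DiffEvent",
    "POLYMORPHISM_TYPES",
    "build_catalog",
    "collapse_by_size",
    "homoplasy_metrics",
    "align_to_reference",
    "classify_differences",
    "polymorphism_counts",
    "type_proportions",
    "reference_allele",
]

# polymorphism categories, repeat tract first then flanks
POLYMORPHISM_TYPES = (
    "repeat_number_variation",
    "snp_in_motif",
    "indel_in_motif",
    "snp_in_flanking",
    "indel_in_flanking",
)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class AlleleRecord:
    """One cataloged allele with its per-locus three-digit code."""

    locus_id: str
    sequence: str
    code: str          # "001".."999", unique within the locus
    length_bp: int
    occurrences: int   # allele copies across called genotypes (homozygote = 2)


def build_catalog(combined: CombinedDataset) -> list[AlleleRecord]:
    """Catalog every called allele with a stable three-digit code.

    Within each locus alleles are sorted by occurrence count (descending),
    then length (ascending), then lexicographically, and coded "001",
    "002", ... in that order.  Occurrences count allele copies, a
    homozygote contributing two.
    """
    per_locus: dict[str, Counter[str]] = {}
    for call in combined.calls:
        if call.is_missing:
            continue
        per_locus.setdefault(call.locus_id, Counter()).update(call.allele_pair())
    records: list[AlleleRecord] = []
    for locus_id in sorted(per_locus):
        counts = per_locus[locus_id]
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0]))
        if len(ordered) > 999:
            raise ValueError(f"locus {locus_id}: more than 999 alleles")
        for i, (seq, occ) in enumerate(ordered, start=1):
            records.append(AlleleRecord(locus_id=locus_id, sequence=seq,
                                        code=f"{i:03d}", length_bp=len(seq),
                                        occurrences=occ))
    return records


def collapse_by_size(catalog: Sequence[AlleleRecord]) -> int:
    """Number of length-distinct alleles at one locus.

    Lengths are measured on the extracted target; primers add a per-locus
    constant, so distinctness is unchanged.
    """
    if not catalog:
        raise ValueError("empty catalog")
    if len({r.locus_id for r in catalog}) != 1:
        raise ValueError("collapse_by_size expects alleles of a single locus")
    return len({r.length_bp for r in catalog})


@dataclass(frozen=True)
class HomoplasyMetrics:
    """Size-homoplasy summary for a locus or a pooled panel.

    ``n_haplotypes`` (H) counts sequence-distinct alleles, ``n_sizes`` (S)
    length-distinct ones.  ``pct_homoplasy`` = 100(H-S)/H is the share of
    alleles invisible to size-based genotyping; ``pct_increase`` =
    100(H-S)/S is the gain in allele count from reading sequences.
    """

    scope: str
    n_haplotypes: int
    n_sizes: int

    @property
    def pct_homoplasy(self) -> float:
        return 100.0 * (self.n_haplotypes - self.n_sizes) / self.n_haplotypes

    @property
    def pct_increase(self) -> float:
        return 100.0 * (self.n_haplotypes - self.n_sizes) / self.n_sizes

    @property
    def pct_homoplasy_rounded(self) -> int:
        return _round_half_up(self.pct_homoplasy)

    @property
    def pct_increase_rounded(self) -> int:
        return _round_half_up(self.pct_increase)


def homoplasy_metrics(n_haplotypes: int, n_sizes: int, scope: str = "") -> HomoplasyMetrics:
    """Size homoplasy from the counts of sequence- and length-distinct alleles."""
    if not 1 <= n_sizes <= n_haplotypes:
        raise ValueError("need 1 <= n_sizes <= n_haplotypes")
    return HomoplasyMetrics(scope=scope, n_haplotypes=n_haplotypes, n_sizes=n_sizes)


@dataclass(frozen=True)
class DiffEvent:
    """A single alignment difference, located on the reference."""

    kind: str       # "substitution" | "insertion" | "deletion"
    start: int      # reference position (insertion: gap position)
    end: int        # reference end (insertion: == start)
    text: str       # haplotype text (substitution/insertion) or deleted reference text


def reference_allele(catalog: Sequence[AlleleRecord]) -> str:
    """Reference = most frequent allele of the locus (ties: longer, then lexicographic)."""
    if not catalog:
        raise ValueError("empty catalog")
    best = min(catalog, key=lambda r: (-r.occurrences, -r.length_bp, r.sequence))
    return best.sequence


def _needleman_wunsch(a: str, b: str) -> list[tuple[str, int, int]]:
    """Optimal unit-cost global alignment of reference *a* vs haplotype *b*.

    Returns alignment operations ('M' diagonal, 'D' deletion from the
    reference, 'I' insertion from the haplotype) as (op, i, j) steps.
    Among alignments of minimal unit cost, one with the fewest gap blocks
    is chosen, so an inserted or deleted stretch surfaces as one contiguous
    event that a later normalisation step snaps onto motif-copy boundaries.
    """
    n, m = len(a), len(b)
    INF = (1 << 30, 1 << 30)
    # three-state DP; score = (edit cost, gap openings), lexicographic
    M = [[INF] * (m + 1) for _ in range(n + 1)]
    D = [[INF] * (m + 1) for _ in range(n + 1)]
    I = [[INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = (0, 0)
    for i in range(1, n + 1):
        D[i][0] = (i, 1)
    for j in range(1, m + 1):
        I[0][j] = (j, 1)
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                sub = int(a[i - 1] != b[j - 1])
                best = min(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
                M[i][j] = (best[0] + sub, best[1])
            if i > 0:
                D[i][j] = min(D[i][j],
                              (D[i - 1][j][0] + 1, D[i - 1][j][1]),
                              (M[i - 1][j][0] + 1, M[i - 1][j][1] + 1),
                              (I[i - 1][j][0] + 1, I[i - 1][j][1] + 1))
            if j > 0:
                I[i][j] = min(I[i][j],
                              (I[i][j - 1][0] + 1, I[i][j - 1][1]),
                              (M[i][j - 1][0] + 1, M[i][j - 1][1] + 1),
                              (D[i][j - 1][0] + 1, D[i][j - 1][1] + 1))
    state = min(("M", "D", "I"), key=lambda s: {"M": M, "D": D, "I": I}[s][n][m])
    ops: list[tuple[str, int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            sub = int(a[i - 1] != b[j - 1])
            ops.append(("M", i - 1, j - 1))
            target = (M[i][j][0] - sub, M[i][j][1])
            i, j = i - 1, j - 1
            state = min(("M", "D", "I"),
                        key=lambda s: ({"M": M, "D": D, "I": I}[s][i][j] != target,
                                       s != "M"))
        elif state == "D":
            ops.append(("D", i - 1, j))
            score = D[i][j]
            i -= 1
            if D[i][j] == (score[0] - 1, score[1]):
                state = "D"
            else:
                target = (score[0] - 1, score[1] - 1)
                state = "M" if M[i][j] == target else "I"
        else:
            ops.append(("I", i, j - 1))
            score = I[i][j]
            j -= 1
            if I[i][j] == (score[0] - 1, score[1]):
                state = "I"
            else:
                target = (score[0] - 1, score[1] - 1)
                state = "M" if M[i][j] == target else "D"
    ops.reverse()
    return ops


def _indel_placements(ref: str, start: int, end: int, text: str,
                      kind: str) -> list[tuple[int, int, str]]:
    """All equivalent placements of an indel event, left to right."""
    placements = [(start, end, text)]
    # slide left
    s, e, t = start, end, text
    while s > 0:
        if kind == "deletion":
            if ref[s - 1] != ref[e - 1]:
                break
            s, e = s - 1, e - 1
            t = ref[s:e]
        else:
            if ref[s - 1] != t[-1]:
                break
            t = ref[s - 1] + t[:-1]
            s = e = s - 1
        placements.insert(0, (s, e, t))
    # slide right
    s, e, t = start, end, text
    while True:
        if kind == "deletion":
            if e >= len(ref) or ref[s] != ref[e]:
                break
            s, e = s + 1, e + 1
            t = ref[s:e]
        else:
            if s >= len(ref) or t[0] != ref[s]:
                break
            t = t[1:] + ref[s]
            s = e = s + 1
        placements.append((s, e, t))
    return placements


def _is_motif_copies(text: str, motif: str) -> bool:
    """True when *text* is one or more full motif copies up to rotation."""
    m = len(motif)
    if not text or len(text) % m != 0:
        return False
    return text in motif * (len(text) // m + 1)


def align_to_reference(haplotype: str, reference: str,
                       locus: LocusDefinition) -> list[DiffEvent]:
    """Difference events between a haplotype and the locus reference allele.

    A global unit-cost alignment is computed; each indel is then re-placed,
    among its cost-equivalent positions, to sit inside the reference's
    maximal motif run on a motif-copy boundary when possible (leftmost
    otherwise), so repeat-number changes surface as whole-motif gaps.
    """
    if haplotype == reference:
        return []
    ops = _needleman_wunsch(reference, haplotype)
    run_start, run_count = maximal_motif_run(reference, locus.motif)
    run_end = run_start + run_count * len(locus.motif)
    mlen = len(locus.motif)

    raw: list[DiffEvent] = []
    idx = 0
    while idx < len(ops):
        op, i, j = ops[idx]
        if op == "M":
            if reference[i] != haplotype[j]:
                raw.append(DiffEvent("substitution", i, i + 1, haplotype[j]))
            idx += 1
            continue
        # collect a maximal gap block of the same kind
        kind = "deletion" if op == "D" else "insertion"
        block = [ops[idx]]
        idx += 1
        while idx < len(ops) and ops[idx][0] == op:
            block.append(ops[idx])
            idx += 1
        if kind == "deletion":
            start, end = block[0][1], block[-1][1] + 1
            text = reference[start:end]
        else:
            start = end = block[0][1]
            text = "".join(haplotype[j] for _, _, j in block)
        raw.append(DiffEvent(kind, start, end, text))

    # snap each indel onto a motif boundary inside the run when possible,
    # without sliding across a neighbouring event
    events: list[DiffEvent] = []
    for k, ev in enumerate(raw):
        if ev.kind == "substitution":
            events.append(ev)
            continue
        left_bound = events[-1].end if events else 0
        right_bound = raw[k + 1].start if k + 1 < len(raw) else len(reference)
        placements = [
            p for p in _indel_placements(reference, ev.start, ev.end, ev.text, ev.kind)
            if p[0] >= left_bound and p[1] <= right_bound
        ] or [(ev.start, ev.end, ev.text)]
        chosen = None
        for s, e, t in placements:
            inside = (run_start <= s and e <= run_end) if ev.kind == "deletion" \
                else (run_start <= s <= run_end)
            if inside and run_count and (s - run_start) % mlen == 0:
                chosen = (s, e, t)
                break
        if chosen is None:
            chosen = placements[0]
        events.append(DiffEvent(ev.kind, chosen[0], chosen[1], chosen[2]))
    return events


def classify_differences(events: Sequence[DiffEvent],
                         locus: LocusDefinition, reference: str) -> set[str]:
    """Polymorphism-type flags an allele exhibits relative to the reference.

    The repeat region is the reference's maximal motif run.  An indel inside
    it made of whole motif copies is repeat number variation; any other
    in-run indel or substitution is an indel/SNP in the motif; differences
    outside the run are flanking SNPs/indels.  Indels straddling the run
    boundary touch flanking bases and count as flanking.
    """
    run_start, run_count = maximal_motif_run(reference, locus.motif)
    run_end = run_start + run_count * len(locus.motif)
    flags: set[str] = set()
    for ev in events:
        if ev.kind == "substitution":
            inside = run_start <= ev.start < run_end
            flags.add("snp_in_motif" if inside else "snp_in_flanking")
            continue
        if ev.kind == "deletion":
            inside = run_count > 0 and ev.start >= run_start and ev.end <= run_end
        else:  # insertion at a gap position
            inside = run_count > 0 and run_start <= ev.start <= run_end
        if inside and _is_motif_copies(ev.text, locus.motif):
            flags.add("repeat_number_variation")
        elif inside:
            flags.add("indel_in_motif")
        else:
            flags.add("indel_in_flanking")
    return flags


def polymorphism_counts(catalog: Sequence[AlleleRecord],
                        loci: Mapping[str, LocusDefinition],
                        ) -> dict[str, tuple[int, int]]:
    """Per-type (allele count, locus count) across a cataloged panel.

    Every non-reference allele is aligned to its locus reference and may
    contribute to several types; per type, the number of such alleles and
    the number of loci where the type occurs are reported.
    """
    allele_counts: Counter[str] = Counter()
    locus_sets: dict[str, set[str]] = {t: set() for t in POLYMORPHISM_TYPES}
    by_locus: dict[str, list[AlleleRecord]] = {}
    for rec in catalog:
        by_locus.setdefault(rec.locus_id, []).append(rec)
    for locus_id, records in sorted(by_locus.items()):
        locus = loci[locus_id]
        ref = reference_allele(records)
        for rec in records:
            if rec.sequence == ref:
                continue
            flags = classify_differences(
                align_to_reference(rec.sequence, ref, locus), locus, ref)
            for t in flags:
                allele_counts[t] += 1
                locus_sets[t].add(locus_id)
    return {t: (allele_counts.get(t, 0), len(locus_sets[t])) for t in POLYMORPHISM_TYPES}


def type_proportions(counts: Mapping[str, int]) -> dict[str, float]:
    """Share of each polymorphism type, percent with one decimal."""
    total = sum(counts.values())
    if total < 1:
        raise ValueError("at least one counted polymorphism is required")
    return {t: round(100.0 * c / total, 1) for t, c in counts.items()}
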