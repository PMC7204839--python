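"""Core allele calling: anchor matching, unique-sequence tallies, stutter
flagging and diploid genotype calls.

The caller mirrors the classic three-step treatment of microsatellite
amplicon reads: (1) locate each locus inside a read by approximate matching
of its anchor sequences, tolerating a fraction of edits (default 8% of the
anchor length, unit-cost Levenshtein); (2) count the occurrences of each
unique extracted target per locus per individual; (3) flag every unique
sequence as a potential allele, a PCR stutter product explained by a more
abundant parent, or low-coverage noise, and finally call one or two alleles
from the potential-allele pool.

Stutter products differ from their parent by whole copies of the repeat
motif.  A sequence is accepted as stutter of a parent when its coverage does
not exceed the parent's coverage multiplied by the per-offset threshold
percentages along some decomposition of the repeat offset into single steps
(e.g. a -2 product is allowed at threshold(-1)^2 of the parent); chains
through intermediate stutters are allowed, matching the multiplicative way
slippage compounds over PCR cycles.
"""

from __future__ import annotations

import enum
import heapq
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .panel import (
    IUPAC_CODES,
    LocusDefinition,
    ParameterSet,
    Strategy,
    effective_anchors,
    reverse_complement,
)
from .reads import ReadRecord

__all__ = [
    "AnchorHit",
    "UniqueSeqTally",
    "Flag",
    "FlaggedSeq",
    "GenotypeCall",
    "find_anchor",
    "extract_target",
    "tally_targets",
    "maximal_motif_run",
    "repeat_offset",
    "stutter_path_factor",
    "flag_sequences",
    "call_genotype",
]

DEFAULT_ANCHOR_MISMATCH_FRAC = 0.08

# edlib equality pairs letting IUPAC ambiguity codes in anchors match plain bases
_IUPAC_EQUALITIES = [
    (code, base)
    for code, bases in IUPAC_CODES.items()
    if code not in "ACGT"
    for base in bases
]


@dataclass(frozen=True)
class AnchorHit:
    """Best occurrence of an anchor inside a read: [start, end) and edit count."""

    start: int
    end: int
    edits: int


def find_anchor(sequence: str, anchor: str,
                max_mismatch_frac: float = DEFAULT_ANCHOR_MISMATCH_FRAC) -> AnchorHit | None:
    """Locate the lowest-edit occurrence of *anchor* within *sequence*.

    Edits are unit-cost Levenshtein operations (substitutions and indels);
    an occurrence is accepted when its edit count is at most
    ``floor(max_mismatch_frac * len(anchor))``.  Ties on edit count are
    broken by the leftmost start.  Returns ``None`` when no acceptable
    occurrence exists.
    """
    if len(anchor) < 10:
        raise ValueError("anchor must be at least 10 nt")
    allowed = math.floor(max_mismatch_frac * len(anchor))
    res = edlib.align(anchor, sequence, mode="HW", task="locations", k=allowed,
                      additionalEqualities=_IUPAC_EQUALITIES)
    if res["editDistance"] < 0:
        return None
    start, end = min(res["locations"])  # leftmost best hit; edlib end is inclusive
    return AnchorHit(start=start if start is not None else 0, end=end + 1,
                     edits=res["editDistance"])


def extract_target(read: ReadRecord | str, locus: LocusDefinition, strategy: Strategy,
                   max_mismatch_frac: float = DEFAULT_ANCHOR_MISMATCH_FRAC,
                   ) -> str | None:
    """Extract the between-anchor target of *locus* from a read, or ``None``.

    Both the read and its reverse complement are searched; the orientation
    with the smaller summed anchor edit count wins (forward on ties).  The
    left anchor must precede the right anchor with a non-negative gap.
    """
    hit = extract_target_with_edits(read, locus, strategy, max_mismatch_frac)
    return None if hit is None else hit[0]


def extract_target_with_edits(read: ReadRecord | str, locus: LocusDefinition,
                              strategy: Strategy,
                              max_mismatch_frac: float = DEFAULT_ANCHOR_MISMATCH_FRAC,
                              ) -> tuple[str, int] | None:
    """Like :func:`extract_target` but also returns the summed anchor edits."""
    seq = read if isinstance(read, str) else read.sequence
    left, right = effective_anchors(locus, strategy)
    best: tuple[str, int] | None = None
    for oriented in (seq, reverse_complement(seq)):
        lhit = find_anchor(oriented, left, max_mismatch_frac)
        if lhit is None:
            continue
        tail = oriented[lhit.end:]
        if len(tail) < len(right):
            continue
        rhit = find_anchor(tail, right, max_mismatch_frac)
        if rhit is None:
            continue
        target = tail[:rhit.start]
        edits = lhit.edits + rhit.edits
        if best is None or edits < best[1]:
            best = (target, edits)
    return best


@dataclass
class UniqueSeqTally:
    """Counts of distinct target sequences for one (locus, individual, combo)."""

    locus_id: str
    individual_id: str
    combo: str
    entries: list[tuple[str, int]] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(c for _, c in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def tally_targets(targets: Iterable[str], *, locus_id: str = "", individual_id: str = "",
                  combo: str = "") -> UniqueSeqTally:
    """Count exact-identity occurrences of extracted targets."""
    counts = Counter(targets)
    entries = sorted(counts.items(), key=lambda kv: (-kv[1], -len(kv[0]), kv[0]))
    return UniqueSeqTally(locus_id=locus_id, individual_id=individual_id, combo=combo,
                          entries=entries)


def maximal_motif_run(seq: str, motif: str) -> tuple[int, int]:
    """(start, n_copies) of the longest tandem run of full *motif* copies.

    Ties go to the leftmost run; ``(0, 0)`` when the motif never occurs.
    """
    m = len(motif)
    best_start, best_count = 0, 0
    i = 0
    n = len(seq)
    while i + m <= n:
        if seq[i:i + m] == motif:
            j = i
            while j + m <= n and seq[j:j + m] == motif:
                j += m
            count = (j - i) // m
            if count > best_count:
                best_start, best_count = i, count
            i = j  # a longer run cannot start inside this one's copies
        else:
            i += 1
    return best_start, best_count


def repeat_offset(child: str, parent: str, motif: str) -> int | None:
    """Signed number of whole motif copies separating *child* from *parent*.

    Returns ``k`` when *child* equals *parent* with ``|k|`` contiguous full
    motif copies inserted (k > 0) or deleted (k < 0) inside parent's maximal
    motif run, ``0`` iff the sequences are identical, and ``None`` otherwise
    (any substitution or non-motif indel disqualifies).
    """
    m = len(motif)
    diff = len(child) - len(parent)
    if diff % m != 0:
        return None
    k = diff // m
    if k == 0:
        return 0 if child == parent else None
    start, r = maximal_motif_run(parent, motif)
    if r == 0 or r + k < 0:
        return None
    prefix = parent[:start]
    suffix = parent[start + r * m:]
    if child == prefix + motif * (r + k) + suffix:
        return k
    return None


def stutter_path_factor(offset: int, thresholds: Mapping[int, float]) -> float:
    """Largest product of per-step threshold fractions reaching *offset*.

    The offset is decomposed into steps drawn from the threshold map (each
    step usable any number of times); the coverage allowance multiplies per
    step, so e.g. offset -2 under ``{-1: 70}`` yields ``0.49``.  Returns 0.0
    when the offset cannot be composed from the available steps.
    """
    if offset == 0:
        return 1.0
    if not thresholds:
        return 0.0
    steps = {k: v / 100.0 for k, v in thresholds.items()}
    max_step = max(abs(k) for k in steps)
    lo = min(0, offset) - max_step
    hi = max(0, offset) + max_step
    # Dijkstra on cumulative offsets with cost -log(fraction); the product
    # depends only on the step multiset, so partial sums can always be kept
    # inside [lo, hi] without loss of optimality.
    costs = {k: -math.log(f) if f < 1.0 else 0.0 for k, f in steps.items()}
    dist: dict[int, float] = {0: 0.0}
    heap: list[tuple[float, int]] = [(0.0, 0)]
    while heap:
        d, node = heapq.heappop(heap)
        if node == offset:
            return math.exp(-d)
        if d > dist.get(node, math.inf):
            continue
        for k, c in costs.items():
            nxt = node + k
            if not lo <= nxt <= hi:
                continue
            nd = d + c
            if nd < dist.get(nxt, math.inf) - 1e-15:
                dist[nxt] = nd
                heapq.heappush(heap, (nd, nxt))
    return 0.0


class Flag(str, enum.Enum):
    ALLELE = "ALLELE"
    STUTTER = "STUTTER"
    LOW = "LOW"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class FlaggedSeq:
    sequence: str
    count: int
    flag: Flag
    parent: str | None = None  # sequence explaining a STUTTER


_EPS = 1e-9


def flag_sequences(tally: UniqueSeqTally, params: ParameterSet, motif: str) -> list[FlaggedSeq]:
    """Partition a tally's unique sequences into ALLELE / STUTTER / LOW.

    Entries are processed in descending coverage (ties: longer sequence
    first, then lexicographic).  The most abundant sequence is an ALLELE.  A
    later entry becomes a STUTTER when some already-flagged ALLELE or
    STUTTER with strictly greater coverage explains it: the repeat offset
    between them decomposes into steps of the parameter set's threshold map
    and the entry's coverage is at most the parent's coverage times the
    product of the step fractions.  Unexplained entries are ALLELE when
    their coverage reaches ``min_allele_reads``, LOW otherwise.
    """
    if not tally.entries:
        raise ValueError("flag_sequences requires a non-empty tally")
    ordered = sorted(tally.entries, key=lambda kv: (-kv[1], -len(kv[0]), kv[0]))
    flagged: list[FlaggedSeq] = []
    for idx, (seq, count) in enumerate(ordered):
        if idx == 0:
            flagged.append(FlaggedSeq(seq, count, Flag.ALLELE))
            continue
        best_allowed = -1.0
        best_parent: str | None = None
        for prev in flagged:
            if prev.flag is Flag.LOW or prev.count <= count:
                continue
            off = repeat_offset(seq, prev.sequence, motif)
            if off is None or off == 0:
                continue
            allowed = prev.count * stutter_path_factor(off, params.stutter_thresholds)
            if allowed > best_allowed:
                best_allowed = allowed
                best_parent = prev.sequence
        if best_parent is not None and count <= best_allowed + _EPS:
            flagged.append(FlaggedSeq(seq, count, Flag.STUTTER, parent=best_parent))
        elif count >= params.min_allele_reads:
            flagged.append(FlaggedSeq(seq, count, Flag.ALLELE))
        else:
            flagged.append(FlaggedSeq(seq, count, Flag.LOW))
    return flagged


@dataclass(frozen=True)
class GenotypeCall:
    """0-2 haplotype alleles for one individual at one locus under one combo."""

    individual_id: str
    locus_id: str
    combo: str
    status: str  # "called" | "missing"
    alleles: tuple[str, ...] = ()
    counts: tuple[int, ...] = ()

    @property
    def is_missing(self) -> bool:
        return self.status == "missing"

    def allele_pair(self) -> tuple[str, str]:
        """Both allele copies; a homozygote is doubled."""
        if self.is_missing:
            raise ValueError("missing genotype has no allele pair")
        if len(self.alleles) == 1:
            return (self.alleles[0], self.alleles[0])
        return (self.alleles[0], self.alleles[1])


def call_genotype(flagged: Sequence[FlaggedSeq], params: ParameterSet, *,
                  individual_id: str = "", locus_id: str = "",
                  combo: str = "") -> GenotypeCall:
    """Call 0-2 alleles from flagged sequences.

    The genotype is missing when total locus coverage is below
    ``min_locus_reads`` or the top potential allele is below
    ``min_allele_reads``.  A second allele is called when it reaches
    ``min_allele_reads`` and ``het_balance_pct`` percent of the top allele's
    coverage; otherwise the call is homozygous for the top allele.
    """
    def missing() -> GenotypeCall:
        return GenotypeCall(individual_id, locus_id, combo, "missing")

    total = sum(f.count for f in flagged)
    if total < params.min_locus_reads:
        return missing()
    candidates = sorted((f for f in flagged if f.flag is Flag.ALLELE),
                        key=lambda f: (-f.count, -len(f.sequence), f.sequence))
    if not candidates or candidates[0].count < params.min_allele_reads:
        return missing()
    top = candidates[0]
    if len(candidates) > 1:
        second = candidates[1]
        if (second.count >= params.min_allele_reads
                and second.count * 100.0 >= params.het_balance_pct * top.count - _EPS):
            return GenotypeCall(individual_id, locus_id, combo, "called",
                                (top.sequence, second.sequence),
                                (top.count, second.count))
    return GenotypeCall(individual_id, locus_id, combo, "called",
                        (top.sequence,), (top.count,))
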