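"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (enumeration, quadratic DP) and shares
no code with the package implementation it checks.
"""

from __future__ import annotations

import itertools
from collections import Counter


def levenshtein(a: str, b: str) -> int:
    """Plain quadratic unit-cost edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def best_infix_edits(anchor: str, seq: str) -> int:
    """Lowest edit distance of *anchor* to any substring of *seq*.

    Exhaustive sliding-window scan over all substrings.
    """
    best = len(anchor)
    for start in range(len(seq) + 1):
        for end in range(start, len(seq) + 1):
            if abs((end - start) - len(anchor)) > best:
                continue
            best = min(best, levenshtein(anchor, seq[start:end]))
    return best


def maximal_run_brute(seq: str, motif: str) -> tuple[int, int]:
    """Leftmost longest tandem run of full motif copies, by enumeration."""
    m = len(motif)
    best = (0, 0)
    for start in range(len(seq)):
        count = 0
        while seq[start + count * m:start + (count + 1) * m] == motif:
            count += 1
        # maximal: not preceded by another full copy
        if count > best[1] and seq[max(0, start - m):start] != motif:
            best = (start, count)
    return best


def stutter_variants(parent: str, motif: str, k: int) -> set[str]:
    """All strings reachable by inserting/deleting k motif copies in the run."""
    start, r = maximal_run_brute(parent, motif)
    if r == 0 or r + k < 0:
        return set()
    m = len(motif)
    prefix, suffix = parent[:start], parent[start + r * m:]
    return {prefix + motif * (r + k) + suffix}


def offset_brute(child: str, parent: str, motif: str) -> int | None:
    """Repeat offset by generating every +-k variant of the parent."""
    if child == parent:
        return 0
    max_k = (abs(len(child) - len(parent)) // len(motif)) + 2
    for k in range(-max_k, max_k + 1):
        if k != 0 and child in stutter_variants(parent, motif, k):
            return k
    return None


def path_factor_brute(offset: int, thresholds: dict[int, float],
                      max_steps: int = 6) -> float:
    """Max product of per-step fractions over all step sequences to *offset*."""
    keys = list(thresholds)
    best = 0.0
    for length in range(1, max_steps + 1):
        for combo in itertools.product(keys, repeat=length):
            if sum(combo) != offset:
                continue
            prod = 1.0
            for step in combo:
                prod *= thresholds[step] / 100.0
            best = max(best, prod)
    return best


def flag_brute(entries: list[tuple[str, int]], thresholds: dict[int, float],
               min_allele_reads: int, motif: str) -> list[tuple[str, str]]:
    """Exhaustive stutter flagging: (sequence, flag) in processing order.

    For each entry, every already-flagged ALLELE/STUTTER with strictly
    greater count is tried as a parent over every step decomposition of the
    brute-force repeat offset.
    """
    ordered = sorted(entries, key=lambda kv: (-kv[1], -len(kv[0]), kv[0]))
    out: list[tuple[str, str]] = []
    counts = dict(ordered)
    for idx, (seq, count) in enumerate(ordered):
        if idx == 0:
            out.append((seq, "ALLELE"))
            continue
        is_stutter = False
        for pseq, pflag in out:
            if pflag == "LOW" or counts[pseq] <= count:
                continue
            off = offset_brute(seq, pseq, motif)
            if off is None or off == 0:
                continue
            allowed = counts[pseq] * path_factor_brute(off, thresholds)
            if count <= allowed + 1e-9:
                is_stutter = True
                break
        if is_stutter:
            out.append((seq, "STUTTER"))
        elif count >= min_allele_reads:
            out.append((seq, "ALLELE"))
        else:
            out.append((seq, "LOW"))
    return out


def select_best_brute(qcs, order: tuple[str, ...]):
    """Ordered-criteria selection by explicit pairwise comparison."""
    reliable = [q for q in qcs if q.reliable]
    if not reliable:
        return None
    best = reliable[0]
    for q in reliable[1:]:
        for a, b, flip in ((q.allelic_error_rate, best.allelic_error_rate, False),
                           (q.missing_rate, best.missing_rate, False),
                           (q.n_alleles, best.n_alleles, True),
                           (order.index(q.combo), order.index(best.combo), False)):
            if a == b:
                continue
            better = (a > b) if flip else (a < b)
            if better:
                best = q
            break
    return best.combo


def genotype_mismatches(pair_a: tuple[str, str], pair_b: tuple[str, str]) -> int:
    """2 - multiset intersection size of two 2-allele genotypes."""
    ca, cb = Counter(pair_a), Counter(pair_b)
    return 2 - sum((ca & cb).values())
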