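"""Anchor matching, target extraction, stutter flagging and allele calls."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strhap.calling import (
    Flag,
    call_genotype,
    extract_target,
    find_anchor,
    flag_sequences,
    maximal_motif_run,
    repeat_offset,
    stutter_path_factor,
    tally_targets,
)
from strhap.panel import ParameterSet, Strategy, reverse_complement

from .oracles import (
    best_infix_edits,
    flag_brute,
    maximal_run_brute,
    offset_brute,
    path_factor_brute,
)


def mutate(seq: str, positions: list[int]) -> str:
    table = {"A": "C", "C": "G", "G": "T", "T": "A"}
    chars = list(seq)
    for p in positions:
        chars[p] = table[chars[p]]
    return "".join(chars)


ANCHOR25 = "GATTACAGATTACAGATTACAGATT"  # 25 nt -> floor(0.08*25) = 2 edits allowed


class TestFindAnchor:
    def test_exact_occurrence_zero_edits(self):
        seq = "CCCC" + ANCHOR25 + "GGGG"
        hit = find_anchor(seq, ANCHOR25)
        assert (hit.start, hit.end, hit.edits) == (4, 29, 0)

    def test_two_substitutions_accepted(self):
        seq = "CCCC" + mutate(ANCHOR25, [5, 17]) + "GGGG"
        assert best_infix_edits(ANCHOR25, seq) == 2  # oracle confirms best hit
        hit = find_anchor(seq, ANCHOR25)
        assert hit is not None and hit.edits == 2

    def test_three_edits_rejected(self):
        seq = "CCCC" + mutate(ANCHOR25, [5, 11, 17]) + "GGGG"
        assert best_infix_edits(ANCHOR25, seq) == 3
        assert find_anchor(seq, ANCHOR25) is None

    def test_iupac_code_in_anchor_matches_any_expansion(self):
        anchor = ANCHOR25[:-1] + "N"
        seq = "TT" + ANCHOR25 + "TT"
        hit = find_anchor(seq, anchor)
        assert hit is not None and hit.edits == 0

    def test_agrees_with_sliding_window_oracle(self):
        rng = random.Random(11)
        for _ in range(60):
            anchor = "".join(rng.choice("ACGT") for _ in range(rng.randint(12, 20)))
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(20, 45)))
            allowed = int(0.25 * len(anchor))  # generous frac to exercise hits
            oracle = best_infix_edits(anchor, seq)
            hit = find_anchor(seq, anchor, max_mismatch_frac=0.25)
            if oracle <= allowed:
                assert hit is not None and hit.edits == oracle
            else:
                assert hit is None

    def test_short_anchor_rejected(self):
        with pytest.raises(ValueError):
            find_anchor("ACGTACGTACGT", "ACGTACGT")


class TestExtractTarget:
    def build_read(self, locus, tract="ACACAC", left=None, right=None):
        left = locus.left_flank if left is None else left
        right = locus.right_flank if right is None else right
        return (locus.forward_primer + left + tract + right
                + reverse_complement(locus.reverse_primer))

    def test_exact_read_full_length(self, locus_ac):
        read = self.build_read(locus_ac)
        assert extract_target(read, locus_ac, Strategy.FULL_LENGTH) == \
            "TTGA" + "ACACAC" + "CCTA"

    def test_exact_read_repeat_focused(self, locus_ac):
        read = self.build_read(locus_ac)
        assert extract_target(read, locus_ac, Strategy.REPEAT_FOCUSED) == "ACACAC"

    def test_reverse_complement_read_same_target(self, locus_ac):
        read = self.build_read(locus_ac)
        for strategy in Strategy:
            assert extract_target(reverse_complement(read), locus_ac, strategy) == \
                extract_target(read, locus_ac, strategy)

    def test_flank_snp_absorbed_by_repeat_focused_anchor(self, locus_ac):
        # one SNP in the left flank: the RepeatFocused left anchor is
        # primer+flank (25 nt), so 2 edits are allowed and the tract is
        # still extracted
        read = self.build_read(locus_ac, left=mutate(locus_ac.left_flank, [1]))
        assert extract_target(read, locus_ac, Strategy.REPEAT_FOCUSED) == "ACACAC"
        # while the FullLength target keeps the SNP visible
        full = extract_target(read, locus_ac, Strategy.FULL_LENGTH)
        assert full == mutate(locus_ac.left_flank, [1]) + "ACACAC" + locus_ac.right_flank

    def test_missing_anchor_returns_none(self, locus_ac):
        assert extract_target("ACGT" * 30, locus_ac, Strategy.FULL_LENGTH) is None


class TestTally:
    def test_counts_and_total(self):
        t = tally_targets(["s1", "s1", "s2"])
        assert dict(t.entries) == {"s1": 2, "s2": 1}
        assert t.total_reads == 3

    def test_empty(self):
        t = tally_targets([])
        assert t.entries == [] and t.total_reads == 0

    def test_single_sequence_bulk(self):
        t = tally_targets(["x" * 5] * 1000)
        assert t.entries == [("xxxxx", 1000)]


class TestRepeatOffset:
    def test_motif_run_detection_matches_brute_force(self):
        rng = random.Random(5)
        for _ in range(50):
            motif = rng.choice(["AC", "AGC", "TATG", "A"])
            seq = "".join(rng.choice(["AC", "AGC", "T", "G", "TATG"])
                          for _ in range(rng.randint(3, 12)))
            assert maximal_motif_run(seq, motif) == maximal_run_brute(seq, motif)

    def test_single_copy_deletion(self):
        parent = "TT" + "AC" * 10 + "GG"
        child = "TT" + "AC" * 9 + "GG"
        assert repeat_offset(child, parent, "AC") == -1

    def test_identical_is_zero(self):
        seq = "TT" + "AC" * 10 + "GG"
        assert repeat_offset(seq, seq, "AC") == 0

    def test_substitution_inside_run_disqualifies(self):
        parent = "TT" + "AC" * 10 + "GG"
        child = mutate(parent, [7])
        assert offset_brute(child, parent, "AC") is None
        assert repeat_offset(child, parent, "AC") is None

    def test_agrees_with_brute_force_variants(self):
        rng = random.Random(3)
        for _ in range(200):
            motif = rng.choice(["AC", "AGC", "TAGA"])
            r = rng.randint(3, 10)
            parent = "TTG" + motif * r + "CCT"
            k = rng.randint(-3, 3)
            if k == 0 or r + k < 1:
                continue
            child = "TTG" + motif * (r + k) + "CCT"
            assert repeat_offset(child, parent, motif) == k
            assert offset_brute(child, parent, motif) == k
            # a non-motif single-base indel never yields an offset
            broken = child[: len(child) // 2] + "A" + child[len(child) // 2:]
            if (len(broken) - len(parent)) % len(motif) == 0:
                assert repeat_offset(broken, parent, motif) == \
                    offset_brute(broken, parent, motif)


class TestStutterPathFactor:
    @pytest.mark.parametrize("offset,thresholds,expected", [
        (-1, {-1: 70.0, +1: 10.0}, 0.70),
        (-2, {-1: 70.0, +1: 10.0}, 0.49),     # chained -1 steps
        (+2, {-1: 50.0, +1: 10.0}, 0.01),
        (-3, {-1: 50.0, +1: 10.0}, 0.125),
        (-2, {+1: 10.0}, 0.0),                # unreachable
    ])
    def test_known_products(self, offset, thresholds, expected):
        assert stutter_path_factor(offset, thresholds) == pytest.approx(expected)

    def test_agrees_with_enumeration(self):
        rng = random.Random(9)
        for _ in range(100):
            thresholds = {-1: rng.choice([10.0, 50.0, 70.0, 90.0]),
                          +1: rng.choice([5.0, 10.0, 30.0])}
            if rng.random() < 0.3:
                thresholds[-2] = rng.choice([20.0, 60.0])
            offset = rng.choice([-4, -3, -2, -1, 1, 2, 3])
            assert stutter_path_factor(offset, thresholds) == pytest.approx(
                path_factor_brute(offset, thresholds, max_steps=6))


def make_tally(entries):
    return tally_targets([s for s, c in entries for _ in range(c)])


class TestFlagSequences:
    def test_ps2_worked_example(self, ps2):
        # parent (AC)x12 at 100 reads; (AC)x11 at 65 is stutter (65 <= 70);
        # (AC)x13 at 12 exceeds the +1 allowance (12 > 10) and, at >= m=10
        # reads, is a second allele
        entries = [("TT" + "AC" * 12 + "GG", 100),
                   ("TT" + "AC" * 11 + "GG", 65),
                   ("TT" + "AC" * 13 + "GG", 12)]
        flags = {f.sequence: f.flag for f in
                 flag_sequences(make_tally(entries), ps2, "AC")}
        assert flags[entries[0][0]] is Flag.ALLELE
        assert flags[entries[1][0]] is Flag.STUTTER
        assert flags[entries[2][0]] is Flag.ALLELE

    def test_chained_minus_two_stutter(self, ps2):
        # -2 product at 40 reads is allowed: 100 * 0.70 * 0.70 = 49 >= 40
        entries = [("TT" + "AC" * 12 + "GG", 100),
                   ("TT" + "AC" * 10 + "GG", 40)]
        flagged = flag_sequences(make_tally(entries), ps2, "AC")
        assert flagged[1].flag is Flag.STUTTER
        assert flagged[1].parent == entries[0][0]

    def test_single_entry_is_allele(self, ps1):
        flagged = flag_sequences(make_tally([("ACACAC", 3)]), ps1, "AC")
        assert [f.flag for f in flagged] == [Flag.ALLELE]

    def test_flag_partition_and_count_conservation(self, ps1):
        entries = [("TT" + "AC" * (8 + k) + "GG", c)
                   for k, c in [(0, 120), (-1, 50), (1, 9), (2, 3), (3, 2)]]
        tally = make_tally(entries)
        flagged = flag_sequences(tally, ps1, "AC")
        assert len(flagged) == len(tally.entries)
        assert sum(f.count for f in flagged) == tally.total_reads
        for f in flagged:
            if f.flag is Flag.STUTTER:
                parent = next(p for p in flagged if p.sequence == f.parent)
                assert parent.count > f.count

    def test_input_order_invariance(self, ps1):
        entries = [("TT" + "AC" * 10 + "GG", 100), ("TT" + "AC" * 9 + "GG", 45),
                   ("TT" + "AC" * 11 + "GG", 8)]
        a = flag_sequences(make_tally(entries), ps1, "AC")
        b = flag_sequences(make_tally(entries[::-1]), ps1, "AC")
        assert a == b

    def test_matches_exhaustive_search_randomized(self, ps1, ps2):
        # oracle equivalence on small random tallies (more cases run in the
        # acceptance suite)
        rng = random.Random(21)
        for case in range(150):
            params = ps1 if case % 2 else ps2
            motif = rng.choice(["AC", "AGC"])
            base = rng.randint(5, 9)
            entries = {}
            for _ in range(rng.randint(1, 6)):
                k = rng.randint(-3, 2)
                seq = "TTG" + motif * max(1, base + k) + "CAT"
                if rng.random() < 0.25:
                    seq = mutate(seq, [rng.randrange(len(seq))])
                entries[seq] = rng.randint(1, 200)
            tally = make_tally(list(entries.items()))
            got = [(f.sequence, f.flag.value)
                   for f in flag_sequences(tally, params, motif)]
            expected = flag_brute(list(entries.items()),
                                  dict(params.stutter_thresholds),
                                  params.min_allele_reads, motif)
            assert got == expected


DNA = st.text(alphabet="ACGT", min_size=0, max_size=6)


class TestFlagInvariants:
    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        motif=st.sampled_from(["AC", "AG", "AGC", "T"]),
        entries=st.lists(
            st.tuples(st.integers(min_value=-3, max_value=3),
                      st.integers(min_value=1, max_value=200),
                      st.booleans()),
            min_size=1, max_size=6),
        base=st.integers(min_value=4, max_value=9),
    )
    def test_partition_and_conservation(self, motif, entries, base):
        """Flags always partition the tally; counts and totals survive."""
        ps1 = ParameterSet("PS1", {-1: 50.0, +1: 10.0}, min_allele_reads=15,
                           min_locus_reads=20)
        seqs = {}
        for k, count, mutate_one in entries:
            seq = "TTG" + motif * max(1, base + k) + "CAT"
            if mutate_one:
                p = len(seq) // 2
                seq = seq[:p] + {"A": "C", "C": "G", "G": "T",
                                 "T": "A"}[seq[p]] + seq[p + 1:]
            seqs[seq] = count
        tally = make_tally(list(seqs.items()))
        flagged = flag_sequences(tally, ps1, motif)
        assert len(flagged) == len(tally.entries)
        assert sum(f.count for f in flagged) == tally.total_reads
        for f in flagged:
            assert (f.parent is not None) == (f.flag is Flag.STUTTER)


class TestCallGenotype:
    def flag(self, entries, params, motif="AC"):
        return flag_sequences(make_tally(entries), params, motif)

    def test_heterozygote_above_balance(self, ps1):
        # 40 >= 25% of 100 and >= m -> het
        flagged = self.flag([("TT" + "AC" * 10 + "GG", 100),
                             ("TT" + "GC" * 10 + "GG", 40)], ps1)
        call = call_genotype(flagged, ps1)
        assert call.status == "called" and len(call.alleles) == 2
        assert call.counts == (100, 40)

    def test_homozygote_below_balance(self, ps1):
        # 20 reads < 25% of 100 -> homozygote for the top allele, and the
        # doubled pair is used in comparisons
        flagged = self.flag([("TT" + "AC" * 10 + "GG", 100),
                             ("TT" + "GC" * 10 + "GG", 20)], ps1)
        call = call_genotype(flagged, ps1)
        assert call.alleles == ("TT" + "AC" * 10 + "GG",)
        assert call.allele_pair() == ("TT" + "AC" * 10 + "GG",) * 2

    def test_low_total_coverage_missing(self, ps1):
        flagged = self.flag([("ACACAC", 12)], ps1)
        call = call_genotype(flagged, ps1)
        assert call.is_missing and call.alleles == ()

    def test_top_below_m_missing(self, ps1):
        # total 24 >= n but the top candidate has fewer than m=15 reads
        flagged = self.flag([("TT" + "AC" * 10 + "GG", 13),
                             ("TT" + "GC" * 10 + "GG", 11)], ps1)
        assert call_genotype(flagged, ps1).is_missing

    def test_called_alleles_are_allele_flagged_with_m_reads(self, ps1):
        flagged = self.flag([("TT" + "AC" * 10 + "GG", 90),
                             ("TT" + "AC" * 9 + "GG", 40),
                             ("TT" + "AC" * 8 + "GG", 17)], ps1)
        call = call_genotype(flagged, ps1)
        by_seq = {f.sequence: f for f in flagged}
        for allele, count in zip(call.alleles, call.counts):
            assert by_seq[allele].flag is Flag.ALLELE
            assert count >= ps1.min_allele_reads
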