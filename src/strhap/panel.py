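"""Locus panel model: marker definitions, analysis parameter sets and strategies.

A panel is the set of microsatellite loci co-amplified in one multiplexed
PCR.  Each locus is anchored by its primer pair and, between the primers,
decomposes into ``left_flank + motif * repeat_count + right_flank``.  Two
analytical strategies are supported for turning reads into alleles:

* ``FULL_LENGTH`` — the whole inter-primer sequence is the allele, so any
  linked SNP or indel in the flanks distinguishes alleles of equal length.
* ``REPEAT_FOCUSED`` — the flanks are absorbed into the matching anchors and
  only the repeat-tract region defines the allele.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "IUPAC_CODES",
    "LocusDefinition",
    "ParameterSet",
    "Strategy",
    "AnalysisCombo",
    "PanelError",
    "DEFAULT_PARAMETER_SETS",
    "COMBO_PREFERENCE_ORDER",
    "reverse_complement",
    "is_primitive_motif",
    "load_panel",
    "write_panel",
    "effective_anchors",
    "default_combos",
]

# IUPAC nucleotide one-letter codes -> set of plain bases they stand for.
IUPAC_CODES: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)

PLAIN_BASES = frozenset("ACGT")


class PanelError(ValueError):
    """Raised on malformed panel files or invalid locus definitions."""


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive_motif(motif: str) -> bool:
    """True when *motif* is not itself a tandem repeat of a shorter unit.

    ``"AC"`` is primitive; ``"ACAC"`` and ``"AAA"`` are not.  Offset
    arithmetic in stutter detection requires a unique repeat unit, so only
    primitive motifs are accepted in a panel.
    """
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif[:d] * (n // d) == motif:
            return False
    return True


class Strategy(str, enum.Enum):
    """Analytical strategy deciding what sequence region defines an allele."""

    FULL_LENGTH = "FullLength"
    REPEAT_FOCUSED = "RepeatFocused"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class LocusDefinition:
    """One microsatellite locus of a multiplexed panel.

    ``forward_primer`` and ``reverse_primer`` are both written 5'->3' on
    their own strand; matching against a read uses the reverse complement of
    the reverse primer.  ``left_flank``/``right_flank`` lie between the
    primers and the repeat tract and may be empty.  ``target_len_range`` is
    the inclusive expected length range (bp) of the inter-primer target.
    """

    locus_id: str
    forward_primer: str
    reverse_primer: str
    left_flank: str
    right_flank: str
    motif: str
    ref_repeat_count: int
    target_len_range: tuple[int, int]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lid = self.locus_id
        if not lid:
            raise PanelError("locus_id must be non-empty")
        for name in ("forward_primer", "reverse_primer"):
            seq = getattr(self, name)
            if len(seq) < 15:
                raise PanelError(f"locus {lid}: {name} shorter than 15 nt")
            bad = set(seq) - set(IUPAC_CODES)
            if bad:
                raise PanelError(f"locus {lid}: {name} has non-IUPAC characters {sorted(bad)}")
        # ambiguity codes are tolerated in primers only
        for name in ("left_flank", "right_flank", "motif"):
            seq = getattr(self, name)
            bad = set(seq) - PLAIN_BASES
            if bad:
                raise PanelError(f"locus {lid}: {name} must be plain ACGT, found {sorted(bad)}")
        if not 1 <= len(self.motif) <= 6:
            raise PanelError(f"locus {lid}: motif length must be in [1,6]")
        if not is_primitive_motif(self.motif):
            raise PanelError(f"locus {lid}: motif {self.motif!r} is not primitive")
        if self.ref_repeat_count < 1:
            raise PanelError(f"locus {lid}: ref_repeat_count must be >= 1")
        # canonical tract boundary: flanks may not silently extend the run
        if self.left_flank.endswith(self.motif):
            raise PanelError(f"locus {lid}: left_flank ends with a full motif copy")
        if self.right_flank.startswith(self.motif):
            raise PanelError(f"locus {lid}: right_flank starts with a full motif copy")
        lo, hi = self.target_len_range
        if not (1 <= lo <= hi):
            raise PanelError(f"locus {lid}: invalid target_len_range {self.target_len_range}")
        ref_len = len(self.reference_target())
        if not lo <= ref_len <= hi:
            raise PanelError(
                f"locus {lid}: reference target length {ref_len} outside range [{lo},{hi}]"
            )

    def reference_target(self) -> str:
        """The inter-primer target reconstructed at the reference repeat count."""
        return self.left_flank + self.motif * self.ref_repeat_count + self.right_flank

    def with_id(self, locus_id: str) -> "LocusDefinition":
        return replace(self, locus_id=locus_id)


@dataclass(frozen=True)
class ParameterSet:
    """Coverage thresholds steering stutter flagging and allele calling.

    ``stutter_thresholds`` maps a signed repeat-unit offset (e.g. -1 for one
    motif copy lost) to the maximum percentage of the parent sequence's
    coverage a stutter product at that offset may reach.  ``min_allele_reads``
    (m) is the minimum coverage for a sequence to be callable as an allele;
    ``min_locus_reads`` (n) is the minimum total coverage for the locus in an
    individual before any genotype is attempted.  ``het_balance_pct`` is the
    minimum percentage of the top allele's coverage required to call a second
    allele (heterozygote balance).
    """

    set_id: str
    stutter_thresholds: Mapping[int, float]
    min_allele_reads: int = 15
    min_locus_reads: int = 20
    het_balance_pct: float = 25.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stutter_thresholds", dict(self.stutter_thresholds))
        for off, pct in self.stutter_thresholds.items():
            if off == 0:
                raise PanelError("stutter threshold offset 0 is meaningless")
            if not 0 < pct <= 100:
                raise PanelError(f"stutter threshold for offset {off} must be in (0,100]")
        if self.min_allele_reads < 1 or self.min_locus_reads < 1:
            raise PanelError("min_allele_reads and min_locus_reads must be >= 1")
        if not 0 < self.het_balance_pct <= 100:
            raise PanelError("het_balance_pct must be in (0,100]")


# Default parameter sets mirroring the published stutter/allele thresholds.
DEFAULT_PARAMETER_SETS: tuple[ParameterSet, ParameterSet] = (
    ParameterSet("PS1", {-1: 50.0, +1: 10.0}, min_allele_reads=15, min_locus_reads=20),
    ParameterSet("PS2", {-1: 70.0, +1: 10.0}, min_allele_reads=10, min_locus_reads=20),
)


@dataclass(frozen=True)
class AnalysisCombo:
    """A (strategy, parameter set) pair identifying one analysis run."""

    strategy: Strategy
    parameter_set: ParameterSet

    @property
    def name(self) -> str:
        return f"{self.strategy.value}.{self.parameter_set.set_id}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def default_combos(parameter_sets: Iterable[ParameterSet] = DEFAULT_PARAMETER_SETS,
                   strategies: Iterable[Strategy] = tuple(Strategy)) -> list[AnalysisCombo]:
    """The default 2x2 grid of analysis combinations."""
    return [AnalysisCombo(s, p) for s in strategies for p in parameter_sets]


# Fixed preference order used to break full ties when choosing a best combo.
COMBO_PREFERENCE_ORDER: tuple[tuple[Strategy, str], ...] = (
    (Strategy.FULL_LENGTH, "PS1"),
    (Strategy.FULL_LENGTH, "PS2"),
    (Strategy.REPEAT_FOCUSED, "PS1"),
    (Strategy.REPEAT_FOCUSED, "PS2"),
)


PANEL_COLUMNS = (
    "locus_id", "forward_primer", "reverse_primer", "left_flank",
    "right_flank", "motif", "ref_repeat_count", "min_len", "max_len",
)


def load_panel(path: str | Path) -> list[LocusDefinition]:
    """Read a tab-separated panel file into validated locus definitions.

    The file has a header and one locus per row (columns ``locus_id,
    forward_primer, reverse_primer, left_flank, right_flank, motif,
    ref_repeat_count, min_len, max_len``).  Loci are returned in file order;
    duplicate ``locus_id`` values are rejected.
    """
    path = Path(path)
    loci: list[LocusDefinition] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(PANEL_COLUMNS):
            raise PanelError(
                f"{path}: bad header {header!r}; expected {list(PANEL_COLUMNS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(PANEL_COLUMNS):
                raise PanelError(
                    f"{path}:{lineno}: expected {len(PANEL_COLUMNS)} fields, got {len(fields)}"
                )
            row = dict(zip(PANEL_COLUMNS, fields))
            try:
                ref_count = int(row["ref_repeat_count"])
                lo, hi = int(row["min_len"]), int(row["max_len"])
            except ValueError as exc:
                raise PanelError(f"{path}:{lineno}: non-integer numeric field ({exc})") from None
            if row["locus_id"] in seen:
                raise PanelError(f"{path}:{lineno}: duplicate locus_id {row['locus_id']!r}")
            seen.add(row["locus_id"])
            try:
                locus = LocusDefinition(
                    locus_id=row["locus_id"],
                    forward_primer=row["forward_primer"].upper(),
                    reverse_primer=row["reverse_primer"].upper(),
                    left_flank=row["left_flank"].upper(),
                    right_flank=row["right_flank"].upper(),
                    motif=row["motif"].upper(),
                    ref_repeat_count=ref_count,
                    target_len_range=(lo, hi),
                )
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from None
            loci.append(locus)
    if not loci:
        raise PanelError(f"{path}: empty panel")
    return loci


def write_panel(loci: Iterable[LocusDefinition], path: str | Path) -> None:
    """Write loci to a tab-separated panel file (inverse of :func:`load_panel`)."""
    with open(path, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for loc in loci:
            lo, hi = loc.target_len_range
            fh.write("\t".join([
                loc.locus_id, loc.forward_primer, loc.reverse_primer,
                loc.left_flank, loc.right_flank, loc.motif,
                str(loc.ref_repeat_count), str(lo), str(hi),
            ]) + "\n")


def effective_anchors(locus: LocusDefinition, strategy: Strategy) -> tuple[str, str]:
    """Anchor pair used to locate a locus inside a read under *strategy*.

    Extraction between the returned anchors yields the inter-primer target
    (``FULL_LENGTH``) or the repeat-tract region (``REPEAT_FOCUSED``, where
    the flanks are folded into the anchors so flank polymorphism is absorbed
    by the mismatch allowance).
    """
    rc_rev = reverse_complement(locus.reverse_primer)
    if strategy is Strategy.FULL_LENGTH:
        return locus.forward_primer, rc_rev
    return locus.forward_primer + locus.left_flank, locus.right_flank + rc_rev
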