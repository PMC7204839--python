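"""Read ingestion: FASTQ I/O, sample sheets, length filtering, panel sorting.

Inputs are merged (or single-end) amplicon reads, demultiplexed to one FASTQ
per sample.  Quality scores are carried through untouched; the pipeline
filters only on read length and primer identity.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadRecord",
    "SampleSheet",
    "SampleEntry",
    "read_fastq",
    "write_fastq",
    "filter_reads",
    "split_by_panel",
]

DEFAULT_MIN_READ_LEN = 70


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read; quality is optional and never interpreted."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SampleEntry:
    fastq_path: str
    individual_id: str
    replicate_group_id: str


class SampleSheet:
    """Maps FASTQ files to individuals and blind-replicate groups.

    Blind repeats of one biological individual are separate samples sharing
    a ``replicate_group_id``; they are what the replicate-based error-rate
    estimate compares.
    """

    def __init__(self, entries: Iterable[SampleEntry]):
        self.entries: list[SampleEntry] = list(entries)
        paths = [e.fastq_path for e in self.entries]
        if len(set(paths)) != len(paths):
            raise ValueError("sample sheet: duplicate fastq_path entries")
        ids = [e.individual_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample sheet: duplicate individual_id entries")

    @classmethod
    def load(cls, path: str | Path) -> "SampleSheet":
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["fastq_path", "individual_id", "replicate_group_id"]
            if header != expected:
                raise ValueError(f"{path}: bad sample sheet header {header!r}")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 fields")
                entries.append(SampleEntry(*fields))
        return cls(entries)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("fastq_path\tindividual_id\treplicate_group_id\n")
            for e in self.entries:
                fh.write(f"{e.fastq_path}\t{e.individual_id}\t{e.replicate_group_id}\n")

    @property
    def individuals(self) -> list[str]:
        return [e.individual_id for e in self.entries]

    def replicate_groups(self) -> dict[str, list[str]]:
        """replicate_group_id -> individual ids, file order preserved."""
        groups: dict[str, list[str]] = {}
        for e in self.entries:
            groups.setdefault(e.replicate_group_id, []).append(e.individual_id)
        return groups

    def __len__(self) -> int:
        return len(self.entries)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream reads from a FASTQ file (plain or gzip)."""
    with _open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield ReadRecord(title.split()[0], seq.upper(), qual)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def filter_reads(reads: Iterable[ReadRecord],
                 min_len: int = DEFAULT_MIN_READ_LEN) -> tuple[list[ReadRecord], int]:
    """Drop reads shorter than *min_len* (a read of exactly *min_len* is kept).

    Returns the kept reads in input order and the number removed.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept: list[ReadRecord] = []
    n_removed = 0
    for r in reads:
        if len(r.sequence) >= min_len:
            kept.append(r)
        else:
            n_removed += 1
    return kept, n_removed


def _hamming_within(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def _matches_primer_prefix(seq: str, primer: str, max_mismatch: int, window_slack: int = 5) -> bool:
    """True if *primer* occurs within the first ``len(primer)+window_slack``
    bases of *seq* with at most *max_mismatch* substitutions (no indels)."""
    plen = len(primer)
    limit = min(len(seq) - plen, window_slack)
    if limit < 0:
        return False
    for start in range(limit + 1):
        if _hamming_within(seq[start:start + plen], primer, max_mismatch):
            return True
    return False


def split_by_panel(reads: Iterable[ReadRecord],
                   panels: dict[str, list[str]],
                   max_mismatch: int = 1) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord]]:
    """Sort pooled reads among species/panel groups by forward-primer match.

    A read is assigned to a panel when one of the panel's forward primers
    occurs near the read start (substitutions only, ``max_mismatch``
    allowed).  Reads matching primers of more than one panel are routed to
    ``unassigned`` rather than duplicated, so no read can be genotyped twice.
    """
    if not panels:
        raise ValueError("at least one panel is required")
    for pid, primers in panels.items():
        if not primers or any(not p for p in primers):
            raise ValueError(f"panel {pid!r} has an empty primer list or primer")
    assigned: dict[str, list[ReadRecord]] = {pid: [] for pid in panels}
    unassigned: list[ReadRecord] = []
    for r in reads:
        hits = [pid for pid, primers in panels.items()
                if any(_matches_primer_prefix(r.sequence, p, max_mismatch) for p in primers)]
        if len(hits) == 1:
            assigned[hits[0]].append(r)
        else:
            unassigned.append(r)
    return assigned, unassigned
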