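"""Read records and FASTQ/FASTA input/output.

Reads carry their per-base Phred qualities and sample/run provenance through
the whole quality-control chain; FASTQ is Phred+33 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .errors import InputError


@dataclass(frozen=True)
class SequenceRead:
    """One mate of a paired-end read."""

    read_id: str
    bases: str
    quals: tuple[int, ...]
    mate: str = "forward"  # "forward" | "reverse"
    sample_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise InputError(
                f"read {self.read_id}: {len(self.bases)} bases vs {len(self.quals)} quals"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def truncated(self, end: int) -> "SequenceRead":
        return replace(self, bases=self.bases[:end], quals=self.quals[:end])


@dataclass(frozen=True)
class MergedRead:
    """Overlap-merged read pair with consensus qualities."""

    bases: str
    quals: tuple[int, ...]
    sample_id: str = ""
    run_id: str = ""
    serial: int = 0

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_quality(self) -> float:
        return sum(self.quals) / len(self.quals)


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ; returns the record count."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.quals) + "\n")
            n += 1
    return n


def read_fastq(path: str | Path, *, mate: str = "forward",
               sample_id: str = "", run_id: str = "") -> Iterator[SequenceRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield SequenceRead(
            read_id=rec.id,
            bases=str(rec.seq).upper(),
            quals=tuple(rec.letter_annotations["phred_quality"]),
            mate=mate,
            sample_id=sample_id,
            run_id=run_id,
        )


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path, *,
                     sample_id: str = "", run_id: str = ""
                     ) -> Iterator[tuple[SequenceRead, SequenceRead]]:
    """Iterate mate pairs from parallel R1/R2 files; lengths must agree."""
    it1 = read_fastq(r1_path, mate="forward", sample_id=sample_id, run_id=run_id)
    it2 = read_fastq(r2_path, mate="reverse", sample_id=sample_id, run_id=run_id)
    sentinel = object()
    from itertools import zip_longest

    for r1, r2 in zip_longest(it1, it2, fillvalue=sentinel):
        if r1 is sentinel or r2 is sentinel:
            raise InputError(f"unequal record counts in {r1_path} / {r2_path}")
        yield r1, r2


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write (header, sequence) pairs as FASTA; returns the record count."""
    n = 0
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.description, str(rec.seq).upper()
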