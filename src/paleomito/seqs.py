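"""Shared sequence primitives: reads, circular-genome helpers, FASTA/FASTQ I/O."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA = "ACGT"
_COMP = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")

MISSING_CHARS = frozenset("N-")


def revcomp(seq: str) -> str:
    """Reverse complement (N and gap characters pass through)."""
    return seq.translate(_COMP)[::-1]


def circular_substring(genome: str, start: int, length: int) -> str:
    """Extract ``length`` bases starting at ``start`` on a circular sequence.

    ``start`` is taken modulo ``len(genome)``; the substring wraps past the
    origin if necessary.  ``length`` must not exceed the genome length.
    """
    n = len(genome)
    if length > n:
        raise ValueError(f"fragment length {length} exceeds genome length {n}")
    start %= n
    end = start + length
    if end <= n:
        return genome[start:end]
    return genome[start:] + genome[: end - n]


@dataclasses.dataclass
class QualityRead:
    """A sequencing read with per-base Phred qualities and a provenance label."""

    read_id: str
    seq: str
    quals: np.ndarray  # integer Phred values, same length as seq
    source: str = ""

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.quals) != len(self.seq):
            raise ValueError("qualities and bases differ in length")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def mean_quality(self) -> float:
        return float(self.quals.mean()) if len(self.quals) else 0.0

    def to_seqrecord(self) -> SeqRecord:
        rec = SeqRecord(Seq(self.seq), id=self.read_id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in self.quals]
        return rec

    @classmethod
    def from_seqrecord(cls, rec: SeqRecord) -> "QualityRead":
        return cls(
            read_id=rec.id,
            seq=str(rec.seq).upper(),
            quals=np.asarray(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[QualityRead], path: str | Path) -> int:
    return SeqIO.write((r.to_seqrecord() for r in reads), str(path), "fastq")


def read_fastq(path: str | Path) -> Iterator[QualityRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield QualityRead.from_seqrecord(rec)


def write_fasta(seqs: dict[str, str], path: str | Path) -> int:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    return SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def random_genome(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(DNA), size=length))


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T); missing characters excluded from the denominator."""
    gc = sum(seq.count(b) for b in "GCgc")
    acgt = sum(seq.count(b) for b in "ACGTacgt")
    if acgt == 0:
        raise ValueError("sequence contains no determined bases")
    return gc / acgt
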