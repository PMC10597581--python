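"""Seeded read mapping to small circular references, deduplication, pileups.

The mapper is deliberately simple: exact k-mer seeding on both strands against
the reference linearized with a wrap pad, followed by ungapped evaluation of
every candidate placement.  It is meant for mitogenome-sized references where
exhaustive candidate evaluation is cheap.  Gapped alignments (I/D operations)
enter the system only through SAM import.

Stringency proxy: instead of a mapping-quality model, placements are retained
only when they are the unique best scoring placement (margin >=
``min_score_gap``) and their mismatch fraction is at most
``max_mismatch_frac``.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqs import QualityRead, circular_substring, revcomp

__all__ = [
    "MapParams",
    "MappedRead",
    "Pileup",
    "ReferenceIndex",
    "map_read",
    "map_reads",
    "select_best_reference",
    "BestReferenceResult",
    "deduplicate",
    "DuplicationStats",
    "make_pileup",
]

_BASE_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}
_DEL_ROW = 4


@dataclasses.dataclass
class MapParams:
    k: int = 13
    max_mismatch_frac: float = 0.1
    band: int = 0  # reserved; the native aligner is ungapped
    min_score_gap: int = 1
    max_read_len: int = 150

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError("seed length k must be >= 11")


@dataclasses.dataclass
class MappedRead:
    """A read placed on a (circular) reference, stored reference-oriented."""

    read_id: str
    ref_id: str
    ref_start: int  # 0-based, in [0, ref_length)
    strand: str  # "+" or "-"
    cigar: tuple[tuple[str, int], ...]  # ops over M/I/D
    seq: str  # read bases in reference orientation
    quals: np.ndarray  # per-base quals, reference orientation
    ref_length: int
    edit_distance: int
    score: int = 0
    unique_best: bool = True

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def ref_end(self) -> int:
        """Exclusive end; may exceed ref_length when the read wraps the origin."""
        return self.ref_start + self.ref_span

    @property
    def wraps(self) -> bool:
        return self.ref_end > self.ref_length

    def columns(self):
        """Yield (ref_pos mod L, op, read_base, read_index) per alignment column.

        Insertions yield ref_pos of the next reference column and consume read
        bases; deletions consume reference positions only.
        """
        rpos = self.ref_start
        qpos = 0
        for op, n in self.cigar:
            if op == "M":
                for _ in range(n):
                    yield rpos % self.ref_length, "M", self.seq[qpos], qpos
                    rpos += 1
                    qpos += 1
            elif op == "I":
                for _ in range(n):
                    yield rpos % self.ref_length, "I", self.seq[qpos], qpos
                    qpos += 1
            elif op == "D":
                for _ in range(n):
                    yield rpos % self.ref_length, "D", None, None
                    rpos += 1
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")

    def read_oriented(self, reference: str) -> tuple[list[str | None], list[str | None]]:
        """(ref_bases, read_bases) column lists in read orientation (5'->3' as
        sequenced); reverse-strand alignments are complemented and flipped."""
        ref_bases: list[str | None] = []
        read_bases: list[str | None] = []
        for rpos, op, base, _ in self.columns():
            ref_bases.append(reference[rpos] if op in "MD" else None)
            read_bases.append(base)
        if self.strand == "-":
            comp = str.maketrans("ACGTN", "TGCAN")
            ref_bases = [b.translate(comp) if b else None for b in reversed(ref_bases)]
            read_bases = [b.translate(comp) if b else None for b in reversed(read_bases)]
        return ref_bases, read_bases


class ReferenceIndex:
    """Exact k-mer index over a circular reference linearized with a wrap pad."""

    def __init__(self, ref_id: str, sequence: str, params: MapParams | None = None):
        self.params = params or MapParams()
        self.ref_id = ref_id
        self.sequence = sequence.upper()
        self.length = len(self.sequence)
        pad = min(self.params.max_read_len - 1, self.length)
        self._padded = self.sequence + self.sequence[:pad]
        k = self.params.k
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(self._padded) - k + 1):
            index[self._padded[i : i + k]].append(i)
        self._index = dict(index)

    def seed_hits(self, kmer: str) -> list[int]:
        return self._index.get(kmer, [])


def _candidate_starts(oriented: str, index: ReferenceIndex) -> set[int]:
    k = index.params.k
    n = len(oriented)
    offsets = list(range(0, n - k + 1, k))
    if offsets[-1] != n - k:
        offsets.append(n - k)
    starts: set[int] = set()
    for off in offsets:
        for hit in index.seed_hits(oriented[off : off + k]):
            starts.add((hit - off) % index.length)
    return starts


def map_read(
    read: QualityRead, index: ReferenceIndex, params: MapParams | None = None
) -> MappedRead | None:
    """Map one read; returns ``None`` when unmapped.

    Both strands are seeded; every candidate placement is scored ungapped
    (score = matches - mismatches).  The best placement is returned with
    ``unique_best`` false when a distinct runner-up placement scores within
    ``min_score_gap`` of the best.  Placements whose mismatch fraction exceeds
    ``max_mismatch_frac`` are rejected.
    """
    params = params or index.params
    n = len(read)
    if n < params.k or n > index.length:
        return None
    ref = index.sequence
    placements: list[tuple[int, str, int, int]] = []  # (score, strand, start, mm)
    for strand, oriented in (("+", read.seq), ("-", revcomp(read.seq))):
        for start in _candidate_starts(oriented, index):
            ref_sub = circular_substring(ref, start, n)
            mm = sum(a != b for a, b in zip(oriented, ref_sub))
            placements.append((n - 2 * mm, strand, start, mm))
    if not placements:
        return None
    placements.sort(key=lambda p: (-p[0], p[1], p[2]))
    score, strand, start, mm = placements[0]
    if mm / n > params.max_mismatch_frac:
        return None
    unique = True
    if len(placements) > 1 and placements[0][0] - placements[1][0] < params.min_score_gap:
        unique = False
    if strand == "+":
        seq, quals = read.seq, read.quals
    else:
        seq, quals = revcomp(read.seq), read.quals[::-1]
    return MappedRead(
        read_id=read.read_id,
        ref_id=index.ref_id,
        ref_start=start,
        strand=strand,
        cigar=(("M", n),),
        seq=seq,
        quals=np.asarray(quals),
        ref_length=index.length,
        edit_distance=mm,
        score=score,
        unique_best=unique,
    )


def map_reads(
    reads: Iterable[QualityRead],
    index: ReferenceIndex,
    params: MapParams | None = None,
    retain_unique_only: bool = True,
) -> list[MappedRead]:
    out = []
    for read in reads:
        m = map_read(read, index, params)
        if m is not None and (m.unique_best or not retain_unique_only):
            out.append(m)
    return out


@dataclasses.dataclass
class BestReferenceResult:
    best_ref: str
    table: pd.DataFrame  # ref_id, n_mapped, n_retained, sum_edit_distance
    mapped: dict[str, list[MappedRead]]  # retained reads per reference
    tie: bool


def select_best_reference(
    reads: Sequence[QualityRead],
    references: dict[str, str],
    params: MapParams | None = None,
) -> BestReferenceResult:
    """Map the read set independently against every candidate reference.

    The best reference is the one retaining the most reads (unique-best,
    mismatch-filtered); ties are broken by the lower summed edit distance,
    then lexicographically by reference id (reported via ``tie``).
    """
    if len(references) < 2:
        raise ValueError("need at least two candidate references")
    params = params or MapParams()
    rows = []
    retained: dict[str, list[MappedRead]] = {}
    for ref_id in sorted(references):
        index = ReferenceIndex(ref_id, references[ref_id], params)
        mapped_all = [m for m in (map_read(r, index, params) for r in reads) if m]
        kept = [m for m in mapped_all if m.unique_best]
        retained[ref_id] = kept
        rows.append(
            {
                "ref_id": ref_id,
                "n_mapped": len(mapped_all),
                "n_retained": len(kept),
                "sum_edit_distance": sum(m.edit_distance for m in kept),
            }
        )
    table = pd.DataFrame(rows)
    if table["n_retained"].sum() == 0:
        raise ValueError("no reference compatible: zero mapped reads everywhere")
    ranked = table.sort_values(
        by=["n_retained", "sum_edit_distance", "ref_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    tie = bool(
        len(ranked) > 1
        and ranked.loc[0, "n_retained"] == ranked.loc[1, "n_retained"]
        and ranked.loc[0, "sum_edit_distance"] == ranked.loc[1, "sum_edit_distance"]
    )
    best = str(ranked.loc[0, "ref_id"])
    return BestReferenceResult(best_ref=best, table=table, mapped=retained, tie=tie)


@dataclasses.dataclass
class DuplicationStats:
    n_in: int
    n_retained: int

    @property
    def duplication_level(self) -> float:
        return 1 - self.n_retained / self.n_in if self.n_in else 0.0


def deduplicate(
    mapped: Sequence[MappedRead],
) -> tuple[list[MappedRead], DuplicationStats]:
    """Coordinate-based duplicate removal.

    Duplicate key is (ref_id, ref_start, ref_end, strand); the representative
    kept per key is the read with the highest summed base quality (ties by
    read id).  Output preserves first-occurrence order of keys.
    """
    best: dict[tuple, MappedRead] = {}
    order: list[tuple] = []
    for m in mapped:
        key = (m.ref_id, m.ref_start, m.ref_end, m.strand)
        cur = best.get(key)
        if cur is None:
            best[key] = m
            order.append(key)
        else:
            m_q, c_q = int(m.quals.sum()), int(cur.quals.sum())
            # higher summed quality wins; on equal quality the smaller read_id wins
            if m_q > c_q or (m_q == c_q and m.read_id < cur.read_id):
                best[key] = m
    kept = [best[k] for k in order]
    return kept, DuplicationStats(n_in=len(mapped), n_retained=len(kept))


class Pileup:
    """Per-position A/C/G/T/deletion counts over a reference."""

    def __init__(self, ref_length: int, ref_id: str = ""):
        self.ref_id = ref_id
        self.length = ref_length
        self.counts = np.zeros((5, ref_length), dtype=np.int64)

    @property
    def depth(self) -> np.ndarray:
        """Per-position read-base depth (deletions excluded)."""
        return self.counts[:4].sum(axis=0)

    def base_counts(self, pos: int) -> dict[str, int]:
        if not 0 <= pos < self.length:
            raise IndexError(f"position {pos} outside [0, {self.length})")
        col = self.counts[:, pos]
        return {"A": int(col[0]), "C": int(col[1]), "G": int(col[2]), "T": int(col[3])}

    def deletion_count(self, pos: int) -> int:
        return int(self.counts[_DEL_ROW, pos])

    def add(self, read: MappedRead) -> None:
        for rpos, op, base, _ in read.columns():
            if not 0 <= rpos < self.length:
                raise ValueError(f"reference position {rpos} out of range")
            if op == "M":
                row = _BASE_ROW.get(base)
                if row is not None:  # ambiguous read bases are not counted
                    self.counts[row, rpos] += 1
            elif op == "D":
                self.counts[_DEL_ROW, rpos] += 1
            # insertions do not consume reference positions


def make_pileup(mapped: Sequence[MappedRead], ref_length: int) -> Pileup:
    """Build a pileup; all reads must be on the same reference."""
    refs = {m.ref_id for m in mapped}
    if len(refs) > 1:
        raise ValueError(f"reads span multiple references: {sorted(refs)}")
    pileup = Pileup(ref_length, ref_id=next(iter(refs)) if refs else "")
    for m in mapped:
        pileup.add(m)
    return pileup
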