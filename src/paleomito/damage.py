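"""Terminal misincorporation and indel frequency profiles from mapped reads.

For read offsets 0..n-1 from the 5' end and, separately, from the 3' end, the
profile records the conditional frequency of each of the 12 substitution types
(reference base -> read base): numerator = reads showing that substitution at
the offset, denominator = reads whose reference base at the offset is the
source base.  Offsets are counted in read orientation — reverse-strand
alignments are complemented and flipped first, so the deamination signatures
line up as 5' C->T and 3' G->A.

Insertion/deletion frequencies use the number of reads covering the offset as
denominator.  Deletions (which consume no read base) are attributed to the
read offset at which the alignment resumes.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mapping import MappedRead

__all__ = ["DamageProfile", "damage_profile", "SUBSTITUTION_TYPES"]

_BASES = "ACGT"
SUBSTITUTION_TYPES = [
    (a, b) for a, b in itertools.product(_BASES, _BASES) if a != b
]
_ENDS = ("5p", "3p")


@dataclasses.dataclass
class DamageProfile:
    n_positions: int
    # per end: {(ref, read): counts[offset]} and {ref: opportunities[offset]}
    sub_counts: dict[str, dict[tuple[str, str], np.ndarray]]
    base_opportunities: dict[str, dict[str, np.ndarray]]
    ins_counts: dict[str, np.ndarray]
    del_counts: dict[str, np.ndarray]
    reads_covering: dict[str, np.ndarray]
    n_reads: int

    def frequency(self, end: str, ref_base: str, read_base: str) -> np.ndarray:
        """Conditional substitution frequency by offset; 0 where no opportunity."""
        num = self.sub_counts[end][(ref_base, read_base)]
        den = self.base_opportunities[end][ref_base]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / np.maximum(den, 1), 0.0)
        return out

    def indel_frequency(self, end: str, which: str) -> np.ndarray:
        num = self.ins_counts[end] if which == "insertion" else self.del_counts[end]
        den = self.reads_covering[end]
        return np.where(den > 0, num / np.maximum(den, 1), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for end in _ENDS:
            for (a, b) in SUBSTITUTION_TYPES:
                freq = self.frequency(end, a, b)
                for off in range(self.n_positions):
                    rows.append(
                        {
                            "end": end,
                            "offset": off,
                            "type": f"{a}>{b}",
                            "count": int(self.sub_counts[end][(a, b)][off]),
                            "opportunities": int(self.base_opportunities[end][a][off]),
                            "frequency": float(freq[off]),
                        }
                    )
            for which, counts in (
                ("insertion", self.ins_counts[end]),
                ("deletion", self.del_counts[end]),
            ):
                freq = self.indel_frequency(end, which)
                for off in range(self.n_positions):
                    rows.append(
                        {
                            "end": end,
                            "offset": off,
                            "type": which,
                            "count": int(counts[off]),
                            "opportunities": int(self.reads_covering[end][off]),
                            "frequency": float(freq[off]),
                        }
                    )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def damage_profile(
    mapped: Sequence[MappedRead], reference: str, n_positions: int = 25
) -> DamageProfile:
    """Compute terminal substitution/indel profiles over the first/last
    ``n_positions`` read positions.

    Reads shorter than ``n_positions`` contribute only their covered offsets.
    """
    if not mapped:
        raise ValueError("empty alignment")
    zeros = lambda: np.zeros(n_positions, dtype=np.int64)
    sub_counts = {e: {t: zeros() for t in SUBSTITUTION_TYPES} for e in _ENDS}
    opps = {e: {b: zeros() for b in _BASES} for e in _ENDS}
    ins_counts = {e: zeros() for e in _ENDS}
    del_counts = {e: zeros() for e in _ENDS}
    covering = {e: zeros() for e in _ENDS}

    for m in mapped:
        ref_bases, read_bases = m.read_oriented(reference)
        read_len = sum(1 for b in read_bases if b is not None)
        cov = min(read_len, n_positions)
        for e in _ENDS:
            covering[e][:cov] += 1
        qpos = 0  # read coordinate of the current column
        for rb, qb in zip(ref_bases, read_bases):
            off5 = qpos
            off3 = read_len - 1 - qpos if qpos < read_len else None
            if qb is None:  # deletion: attribute to the resuming read offset
                if rb in _BASES:
                    if off5 < n_positions:
                        del_counts["5p"][off5] += 1
                    if off3 is not None and off3 < n_positions:
                        del_counts["3p"][off3] += 1
                continue
            if rb is None:  # insertion
                if off5 < n_positions:
                    ins_counts["5p"][off5] += 1
                if off3 is not None and off3 < n_positions:
                    ins_counts["3p"][off3] += 1
            else:
                for end, off in (("5p", off5), ("3p", off3)):
                    if off is None or off >= n_positions:
                        continue
                    if rb in _BASES:
                        opps[end][rb][off] += 1
                        if qb != rb and qb in _BASES:
                            sub_counts[end][(rb, qb)][off] += 1
            qpos += 1

    return DamageProfile(
        n_positions=n_positions,
        sub_counts=sub_counts,
        base_opportunities=opps,
        ins_counts=ins_counts,
        del_counts=del_counts,
        reads_covering=covering,
        n_reads=len(mapped),
    )
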