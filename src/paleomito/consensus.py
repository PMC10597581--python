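"""Consensus calling with minimum-depth masking, coverage statistics, retention QC."""

from __future__ import annotations

import dataclasses

import numpy as np

from .mapping import Pileup
from .seqs import gc_fraction

__all__ = ["CoverageStats", "ConsensusResult", "call_consensus", "qc_retain", "gc_content"]

_ROWS = "ACGT"


@dataclasses.dataclass
class CoverageStats:
    mean_depth: float
    breadth: dict[int, float]  # k -> fraction of positions with depth >= k
    undetermined_fraction: float

    def breadth_at(self, k: int) -> float:
        return self.breadth[k]


@dataclasses.dataclass
class ConsensusResult:
    sequence: str  # over {A,C,G,T,N}, same length as the reference
    depth: np.ndarray
    stats: CoverageStats
    retained: bool = True
    reasons: list[str] = dataclasses.field(default_factory=list)


def call_consensus(pileup: Pileup, min_depth: int = 2) -> ConsensusResult:
    """Majority-base consensus.

    Per position: the base with the highest count; undetermined (N) when the
    read depth is below ``min_depth`` or the top count is tied.
    """
    depth = pileup.depth
    counts = pileup.counts[:4]
    top = counts.max(axis=0)
    argmax = counts.argmax(axis=0)
    tied = (counts == top).sum(axis=0) > 1
    bases = np.array(list(_ROWS))[argmax]
    masked = (depth < min_depth) | tied
    bases[masked] = "N"
    seq = "".join(bases)
    n = pileup.length
    stats = CoverageStats(
        mean_depth=float(depth.sum() / n),
        breadth={k: float((depth >= k).mean()) for k in (1, 2, 3)},
        undetermined_fraction=seq.count("N") / n,
    )
    return ConsensusResult(sequence=seq, depth=depth, stats=stats)


def qc_retain(
    consensus: ConsensusResult, breadth3_min: float = 0.80
) -> tuple[bool, list[str]]:
    """Retention gate: at least ``breadth3_min`` of positions covered at 3x.

    Updates ``consensus.retained``/``reasons`` in place and returns them.
    """
    reasons = []
    if consensus.stats.breadth_at(3) < breadth3_min:
        reasons.append("breadth3")
    consensus.retained = not reasons
    consensus.reasons = reasons
    return consensus.retained, reasons


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T), Ns excluded; errors on all-N input."""
    return gc_fraction(sequence)
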