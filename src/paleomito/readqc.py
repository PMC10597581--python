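"""Quality trimming and read filtering.

Implements the classic single-end trimming steps — LEADING, TRAILING,
SLIDINGWINDOW, MINLEN, AVGQUAL — applied in a configurable order.  The default
order is MINLEN, SLIDINGWINDOW, LEADING, TRAILING, AVGQUAL.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .seqs import QualityRead

__all__ = ["TrimConfig", "TrimStats", "trim_read", "trim_set", "DEFAULT_STEP_ORDER"]

DEFAULT_STEP_ORDER = ("MINLEN", "SLIDINGWINDOW", "LEADING", "TRAILING", "AVGQUAL")
_KNOWN_STEPS = frozenset(DEFAULT_STEP_ORDER)


@dataclasses.dataclass
class TrimConfig:
    leading_q: int = 20
    trailing_q: int = 20
    window_len: int = 4
    window_q: float = 20.0
    min_len: int = 30
    min_avg_q: float = 30.0
    step_order: Sequence[str] = DEFAULT_STEP_ORDER

    def __post_init__(self) -> None:
        unknown = set(self.step_order) - _KNOWN_STEPS
        if unknown:
            raise ValueError(f"unknown trimming steps: {sorted(unknown)}")


@dataclasses.dataclass
class TrimStats:
    n_in: int
    n_kept: int
    bases_in: int
    bases_kept: int
    discarded_by_step: dict[str, int]

    @property
    def survival_fraction(self) -> float:
        return self.n_kept / self.n_in if self.n_in else 1.0


def _leading(seq: str, quals: np.ndarray, cfg: TrimConfig):
    i = 0
    while i < len(quals) and quals[i] < cfg.leading_q:
        i += 1
    return seq[i:], quals[i:]


def _trailing(seq: str, quals: np.ndarray, cfg: TrimConfig):
    j = len(quals)
    while j > 0 and quals[j - 1] < cfg.trailing_q:
        j -= 1
    return seq[:j], quals[:j]


def _sliding_window(seq: str, quals: np.ndarray, cfg: TrimConfig):
    w = cfg.window_len
    n = len(quals)
    if n < w:
        return seq, quals
    # scan 5'->3'; truncate at the start of the first window whose mean < threshold
    cumsum = np.concatenate(([0], np.cumsum(quals)))
    for start in range(n - w + 1):
        mean = (cumsum[start + w] - cumsum[start]) / w
        if mean < cfg.window_q:
            return seq[:start], quals[:start]
    return seq, quals


def _apply_steps(
    read: QualityRead, cfg: TrimConfig
) -> tuple[QualityRead | None, str | None]:
    """Run the configured steps; returns (trimmed read, None) or (None, step)."""
    seq, quals = read.seq, read.quals
    for step in cfg.step_order:
        if step == "MINLEN":
            if len(seq) < cfg.min_len:
                return None, "MINLEN"
        elif step == "SLIDINGWINDOW":
            seq, quals = _sliding_window(seq, quals, cfg)
        elif step == "LEADING":
            seq, quals = _leading(seq, quals, cfg)
        elif step == "TRAILING":
            seq, quals = _trailing(seq, quals, cfg)
        elif step == "AVGQUAL":
            if len(quals) == 0 or quals.mean() < cfg.min_avg_q:
                return None, "AVGQUAL"
        if len(seq) == 0:
            return None, step
    out = QualityRead(read_id=read.read_id, seq=seq, quals=quals, source=read.source)
    return out, None


def trim_read(read: QualityRead, cfg: TrimConfig) -> QualityRead | None:
    """Trim one read; returns the trimmed read or ``None`` (discard).

    The surviving read is always a contiguous substring of the input.  An
    empty input read yields a discard signal, not an error.
    """
    out, _ = _apply_steps(read, cfg)
    return out


def trim_set(
    reads: Iterable[QualityRead], cfg: TrimConfig | None = None
) -> tuple[list[QualityRead], TrimStats]:
    """Trim a read set, preserving input order among survivors."""
    cfg = cfg or TrimConfig()
    kept: list[QualityRead] = []
    n_in = bases_in = bases_kept = 0
    discarded: dict[str, int] = {}
    for read in reads:
        n_in += 1
        bases_in += len(read)
        out, step = _apply_steps(read, cfg)
        if out is None:
            discarded[step] = discarded.get(step, 0) + 1
        else:
            kept.append(out)
            bases_kept += len(out)
    return kept, TrimStats(
        n_in=n_in,
        n_kept=len(kept),
        bases_in=bases_in,
        bases_kept=bases_kept,
        discarded_by_step=discarded,
    )
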