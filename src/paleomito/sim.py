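"""Synthetic ancient-DNA generator with complete ground truth.

Produces (a) multi-clade mitogenome panels with planted inter-clade fixed
differences, and (b) single-end reads from a circular genome with terminal
deamination-like damage (C->T at the 5' end, G->A at the 3' end, geometrically
decaying into the read), uniform sequencing error, exact PCR-style duplicates,
and optional contaminant admixture.  Every stochastic event is recorded in a
``SimTruth`` table so downstream estimators can be checked against known truth.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostics import CladePanel
from .seqs import DNA, QualityRead, circular_substring, random_genome, revcomp

__all__ = [
    "PanelConfig",
    "ReadSimParams",
    "ReadTruth",
    "SimTruth",
    "simulate_panel",
    "simulate_reads",
    "mix_contamination",
]

_SPECIES_POOL = ["P. hamadryas", "P. anubis", "P. cynocephalus", "P. papio"]


@dataclasses.dataclass
class PanelConfig:
    """Configuration for a synthetic aligned mitogenome panel."""

    n_clades: int = 3
    samples_per_clade: int = 5
    genome_length: int = 2000
    planted_fixed_diffs_per_clade: int = 10
    intra_clade_mut_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clades < 2:
            raise ValueError("need at least two clades")
        if self.samples_per_clade < 1:
            raise ValueError("need at least one sample per clade")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if not 0 <= self.intra_clade_mut_rate < 0.05:
            raise ValueError("intra_clade_mut_rate must be in [0, 0.05)")
        if self.n_clades * self.planted_fixed_diffs_per_clade > self.genome_length:
            raise ValueError("planted positions exceed genome length")


@dataclasses.dataclass
class ReadSimParams:
    """Parameters of the single-end ancient-read simulator.

    Damage probability at read offset ``i`` is ``d5 * lambda_decay**i`` for
    5' C->T and ``d3 * lambda_decay**i`` for 3' G->A (offset counted from the
    3' end).  Damage is applied before sequencing error.  Fragment lengths are
    log-normal, truncated to ``[min_len, max_len]``.
    """

    n_fragments: int = 1000
    frag_len_mean: float = 60.0
    frag_len_sd: float = 15.0
    min_len: int = 30
    max_len: int = 150
    d5: float = 0.0
    d3: float = 0.0
    lambda_decay: float = 0.5
    seq_error: float = 0.0
    dup_rate: float = 0.0
    qual_high: int = 37
    qual_low: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")
        if not (0 <= self.d5 <= 0.2 and 0 <= self.d3 <= 0.2):
            raise ValueError("terminal damage probabilities must be in [0, 0.2]")
        if not 0 < self.lambda_decay < 1:
            raise ValueError("lambda_decay must be in (0, 1)")
        if not 0 <= self.dup_rate < 1:
            raise ValueError("dup_rate must be in [0, 1)")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("invalid fragment length bounds")

    def lognormal_params(self) -> tuple[float, float]:
        """Method-of-moments (mu, sigma) of the underlying normal."""
        m, s = self.frag_len_mean, self.frag_len_sd
        sigma2 = math.log(1 + (s / m) ** 2)
        mu = math.log(m) - sigma2 / 2
        return mu, math.sqrt(sigma2)


@dataclasses.dataclass
class ReadTruth:
    """Ground truth for one emitted read."""

    read_id: str
    source: str
    start: int  # 0-based on the circle
    end: int  # exclusive; stored modulo genome length
    wrap: bool
    strand: str
    length: int
    damage_positions: tuple[int, ...]  # read coordinates (5'->3' as sequenced)
    error_positions: tuple[int, ...]
    dup_group: int
    is_duplicate: bool


@dataclasses.dataclass
class SimTruth:
    """Complete provenance of a simulated read set."""

    reads: dict[str, ReadTruth]
    genome_length: int
    params: dict

    def __post_init__(self) -> None:
        if len({t.read_id for t in self.reads.values()}) != len(self.reads):
            raise ValueError("duplicate read ids in truth")

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(t) for t in self.reads.values()]
        df = pd.DataFrame(rows)
        for col in ("damage_positions", "error_positions"):
            df[col] = df[col].map(lambda t: ",".join(map(str, t)))
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def merged_with(self, other: "SimTruth") -> "SimTruth":
        clash = set(self.reads) & set(other.reads)
        if clash:
            raise ValueError(f"read id collision: {sorted(clash)[:5]}")
        return SimTruth(
            reads={**self.reads, **other.reads},
            genome_length=self.genome_length,
            params={"merged": [self.params, other.params]},
        )


def simulate_panel(
    config: PanelConfig, return_truth: bool = False
) -> tuple[CladePanel, dict[str, str]] | tuple[CladePanel, dict[str, str], dict[str, list[int]]]:
    """Simulate an aligned panel plus per-clade reference mitogenomes.

    A single root sequence receives, for each clade, ``planted_fixed_diffs_per_clade``
    substitutions at clade-unique positions shared by all of the clade's
    samples; each sample additionally carries private substitutions at rate
    ``intra_clade_mut_rate``, never at planted positions.  Returns the panel
    (no indels, so alignment == sequences) and the per-clade consensus
    genomes used as mapping references; with ``return_truth`` also the planted
    positions per clade.
    """
    rng = np.random.default_rng(config.seed)
    root = random_genome(config.genome_length, rng)
    n_planted = config.n_clades * config.planted_fixed_diffs_per_clade
    planted = rng.choice(config.genome_length, size=n_planted, replace=False)
    planted_set = set(int(p) for p in planted)
    clade_names = [f"clade{i + 1}" for i in range(config.n_clades)]

    consensuses: dict[str, str] = {}
    sequences: dict[str, str] = {}
    clades: dict[str, str] = {}
    meta_rows = []
    for ci, clade in enumerate(clade_names):
        own = planted[
            ci * config.planted_fixed_diffs_per_clade : (ci + 1) * config.planted_fixed_diffs_per_clade
        ]
        cons = list(root)
        for pos in own:
            cons[pos] = _other_base(cons[pos], rng)
        consensuses[clade] = "".join(cons)
        for si in range(config.samples_per_clade):
            sample_id = f"{clade}_s{si + 1}"
            seq = list(consensuses[clade])
            if config.intra_clade_mut_rate > 0:
                hits = np.flatnonzero(
                    rng.random(config.genome_length) < config.intra_clade_mut_rate
                )
                for pos in hits:
                    if int(pos) not in planted_set:
                        seq[pos] = _other_base(seq[pos], rng)
            sequences[sample_id] = "".join(seq)
            clades[sample_id] = clade
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "species": _SPECIES_POOL[ci % len(_SPECIES_POOL)],
                    "latitude": round(10.0 + 3 * ci + 0.1 * si, 3),
                    "longitude": round(35.0 + 2 * ci + 0.1 * si, 3),
                }
            )
    panel = CladePanel(
        sequences=sequences, clades=clades, metadata=pd.DataFrame(meta_rows)
    )
    if return_truth:
        k = config.planted_fixed_diffs_per_clade
        truth = {
            clade: sorted(int(p) for p in planted[ci * k : (ci + 1) * k])
            for ci, clade in enumerate(clade_names)
        }
        return panel, consensuses, truth
    return panel, consensuses


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in DNA if b != base]
    return choices[rng.integers(len(choices))]


def _truncated_lognormal_lengths(
    params: ReadSimParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    mu, sigma = params.lognormal_params()
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.rint(rng.lognormal(mu, sigma, size=2 * (n - filled))).astype(np.int64)
        ok = draw[(draw >= params.min_len) & (draw <= params.max_len)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def simulate_reads(
    genome: str,
    params: ReadSimParams,
    source: str = "endogenous",
    id_prefix: str = "read",
) -> tuple[list[QualityRead], SimTruth]:
    """Simulate single-end reads from a circular genome.

    Fragment starts are uniform on the circle, lengths truncated log-normal,
    strands uniform.  Damage (5' C->T, 3' G->A, geometric decay) precedes
    sequencing error; damaged and erroneous bases get ``qual_low``, all others
    ``qual_high``.  A fraction ``dup_rate`` of emitted reads are exact copies
    of previously emitted reads (fresh ids, shared ``dup_group``).
    """
    if set(genome) - set(DNA):
        raise ValueError("genome must contain only A/C/G/T")
    n = len(genome)
    if n < params.min_len:
        raise ValueError("genome shorter than the minimum fragment length")
    rng = np.random.default_rng(params.seed)

    reads: list[QualityRead] = []
    truths: dict[str, ReadTruth] = {}
    emitted: list[ReadTruth] = []

    n_frag = params.n_fragments
    starts = rng.integers(0, n, size=n_frag)
    lengths = _truncated_lognormal_lengths(params, n_frag, rng)
    strands = np.where(rng.random(n_frag) < 0.5, "+", "-")
    dup_draw = rng.random(n_frag) < params.dup_rate

    for i in range(n_frag):
        read_id = f"{id_prefix}{i:06d}"
        if dup_draw[i] and emitted:
            template_idx = int(rng.integers(len(emitted)))
            template = emitted[template_idx]
            src_read = reads[template_idx]
            read = QualityRead(
                read_id=read_id,
                seq=src_read.seq,
                quals=src_read.quals.copy(),
                source=source,
            )
            truth = dataclasses.replace(
                template, read_id=read_id, is_duplicate=True
            )
        else:
            read, truth = _simulate_one(
                genome, int(starts[i]), int(lengths[i]), str(strands[i]),
                params, rng, read_id, source, dup_group=i,
            )
        reads.append(read)
        truths[read_id] = truth
        emitted.append(truth)

    sim_truth = SimTruth(
        reads=truths, genome_length=n, params=dataclasses.asdict(params) | {"source": source}
    )
    return reads, sim_truth


def _simulate_one(
    genome: str,
    start: int,
    length: int,
    strand: str,
    params: ReadSimParams,
    rng: np.random.Generator,
    read_id: str,
    source: str,
    dup_group: int,
) -> tuple[QualityRead, ReadTruth]:
    n = len(genome)
    frag = circular_substring(genome, start, length)
    if strand == "-":
        frag = revcomp(frag)
    bases = np.frombuffer(frag.encode(), dtype="S1").astype("U1")

    # deamination-like damage, read orientation: 5' C->T, 3' G->A
    offsets = np.arange(length)
    p5 = params.d5 * params.lambda_decay**offsets
    p3 = params.d3 * params.lambda_decay**offsets[::-1]
    u5 = rng.random(length)
    u3 = rng.random(length)
    dmg5 = (bases == "C") & (u5 < p5)
    dmg3 = (bases == "G") & (u3 < p3)
    bases[dmg5] = "T"
    bases[dmg3] = "A"
    damage_pos = np.flatnonzero(dmg5 | dmg3)

    # sequencing error after damage
    err = rng.random(length) < params.seq_error
    err_pos = np.flatnonzero(err)
    for pos in err_pos:
        bases[pos] = _other_base(str(bases[pos]), rng)

    quals = np.full(length, params.qual_high, dtype=np.int64)
    low = np.union1d(damage_pos, err_pos)
    quals[low] = params.qual_low

    read = QualityRead(read_id=read_id, seq="".join(bases), quals=quals, source=source)
    truth = ReadTruth(
        read_id=read_id,
        source=source,
        start=start,
        end=(start + length) % n,
        wrap=start + length > n,
        strand=strand,
        length=length,
        damage_positions=tuple(int(p) for p in damage_pos),
        error_positions=tuple(int(p) for p in err_pos),
        dup_group=dup_group,
        is_duplicate=False,
    )
    return read, truth


def mix_contamination(
    endogenous: Sequence[QualityRead],
    endo_truth: SimTruth,
    contaminant: Sequence[QualityRead],
    cont_truth: SimTruth,
    fraction: float,
    seed: int = 0,
) -> tuple[list[QualityRead], SimTruth]:
    """Pool endogenous and contaminant reads at an expected contaminant share.

    Each of ``len(endogenous)`` output slots is independently filled from the
    contaminant set with probability ``fraction`` (sampling contaminant reads
    without replacement), otherwise from the endogenous set in order.  Read
    ids must be unique across the two sets.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    clash = {r.read_id for r in endogenous} & {r.read_id for r in contaminant}
    if clash:
        raise ValueError(f"read id collision between pools: {sorted(clash)[:5]}")
    rng = np.random.default_rng(seed)
    n = len(endogenous)
    take_cont = rng.random(n) < fraction
    n_cont = int(take_cont.sum())
    if n_cont > len(contaminant):
        raise ValueError(
            f"contaminant pool too small: need {n_cont}, have {len(contaminant)}"
        )
    cont_order = rng.permutation(len(contaminant))[:n_cont]
    pooled: list[QualityRead] = []
    truths: dict[str, ReadTruth] = {}
    ci = 0
    for i in range(n):
        if take_cont[i]:
            read = contaminant[cont_order[ci]]
            truth = dataclasses.replace(
                cont_truth.reads[read.read_id], source="contaminant"
            )
            ci += 1
        else:
            read = endogenous[i]
            truth = endo_truth.reads[read.read_id]
        pooled.append(read)
        truths[read.read_id] = truth
    return pooled, SimTruth(
        reads=truths,
        genome_length=endo_truth.genome_length,
        params={"fraction": fraction, "seed": seed},
    )
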