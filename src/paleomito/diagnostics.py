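"""Clade-diagnostic site discovery, read-agreement statistics, and clade assignment.

The contamination check works on two kinds of diagnostic columns of an aligned
multi-clade mitogenome panel:

* ``inter_clade_fixed`` — columns at which every clade is monomorphic (missing
  characters ignored) and at least two clades carry different bases;
* ``clade_fixed_query_divergent`` — columns at which one focal clade is
  monomorphic but an externally supplied query consensus carries a different,
  determined base.

Per-site read agreement is the fraction of pileup bases matching the focal base,
summarised by the median and interquartile range over covered sites.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seqs import MISSING_CHARS

__all__ = [
    "CladePanel",
    "DiagnosticSite",
    "AgreementStats",
    "CladeAssignment",
    "find_inter_clade_fixed_sites",
    "find_clade_fixed_query_divergent_sites",
    "site_agreement",
    "assign_clade",
    "extract_region",
    "filter_missing",
    "map_sites_to_reference",
    "p_distance",
]


@dataclasses.dataclass
class CladePanel:
    """Aligned sequence panel with per-sample clade labels and metadata.

    ``sequences`` maps sample id to an aligned sequence over {A,C,G,T,N,-};
    all sequences must have equal length and every sample exactly one clade.
    """

    sequences: dict[str, str]
    clades: dict[str, str]
    metadata: pd.DataFrame | None = None  # sample_id, species, latitude, longitude

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"panel sequences have unequal lengths: {sorted(lengths)}")
        missing = set(self.sequences) - set(self.clades)
        if missing:
            raise ValueError(f"samples without clade label: {sorted(missing)}")
        if len(self.clade_names) < 2:
            raise ValueError("panel must contain at least two clades")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def clade_names(self) -> list[str]:
        return sorted(set(self.clades[s] for s in self.sequences))

    def members(self, clade: str) -> list[str]:
        return sorted(s for s in self.sequences if self.clades[s] == clade)

    def clade_consensus(self, clade: str, exclude: Sequence[str] = ()) -> str:
        """Per-column majority base over the clade's members (ties/all-missing -> N)."""
        rows = [self.sequences[s] for s in self.members(clade) if s not in set(exclude)]
        if not rows:
            raise ValueError(f"clade {clade!r} has no members")
        out = []
        for col in zip(*rows):
            counts = Counter(c for c in col if c not in MISSING_CHARS)
            if not counts:
                out.append("N")
                continue
            ranked = counts.most_common()
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                out.append("N")
            else:
                out.append(ranked[0][0])
        return "".join(out)

    def to_files(self, fasta_path: str | Path, tsv_path: str | Path) -> None:
        from .seqs import write_fasta

        write_fasta(self.sequences, fasta_path)
        meta = self.metadata
        if meta is None:
            meta = pd.DataFrame({"sample_id": list(self.sequences)})
        meta = meta.copy()
        meta["clade"] = [self.clades[s] for s in meta["sample_id"]]
        cols = ["sample_id", "clade"] + [c for c in meta.columns if c not in ("sample_id", "clade")]
        meta[cols].to_csv(tsv_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, fasta_path: str | Path, tsv_path: str | Path) -> "CladePanel":
        from .seqs import read_fasta

        seqs = read_fasta(fasta_path)
        meta = pd.read_csv(tsv_path, sep="\t", dtype=str)
        clades = dict(zip(meta["sample_id"], meta["clade"]))
        return cls(sequences=seqs, clades=clades, metadata=meta)


@dataclasses.dataclass(frozen=True)
class DiagnosticSite:
    """A diagnostic alignment column.

    ``column`` is the 0-based alignment index; ``clade_bases`` records each
    clade's (monomorphic) base where determined; ``focal_base`` is the base
    against which read agreement is measured.
    """

    column: int
    kind: str  # "inter_clade_fixed" | "clade_fixed_query_divergent"
    clade_bases: tuple[tuple[str, str], ...]
    focal_base: str | None = None

    def base_of(self, clade: str) -> str | None:
        return dict(self.clade_bases).get(clade)

    def with_focal(self, base: str) -> "DiagnosticSite":
        return dataclasses.replace(self, focal_base=base)


@dataclasses.dataclass
class AgreementStats:
    """Median/IQR summary of per-site read agreement with the focal base."""

    per_site: pd.DataFrame  # column, ref_pos, focal_base, depth, agree, agreement
    median: float
    iqr: float
    n_sites: int
    n_uncovered: int

    @property
    def agreements(self) -> np.ndarray:
        return self.per_site.loc[self.per_site["depth"] > 0, "agreement"].to_numpy()


@dataclasses.dataclass
class CladeAssignment:
    assigned_clade: str
    votes: dict[str, int]
    p_distances: dict[str, float]
    n_usable_sites: int
    decision_rule: str
    tied: bool = False


def _column_missing_fraction(column: Sequence[str]) -> float:
    return sum(c in MISSING_CHARS for c in column) / len(column)


def _clade_base(column_chars: Sequence[str]) -> str | None | bool:
    """Monomorphic base of a clade at one column.

    Returns the base, None if the clade is all-missing (no constraint), or
    False if the clade is polymorphic.
    """
    seen = {c for c in column_chars if c not in MISSING_CHARS}
    if not seen:
        return None
    if len(seen) > 1:
        return False
    return next(iter(seen))


def find_inter_clade_fixed_sites(
    panel: CladePanel,
    max_missing_frac: float = 0.1,
    focal_clade: str | None = None,
) -> list[DiagnosticSite]:
    """Columns monomorphic within every clade with >= 2 clades differing.

    Columns whose overall missing-character fraction exceeds
    ``max_missing_frac`` are skipped.  A clade that is entirely missing at a
    column contributes no constraint.  If ``focal_clade`` is given, each
    site's ``focal_base`` is set to that clade's base.
    """
    clade_rows = {
        c: [panel.sequences[s] for s in panel.members(c)] for c in panel.clade_names
    }
    if focal_clade is not None and focal_clade not in clade_rows:
        raise ValueError(f"unknown focal clade {focal_clade!r}")
    all_rows = [panel.sequences[s] for s in sorted(panel.sequences)]
    sites: list[DiagnosticSite] = []
    for col in range(panel.n_columns):
        column = [row[col] for row in all_rows]
        if _column_missing_fraction(column) > max_missing_frac:
            continue
        bases: dict[str, str] = {}
        ok = True
        for clade, rows in clade_rows.items():
            b = _clade_base([row[col] for row in rows])
            if b is False:
                ok = False
                break
            if b is not None:
                bases[clade] = b
        if not ok or len(set(bases.values())) < 2:
            continue
        focal = bases.get(focal_clade) if focal_clade is not None else None
        sites.append(
            DiagnosticSite(
                column=col,
                kind="inter_clade_fixed",
                clade_bases=tuple(sorted(bases.items())),
                focal_base=focal,
            )
        )
    return sites


def find_clade_fixed_query_divergent_sites(
    panel: CladePanel,
    focal_clade: str,
    query: str,
    exclude: Sequence[str] = (),
) -> list[DiagnosticSite]:
    """Columns fixed within ``focal_clade`` at which ``query`` carries a
    different determined base.

    ``query`` must be aligned to panel coordinates; samples listed in
    ``exclude`` (e.g. the query itself, if present in the panel) are ignored.
    The focal base is the *query's* base: agreement then measures read support
    for the query's private variant.
    """
    members = [s for s in panel.members(focal_clade) if s not in set(exclude)]
    if not members:
        raise ValueError(f"focal clade {focal_clade!r} has no members after exclusion")
    if len(query) != panel.n_columns:
        raise ValueError("query length does not match panel alignment")
    rows = [panel.sequences[s] for s in members]
    sites = []
    for col in range(panel.n_columns):
        b = _clade_base([row[col] for row in rows])
        if b is None or b is False:
            continue
        q = query[col]
        if q in MISSING_CHARS or q == b:
            continue
        sites.append(
            DiagnosticSite(
                column=col,
                kind="clade_fixed_query_divergent",
                clade_bases=((focal_clade, b),),
                focal_base=q,
            )
        )
    return sites


def map_sites_to_reference(
    sites: Sequence[DiagnosticSite], aligned_reference: str
) -> tuple[list[tuple[DiagnosticSite, int]], list[DiagnosticSite]]:
    """Translate panel columns into coordinates of the gap-free reference.

    ``aligned_reference`` is the reference sample's row of the alignment; its
    gap columns are dropped to produce reference coordinates.  Sites falling
    in reference-gap columns cannot be located on the reference: they are
    returned separately rather than silently discarded.
    """
    ref_pos = np.cumsum([0 if c == "-" else 1 for c in aligned_reference]) - 1
    mapped, dropped = [], []
    for site in sites:
        if aligned_reference[site.column] == "-":
            dropped.append(site)
        else:
            mapped.append((site, int(ref_pos[site.column])))
    return mapped, dropped


def site_agreement(
    pileup,
    sites: Sequence[tuple[DiagnosticSite, int]] | Sequence[DiagnosticSite],
) -> AgreementStats:
    """Per-site agreement of pileup bases with each site's focal base.

    ``sites`` is either a list of ``(site, reference_position)`` pairs (from
    :func:`map_sites_to_reference`) or bare sites whose alignment column is
    already a reference coordinate.  Median and IQR (Q3 - Q1, linear
    interpolation) are computed over covered sites only; uncovered sites are
    excluded and counted.
    """
    pairs = [
        s if isinstance(s, tuple) else (s, s.column) for s in sites
    ]
    if not pairs:
        raise ValueError("no diagnostic sites supplied")
    records = []
    for site, pos in pairs:
        if site.focal_base is None:
            raise ValueError(f"site at column {site.column} has no focal base")
        counts = pileup.base_counts(pos)
        depth = int(sum(counts.values()))
        agree = int(counts.get(site.focal_base, 0))
        records.append(
            {
                "column": site.column,
                "ref_pos": pos,
                "kind": site.kind,
                "focal_base": site.focal_base,
                "depth": depth,
                "agree": agree,
                "A": counts.get("A", 0),
                "C": counts.get("C", 0),
                "G": counts.get("G", 0),
                "T": counts.get("T", 0),
                "agreement": agree / depth if depth else np.nan,
            }
        )
    table = pd.DataFrame.from_records(records)
    covered = table.loc[table["depth"] > 0, "agreement"].to_numpy()
    if covered.size == 0:
        raise ValueError("no diagnostic site is covered by any read")
    q1, med, q3 = np.percentile(covered, [25, 50, 75])  # linear interpolation
    return AgreementStats(
        per_site=table,
        median=float(med),
        iqr=float(q3 - q1),
        n_sites=len(table),
        n_uncovered=int((table["depth"] == 0).sum()),
    )


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites, pairwise deletion of missing characters."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    diffs = total = 0
    for x, y in zip(a, b):
        if x in MISSING_CHARS or y in MISSING_CHARS:
            continue
        total += 1
        diffs += x != y
    return diffs / total if total else np.nan


def assign_clade(
    query: str,
    panel: CladePanel,
    max_missing_frac: float = 0.1,
    exclude: Sequence[str] = (),
) -> CladeAssignment:
    """Assign ``query`` to a clade by votes over inter-clade fixed sites.

    At every inter-clade fixed site where the query base is determined, each
    clade whose base equals the query base receives one vote.  The clade with
    strictly most votes wins; ties are broken by the smallest p-distance to
    the clade consensus.
    """
    work = panel
    if exclude:
        keep = {s for s in panel.sequences if s not in set(exclude)}
        work = CladePanel(
            sequences={s: panel.sequences[s] for s in keep},
            clades={s: panel.clades[s] for s in keep},
        )
    sites = find_inter_clade_fixed_sites(work, max_missing_frac=max_missing_frac)
    votes = {c: 0 for c in work.clade_names}
    usable = 0
    for site in sites:
        q = query[site.column]
        if q in MISSING_CHARS:
            continue
        usable += 1
        for clade, base in site.clade_bases:
            if base == q:
                votes[clade] += 1
    if usable == 0:
        raise ValueError("unassignable: no usable diagnostic sites")
    dists = {c: p_distance(query, work.clade_consensus(c)) for c in work.clade_names}
    ranked = sorted(votes.items(), key=lambda kv: -kv[1])
    tied = len(ranked) > 1 and ranked[0][1] == ranked[1][1]
    if tied:
        top = [c for c, v in votes.items() if v == ranked[0][1]]
        winner = min(top, key=lambda c: (dists[c], c))
        rule = "vote_tie_broken_by_p_distance"
    else:
        winner = ranked[0][0]
        rule = "majority_vote"
    return CladeAssignment(
        assigned_clade=winner,
        votes=votes,
        p_distances=dists,
        n_usable_sites=usable,
        decision_rule=rule,
        tied=tied,
    )


def extract_region(
    alignment: dict[str, str], interval: tuple[int, int]
) -> dict[str, str]:
    """Column slice ``[start, end)`` of an alignment (0-based half-open)."""
    start, end = interval
    n_cols = len(next(iter(alignment.values())))
    if not (0 <= start < end <= n_cols):
        raise ValueError(f"invalid interval {interval!r} for alignment of {n_cols} columns")
    return {name: seq[start:end] for name, seq in alignment.items()}


def filter_missing(
    alignment: dict[str, str], max_frac: float = 0.10
) -> tuple[dict[str, str], list[str]]:
    """Drop sequences whose missing-character fraction strictly exceeds ``max_frac``.

    Returns the retained alignment and the list of removed sequence ids.
    """
    kept, removed = {}, []
    for name, seq in alignment.items():
        frac = sum(c in MISSING_CHARS for c in seq) / len(seq)
        if frac > max_frac:
            removed.append(name)
        else:
            kept[name] = seq
    return kept, removed
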