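"""Haplotype collapsing, minimum-spanning networks, and median-joining networks.

Missing data are handled by network-wide column masking (complete deletion):
any alignment column containing an N or a gap in any sequence is removed
before haplotypes are compared, so all distances are true Hamming distances.

The minimum-spanning network (MSN) is the union of all minimum spanning trees
under Hamming distance: edges are added tier by tier of increasing distance,
keeping every edge that joins two components as they stood at the start of its
tier.  Median-joining grows the node set with coordinate-wise majority
("median") vectors of mutually connected triples, then prunes inferred nodes
that are not on any shortest path between observed haplotypes.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import defaultdict
from pathlib import Path

import networkx as nx

__all__ = [
    "Haplotype",
    "HaplotypeNetwork",
    "MJConvergenceError",
    "collapse_haplotypes",
    "hamming",
    "minimum_spanning_network",
    "median_joining",
]


@dataclasses.dataclass
class Haplotype:
    hap_id: str
    seq: str  # masked sequence over {A,C,G,T}
    members: list[str]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclasses.dataclass
class HaplotypeNetwork:
    """Undirected network over observed haplotypes and inferred median vectors."""

    graph: nx.Graph  # node attrs: seq, type ("observed"|"median"), count, members
    haplotypes: dict[str, Haplotype]

    @property
    def total_cost(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["type"] == "median"]

    def write_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tweight\n")
            for a, b, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{a}\t{b}\t{d['weight']}\n")

    def write_node_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_id\ttype\tcount\tmembers\n")
            for n, d in sorted(self.graph.nodes(data=True)):
                members = ",".join(d.get("members", []))
                fh.write(f"{n}\t{d['type']}\t{d.get('count', 0)}\t{members}\n")

    def write_gml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for _, d in g.nodes(data=True):
            d["members"] = ",".join(d.get("members", []))
        nx.write_gml(g, str(path))


class MJConvergenceError(RuntimeError):
    def __init__(self, message: str, partial: HaplotypeNetwork):
        super().__init__(message)
        self.partial = partial


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


def collapse_haplotypes(
    alignment: dict[str, str]
) -> tuple[list[Haplotype], list[int]]:
    """Group identical sequences after network-wide masking of incomplete columns.

    Returns the haplotypes (ordered by first-seen sample) and the masked
    column indices.
    """
    if not alignment:
        raise ValueError("no sequences to collapse")
    names = list(alignment)
    n_cols = len(alignment[names[0]])
    masked = [
        c
        for c in range(n_cols)
        if any(alignment[s][c] in "N-" for s in names)
    ]
    masked_set = set(masked)
    keep_cols = [c for c in range(n_cols) if c not in masked_set]
    groups: dict[str, Haplotype] = {}
    order: list[str] = []
    for name in names:
        key = "".join(alignment[name][c] for c in keep_cols)
        if key not in groups:
            hap = Haplotype(hap_id=f"H{len(groups) + 1}", seq=key, members=[])
            groups[key] = hap
            order.append(key)
        groups[key].members.append(name)
    return [groups[k] for k in order], masked


def _msn_edges(seqs: dict[str, str]) -> list[tuple[str, str, int]]:
    """Union-of-all-MSTs edge set under Hamming distance."""
    nodes = sorted(seqs)
    by_dist: dict[int, list[tuple[str, str]]] = defaultdict(list)
    for a, b in itertools.combinations(nodes, 2):
        d = hamming(seqs[a], seqs[b])
        if d == 0:
            raise ValueError(f"duplicate haplotype sequences: {a}, {b}")
        by_dist[d].append((a, b))
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[str, str, int]] = []
    for d in sorted(by_dist):
        # components as of the start of this tier decide admissibility
        comp_at_tier = {n: find(n) for n in nodes}
        tier = [
            (a, b) for a, b in by_dist[d] if comp_at_tier[a] != comp_at_tier[b]
        ]
        for a, b in tier:
            edges.append((a, b, d))
        for a, b in tier:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    return edges


def _build_graph(
    seqs: dict[str, str], haplotypes: dict[str, Haplotype]
) -> nx.Graph:
    g = nx.Graph()
    for node, seq in seqs.items():
        hap = haplotypes.get(node)
        g.add_node(
            node,
            seq=seq,
            type="observed" if hap else "median",
            count=hap.count if hap else 0,
            members=list(hap.members) if hap else [],
        )
    for a, b, d in _msn_edges(seqs):
        g.add_edge(a, b, weight=d)
    return g


def minimum_spanning_network(haplotypes: list[Haplotype]) -> HaplotypeNetwork:
    """Network containing every edge that occurs in some minimum spanning tree."""
    if len(haplotypes) < 2:
        raise ValueError("need at least two haplotypes")
    seqs = {h.hap_id: h.seq for h in haplotypes}
    hap_map = {h.hap_id: h for h in haplotypes}
    return HaplotypeNetwork(graph=_build_graph(seqs, hap_map), haplotypes=hap_map)


def _median_vector(a: str, b: str, c: str) -> str | None:
    """Coordinate-wise strict-majority sequence; None if any column has three
    distinct bases (no strict majority)."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            return None
    return "".join(out)


def median_joining(
    haplotypes: list[Haplotype], epsilon: int = 0, max_iter: int = 50
) -> HaplotypeNetwork:
    """Median-joining network.

    Iteratively builds the MSN over the current node set, computes median
    vectors for mutually connected node triples, and adds those whose
    connection cost (summed distance to the triple) is within ``epsilon`` of
    the round's minimum.  After convergence, inferred nodes that are not on
    any shortest path between observed haplotypes, or that have degree < 3,
    are pruned and the MSN is rebuilt.
    """
    if len(haplotypes) < 2:
        raise ValueError("need at least two haplotypes")
    hap_map = {h.hap_id: h for h in haplotypes}
    seqs = {h.hap_id: h.seq for h in haplotypes}
    known = set(seqs.values())
    n_medians = 0

    for iteration in range(max_iter + 1):
        g = _build_graph(seqs, hap_map)
        if iteration == max_iter:
            raise MJConvergenceError(
                f"median-joining did not converge in {max_iter} iterations",
                HaplotypeNetwork(graph=g, haplotypes=hap_map),
            )
        candidates: dict[str, int] = {}
        for tri in _triangles(g):
            m = _median_vector(*(seqs[n] for n in tri))
            if m is None or m in known:
                continue
            cost = sum(hamming(m, seqs[n]) for n in tri)
            if m not in candidates or cost < candidates[m]:
                candidates[m] = cost
        if not candidates:
            break
        min_cost = min(candidates.values())
        added = False
        for m, cost in sorted(candidates.items(), key=lambda kv: (kv[1], kv[0])):
            if cost <= min_cost + epsilon:
                n_medians += 1
                seqs[f"MV{n_medians}"] = m
                known.add(m)
                added = True
        if not added:
            break

    # prune inferred nodes not on any observed-pair shortest path or of low degree
    observed = set(hap_map)
    while True:
        g = _build_graph(seqs, hap_map)
        sp = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        drop = []
        for node in seqs:
            if node in observed:
                continue
            if g.degree(node) < 3 or not _on_shortest_path(node, observed, sp):
                drop.append(node)
        if not drop:
            break
        for node in drop:
            del seqs[node]
    g = _build_graph(seqs, hap_map)
    return HaplotypeNetwork(graph=g, haplotypes=hap_map)


def _triangles(g: nx.Graph):
    for a, b in g.edges():
        for c in set(g[a]) & set(g[b]):
            if a < c and b < c:
                yield (a, b, c)


def _on_shortest_path(node: str, observed: set[str], sp: dict) -> bool:
    for a, b in itertools.combinations(sorted(observed), 2):
        if sp[a].get(node) is None or sp[b].get(node) is None:
            continue
        if sp[a][node] + sp[node][b] == sp[a][b]:
            return True
    return False
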