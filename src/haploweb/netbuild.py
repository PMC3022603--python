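"""Haplotype network ("haplonet") construction.

Distances are per-column mismatch counts on the alignment, with gaps either a
fifth character state (default) or ignored.  Two topologies are offered:

* the minimum-spanning network (MSN): the union of all minimum spanning trees
  of the complete mutation-distance graph;
* the median-joining network (MJN) of Bandelt, Forster & Röhl (1999): the MSN
  is iteratively enriched with "median vectors" — unobserved consensus
  sequences of connected node triplets — whenever they reduce the total
  connection cost, then pruned of medians that end up peripheral.

The relaxation parameter epsilon admits edges up to epsilon steps longer than
strictly necessary to connect their endpoints; epsilon = 0 gives the plain
MSN.  Networks are built for visualisation and reporting only — allele-pool
and FFR delineation never read network topology.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .errors import AlignmentLengthError, FormatError, NonTerminationError
from .io_model import HaplotypeTable, _natural_hap_key

GAP = "-"
GAP_MODES = ("fifth_state", "ignore")


def mutation_distance(
    seq_a: str, seq_b: str, gap_mode: str = "fifth_state"
) -> tuple[int, list[int]]:
    """Number of differing alignment columns and their 1-based positions.

    ``fifth_state`` treats ``-`` as an ordinary character; ``ignore`` skips
    any column where either sequence has a gap.
    """
    if len(seq_a) != len(seq_b):
        raise AlignmentLengthError(
            f"cannot compare sequences of lengths {len(seq_a)} and {len(seq_b)}"
        )
    if gap_mode not in GAP_MODES:
        raise FormatError(f"unknown gap_mode {gap_mode!r}")
    positions = []
    for i, (a, b) in enumerate(zip(seq_a.upper(), seq_b.upper()), start=1):
        if gap_mode == "ignore" and (a == GAP or b == GAP):
            continue
        if a != b:
            positions.append(i)
    return len(positions), positions


@dataclass(frozen=True)
class NetNode:
    node_id: str
    kind: str  # "observed" | "median"
    sequence: str
    hap_id: str | None = None
    count: int = 0

    @property
    def observed(self) -> bool:
        return self.kind == "observed"


@dataclass(frozen=True)
class NetEdge:
    u: str
    v: str
    length: int
    positions: tuple[int, ...]


@dataclass
class HaplotypeNetwork:
    marker: str
    nodes: dict[str, NetNode]
    edges: list[NetEdge]
    epsilon: int = 0
    gap_mode: str = "fifth_state"

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for nid, node in self.nodes.items():
            g.add_node(
                nid,
                kind=node.kind,
                hap_id=node.hap_id or "",
                count=node.count,
                sequence=node.sequence,
            )
        for e in self.edges:
            g.add_edge(e.u, e.v, length=e.length,
                       positions=",".join(map(str, e.positions)))
        return g

    @property
    def observed_nodes(self) -> list[NetNode]:
        return [n for n in self.nodes.values() if n.observed]

    @property
    def median_nodes(self) -> list[NetNode]:
        return [n for n in self.nodes.values() if not n.observed]

    def total_edge_weight(self) -> int:
        return sum(e.length for e in self.edges)


def _node_sort_key(node_id: str):
    # observed h<i> before medians mv<j>, each in numeric order
    kind = 0 if not node_id.startswith("mv") else 1
    return (kind, _natural_hap_key(node_id))


def _pairwise(seqs: dict[str, str], gap_mode: str) -> dict[tuple[str, str], int]:
    d = {}
    for u, v in itertools.combinations(sorted(seqs, key=_node_sort_key), 2):
        d[(u, v)] = mutation_distance(seqs[u], seqs[v], gap_mode)[0]
    return d


def _dist(d, u, v):
    return d[(u, v)] if (u, v) in d else d[(v, u)]


def _kruskal_mst(nodes: list[str], d) -> tuple[list[tuple[str, str]], int]:
    """Deterministic Kruskal MST; returns edge list and total weight."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = sorted(
        ((u, v) for u, v in itertools.combinations(nodes, 2)),
        key=lambda uv: (_dist(d, *uv), _node_sort_key(uv[0]), _node_sort_key(uv[1])),
    )
    mst, total = [], 0
    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            mst.append((u, v))
            total += _dist(d, u, v)
            if len(mst) == len(nodes) - 1:
                break
    return mst, total


def _bottleneck(nodes: list[str], mst_edges, d) -> dict[tuple[str, str], int]:
    """Minimax (bottleneck) distance between all pairs = max edge on MST path."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in mst_edges:
        g.add_edge(u, v, weight=_dist(d, u, v))
    out = {}
    for src in nodes:
        # DFS carrying the running max edge weight
        best = {src: 0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y in g.neighbors(x):
                if y not in best:
                    best[y] = max(best[x], g[x][y]["weight"])
                    stack.append(y)
        for dst, w in best.items():
            if src < dst:
                out[(src, dst)] = w
    return out


def _relaxed_msn_edges(
    seqs: dict[str, str], epsilon: int, gap_mode: str
) -> list[tuple[str, str]]:
    """Edges of the epsilon-relaxed minimum-spanning network.

    An edge (u, v) is kept iff d(u, v) <= t(u, v) + epsilon where t is the
    bottleneck (minimax path) distance; at epsilon = 0 this is exactly the
    union of all minimum spanning trees.
    """
    nodes = sorted(seqs, key=_node_sort_key)
    if len(nodes) < 2:
        return []
    d = _pairwise(seqs, gap_mode)
    mst_edges, _ = _kruskal_mst(nodes, d)
    t = _bottleneck(nodes, mst_edges, d)
    kept = []
    for u, v in itertools.combinations(nodes, 2):
        key = (u, v) if (u, v) in t else (v, u)
        if _dist(d, u, v) <= t[key] + epsilon:
            kept.append((u, v))
    return kept


def _network_from(
    marker: str,
    seqs: dict[str, str],
    meta: dict[str, NetNode],
    epsilon: int,
    gap_mode: str,
) -> HaplotypeNetwork:
    edge_pairs = _relaxed_msn_edges(seqs, epsilon, gap_mode)
    edges = []
    for u, v in edge_pairs:
        n, pos = mutation_distance(seqs[u], seqs[v], gap_mode)
        edges.append(NetEdge(u, v, n, tuple(pos)))
    nodes = {nid: meta[nid] for nid in sorted(seqs, key=_node_sort_key)}
    return HaplotypeNetwork(marker, nodes, edges, epsilon, gap_mode)


def build_msn(
    table: HaplotypeTable, gap_mode: str = "fifth_state", epsilon: int = 0
) -> HaplotypeNetwork:
    """Minimum-spanning network over the observed haplotypes."""
    if not table.entries:
        raise FormatError(f"empty haplotype table for marker {table.marker!r}")
    seqs = {e.hap_id: e.sequence for e in table.entries}
    meta = {
        e.hap_id: NetNode(e.hap_id, "observed", e.sequence, e.hap_id, e.count)
        for e in table.entries
    }
    return _network_from(table.marker, seqs, meta, epsilon, gap_mode)


def _median_sequence(sa: str, sb: str, sc: str) -> str:
    """Column-wise majority consensus; three-way ties resolve to ``sa``."""
    out = []
    for a, b, c in zip(sa, sb, sc):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(a)  # all three differ: keep the state of the first node
    return "".join(out)


def build_mjn(
    table: HaplotypeTable,
    epsilon: int = 0,
    gap_mode: str = "fifth_state",
    iteration_cap: int | None = None,
) -> HaplotypeNetwork:
    """Median-joining network over the observed haplotypes.

    Repeats: (i) build the epsilon-relaxed MSN over the current node set;
    (ii) for each triplet of mutually connected nodes compute its majority
    consensus median (ties take the state of the triplet member with the
    smallest node id); (iii) add medians that strictly reduce the minimum
    spanning tree total weight, until no median is added.  Median vectors
    left with degree <= 1 are then pruned and the final relaxed MSN emitted.
    """
    if not table.entries:
        raise FormatError(f"empty haplotype table for marker {table.marker!r}")
    cap = iteration_cap if iteration_cap is not None else 10 * len(table.entries)

    seqs = {e.hap_id: e.sequence for e in table.entries}
    meta = {
        e.hap_id: NetNode(e.hap_id, "observed", e.sequence, e.hap_id, e.count)
        for e in table.entries
    }
    n_medians = 0

    iterations = 0
    while True:
        iterations += 1
        if iterations > cap:
            raise NonTerminationError(
                f"median-joining did not converge within {cap} iterations "
                f"for marker {table.marker!r}"
            )
        edge_pairs = _relaxed_msn_edges(seqs, epsilon, gap_mode)
        adj: dict[str, set[str]] = {n: set() for n in seqs}
        for u, v in edge_pairs:
            adj[u].add(v)
            adj[v].add(u)

        candidates = set()
        nodes = sorted(seqs, key=_node_sort_key)
        for u, v, w in itertools.combinations(nodes, 3):
            if v in adj[u] and w in adj[u] and w in adj[v]:
                med = _median_sequence(seqs[u], seqs[v], seqs[w])
                if med not in set(seqs.values()):
                    candidates.add(med)

        added = False
        d = _pairwise(seqs, gap_mode)
        _, base_cost = _kruskal_mst(nodes, d)
        for med in sorted(candidates):
            if med in set(seqs.values()):
                continue
            trial = dict(seqs)
            trial_id = f"mv{n_medians + 1}"
            trial[trial_id] = med
            td = _pairwise(trial, gap_mode)
            _, cost = _kruskal_mst(sorted(trial, key=_node_sort_key), td)
            if cost < base_cost:
                n_medians += 1
                seqs[trial_id] = med
                meta[trial_id] = NetNode(trial_id, "median", med)
                base_cost = cost
                nodes = sorted(seqs, key=_node_sort_key)
                added = True
        if not added:
            break

    # prune obsolete median vectors (degree <= 1), repeatedly
    while True:
        edge_pairs = _relaxed_msn_edges(seqs, epsilon, gap_mode)
        degree = {n: 0 for n in seqs}
        for u, v in edge_pairs:
            degree[u] += 1
            degree[v] += 1
        obsolete = [
            n for n in seqs if meta[n].kind == "median" and degree[n] <= 1
        ]
        if not obsolete:
            break
        for n in obsolete:
            del seqs[n]
            del meta[n]

    return _network_from(table.marker, seqs, meta, epsilon, gap_mode)
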