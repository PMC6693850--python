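"""Minimum-spanning and median-joining haplotype networks.

The minimum spanning network (MSN) is the union of all minimum spanning
trees: Kruskal's construction in which, at each distance level, *every*
tie edge joining components that were distinct before the level is kept.
The median-joining (MJ) algorithm iteratively augments the node set with
"median vectors" — unsampled consensus sequences of triples of connected
nodes — whenever doing so strictly shortens the MSN, then prunes medians
that no longer earn their place.  With epsilon = 0 the construction is the
strictest variant: only ties at the current distance level are admitted.

Median vectors are hypothetical ancestors; in published network figures
they are the black nodes between sampled haplotypes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .haplotypes import DistanceMatrix, HaplotypeTable

logger = logging.getLogger(__name__)


@dataclass
class NetworkNode:
    node_id: str
    kind: str                 # "sampled" | "median"
    sequence: str             # over masked columns; may be "" for MSN-only
    members: list[str] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeNetwork:
    """Undirected weighted haplotype graph.

    Edge weights are integer Hamming distances between the endpoint
    sequences.  Sampled nodes correspond 1:1 with haplotypes; median nodes
    carry no members.
    """

    nodes: list[NetworkNode]
    graph: nx.Graph
    epsilon: int = 0

    @property
    def n_medians(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "median")

    def node(self, node_id: str) -> NetworkNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def edges(self) -> list[tuple[str, str, int]]:
        return sorted(
            (min(u, v), max(u, v), int(d["weight"]))
            for u, v, d in self.graph.edges(data=True)
        )


def network_length(network: HaplotypeNetwork | nx.Graph) -> int:
    """Sum of edge weights."""
    graph = network.graph if isinstance(network, HaplotypeNetwork) else network
    return int(sum(d["weight"] for _, _, d in graph.edges(data=True)))


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype="S1")


def _msn_graph(ids: list[str], dist: np.ndarray, epsilon: int = 0) -> nx.Graph:
    """Kruskal construction keeping all ties at each distance level.

    Distinct distance values are processed in ascending order; at level d
    every pair at distance <= d + epsilon whose endpoints lay in different
    components *before the level started* is added, so equal-weight
    alternatives all survive and the result is a network, not a tree.
    """
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    n = len(ids)
    if n <= 1:
        return graph
    iu, ju = np.triu_indices(n, k=1)
    values = np.unique(dist[iu, ju])
    values = values[values > 0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for level in values:
        # snapshot components before this level's additions
        comp_before = [find(i) for i in range(n)]
        added: list[tuple[int, int]] = []
        for i, j in zip(iu, ju):
            d = dist[i, j]
            if 0 < d <= level + epsilon and comp_before[i] != comp_before[j]:
                if not graph.has_edge(ids[i], ids[j]):
                    graph.add_edge(ids[i], ids[j], weight=int(d))
                    added.append((int(i), int(j)))
        for i, j in added:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        if len({find(i) for i in range(n)}) == 1 and epsilon == 0:
            break
    return graph


def minimum_spanning_network(
    distances: DistanceMatrix, epsilon: int = 0
) -> HaplotypeNetwork:
    """Build the MSN over sampled haplotypes only (no median vectors)."""
    if len(distances.ids) < 1:
        raise ValueError("need at least one haplotype")
    graph = _msn_graph(distances.ids, distances.matrix, epsilon)
    nodes = [NetworkNode(i, "sampled", "") for i in distances.ids]
    return HaplotypeNetwork(nodes, graph, epsilon)


def majority_median(a: str, b: str, c: str) -> str:
    """Column-wise majority consensus of three equal-length sequences.

    Where all three states differ (a three-way tie) the state of the
    lexicographically smallest of the three sequences is copied, which
    keeps the construction deterministic and independent of input order.
    """
    order = sorted([a, b, c])
    return _median_arr(
        _seq_array(order[0]), _seq_array(order[1]), _seq_array(order[2])
    ).tobytes().decode("ascii")


def _median_arr(small: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Majority consensus; ``small`` supplies the state at 3-way ties."""
    out = small.copy()
    bc = b == c
    out[bc] = b[bc]
    return out


def _pairwise_int(seqs: list[np.ndarray]) -> np.ndarray:
    n = len(seqs)
    mat = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d = int((seqs[i] != seqs[j]).sum())
            mat[i, j] = mat[j, i] = d
    return mat


def _extend_dist(D: np.ndarray, row: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    out = np.zeros((n + 1, n + 1), dtype=np.int64)
    out[:n, :n] = D
    out[n, :n] = row
    out[:n, n] = row
    return out


def median_joining(
    table: HaplotypeTable,
    epsilon: int = 0,
    pair_escape_limit: int = 30,
) -> HaplotypeNetwork:
    """Median-joining network over the haplotype table's masked sequences.

    The loop alternates MSN construction with median insertion: candidate
    medians are majority consensuses of u-v-w paths in the current network
    (v adjacent to both u and w); candidates are tried in ascending order
    of connection cost d(m,u)+d(m,v)+d(m,w) (ties broken lexicographically
    on the median sequence) and the first one that strictly reduces total
    network length is added.  When no single candidate helps, a two-step
    lookahead tries pairs (m1, m2) with m2 a median of a triple involving
    m1 — two unsampled ancestors are sometimes needed jointly before
    either pays off; ``pair_escape_limit`` caps how many m1 candidates the
    lookahead examines.  Finally, median nodes whose removal does not
    increase total network length are deleted (this covers isolated and
    degree-1 medians and degree-2 medians lying on a shortest path between
    their neighbours, while keeping medians whose removal would re-open
    equal-weight alternative edges).
    """
    if len(table) < 1:
        raise ValueError("need at least one haplotype")
    sampled_ids = list(table.ids)
    seqs: dict[str, np.ndarray] = {
        h.haplotype_id: _seq_array(h.key) for h in table.haplotypes
    }
    members = {h.haplotype_id: list(h.members) for h in table.haplotypes}
    ids: list[str] = list(sampled_ids)
    D = _pairwise_int([seqs[i] for i in ids])
    median_counter = itertools.count(1)

    def dist_row(arr: np.ndarray, id_list: list[str]) -> np.ndarray:
        return np.array(
            [int((seqs[i] != arr).sum()) for i in id_list], dtype=np.int64
        )

    def length_of(id_list: list[str], dmat: np.ndarray) -> int:
        return network_length(_msn_graph(id_list, dmat, epsilon))

    def feasible_candidates(graph: nx.Graph) -> list[tuple[int, str]]:
        existing = {seqs[i].tobytes() for i in ids}
        cand: dict[bytes, int] = {}
        for v in graph.nodes:
            for u, w in itertools.combinations(sorted(graph.neighbors(v)), 2):
                trio = sorted(
                    (seqs[u], seqs[v], seqs[w]), key=lambda x: x.tobytes()
                )
                marr = _median_arr(*trio)
                mb = marr.tobytes()
                if mb in existing:
                    continue
                cost = int(
                    (marr != seqs[u]).sum()
                    + (marr != seqs[v]).sum()
                    + (marr != seqs[w]).sum()
                )
                if mb not in cand or cost < cand[mb]:
                    cand[mb] = cost
        return sorted(
            (cost, mb.decode("ascii")) for mb, cost in cand.items()
        )

    while True:
        graph = _msn_graph(ids, D, epsilon)
        base = network_length(graph)
        candidates = feasible_candidates(graph)
        improved = False
        for cost, m in candidates:
            marr = _seq_array(m)
            row = dist_row(marr, ids)
            if length_of(ids + ["?"], _extend_dist(D, row)) < base:
                mid = f"M{next(median_counter)}"
                seqs[mid] = marr
                ids.append(mid)
                D = _extend_dist(D, row)
                improved = True
                break
        if improved:
            continue
        # plateau escape: try adding two medians jointly
        found = None
        for cost1, m1 in candidates[:pair_escape_limit]:
            m1arr = _seq_array(m1)
            row1 = dist_row(m1arr, ids)
            D1 = _extend_dist(D, row1)
            seen = {seqs[i].tobytes() for i in ids} | {m1.encode("ascii")}
            pool = [seqs[i] for i in ids] + [m1arr]
            for a, b in itertools.combinations(range(len(pool) - 1), 2):
                trio = sorted(
                    [pool[a], pool[b], m1arr], key=lambda x: x.tobytes()
                )
                m2arr = _median_arr(*trio)
                m2b = m2arr.tobytes()
                if m2b in seen:
                    continue
                seen.add(m2b)
                row2 = np.append(
                    dist_row(m2arr, ids), int((m2arr != m1arr).sum())
                )
                length = length_of(
                    ids + ["?", "??"], _extend_dist(D1, row2)
                )
                key = (length, m1, m2b.decode("ascii"))
                if length < base and (found is None or key < found):
                    found = key
        if found is None:
            break
        _, m1, m2 = found
        for m in (m1, m2):
            mid = f"M{next(median_counter)}"
            seqs[mid] = _seq_array(m)
            D = _extend_dist(D, dist_row(seqs[mid], ids))
            ids.append(mid)

    # prune: drop any median whose removal does not increase total length
    while True:
        base = length_of(ids, D)
        removed = False
        for k, nid in enumerate(ids):
            if nid in members:
                continue
            keep = [i for i in range(len(ids)) if i != k]
            if length_of([ids[i] for i in keep], D[np.ix_(keep, keep)]) <= base:
                ids.pop(k)
                D = D[np.ix_(keep, keep)]
                del seqs[nid]
                removed = True
                break
        if not removed:
            break

    graph = _msn_graph(ids, D, epsilon)
    nodes = [
        NetworkNode(
            nid,
            "sampled" if nid in members else "median",
            seqs[nid].tobytes().decode("ascii"),
            members.get(nid, []),
        )
        for nid in ids
    ]
    logger.info(
        "median_joining: %d sampled, %d median nodes, length %d",
        len(sampled_ids), len(ids) - len(sampled_ids), network_length(graph),
    )
    return HaplotypeNetwork(nodes, graph, epsilon)


def export_network(
    network: HaplotypeNetwork,
    path: str | Path,
    fmt: str = "graphml",
    origins: dict[str, str] | None = None,
) -> None:
    """Write the network as GraphML, a TSV edge list, or a NEXUS block.

    ``origins`` optionally maps specimen ID -> origin label; per-origin
    member counts are then attached to GraphML node attributes.
    """
    path = Path(path)
    if fmt == "graphml":
        g = nx.Graph()
        for node in network.nodes:
            attrs = {
                "kind": node.kind,
                "n_members": node.n_members,
                "sequence": node.sequence,
            }
            if origins is not None:
                comp: dict[str, int] = {}
                for sid in node.members:
                    comp[origins.get(sid, "unknown")] = (
                        comp.get(origins.get(sid, "unknown"), 0) + 1
                    )
                attrs["origin_composition"] = ";".join(
                    f"{k}:{v}" for k, v in sorted(comp.items())
                )
            g.add_node(node.node_id, **attrs)
        for u, v, w in network.edges():
            g.add_edge(u, v, weight=w)
        nx.write_graphml(g, path)
    elif fmt in {"edge-tsv", "tsv"}:
        pd.DataFrame(
            network.edges(), columns=["source", "target", "weight"]
        ).to_csv(path, sep="\t", index=False)
    elif fmt == "nexus":
        sampled = [n for n in network.nodes if n.kind == "sampled"]
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN TAXA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(sampled)};\n  TAXLABELS\n")
            for n in sampled:
                fh.write(f"    {n.node_id}\n")
            fh.write("  ;\nEND;\n\nBEGIN NETWORK;\n")
            fh.write(
                f"  DIMENSIONS NVERTICES={len(network.nodes)} "
                f"NEDGES={network.graph.number_of_edges()};\n"
            )
            fh.write("  VERTICES\n")
            for n in network.nodes:
                fh.write(f"    {n.node_id} kind={n.kind} n={n.n_members}\n")
            fh.write("  ;\n  EDGES\n")
            for u, v, w in network.edges():
                fh.write(f"    {u} {v} weight={w}\n")
            fh.write("  ;\nEND;\n")
    else:
        raise ValueError(f"unknown network format: {fmt!r}")


def node_table(
    network: HaplotypeNetwork, origins: dict[str, str] | None = None
) -> pd.DataFrame:
    """Node attribute table (id, kind, member count, origin composition)."""
    rows = []
    for node in network.nodes:
        row = {
            "node_id": node.node_id,
            "kind": node.kind,
            "n_members": node.n_members,
        }
        if origins is not None:
            comp: dict[str, int] = {}
            for sid in node.members:
                o = origins.get(sid, "unknown")
                comp[o] = comp.get(o, 0) + 1
            row["origins"] = ";".join(f"{k}:{v}" for k, v in sorted(comp.items()))
        rows.append(row)
    return pd.DataFrame(rows)
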