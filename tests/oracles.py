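"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: spanning-tree
enumeration, exhaustive subset search over the quasi-median closure, and
per-column counting are all written from the definitions.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from mitotrace.haplotypes import Haplotype, HaplotypeTable
from mitotrace.mj_network import _msn_graph, _pairwise_int, _seq_array
from mitotrace.mj_network import majority_median


def table_from(seqs: list[str], counts: list[int] | None = None) -> HaplotypeTable:
    """Build a HaplotypeTable directly from masked sequences."""
    counts = counts or [1] * len(seqs)
    haps = [
        Haplotype(f"H{i + 1:02d}", s, [f"s{i}_{j}" for j in range(c)])
        for i, (s, c) in enumerate(zip(seqs, counts))
    ]
    back = {m: i for i, h in enumerate(haps) for m in h.members}
    return HaplotypeTable(haps, back)


def msn_length(seqs: list[str], epsilon: int = 0) -> int:
    arrs = [_seq_array(s) for s in seqs]
    g = _msn_graph([str(i) for i in range(len(seqs))], _pairwise_int(arrs),
                   epsilon)
    return sum(d["weight"] for _, _, d in g.edges(data=True))


def quasi_median_closure(seqs: list[str], cap: int = 120) -> set[str]:
    """Fixed point of adding majority medians of all triples."""
    pool = set(seqs)
    while True:
        new = set()
        for a, b, c in combinations(sorted(pool), 3):
            m = majority_median(a, b, c)
            if m not in pool:
                new.add(m)
        if not new:
            return pool
        pool |= new
        if len(pool) > cap:
            return pool


def steiner_optimum(seqs: list[str], epsilon: int = 0) -> int:
    """Exhaustive minimum MSN length over subsets of closure medians."""
    medians = sorted(quasi_median_closure(seqs) - set(seqs))
    best = msn_length(seqs, epsilon)
    for r in range(1, len(medians) + 1):
        for sub in combinations(medians, r):
            best = min(best, msn_length(list(seqs) + list(sub), epsilon))
    return best


def all_spanning_trees_msn(ids: list[str], dist: np.ndarray):
    """Union of all minimum spanning trees, by exhaustive enumeration.

    Only usable for a handful of nodes: enumerates every spanning tree
    (as edge subsets forming a connected acyclic cover) and keeps the
    edges of all trees attaining the minimum total weight.
    """
    import networkx as nx

    n = len(ids)
    pairs = list(combinations(range(n), 2))
    best_weight = None
    best_edges: set[tuple[int, int]] = set()
    for subset in combinations(pairs, n - 1):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(subset)
        if not nx.is_connected(g):
            continue
        w = sum(dist[i, j] for i, j in subset)
        if best_weight is None or w < best_weight:
            best_weight = w
            best_edges = set(subset)
        elif w == best_weight:
            best_edges |= set(subset)
    return best_weight, {
        (ids[min(i, j)], ids[max(i, j)]) for i, j in best_edges
    }


def draw_radiation(rng: np.random.Generator) -> list[str]:
    """Clonal radiation instance: <=5 sampled haplotypes, <=12 sites.

    A small tree grows from a random root with every mutation at a fresh
    column (no homoplasy); sampling is biased toward leaves so that
    unsampled internal nodes (median vectors) are frequently required.
    """
    length = int(rng.integers(8, 13))
    bases = np.frombuffer(b"ACGT", dtype="S1")
    root = rng.choice(bases, size=length)
    nodes = [root]
    children: dict[int, list[int]] = {0: []}
    free = list(rng.permutation(length))
    n_nodes = int(rng.integers(4, 9))
    while len(nodes) < n_nodes and free:
        parent = int(rng.integers(len(nodes)))
        s = nodes[parent].copy()
        for _ in range(min(int(rng.integers(1, 3)), len(free))):
            col = free.pop()
            s[col] = rng.choice([b for b in bases if b != s[col]])
        children[parent].append(len(nodes))
        children[len(nodes)] = []
        nodes.append(s)
    pick = [i for i in range(len(nodes)) if not children[i]]
    for i in range(len(nodes)):
        if children[i] and rng.random() < 0.25:
            pick.append(i)
    rng.shuffle(pick)
    out: list[str] = []
    for i in pick[:5]:
        s = nodes[i].tobytes().decode("ascii")
        if s not in out:
            out.append(s)
    return out


def pi_count_bruteforce(matrix: np.ndarray) -> int:
    """Parsimony-informative columns counted straight from the definition."""
    count = 0
    for j in range(matrix.shape[1]):
        column = [matrix[i, j] for i in range(matrix.shape[0])]
        states_with_2 = {s for s in set(column) if column.count(s) >= 2}
        if len(states_with_2) >= 2:
            count += 1
    return count
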