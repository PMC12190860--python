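"""Independent brute-force oracles used to validate graph statistics.

These deliberately avoid networkx and scipy.csgraph (which back the
implementation): path enumeration is a hand-written DFS and distances
come from a hand-written heap Dijkstra, so agreement is a genuine
cross-check.
"""

from __future__ import annotations

import heapq
import itertools
import math

Edges = dict[tuple[str, str], float]


def _neighbors(edges: Edges) -> dict[str, dict[str, float]]:
    adj: dict[str, dict[str, float]] = {}
    for (u, v), d in edges.items():
        adj.setdefault(u, {})[v] = d
        adj.setdefault(v, {})[u] = d
    return adj


def graph_as_edges(residue_graph) -> tuple[list[str], Edges]:
    """Extract plain node list and edge dict from a ResidueGraph."""
    nodes = list(residue_graph.graph.nodes)
    edges = {
        (u, v): data["distance"]
        for u, v, data in residue_graph.graph.edges(data=True)
    }
    return nodes, edges


def all_simple_paths(adj, source, target):
    """DFS enumeration of all simple paths with their total distance."""
    stack = [(source, [source], 0.0)]
    while stack:
        node, path, dist = stack.pop()
        if node == target:
            yield path, dist
            continue
        for nbr, d in adj.get(node, {}).items():
            if nbr not in path:
                stack.append((nbr, path + [nbr], dist + d))


def enumerate_shortest_paths(nodes, edges: Edges, source, target,
                             rel_tol: float = 1e-9):
    """All co-minimal simple paths between source and target."""
    adj = _neighbors(edges)
    paths = list(all_simple_paths(adj, source, target))
    if not paths:
        return [], math.inf
    best = min(d for _, d in paths)
    tol = rel_tol * max(1.0, abs(best))
    minimal = [p for p, d in paths if d <= best + tol]
    return minimal, best


def components(nodes, edges: Edges) -> list[set]:
    adj = _neighbors(edges)
    seen: set = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            n = frontier.pop()
            for nbr in adj.get(n, {}):
                if nbr not in comp:
                    comp.add(nbr)
                    frontier.append(nbr)
        seen |= comp
        comps.append(comp)
    return comps


def oracle_betweenness(nodes, edges: Edges) -> dict[str, float]:
    """Normalized betweenness by exhaustive shortest-path enumeration.

    For every unordered pair (j, k) the fraction of co-minimal paths
    through each interior node is accumulated; each node is normalized
    by (N-1)(N-2)/2 of its connected component.
    """
    raw = {n: 0.0 for n in nodes}
    comps = components(nodes, edges)
    for comp in comps:
        for j, k in itertools.combinations(sorted(comp), 2):
            minimal, _ = enumerate_shortest_paths(nodes, edges, j, k)
            if not minimal:
                continue
            g_jk = len(minimal)
            for path in minimal:
                for interior in path[1:-1]:
                    raw[interior] += 1.0 / g_jk
    out = {}
    for comp in comps:
        n = len(comp)
        denom = (n - 1) * (n - 2) / 2.0
        for node in comp:
            out[node] = raw[node] / denom if denom > 0 else 0.0
    return out


def oracle_raw_betweenness(nodes, edges: Edges) -> dict[str, float]:
    """Unnormalized fractional interior-traversal counts."""
    raw = {n: 0.0 for n in nodes}
    for comp in components(nodes, edges):
        for j, k in itertools.combinations(sorted(comp), 2):
            minimal, _ = enumerate_shortest_paths(nodes, edges, j, k)
            g_jk = len(minimal)
            for path in minimal:
                for interior in path[1:-1]:
                    raw[interior] += 1.0 / g_jk
    return raw


def dijkstra(adj, source) -> dict[str, float]:
    dist = {source: 0.0}
    heap = [(0.0, source)]
    done: set = set()
    while heap:
        d, node = heapq.heappop(heap)
        if node in done:
            continue
        done.add(node)
        for nbr, w in adj.get(node, {}).items():
            nd = d + w
            if nd < dist.get(nbr, math.inf):
                dist[nbr] = nd
                heapq.heappush(heap, (nd, nbr))
    return dist


def oracle_shortest_distance(nodes, edges: Edges, source, target) -> float:
    adj = _neighbors(edges)
    return dijkstra(adj, source).get(target, math.inf)


def oracle_aspl(nodes, edges: Edges) -> float:
    """Mean shortest-path distance over reachable unordered pairs."""
    adj = _neighbors(edges)
    total, count = 0.0, 0
    for i, source in enumerate(nodes):
        dist = dijkstra(adj, source)
        for target in nodes[i + 1:]:
            if target in dist:
                total += dist[target]
                count += 1
    return total / count if count else 0.0


def quaternion_superpose_rmsd(mobile, target) -> float:
    """Optimal-superposition RMSD via Horn's quaternion method."""
    import numpy as np

    x = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    y = np.asarray(target, float) - np.mean(target, axis=0)
    sxx = x.T @ y
    sxx_t = sxx.T
    a = sxx - sxx_t
    delta = np.array([a[1, 2], a[2, 0], a[0, 1]])
    k = np.empty((4, 4))
    k[0, 0] = np.trace(sxx)
    k[0, 1:] = delta
    k[1:, 0] = delta
    k[1:, 1:] = sxx + sxx_t - np.trace(sxx) * np.eye(3)
    lam = np.linalg.eigvalsh(k)[-1]
    n = x.shape[0]
    msd = max(((x ** 2).sum() + (y ** 2).sum() - 2.0 * lam) / n, 0.0)
    return float(np.sqrt(msd))


def random_connected_graph(rng, n_max: int = 8):
    """Seeded random connected weighted graph (nodes 'n0'..'n{k-1}')."""
    import numpy as np

    n = int(rng.integers(4, n_max + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges: Edges = {}
    # random spanning tree ensures connectivity
    order = list(rng.permutation(n))
    for i in range(1, n):
        u = nodes[order[i]]
        v = nodes[order[int(rng.integers(0, i))]]
        edges[(u, v)] = float(rng.uniform(0.2, 2.0))
    for i, j in itertools.combinations(range(n), 2):
        u, v = nodes[i], nodes[j]
        if (u, v) in edges or (v, u) in edges:
            continue
        if rng.random() < 0.4:
            edges[(u, v)] = float(rng.uniform(0.2, 2.0))
    return nodes, edges


def edges_to_residue_graph(nodes, edges: Edges):
    """Wrap plain nodes/edges as a ResidueGraph (g = exp(-d))."""
    import math as _math

    import networkx as nx

    from allonet.network import ResidueGraph

    g = nx.Graph()
    aa = "ACDEFGHIKLMNPQRSTVWY"
    for i, node in enumerate(nodes):
        g.add_node(node, aa=aa[i % 20])
    for (u, v), d in edges.items():
        g.add_edge(u, v, g=_math.exp(-d), distance=d, occupancy=1.0)
    return ResidueGraph(graph=g)
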