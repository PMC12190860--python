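"""Dynamically weighted residue interaction networks.

Residues are nodes; an edge joins every residue pair whose ensemble
contact occupancy reaches a threshold tau, plus sequence-adjacent
residues of the same chain (communication physically propagates through
the backbone, and betweenness presumes meaningful path structure). Each
edge carries a coupling g in (0, 1] — the generalized correlation or
|DCCM| of the pair, optionally mixed with min-max-normalized
coevolutionary mutual information — and a communication distance
d = -ln(g), so strongly coupled pairs are close.

Shortest-path betweenness centrality (SPC) of node i is the sum over
node pairs (j, k), j != i != k, of the fraction of minimal-distance
paths between j and k that pass through i, normalized by
(N - 1)(N - 2) / 2 within i's connected component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .dynamics import ContactOccupancyMap, CorrelationMatrix, ResidueProfile

#: Couplings are clamped to this range before the -ln transform, capping
#: any single-edge distance at ln(100).
G_FLOOR = 0.01
G_CEIL = 1.0 - 1e-9


@dataclass
class ResidueGraph:
    """Weighted undirected residue graph.

    Wraps a :class:`networkx.Graph` whose edges carry ``occupancy``,
    coupling ``g`` and ``distance`` (= -ln g) attributes; nodes may carry
    a one-letter ``aa`` attribute used by reweighting perturbations.
    """

    graph: nx.Graph
    build_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError("self-edges are not allowed")
            d = data.get("distance")
            g = data.get("g")
            if g is None or not (0 < g <= 1):
                raise ValueError(f"edge ({u}, {v}) coupling must be in (0,1]")
            if d is None or abs(d - (-np.log(g))) > 1e-12:
                raise ValueError(
                    f"edge ({u}, {v}) distance is not -ln(g)"
                )

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def copy(self) -> "ResidueGraph":
        return ResidueGraph(graph=self.graph.copy(),
                            build_options=dict(self.build_options))


@dataclass
class CentralityProfile:
    """Normalized betweenness (spc) plus raw fractional pair counts."""

    residue_labels: list[str]
    spc: np.ndarray
    raw_spc: np.ndarray

    def as_profile(self) -> ResidueProfile:
        return ResidueProfile(residue_labels=self.residue_labels,
                              values=self.spc, statistic="spc")


def clamp_coupling(g: np.ndarray | float) -> np.ndarray | float:
    return np.clip(g, G_FLOOR, G_CEIL)


def _minmax_normalize(m: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(m), np.nanmax(m)
    if hi - lo < 1e-15:
        return np.full_like(m, 0.5)
    return (m - lo) / (hi - lo)


def build_residue_graph(occupancy: ContactOccupancyMap,
                        coupling: CorrelationMatrix,
                        tau: float = 0.5,
                        lam: float = 0.0,
                        coev_mi: np.ndarray | None = None,
                        residue_aa: dict[str, str] | None = None,
                        chain_of: list[str] | None = None) -> ResidueGraph:
    """Build the residue interaction graph from occupancy and coupling.

    Edges join pairs with ``occupancy >= tau``; the coupling is
    ``g = (1 - lam) * g_dyn + lam * g_coev`` with ``g_dyn`` the absolute
    DCCM (signed input) or the generalized coefficient, and ``g_coev``
    the min-max-normalized mutual information. Consecutive residues of
    the same chain are always connected (backbone augmentation) with
    their computed coupling. ``chain_of`` gives each residue's chain; if
    omitted it is parsed from ``chain:resnum`` labels.
    """
    if occupancy.residue_labels != coupling.residue_labels:
        raise ValueError("occupancy and coupling labels differ")
    if not 0 <= tau <= 1:
        raise ValueError("tau must lie in [0, 1]")
    if not 0 <= lam <= 1:
        raise ValueError("lambda must lie in [0, 1]")
    if lam > 0 and coev_mi is None:
        raise ValueError("lambda > 0 requires a coevolutionary MI matrix")

    labels = occupancy.residue_labels
    n = len(labels)
    g_dyn = np.abs(coupling.values) if coupling.kind == "signed_dccm" \
        else coupling.values.copy()
    if coev_mi is not None:
        coev_mi = np.asarray(coev_mi, dtype=float)
        if coev_mi.shape != (n, n):
            raise ValueError("coev_mi shape does not match labels")
        g_coev = _minmax_normalize(coev_mi)
        g_mix = (1.0 - lam) * g_dyn + lam * g_coev
    else:
        g_mix = g_dyn
    g_mix = clamp_coupling(g_mix)

    if chain_of is None:
        chain_of = [label.split(":", 1)[0] for label in labels]

    graph = nx.Graph()
    for i, label in enumerate(labels):
        attrs = {}
        if residue_aa is not None and label in residue_aa:
            attrs["aa"] = residue_aa[label]
        graph.add_node(label, **attrs)

    def add_edge(i: int, j: int, backbone: bool) -> None:
        g = float(g_mix[i, j])
        graph.add_edge(labels[i], labels[j], occupancy=float(
            occupancy.values[i, j]), g=g, distance=float(-np.log(g)),
            backbone=backbone)

    iu, ju = np.where(np.triu(occupancy.values >= tau, k=1))
    for i, j in zip(iu, ju):
        add_edge(int(i), int(j), backbone=False)
    for i in range(n - 1):
        if chain_of[i] == chain_of[i + 1] and \
                not graph.has_edge(labels[i], labels[i + 1]):
            add_edge(i, i + 1, backbone=True)

    return ResidueGraph(graph=graph, build_options={
        "tau": tau, "lambda": lam,
        "coupling_kind": coupling.kind,
        "occupancy_cutoff": occupancy.cutoff,
        "atom_mode": occupancy.atom_mode,
        "clamp": [G_FLOOR, G_CEIL],
        "coevolution_mixed": coev_mi is not None,
    })


def compute_spc(graph: ResidueGraph) -> CentralityProfile:
    """Normalized shortest-path betweenness centrality per residue.

    All co-minimal paths are counted with multiplicity (Brandes
    accumulation of path-count fractions); normalization is
    (N - 1)(N - 2) / 2 within each connected component, endpoints
    excluded.
    """
    for u, v, d in graph.graph.edges(data="distance"):
        if d is None or d <= 0:
            raise ValueError(f"edge ({u}, {v}) has non-positive distance")
    labels = graph.nodes
    spc = np.zeros(len(labels))
    raw = np.zeros(len(labels))
    pos = {node: i for i, node in enumerate(labels)}
    for comp in nx.connected_components(graph.graph):
        sub = graph.graph.subgraph(comp)
        n = sub.number_of_nodes()
        raw_bc = nx.betweenness_centrality(
            sub, normalized=False, weight="distance"
        )
        denom = (n - 1) * (n - 2) / 2.0
        for node, value in raw_bc.items():
            raw[pos[node]] = value
            spc[pos[node]] = value / denom if denom > 0 else 0.0
    return CentralityProfile(residue_labels=labels, spc=spc, raw_spc=raw)


@dataclass
class PathResult:
    """Outcome of a shortest-path query; ``reachable`` is False for
    disconnected pairs (path empty, distance infinite)."""

    path: list[str]
    distance: float
    reachable: bool = True


def shortest_path(graph: ResidueGraph, source: str, target: str
                  ) -> PathResult:
    """One minimal-distance path, ties broken lexicographically.

    Among co-minimal paths the one whose node sequence is smallest in
    lexicographic order is returned (deterministic).
    """
    g = graph.graph
    if source not in g or target not in g:
        raise ValueError("source or target not in graph")
    if source == target:
        return PathResult(path=[source], distance=0.0)
    try:
        dist_fwd = nx.single_source_dijkstra_path_length(
            g, source, weight="distance")
    except nx.NetworkXNoPath:  # pragma: no cover
        dist_fwd = {}
    if target not in dist_fwd:
        return PathResult(path=[], distance=np.inf, reachable=False)
    dist_bwd = nx.single_source_dijkstra_path_length(
        g, target, weight="distance")
    total = dist_fwd[target]
    # Greedy walk over edges on *some* shortest path, smallest label first.
    path = [source]
    node = source
    tol = 1e-12 * max(1.0, total)
    while node != target:
        candidates = []
        for nbr in g.neighbors(node):
            d_edge = g[node][nbr]["distance"]
            if nbr in dist_bwd and abs(
                    dist_fwd[node] + d_edge + dist_bwd[nbr] - total) <= tol:
                candidates.append(nbr)
        node = min(candidates)
        dist_fwd[node] = total - dist_bwd[node]
        path.append(node)
    return PathResult(path=path, distance=float(total))


def export_graph(graph: ResidueGraph, path: str | Path) -> None:
    """TSV edge list ``node_i node_j occupancy g distance`` with a JSON
    header line carrying the build options; re-importable losslessly.
    Labels containing whitespace are JSON-quoted."""
    path = Path(path)
    lines = ["#" + json.dumps({
        "build_options": graph.build_options,
        "nodes": [[node, data.get("aa")]
                  for node, data in graph.graph.nodes(data=True)],
    })]
    lines.append("node_i\tnode_j\toccupancy\tg\tdistance")

    def fmt(label: str) -> str:
        return json.dumps(label) if any(c.isspace() for c in label) \
            else label

    for u, v, data in graph.graph.edges(data=True):
        lines.append(
            f"{fmt(u)}\t{fmt(v)}\t{data.get('occupancy', 1.0):.17g}\t"
            f"{data['g']:.17g}\t{data['distance']:.17g}"
        )
    path.write_text("\n".join(lines) + "\n")


def import_graph(path: str | Path) -> ResidueGraph:
    """Inverse of :func:`export_graph`."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError("missing JSON header line")
    header = json.loads(lines[0][1:])
    g = nx.Graph()
    for node, aa in header.get("nodes", []):
        if aa is None:
            g.add_node(node)
        else:
            g.add_node(node, aa=aa)

    def unfmt(token: str) -> str:
        return json.loads(token) if token.startswith('"') else token

    for line in lines[2:]:
        if not line.strip():
            continue
        u, v, occ, gval, dist = line.split("\t")
        g.add_edge(unfmt(u), unfmt(v), occupancy=float(occ),
                   g=float(gval), distance=float(dist))
    return ResidueGraph(graph=g,
                        build_options=header.get("build_options", {}))


def alignment_mutual_information(sequences: list[str]) -> np.ndarray:
    """Column-pair mutual information (nats) of an alignment.

    Plug-in estimator from empirical column frequencies; used as the
    coevolutionary coupling matrix when mixing evolutionary information
    into edge weights.
    """
    if not sequences:
        raise ValueError("empty alignment")
    width = len(sequences[0])
    if any(len(s) != width for s in sequences):
        raise ValueError("alignment rows differ in length")
    arr = np.array([[ord(c) for c in s] for s in sequences], dtype=np.int16)
    n_seq = arr.shape[0]
    mi = np.zeros((width, width))
    cols = [np.unique(arr[:, i], return_inverse=True) for i in range(width)]
    for i in range(width):
        ui, inv_i = cols[i]
        pi = np.bincount(inv_i) / n_seq
        for j in range(i + 1, width):
            uj, inv_j = cols[j]
            pj = np.bincount(inv_j) / n_seq
            joint = np.zeros((ui.size, uj.size))
            np.add.at(joint, (inv_i, inv_j), 1.0)
            joint /= n_seq
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = joint / (pi[:, None] * pj[None, :])
                terms = np.where(joint > 0, joint * np.log(ratio), 0.0)
            mi[i, j] = mi[j, i] = max(terms.sum(), 0.0)
    return mi
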