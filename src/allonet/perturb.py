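"""Network-based mutational profiling of allosteric hotspots.

Each residue node i is perturbed by all 19 substitutions j; the change
of a global network observable — the average shortest-path length
(ASPL, the characteristic path length) or the node betweenness profile —
defines

    dL_i = < |dL_i^(node j)|^2 >_j         (mean over mutations)
    Z_i  = (dL_i - <dL>) / sigma

with the mean and population standard deviation taken over nodes.
Residues whose mutation most degrades network communication stand out
as high-Z allosteric hotspots.

Two perturbation modes are provided: ``remove`` deletes the node (all
19 substitutions then give the same change — the classic node-removal
centrality), and ``reweight`` multiplies each incident edge's coupling
by a substitution-similarity factor s(wt, j) in (0, 1], so conservative
substitutions perturb communication less than drastic ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .ensemble_io import AA_ORDER
from .network import CentralityProfile, ResidueGraph, clamp_coupling, \
    compute_spc

logger = logging.getLogger(__name__)


@dataclass
class SubstitutionSimilarity:
    """20 x 20 similarity s(a, b) in (0, 1] with unit diagonal.

    The default is derived from the BLOSUM62 log-odds matrix through the
    normalized odds ratio s(a, b) = 2^{(B(a,b) - (B(a,a)+B(b,b))/2) / 2},
    clipped to (0, 1]: identical residues score 1, conservative pairs
    stay close to 1, drastic changes approach 0.
    """

    table: np.ndarray
    source: str = "custom"

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.shape != (20, 20):
            raise ValueError("similarity table must be 20 x 20")
        if not np.allclose(t, t.T):
            raise ValueError("similarity table must be symmetric")
        if not np.allclose(np.diag(t), 1.0):
            raise ValueError("similarity diagonal must be exactly 1")
        if np.any(t <= 0) or np.any(t > 1):
            raise ValueError("similarities must lie in (0, 1]")
        self.table = t

    def s(self, a: str, b: str) -> float:
        return float(self.table[AA_ORDER.index(a), AA_ORDER.index(b)])


def blosum_similarity() -> SubstitutionSimilarity:
    """Default similarity table from BLOSUM62 (see class docstring)."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    t = np.empty((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            odds = blosum[a, b] - (blosum[a, a] + blosum[b, b]) / 2.0
            t[i, j] = 2.0 ** (odds / 2.0)
    t = np.minimum(t, 1.0)
    np.fill_diagonal(t, 1.0)
    return SubstitutionSimilarity(table=t, source="blosum62_odds")


@dataclass
class PerturbationProfile:
    """Per-node dL and Z from mutational network perturbation."""

    residue_labels: list[str]
    per_mutation_delta: np.ndarray     # nodes x 19
    delta_L: np.ndarray
    z: np.ndarray
    observable: str = "aspl"
    mode: str = "remove"
    aggregation: str = "mean_square"

    def __post_init__(self) -> None:
        n = len(self.residue_labels)
        self.per_mutation_delta = np.asarray(self.per_mutation_delta, float)
        self.delta_L = np.asarray(self.delta_L, float)
        self.z = np.asarray(self.z, float)
        if self.per_mutation_delta.shape != (n, 19):
            raise ValueError("per_mutation_delta must be nodes x 19")
        if self.delta_L.shape != (n,) or self.z.shape != (n,):
            raise ValueError("profile vectors must match node count")


def _zscore(values: np.ndarray) -> np.ndarray:
    sigma = values.std()  # population standard deviation
    if sigma == 0.0:
        return np.zeros_like(values)
    return (values - values.mean()) / sigma


def _distance_matrix(graph: ResidueGraph) -> tuple[np.ndarray, list[str]]:
    nodes = graph.nodes
    pos = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    adj = np.full((n, n), np.inf)
    for u, v, d in graph.graph.edges(data="distance"):
        adj[pos[u], pos[v]] = adj[pos[v], pos[u]] = d
    return adj, nodes


def _aspl_from_adjacency(adj: np.ndarray) -> tuple[float, bool]:
    """Mean shortest-path distance over reachable ordered pairs.

    Returns ``(aspl, connected)``; unreachable pairs are excluded from
    the mean.
    """
    n = adj.shape[0]
    if n == 0:
        raise ValueError("empty graph has no path length")
    if n == 1:
        return 0.0, True
    dist = _csgraph_shortest_path(adj, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    if not finite.any():
        return 0.0, False
    return float(dist[finite].mean()), bool(finite.all())


def graph_observable(graph: ResidueGraph, observable: str = "aspl"):
    """Global network observable: scalar ASPL or the per-node SPC vector.

    ASPL averages the shortest-path distance over all reachable ordered
    node pairs; for a disconnected graph unreachable pairs are simply
    excluded.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    if observable == "aspl":
        adj, _ = _distance_matrix(graph)
        return _aspl_from_adjacency(adj)[0]
    if observable == "node_spc":
        return compute_spc(graph)
    raise ValueError(f"unknown observable {observable!r}")


def perturb_node(graph: ResidueGraph, node: str, mutation: str,
                 mode: str = "remove",
                 similarity: SubstitutionSimilarity | None = None
                 ) -> ResidueGraph:
    """Perturbed copy of the graph for one substitution at one node.

    ``remove`` deletes the node and its incident edges (the mutation
    argument is irrelevant); ``reweight`` multiplies each incident
    edge's coupling g by s(wildtype, mutation), re-clamps, and
    recomputes the -ln distance, which preserves connectivity because
    the coupling floor caps every distance.
    """
    if node not in graph.graph:
        raise ValueError(f"unknown node {node!r}")
    out = graph.copy()
    if mode == "remove":
        out.graph.remove_node(node)
        return out
    if mode != "reweight":
        raise ValueError(f"unknown mode {mode!r}")
    if similarity is None:
        similarity = blosum_similarity()
    wt = graph.graph.nodes[node].get("aa")
    if wt is None:
        raise ValueError(f"node {node!r} has no wild-type aa attribute")
    if mutation == wt:
        raise ValueError("reweight mutation must differ from wild type")
    factor = similarity.s(wt, mutation)
    for nbr in out.graph.neighbors(node):
        data = out.graph[node][nbr]
        g_new = float(clamp_coupling(data["g"] * factor))
        data["g"] = g_new
        data["distance"] = float(-np.log(g_new))
    return out


def _spc_change(before: CentralityProfile, after: CentralityProfile
                ) -> float:
    """RMS per-node SPC change over nodes present in both graphs."""
    pos = {n: i for i, n in enumerate(after.residue_labels)}
    common = [n for n in before.residue_labels if n in pos]
    if not common:
        return 0.0
    b = np.array([before.spc[before.residue_labels.index(n)]
                  for n in common])
    a = np.array([after.spc[pos[n]] for n in common])
    return float(np.sqrt(((a - b) ** 2).mean()))


def _aggregate(deltas: np.ndarray, aggregation: str) -> np.ndarray:
    if aggregation == "mean_square":
        return (np.abs(deltas) ** 2).mean(axis=1)
    if aggregation == "rms":
        return np.sqrt((np.abs(deltas) ** 2).mean(axis=1))
    if aggregation == "mean_abs":
        return np.abs(deltas).mean(axis=1)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def profile_perturbations(graph: ResidueGraph, mode: str = "remove",
                          observable: str = "aspl",
                          similarity: SubstitutionSimilarity | None = None,
                          aggregation: str = "mean_square"
                          ) -> PerturbationProfile:
    """dL and Z profile from systematic perturbation of every node.

    For each node i and each of its 19 substitutions j the observable
    change dL_i^(node j) = L(perturbed) - L(original) is recorded (for
    the vector-valued ``node_spc`` observable, its RMS per-node change).
    Node aggregation follows ``aggregation`` (mean of squared changes by
    default), and Z standardizes dL over nodes with the population
    standard deviation. In remove mode the 19 substitutions coincide, so
    a single removal per node is computed.
    """
    nodes = graph.nodes
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    if mode == "reweight" and similarity is None:
        similarity = blosum_similarity()

    if observable == "aspl":
        adj, _ = _distance_matrix(graph)
        base = _aspl_from_adjacency(adj)[0]
    elif observable == "node_spc":
        base_profile = compute_spc(graph)
    else:
        raise ValueError(f"unknown observable {observable!r}")

    deltas = np.zeros((n, 19))
    disconnect_logged = False
    for i, node in enumerate(nodes):
        if mode == "remove":
            if observable == "aspl":
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                sub = adj[np.ix_(mask, mask)]
                value, connected = _aspl_from_adjacency(sub)
                if not connected and not disconnect_logged:
                    logger.info(
                        "node removal disconnects the graph; ASPL is "
                        "averaged over reachable pairs only"
                    )
                    disconnect_logged = True
                change = value - base
            else:
                perturbed = perturb_node(graph, node, "A", mode="remove")
                change = _spc_change(base_profile, compute_spc(perturbed))
            deltas[i, :] = change
        else:
            wt = graph.graph.nodes[node].get("aa")
            if wt is None:
                raise ValueError(
                    f"node {node!r} has no wild-type aa attribute; "
                    "reweight mode needs residue identities (build the "
                    "graph with residue_aa, or use remove mode)"
                )
            targets = [a for a in AA_ORDER if a != wt]
            for j, aa in enumerate(targets):
                perturbed = perturb_node(graph, node, aa, mode="reweight",
                                         similarity=similarity)
                if observable == "aspl":
                    p_adj, _ = _distance_matrix(perturbed)
                    deltas[i, j] = _aspl_from_adjacency(p_adj)[0] - base
                else:
                    deltas[i, j] = _spc_change(
                        base_profile, compute_spc(perturbed))

    delta_l = _aggregate(deltas, aggregation)
    return PerturbationProfile(
        residue_labels=nodes, per_mutation_delta=deltas,
        delta_L=delta_l, z=_zscore(delta_l),
        observable=observable, mode=mode, aggregation=aggregation,
    )


def ensemble_average_profile(profiles: list[PerturbationProfile]
                             ) -> PerturbationProfile:
    """Average snapshot-level profiles; dL is averaged node-wise across
    profiles and Z re-standardized over nodes."""
    if not profiles:
        raise ValueError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if p.residue_labels != first.residue_labels:
            raise ValueError("profiles have different residue labels")
        if p.mode != first.mode or p.observable != first.observable:
            raise ValueError("profiles mix modes or observables")
        if p.aggregation != first.aggregation:
            raise ValueError("profiles mix aggregations")
    delta = np.mean([p.delta_L for p in profiles], axis=0)
    per_mut = np.mean([p.per_mutation_delta for p in profiles], axis=0)
    return PerturbationProfile(
        residue_labels=first.residue_labels,
        per_mutation_delta=per_mut, delta_L=delta, z=_zscore(delta),
        observable=first.observable, mode=first.mode,
        aggregation=first.aggregation,
    )


def rank_hotspots(profile: PerturbationProfile,
                  z_min: float = 1.0) -> list[str]:
    """Residues with Z >= z_min, descending Z, ties by residue ordinal."""
    order = sorted(
        range(len(profile.residue_labels)),
        key=lambda i: (-profile.z[i], i),
    )
    return [profile.residue_labels[i] for i in order
            if profile.z[i] >= z_min]
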