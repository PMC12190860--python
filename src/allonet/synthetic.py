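"""Synthetic ensembles, complexes, alignments and graphs with ground truth.

Every pipeline stage is testable without external data: toy bead
structures (C-alpha plus a pseudo side-chain bead), Gaussian ensembles
sampled from an isotropic elastic-network (GNM) covariance with an
analytic DCCM, two-chain complexes with a planted interface, dumbbell
graphs with a planted communication bottleneck, and multiple-sequence
alignments with planted covarying column pairs.

The GNM covariance is Kirchhoff-based with three identical Cartesian
blocks: Gamma_ij = -1 for C-alpha pairs within the cutoff, diagonal set
to minus the row sum, and the per-axis displacement covariance is
``kT / k_spring`` times the pseudo-inverse of Gamma (null space removed
by eigenvalue thresholding). Sequence-adjacent residues of a chain are
always linked so the network cannot disconnect along the backbone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .ensemble_io import (
    AA_ORDER,
    AtomRecord,
    ConformationalEnsemble,
    ONE_TO_THREE,
    ReferenceStructure,
)

_STANDARD_CYCLE = [ONE_TO_THREE[a] for a in AA_ORDER]


@dataclass
class ENMSpec:
    """Parameters of the elastic-network sampler.

    cutoff : angstrom, C-alpha pairs closer than this are springs.
    spring_constant : energy / angstrom^2 (arbitrary energy unit).
    kT : same energy unit; sets the fluctuation amplitude.
    """

    cutoff: float = 12.0
    spring_constant: float = 1.0
    kT: float = 0.5
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.spring_constant <= 0:
            raise ValueError("cutoff and spring_constant must be positive")
        if self.kT < 0:
            raise ValueError("kT must be non-negative")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


@dataclass
class GroundTruth:
    """Analytic quantities carried alongside a synthetic fixture."""

    covariance: np.ndarray | None = None       # 3N x 3N
    analytic_dccm: np.ndarray | None = None    # N x N
    planted_interface: list[str] = field(default_factory=list)
    planted_bottleneck: list[str] = field(default_factory=list)


def _make_structure(ca: np.ndarray, chain_ids: list[str],
                    residue_numbers: list[str],
                    names: list[str]) -> ReferenceStructure:
    """Bead model: C-alpha plus a pseudo side-chain bead (CB) 1.5 A off
    the local chain axis. Glycine gets no side-chain bead."""
    n = ca.shape[0]
    atoms: list[AtomRecord] = []
    for i in range(n):
        atoms.append(AtomRecord(
            chain_id=chain_ids[i], residue_number=residue_numbers[i],
            residue_name=names[i], atom_name="CA", element="C",
            position=ca[i].copy(),
        ))
        if names[i] == "GLY":
            continue
        # Perpendicular offset to the preceding CA-CA direction.
        prev = ca[i - 1] if i > 0 and chain_ids[i - 1] == chain_ids[i] \
            else ca[i] - np.array([1.0, 0.0, 0.0])
        axis = ca[i] - prev
        norm = np.linalg.norm(axis)
        axis = axis / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        perp = np.cross(axis, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(axis, [0.0, 1.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        atoms.append(AtomRecord(
            chain_id=chain_ids[i], residue_number=residue_numbers[i],
            residue_name=names[i], atom_name="CB", element="C",
            position=ca[i] + 1.5 * perp,
        ))
    return ReferenceStructure(atoms=atoms)


def _compact_cluster(n: int, rng: np.random.Generator,
                     min_sep: float = 3.8) -> np.ndarray:
    """Seeded compact point cloud with pairwise separation >= min_sep.

    Points sit on a jittered cubic lattice (spacing min_sep + 0.4 A,
    jitter +-0.2 A), taking the n sites nearest the centroid, so the
    cloud is globular and the separation guarantee holds for any n.
    """
    spacing = min_sep + 0.4
    side = int(np.ceil(n ** (1 / 3))) + 1
    grid = np.arange(-side, side + 1) * spacing
    sites = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
    order = np.argsort((sites ** 2).sum(axis=1), kind="stable")
    pts = sites[order[:n]].astype(float)
    pts += rng.uniform(-0.2, 0.2, size=pts.shape)
    return pts - pts.mean(axis=0)


def build_toy_structure(n_residues: int, geometry: str = "extended",
                        seed: int = 0,
                        sequence: str | None = None) -> ReferenceStructure:
    """Deterministic toy structure of ``n_residues`` beads.

    geometry:
      ``extended`` — straight chain, consecutive C-alpha spacing 3.8 A;
      ``helix`` — ideal alpha-helical spiral (2.3 A radius, 1.5 A rise,
      100 degrees per residue);
      ``dumbbell`` — two compact clusters joined by a 3-residue linker,
      so the linker is the only short-range path between the halves.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(seed)
    if sequence is not None:
        if len(sequence) != n_residues:
            raise ValueError("sequence length must equal n_residues")
        names = [ONE_TO_THREE[a] for a in sequence]
    else:
        names = [
            _STANDARD_CYCLE[i % 20] for i in range(n_residues)
        ]
    if geometry == "extended":
        ca = np.zeros((n_residues, 3))
        ca[:, 0] = 3.8 * np.arange(n_residues)
    elif geometry == "helix":
        t = np.deg2rad(100.0) * np.arange(n_residues)
        ca = np.column_stack([
            2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n_residues)
        ])
    elif geometry == "dumbbell":
        n_linker = 3
        n_a = (n_residues - n_linker) // 2
        n_b = n_residues - n_linker - n_a
        if min(n_a, n_b) < 1:
            raise ValueError("dumbbell needs at least 5 residues")
        left = _compact_cluster(n_a, rng)
        right = _compact_cluster(n_b, rng)
        gap = 4.0 * (n_linker + 1)
        left -= left.max(axis=0) * [1, 0, 0] + [1.0, 0.0, 0.0]
        right -= right.min(axis=0) * [1, 0, 0] - [gap + 1.0, 0.0, 0.0]
        linker = np.column_stack([
            np.linspace(2.0, gap - 2.0, n_linker),
            np.zeros(n_linker), np.zeros(n_linker),
        ])
        ca = np.vstack([left, linker, right])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    chain_ids = ["A"] * n_residues
    residue_numbers = [str(i + 1) for i in range(n_residues)]
    return _make_structure(ca, chain_ids, residue_numbers, names)


def _kirchhoff(ca: np.ndarray, chain_ids: list[str],
               cutoff: float) -> np.ndarray:
    from scipy.spatial.distance import squareform, pdist

    n = ca.shape[0]
    contact = squareform(pdist(ca)) <= cutoff
    np.fill_diagonal(contact, False)
    for i in range(n - 1):  # backbone springs keep chains connected
        if chain_ids[i] == chain_ids[i + 1]:
            contact[i, i + 1] = contact[i + 1, i] = True
    gamma = -contact.astype(float)
    np.fill_diagonal(gamma, contact.sum(axis=1))
    return gamma


def gnm_covariance(structure: ReferenceStructure,
                   spec: ENMSpec,
                   allow_disconnected: bool = False) -> np.ndarray:
    """3N x 3N displacement covariance of the isotropic GNM.

    Per-axis covariance is ``kT / k`` times the Kirchhoff pseudo-inverse;
    the three Cartesian axes are independent and identical. A spatially
    disconnected network is an error unless ``allow_disconnected`` is
    set, in which case each rigid body fluctuates about its own mean
    (one null mode dropped per component).
    """
    ca = structure.reference_coordinates()[structure.ca_index]
    chains = structure.chain_of_residue()
    gamma = _kirchhoff(ca, chains, spec.cutoff)
    evals, evecs = np.linalg.eigh(gamma)
    thresh = 1e-8 * evals.max()
    keep = evals > thresh
    if (~keep).sum() > 1 and not allow_disconnected:
        raise ValueError(
            "elastic network is disconnected; increase the cutoff"
        )
    inv = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T
    per_axis = spec.kT / spec.spring_constant * inv
    n = ca.shape[0]
    cov = np.zeros((3 * n, 3 * n))
    for d in range(3):
        cov[d::3, d::3] = per_axis
    return cov


def sample_enm_ensemble(structure: ReferenceStructure, spec: ENMSpec,
                        allow_disconnected: bool = False
                        ) -> tuple[ConformationalEnsemble, GroundTruth]:
    """Draw Gaussian frames from the GNM covariance about the reference.

    C-alpha displacements are sampled from the analytic covariance; each
    residue's side-chain bead rides rigidly with its C-alpha. Ground truth
    carries the 3N x 3N covariance and the analytic DCCM.
    """
    from .dynamics import dccm_from_covariance

    cov = gnm_covariance(structure, spec, allow_disconnected)
    n = structure.n_residues
    per_axis = cov[0::3, 0::3]
    evals, evecs = np.linalg.eigh(per_axis)
    evals = np.clip(evals, 0.0, None)
    root = evecs * np.sqrt(evals)
    rng = np.random.default_rng(spec.seed)
    # Independent identical sampling per Cartesian axis.
    z = rng.standard_normal((spec.n_frames, 3, n))
    ca_disp = np.einsum("nk,fdk->fnd", root, z)

    ref = structure.reference_coordinates()
    frames = np.broadcast_to(ref, (spec.n_frames,) + ref.shape).copy()
    atom_residue = np.array([
        structure.residue_index[(a.chain_id, a.residue_number)]
        for a in structure.atoms
    ])
    frames += ca_disp[:, atom_residue, :]
    ens = ConformationalEnsemble(reference=structure, frames=frames)
    truth = GroundTruth(
        covariance=cov, analytic_dccm=dccm_from_covariance(cov)
    )
    return ens, truth


def make_toy_complex(n_a: int, n_b: int, n_interface_contacts: int,
                     seed: int = 0, n_frames: int = 100,
                     enm: ENMSpec | None = None
                     ) -> tuple[ConformationalEnsemble, GroundTruth]:
    """Two-chain complex with exactly ``n_interface_contacts`` planted
    interface residues on chain A.

    The planted A-residues protrude toward chain B with heavy atoms within
    4.5 A of B in the reference; all other A-residues stay beyond 6.5 A.
    The ensemble is sampled via the GNM over the whole complex; modest
    ``kT`` keeps fluctuations small enough that contact occupancy cleanly
    separates planted from unplanted pairs.
    """
    if n_interface_contacts > min(n_a, n_b):
        raise ValueError("more planted contacts than residues in a chain")
    if n_a < 4 or n_b < 4:
        raise ValueError("each chain needs at least 4 residues")
    if enm is None:
        enm = ENMSpec(cutoff=12.0, spring_constant=1.0, kT=0.1,
                      n_frames=n_frames, seed=seed)
    k = n_interface_contacts
    for attempt in range(50):
        rng = np.random.default_rng((seed, attempt))
        a_pts = _compact_cluster(n_a, rng)
        b_pts = _compact_cluster(n_b, rng)
        # Chain A sits at negative x; planted residues protrude toward B.
        a_pts -= [a_pts[:, 0].max() + 1.0, 0.0, 0.0]
        order = np.argsort(-a_pts[:, 0])
        planted = np.sort(order[:k])
        a_pts[planted, 0] += 2.5
        if k > 0:
            gap = 4.0  # CA-CA spacing across the interface
            anchors = a_pts[planted] + [gap, 0.0, 0.0]
            b_rest = b_pts[k:] if n_b > k else np.empty((0, 3))
            if b_rest.size:
                b_rest = b_rest - [b_rest[:, 0].min(), 0.0, 0.0]
                b_rest += [anchors[:, 0].max() + 5.0, 0.0, 0.0]
            b_all = np.vstack([anchors, b_rest])
        else:
            b_all = b_pts - [b_pts[:, 0].min(), 0.0, 0.0]
            b_all += [25.0, 0.0, 0.0]
        ca = np.vstack([a_pts, b_all])
        chain_ids = ["A"] * n_a + ["B"] * n_b
        numbers = [str(i + 1) for i in range(n_a)] + \
                  [str(i + 1) for i in range(n_b)]
        names = [_STANDARD_CYCLE[i % 20] for i in range(n_a + n_b)]
        structure = _make_structure(ca, chain_ids, numbers, names)
        if _interface_ok(structure, n_a, planted, k):
            break
    else:
        raise ValueError("could not pack a complex with the requested "
                         "interface after bounded retries")
    # a zero-contact complex is two separate elastic bodies by design
    ens, truth = sample_enm_ensemble(structure, enm,
                                     allow_disconnected=(k == 0))
    labels = structure.residue_labels
    truth.planted_interface = [labels[i] for i in planted]
    return ens, truth


def _interface_ok(structure: ReferenceStructure, n_a: int,
                  planted: np.ndarray, k: int) -> bool:
    """Planted residues within 4.5 A of chain B, all others beyond 6.5 A."""
    from scipy.spatial.distance import cdist

    coords = structure.reference_coordinates()
    chains = structure.chain_of_residue()
    b_atoms = [i for i, a in enumerate(structure.atoms) if a.chain_id == "B"]
    if not b_atoms:
        return True
    planted_set = set(int(p) for p in planted)
    for ordinal in range(n_a):
        if chains[ordinal] != "A":
            continue
        atoms = structure.atoms_of_residue(ordinal)
        dmin = cdist(coords[atoms], coords[b_atoms]).min() if atoms else np.inf
        if ordinal in planted_set:
            if dmin > 4.5:
                return False
        elif dmin < 6.5:
            return False
    return True


def plant_bottleneck_graph(cluster_sizes: tuple[int, ...] = (6, 6),
                           inter_edge_g: float = 0.5,
                           intra_edge_g: float = 0.8,
                           seed: int = 0):
    """Dense clusters joined only through one articulation node.

    Returns ``(ResidueGraph, GroundTruth)`` with the articulation node
    recorded as the planted bottleneck. Intra-cluster couplings are
    jittered around ``intra_edge_g`` (seeded) so shortest paths are
    generically unique.
    """
    from .network import ResidueGraph

    if len(cluster_sizes) < 2:
        raise ValueError("need at least 2 clusters")
    if any(s < 3 for s in cluster_sizes):
        raise ValueError("cluster size must be at least 3")
    if not (0 < inter_edge_g < 1 and 0 < intra_edge_g < 1):
        raise ValueError("edge couplings must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    import networkx as nx

    g = nx.Graph()
    hub = "HUB"
    aa_cycle = itertools.cycle(AA_ORDER)
    g.add_node(hub, aa=next(aa_cycle))
    truth = GroundTruth(planted_bottleneck=[hub])
    for c, size in enumerate(cluster_sizes):
        nodes = [f"C{c}:{i}" for i in range(size)]
        for node in nodes:
            g.add_node(node, aa=next(aa_cycle))
        for u, v in itertools.combinations(nodes, 2):
            jitter = rng.uniform(-0.05, 0.05)
            coupling = float(np.clip(intra_edge_g + jitter, 0.01, 0.99))
            g.add_edge(u, v, g=coupling, occupancy=1.0,
                       distance=-np.log(coupling))
        # The hub is each cluster's only link to the rest of the graph.
        gateway = nodes[0]
        g.add_edge(hub, gateway, g=inter_edge_g, occupancy=1.0,
                   distance=-np.log(inter_edge_g))
    graph = ResidueGraph(graph=g, build_options={
        "generator": "plant_bottleneck_graph",
        "cluster_sizes": list(cluster_sizes),
        "inter_edge_g": inter_edge_g, "intra_edge_g": intra_edge_g,
        "seed": seed,
    })
    return graph, truth


def sample_coupled_msa(n_sequences: int, n_columns: int,
                       coupled_pairs: list[tuple[int, int]],
                       coupling_strength: float, seed: int = 0
                       ) -> tuple[list[str], dict[tuple[int, int], float]]:
    """Alignment with planted covarying column pairs.

    Columns are i.i.d. uniform over the 20 amino acids except the coupled
    pairs: with probability ``coupling_strength`` the second column copies
    the first, otherwise it is drawn independently. Returns the sequences
    and the analytic mutual information (nats) of each planted pair under
    that mixture.
    """
    if not 0 <= coupling_strength <= 1:
        raise ValueError("coupling_strength must lie in [0, 1]")
    flat = [c for pair in coupled_pairs for c in pair]
    if len(set(flat)) != len(flat):
        raise ValueError("coupled pairs must be disjoint")
    if any(c < 0 or c >= n_columns for c in flat):
        raise ValueError("coupled column index out of range")
    rng = np.random.default_rng(seed)
    msa = rng.integers(0, 20, size=(n_sequences, n_columns))
    for (i, j) in coupled_pairs:
        copy = rng.random(n_sequences) < coupling_strength
        msa[copy, j] = msa[copy, i]

    # Analytic MI of the mixture joint p(a,b) = s/20 [a==b] + (1-s)/400.
    s = coupling_strength
    p_same = s / 20.0 + (1.0 - s) / 400.0
    p_diff = (1.0 - s) / 400.0
    mi = 0.0
    if p_same > 0:
        mi += 20 * p_same * np.log(p_same * 400.0)
    if p_diff > 0:
        mi += 380 * p_diff * np.log(p_diff * 400.0)
    truth = {tuple(pair): float(mi) for pair in coupled_pairs}

    seqs = ["".join(AA_ORDER[c] for c in row) for row in msa]
    return seqs, truth


def write_msa_fasta(sequences: list[str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s), id=f"seq{i}", description="")
        for i, s in enumerate(sequences)
    ]
    seqio_write(records, str(path), "fasta")
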