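"""Per-residue dynamics statistics over conformational ensembles.

Implements least-squares superposition, RMSD/RMSF profiles, the dynamic
cross-correlation matrix (DCCM)

    C_ij = <dr_i . dr_j> / (<dr_i^2> <dr_j^2>)^(1/2)

with displacements dr taken about the ensemble-mean C-alpha position, the
mutual-information-based generalized correlation coefficient

    I_ij = 1/2 ln( det(S_i) det(S_j) / det(S_ij) ),
    r_ij = sqrt(1 - exp(-2 I_ij / 3)),

and ensemble contact-occupancy maps used downstream for graph construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .ensemble_io import ConformationalEnsemble, ReferenceStructure

AtomMode = Literal["sidechain_heavy", "all_heavy", "ca_only"]


@dataclass
class CorrelationMatrix:
    """N x N residue-residue coupling matrix.

    ``kind='signed_dccm'`` holds signed correlations in [-1, 1];
    ``kind='generalized'`` holds mutual-information-based coefficients
    in [0, 1]. Diagonal is exactly 1 in both cases.
    """

    values: np.ndarray
    kind: Literal["signed_dccm", "generalized"]
    residue_labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.residue_labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match "
                             f"{n} labels")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        self.values = v


@dataclass
class ContactOccupancyMap:
    """Fraction of frames in which residue pairs are within ``cutoff``."""

    values: np.ndarray
    atom_mode: AtomMode
    cutoff: float
    residue_labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("occupancy must lie in [0, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = v


@dataclass
class ResidueProfile:
    """Named per-residue statistic (RMSF in angstrom, SPC, Z, ...)."""

    residue_labels: list[str]
    values: np.ndarray
    statistic: str = "value"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.residue_labels),):
            raise ValueError("profile length must equal residue count")


def _selection_to_ca_atoms(reference: ReferenceStructure,
                           selection: Sequence[int] | None) -> np.ndarray:
    if selection is None:
        residues = np.arange(reference.n_residues)
    else:
        residues = np.asarray(sorted(set(int(s) for s in selection)))
        if residues.size == 0:
            raise ValueError("selection must be non-empty")
        if residues.min() < 0 or residues.max() >= reference.n_residues:
            raise ValueError("selection out of residue range")
    return np.asarray(reference.ca_index)[residues]


def _kabsch(mobile: np.ndarray, target: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation R and centroids aligning ``mobile`` onto ``target``."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, mc, tc


def superpose_frames(ens: ConformationalEnsemble,
                     selection: Sequence[int] | None = None
                     ) -> ConformationalEnsemble:
    """Rigid-body fit every frame onto the reference structure.

    The least-squares optimal rotation (Kabsch) is computed over the
    C-alpha atoms of ``selection`` (residue ordinals; all residues when
    None) and applied to all atoms of the frame. Returns a new ensemble;
    the input is untouched.
    """
    ca_atoms = _selection_to_ca_atoms(ens.reference, selection)
    if ca_atoms.size < 3:
        raise ValueError("superposition needs at least 3 selected residues")
    target = ens.reference.reference_coordinates()[ca_atoms]
    span = np.linalg.svd(target - target.mean(axis=0), compute_uv=False)
    if span[1] < 1e-8:
        raise ValueError("selected C-alpha atoms are collinear")
    out = np.empty_like(ens.frames)
    for f in range(ens.n_frames):
        rot, mc, tc = _kabsch(ens.frames[f, ca_atoms], target)
        out[f] = (ens.frames[f] - mc) @ rot.T + tc
    return ConformationalEnsemble(
        reference=ens.reference, frames=out,
        frame_labels=list(ens.frame_labels),
    )


def compute_rmsd_series(ens: ConformationalEnsemble,
                        selection: Sequence[int] | None = None,
                        superpose: bool = False) -> np.ndarray:
    """Per-frame C-alpha RMSD (angstrom) to the reference structure."""
    work = superpose_frames(ens, selection) if superpose else ens
    ca_atoms = _selection_to_ca_atoms(work.reference, selection)
    if ca_atoms.size == 0:
        raise ValueError("selection must be non-empty")
    ref = work.reference.reference_coordinates()[ca_atoms]
    diff = work.frames[:, ca_atoms, :] - ref[None]
    return np.sqrt((diff ** 2).sum(axis=2).mean(axis=1))


def compute_rmsf(ens: ConformationalEnsemble) -> ResidueProfile:
    """Per-residue C-alpha RMSF about the ensemble-mean position.

    RMSF_i = sqrt( mean over frames of |r_i - <r_i>|^2 ), in angstrom.
    The ensemble is assumed superposed.
    """
    if ens.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    ca = ens.ca_coordinates()
    disp = ca - ca.mean(axis=0, keepdims=True)
    rmsf = np.sqrt((disp ** 2).sum(axis=2).mean(axis=0))
    return ResidueProfile(
        residue_labels=ens.reference.residue_labels,
        values=rmsf, statistic="rmsf",
    )


def _ca_displacements(ens: ConformationalEnsemble) -> np.ndarray:
    ca = ens.ca_coordinates()
    return ca - ca.mean(axis=0, keepdims=True)


def compute_dccm(ens: ConformationalEnsemble) -> CorrelationMatrix:
    """Signed dynamic cross-correlation matrix of C-alpha displacements.

    Residues with zero fluctuation get zero off-diagonal correlation
    (diagonal 1) with a warning, so that downstream graph construction
    stays total.
    """
    if ens.n_frames < 2:
        raise ValueError("DCCM requires at least 2 frames")
    disp = _ca_displacements(ens)                     # F x N x 3
    inner = np.einsum("fid,fjd->ij", disp, disp) / ens.n_frames
    var = np.diag(inner).copy()
    zero = var <= 0.0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} residues have zero fluctuation; their "
            "correlations are set to 0", stacklevel=2
        )
    denom = np.sqrt(np.where(zero, 1.0, var))
    c = inner / denom[:, None] / denom[None, :]
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    c = (c + c.T) / 2.0
    return CorrelationMatrix(values=c, kind="signed_dccm",
                             residue_labels=ens.reference.residue_labels)


def dccm_from_covariance(cov: np.ndarray) -> np.ndarray:
    """Analytic DCCM from a 3N x 3N displacement covariance matrix.

    C_ij = tr(Sigma_ij) / sqrt(tr(Sigma_ii) tr(Sigma_jj)) where Sigma_ij
    is the 3x3 cross-covariance block of residues i and j.
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0] // 3
    blocks = cov.reshape(n, 3, n, 3)
    inner = np.einsum("idjd->ij", blocks)
    var = np.diag(inner)
    denom = np.sqrt(np.where(var <= 0, 1.0, var))
    c = inner / denom[:, None] / denom[None, :]
    np.fill_diagonal(c, 1.0)
    return np.clip((c + c.T) / 2.0, -1.0, 1.0)


def generalized_correlation_from_covariance(
        cov: np.ndarray, labels: list[str] | None = None
) -> CorrelationMatrix:
    """Generalized correlation matrix from a 3N x 3N covariance.

    Uses the linear-Gaussian mutual information between the two 3-vectors,
    I = 1/2 ln( det(S_i) det(S_j) / det(S_ij) ), mapped to [0, 1) via
    r = sqrt(1 - exp(-2 I / 3)). Pairs with a singular 3x3 marginal get
    r = 0 with a warning.
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0] // 3
    blocks = cov.reshape(n, 3, n, 3).transpose(0, 2, 1, 3)  # i, j, 3, 3
    diag = np.array([blocks[i, i] for i in range(n)])
    sign, logdet = np.linalg.slogdet(diag)
    singular = sign <= 0
    if np.any(singular):
        warnings.warn(
            f"{int(singular.sum())} residues have singular marginal "
            "covariance; their generalized correlations are set to 0",
            stacklevel=2,
        )
    r = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    joint = np.empty((iu.size, 6, 6))
    joint[:, :3, :3] = diag[iu]
    joint[:, 3:, 3:] = diag[ju]
    joint[:, :3, 3:] = blocks[iu, ju]
    joint[:, 3:, :3] = blocks[ju, iu]
    sign_j, logdet_j = np.linalg.slogdet(joint)
    ok = (~singular[iu]) & (~singular[ju]) & (sign_j > 0)
    mi = np.zeros(iu.size)
    mi[ok] = 0.5 * (logdet[iu][ok] + logdet[ju][ok] - logdet_j[ok])
    mi = np.maximum(mi, 0.0)
    # Perfect linear coupling makes the joint singular: r -> 1.
    perfect = (~singular[iu]) & (~singular[ju]) & (sign_j <= 0)
    rvals = np.sqrt(1.0 - np.exp(-2.0 * mi / 3.0))
    rvals[perfect] = 1.0
    rvals[singular[iu] | singular[ju]] = 0.0
    r[iu, ju] = rvals
    r[ju, iu] = rvals
    np.fill_diagonal(r, 1.0)
    r[singular, singular] = 1.0
    return CorrelationMatrix(
        values=r, kind="generalized",
        residue_labels=labels or [str(i) for i in range(n)],
    )


def compute_generalized_correlation(
        ens: ConformationalEnsemble) -> CorrelationMatrix:
    """Generalized correlation estimated from the sample C-alpha covariance."""
    if ens.n_frames < 2:
        raise ValueError("generalized correlation requires >= 2 frames")
    disp = _ca_displacements(ens)                 # F x N x 3
    flat = disp.reshape(ens.n_frames, -1)
    cov = flat.T @ flat / ens.n_frames
    return generalized_correlation_from_covariance(
        cov, labels=ens.reference.residue_labels
    )


def _contact_atom_groups(reference: ReferenceStructure,
                         atom_mode: AtomMode) -> list[np.ndarray]:
    """Atom indices per residue used for contact evaluation.

    ``sidechain_heavy``: heavy atoms beyond the backbone (glycine falls
    back to its C-alpha); ``all_heavy``: all non-hydrogen atoms;
    ``ca_only``: the C-alpha atom.
    """
    backbone = {"N", "CA", "C", "O", "OXT"}
    groups: list[np.ndarray] = []
    for ordinal in range(reference.n_residues):
        atoms = reference.atoms_of_residue(ordinal)
        if atom_mode == "ca_only":
            sel = [reference.ca_index[ordinal]]
        elif atom_mode == "all_heavy":
            sel = [i for i in atoms if not reference.atoms[i].is_hydrogen]
        elif atom_mode == "sidechain_heavy":
            sel = [
                i for i in atoms
                if not reference.atoms[i].is_hydrogen
                and reference.atoms[i].atom_name.strip() not in backbone
            ]
            if not sel:  # glycine contributes its C-alpha
                sel = [reference.ca_index[ordinal]]
        else:
            raise ValueError(f"unknown atom_mode {atom_mode!r}")
        groups.append(np.asarray(sel, dtype=int))
    return groups


def _pad_groups(groups: list[np.ndarray]) -> np.ndarray:
    """Pad per-residue atom index lists to a uniform width (repeating the
    first atom) so residue-pair minima reduce with one vectorized min."""
    width = max(g.size for g in groups)
    return np.stack([
        np.concatenate([g, np.full(width - g.size, g[0])]) for g in groups
    ])


def _min_distance_matrix(frame: np.ndarray, padded: np.ndarray
                         ) -> np.ndarray:
    """N x N matrix of minimal inter-group atom distances in one frame."""
    n, width = padded.shape
    flat = frame[padded.ravel()]
    d = cdist(flat, flat).reshape(n, width, n, width)
    return d.min(axis=(1, 3))


def compute_contact_occupancy(
        ens: ConformationalEnsemble, cutoff: float = 5.0,
        atom_mode: AtomMode = "sidechain_heavy") -> ContactOccupancyMap:
    """Fraction of frames in which residue pairs have any selected-atom
    pair within ``cutoff`` angstrom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    groups = _contact_atom_groups(ens.reference, atom_mode)
    padded = _pad_groups(groups)
    n = ens.n_residues
    counts = np.zeros((n, n))
    for f in range(ens.n_frames):
        dmin = _min_distance_matrix(ens.frames[f], padded)
        counts += dmin <= cutoff
    occ = counts / ens.n_frames
    np.fill_diagonal(occ, 0.0)
    return ContactOccupancyMap(
        values=occ, atom_mode=atom_mode, cutoff=cutoff,
        residue_labels=ens.reference.residue_labels,
    )


def subsample(ens: ConformationalEnsemble, n: int,
              scheme: Literal["stride", "random"] = "stride",
              seed: int | None = None) -> ConformationalEnsemble:
    """Select ``n`` frames by even stride (deterministic, includes the last
    frame) or uniformly at random without replacement (seeded)."""
    f = ens.n_frames
    if not 1 <= n <= f:
        raise ValueError(f"cannot select {n} frames from {f}")
    if scheme == "stride":
        idx = np.ceil((np.arange(n) + 1) * f / n).astype(int) - 1
    elif scheme == "random":
        if seed is None:
            raise ValueError("random subsampling requires an explicit seed")
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(f, size=n, replace=False))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return ConformationalEnsemble(
        reference=ens.reference,
        frames=ens.frames[idx].copy(),
        frame_labels=[ens.frame_labels[i] for i in idx],
    )
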