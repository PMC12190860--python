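"""Reading and writing conformational ensembles.

An ensemble is a reference topology (chains, residues, atoms) plus an
``F x A x 3`` stack of coordinate frames, typically snapshots of a
molecular-dynamics trajectory or samples from an elastic-network model.
Supported on-disk forms are the multi-model PDB convention
(``MODEL``/``ENDMDL`` blocks) and a plain-text two-file layout: a
whitespace-separated coordinate table (one frame per row, ``3A`` floats)
with a topology TSV sidecar.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

logger = logging.getLogger(__name__)

#: Three-letter codes of the 20 standard amino acids.
STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Canonical one-letter ordering used for all 20-column substitution tables.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Solvent and common monoatomic ions are dropped on ingest.
_SOLVENT_RESNAMES = {
    "HOH", "WAT", "TIP", "TIP3", "SOL", "NA", "CL", "K", "MG", "CA",
    "ZN", "MN", "NA+", "CL-", "K+",
}


class EnsembleError(ValueError):
    """Structured error raised on malformed ensemble input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the reference topology.

    ``residue_number`` is the author-assigned label (insertion codes are
    appended verbatim, so it is stored as a string such as ``"52"`` or
    ``"52A"``).
    """

    chain_id: str
    residue_number: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    @property
    def is_standard(self) -> bool:
        return self.residue_name in STANDARD_RESIDUES


@dataclass
class ReferenceStructure:
    """Ordered atom list with residue bookkeeping.

    Residue ordinals are assigned in file order, 0-based. Reported tables
    use author ``chain:residue_number`` labels throughout.
    """

    atoms: list[AtomRecord]
    residue_index: dict[tuple[str, str], int] = field(default_factory=dict)
    ca_index: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residue_index:
            self._build_index()

    def _build_index(self) -> None:
        index: dict[tuple[str, str], int] = {}
        ca: dict[int, int] = {}
        for i, atom in enumerate(self.atoms):
            key = (atom.chain_id, atom.residue_number)
            if key not in index:
                index[key] = len(index)
            if atom.atom_name.strip() == "CA":
                ordinal = index[key]
                if ordinal in ca:
                    raise EnsembleError(
                        f"residue {key} has more than one CA atom"
                    )
                ca[ordinal] = i
        missing = [k for k, v in index.items() if v not in ca]
        if missing:
            raise EnsembleError(f"residues lacking a CA atom: {missing[:5]}")
        self.residue_index = index
        self.ca_index = [ca[i] for i in range(len(index))]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residue_index)

    @property
    def residue_labels(self) -> list[str]:
        """Author labels ``chain:residue_number`` in ordinal order."""
        ordered = sorted(self.residue_index.items(), key=lambda kv: kv[1])
        return [f"{c}:{r}" for (c, r), _ in ordered]

    def residue_names(self) -> list[str]:
        """Three-letter residue name per ordinal."""
        names = [""] * self.n_residues
        for atom in self.atoms:
            ordinal = self.residue_index[(atom.chain_id, atom.residue_number)]
            if not names[ordinal]:
                names[ordinal] = atom.residue_name
        return names

    def residue_one_letter(self) -> list[str]:
        """One-letter code per ordinal; ``X`` for nonstandard residues."""
        return [THREE_TO_ONE.get(n, "X") for n in self.residue_names()]

    def chain_of_residue(self) -> list[str]:
        chains = [""] * self.n_residues
        for (chain, _), ordinal in self.residue_index.items():
            chains[ordinal] = chain
        return chains

    def atoms_of_residue(self, ordinal: int) -> list[int]:
        return [
            i for i, a in enumerate(self.atoms)
            if self.residue_index[(a.chain_id, a.residue_number)] == ordinal
        ]

    def reference_coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass
class ConformationalEnsemble:
    """Reference structure plus ``F x A x 3`` coordinate frames (angstrom)."""

    reference: ReferenceStructure
    frames: np.ndarray
    frame_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise EnsembleError(
                f"frames must be F x A x 3, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise EnsembleError("ensemble must contain at least one frame")
        if self.frames.shape[1] != self.reference.n_atoms:
            raise EnsembleError(
                f"frames have {self.frames.shape[1]} atoms but reference "
                f"has {self.reference.n_atoms}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise EnsembleError("frame coordinates contain non-finite values")
        if self.frame_labels is None:
            self.frame_labels = [str(i + 1) for i in range(self.n_frames)]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def n_residues(self) -> int:
        return self.reference.n_residues

    def ca_coordinates(self) -> np.ndarray:
        """``F x N x 3`` coordinates of the C-alpha atoms."""
        return self.frames[:, self.reference.ca_index, :]


def _atom_sort_key(atom) -> tuple:
    # Highest occupancy first; ties broken by altloc letter.
    occ = atom.get_occupancy()
    return (-(occ if occ is not None else 1.0), atom.get_altloc())


def read_multimodel_pdb(path: str | Path) -> ConformationalEnsemble:
    """Read a multi-model PDB file into a :class:`ConformationalEnsemble`.

    Frames are ordered by MODEL number. Hydrogens are retained (flagged via
    :attr:`AtomRecord.is_hydrogen`); solvent and monoatomic ions are dropped
    with a logged count. For altloc groups the highest-occupancy conformer
    is kept, ties broken by altloc letter.

    Raises
    ------
    EnsembleError
        If no atoms can be parsed, or a model's atom list does not match
        the first model.
    """
    path = Path(path)
    if not path.exists():
        raise EnsembleError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("ensemble", str(path))
    models = list(structure.get_models())
    if not models:
        raise EnsembleError(f"no models parsed from {path}")

    dropped = 0
    reference_atoms: list[AtomRecord] = []
    key_order: list[tuple] = []
    frames = []
    labels = []
    for m_i, model in enumerate(models):
        coords = []
        keys = []
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip()
                if resname in _SOLVENT_RESNAMES:
                    dropped += 1
                    continue
                hetflag, resseq, icode = residue.get_id()
                resnum = f"{resseq}{icode.strip()}"
                # Pick one conformer per atom name.
                by_name: dict[str, object] = {}
                for atom in sorted(residue.get_atoms(), key=_atom_sort_key):
                    name = atom.get_name()
                    by_name.setdefault(name, atom)
                for name, atom in by_name.items():
                    key = (chain.get_id(), resnum, name)
                    keys.append(key)
                    coords.append(atom.get_coord())
                    if m_i == 0:
                        element = (atom.element or "").strip() or name[:1]
                        reference_atoms.append(
                            AtomRecord(
                                chain_id=chain.get_id(),
                                residue_number=resnum,
                                residue_name=resname,
                                atom_name=name,
                                element=element,
                                position=np.asarray(atom.get_coord(), float),
                            )
                        )
        if m_i == 0:
            key_order = keys
            if not keys:
                raise EnsembleError(f"zero parsable atoms in {path}")
        elif keys != key_order:
            raise EnsembleError(
                f"MODEL {model.get_id() + 1}: atom list does not match "
                f"MODEL {models[0].get_id() + 1} "
                f"({len(keys)} atoms vs {len(key_order)})"
            )
        frames.append(np.asarray(coords, dtype=float))
        labels.append(str(model.get_id() + 1))

    if dropped:
        logger.info("dropped %d solvent/ion residues on ingest", dropped)
    reference = ReferenceStructure(atoms=reference_atoms)
    return ConformationalEnsemble(
        reference=reference, frames=np.stack(frames), frame_labels=labels
    )


_TOPOLOGY_COLUMNS = ["chain", "residue_number", "residue_name", "atom_name",
                     "element"]


def read_coord_table(
    coords_path: str | Path, topology_path: str | Path
) -> ConformationalEnsemble:
    """Read the plain-text coordinate-table layout.

    ``coords_path`` holds F rows of ``3A`` whitespace-separated floats
    (x1 y1 z1 x2 y2 z2 ...); ``topology_path`` is a TSV with header
    ``chain  residue_number  residue_name  atom_name  element``, one row
    per atom, in atom order. The first frame serves as the reference
    coordinates.
    """
    import pandas as pd

    topo = pd.read_csv(topology_path, sep="\t", dtype=str)
    if list(topo.columns) != _TOPOLOGY_COLUMNS:
        raise EnsembleError(
            f"topology header must be {_TOPOLOGY_COLUMNS}, "
            f"got {list(topo.columns)}"
        )
    triples = list(zip(topo["chain"], topo["residue_number"],
                       topo["atom_name"]))
    if len(set(triples)) != len(triples):
        dup = next(t for t in triples if triples.count(t) > 1)
        raise EnsembleError(f"duplicate atom triple in topology: {dup}")
    n_atoms = len(topo)

    raw = np.loadtxt(coords_path, dtype=float, ndmin=2)
    if raw.shape[1] % 3 != 0 or raw.shape[1] != 3 * n_atoms:
        raise EnsembleError(
            f"coordinate rows have {raw.shape[1]} values; expected "
            f"3 x {n_atoms} = {3 * n_atoms}"
        )
    frames = raw.reshape(raw.shape[0], n_atoms, 3)

    atoms = [
        AtomRecord(
            chain_id=str(row.chain),
            residue_number=str(row.residue_number),
            residue_name=str(row.residue_name),
            atom_name=str(row.atom_name),
            element=str(row.element),
            position=frames[0, i].copy(),
        )
        for i, row in enumerate(topo.itertuples(index=False))
    ]
    reference = ReferenceStructure(atoms=atoms)
    return ConformationalEnsemble(reference=reference, frames=frames)


def write_coord_table(
    ens: ConformationalEnsemble,
    coords_path: str | Path,
    topology_path: str | Path,
) -> None:
    """Write the two-file coordinate-table layout (inverse of
    :func:`read_coord_table`)."""
    with open(topology_path, "w") as fh:
        fh.write("\t".join(_TOPOLOGY_COLUMNS) + "\n")
        for a in ens.reference.atoms:
            fh.write(
                f"{a.chain_id}\t{a.residue_number}\t{a.residue_name}\t"
                f"{a.atom_name}\t{a.element}\n"
            )
    flat = ens.frames.reshape(ens.n_frames, -1)
    np.savetxt(coords_path, flat, fmt="%.8f")


def write_ensemble_pdb(ens: ConformationalEnsemble, path: str | Path) -> None:
    """Write a standard multi-model PDB (coordinates to 3 decimals).

    A single-frame ensemble is still wrapped in ``MODEL 1``/``ENDMDL``
    so that round-tripping is uniform.
    """
    if ens.n_frames < 1:
        raise EnsembleError("cannot write an empty ensemble")
    path = Path(path)
    lines = []
    for f in range(ens.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        serial = 1
        for i, atom in enumerate(ens.reference.atoms):
            x, y, z = ens.frames[f, i]
            if max(abs(x), abs(y), abs(z)) >= 10000:
                raise EnsembleError(
                    "coordinate exceeds PDB fixed-width field"
                )
            name = atom.atom_name
            # PDB column convention: 1-3 character names start in column 14.
            padded = f" {name:<3s}" if len(name) < 4 else name
            resnum = atom.residue_number
            icode = " "
            if resnum and not resnum[-1].isdigit():
                icode = resnum[-1]
                resnum = resnum[:-1]
            lines.append(
                f"ATOM  {serial:5d} {padded:<4s} {atom.residue_name:<3s} "
                f"{atom.chain_id:1s}{int(resnum):4d}{icode:1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial = min(serial + 1, 99999)
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_labeled_matrix(values: np.ndarray, labels: list[str],
                         path: str | Path) -> None:
    """Square matrix as CSV with residue labels as first row and column."""
    import pandas as pd

    pd.DataFrame(values, index=labels, columns=labels).to_csv(path)


def read_labeled_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_profile(labels: list[str], values: np.ndarray, path: str | Path,
                  value_name: str = "value") -> None:
    """Per-residue profile as two-column CSV ``residue,<value_name>``."""
    import pandas as pd

    pd.DataFrame({"residue": labels, value_name: values}).to_csv(
        path, index=False
    )
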