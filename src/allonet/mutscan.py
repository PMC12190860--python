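"""Ensemble-averaged mutational scanning of binding free-energy changes.

Every scanned position is mutated to each of the 20 standard amino
acids; a pluggable scorer evaluates the per-frame binding free-energy
change ddG (kcal/mol, positive = destabilizing) of each substitution and
the table reports the mean and standard error over the selected
equilibrium frames. Scoring every frame and then averaging — rather
than scoring a mean structure — is the point of the ensemble framework:
it captures how the contact environment of a position fluctuates.

The built-in scorer is a documented residue-contact potential: for a
substitution wt -> a at position p, each partner-chain residue q in
heavy-atom contact with p contributes e(a, aa_q) - e(wt, aa_q), plus a
burial-weighted hydrophobicity penalty. The default pair table is a
hydrophobicity-product contact potential constructed from the
Kyte-Doolittle scale (favourable, i.e. negative, for hydrophobic
pairs); any symmetric 20 x 20 table can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .dynamics import _contact_atom_groups, subsample
from .ensemble_io import (
    AA_ORDER,
    ConformationalEnsemble,
    THREE_TO_ONE,
)

#: Kyte-Doolittle hydropathy (one-letter order of AA_ORDER).
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


def default_pair_energy_table() -> np.ndarray:
    """Symmetric 20 x 20 contact energies (kcal/mol), AA_ORDER indexing.

    e(a, b) = -h'(a) * h'(b) with h' the Kyte-Doolittle scale rescaled to
    [0, 1], scaled by 2 kcal/mol: hydrophobic-hydrophobic contacts are
    most favourable, mirroring the dominant signal of knowledge-based
    contact potentials.
    """
    h = np.array([KYTE_DOOLITTLE[a] for a in AA_ORDER])
    h = (h - h.min()) / (h.max() - h.min())
    return -2.0 * np.outer(h, h)


class SubstitutionScorer(Protocol):
    """Per-frame substitution scorer.

    ``score(frame, position, target_aa)`` returns the frame's ddG
    contribution in kcal/mol; the wild-type substitution must score 0
    for every frame.
    """

    name: str
    parameters: dict

    def score(self, ens: ConformationalEnsemble, frame_index: int,
              position: int, target_aa: str) -> float: ...


@dataclass
class FunctionScorer:
    """Adapter wrapping a plain function as a :class:`SubstitutionScorer`."""

    fn: Callable[[ConformationalEnsemble, int, int, str], float]
    name: str = "function"
    parameters: dict = field(default_factory=dict)

    def score(self, ens, frame_index, position, target_aa):
        return self.fn(ens, frame_index, position, target_aa)


@dataclass
class ContactScorer:
    """Built-in residue-contact substitution scorer.

    Per-frame score of mutating position p (wild type wt) to a:

        sum over partner-chain residues q with any heavy atom within
        ``cutoff`` of p's heavy atoms of [e(a, aa_q) - e(wt, aa_q)]
        + burial_weight * (h(wt) - h(a)) * burial(p)

    where h is the Kyte-Doolittle scale rescaled to [0, 1] and burial(p)
    is a contact-count exposure proxy: the number of residues (any
    chain) within the cutoff, divided by ``burial_saturation`` and
    clipped to [0, 1]. Positive scores are destabilizing.
    """

    pair_energy: np.ndarray
    burial_weight: float = 0.0
    cutoff: float = 5.0
    burial_saturation: int = 10
    partner_chains: frozenset[str] | None = None
    name: str = "builtin_contact"

    def __post_init__(self) -> None:
        self.pair_energy = np.asarray(self.pair_energy, dtype=float)
        if self.pair_energy.shape != (20, 20):
            raise ValueError("pair energy table must be 20 x 20")
        if not np.allclose(self.pair_energy, self.pair_energy.T):
            raise ValueError("pair energy table must be symmetric")
        self._h = np.array([KYTE_DOOLITTLE[a] for a in AA_ORDER])
        self._h = (self._h - self._h.min()) / (self._h.max() -
                                               self._h.min())
        self._cache: dict[int, tuple] = {}

    @property
    def parameters(self) -> dict:
        return {
            "burial_weight": self.burial_weight,
            "cutoff": self.cutoff,
            "burial_saturation": self.burial_saturation,
        }

    def _topology(self, ens: ConformationalEnsemble):
        key = id(ens)
        if key not in self._cache:
            ref = ens.reference
            self._cache[key] = {
                "groups": _contact_atom_groups(ref, "all_heavy"),
                "chains": ref.chain_of_residue(),
                "aa_index": np.array([
                    AA_ORDER.index(a) if a in AA_ORDER else -1
                    for a in ref.residue_one_letter()
                ]),
                "env": {},
            }
        return self._cache[key]

    def _position_environment(self, ens: ConformationalEnsemble,
                              position: int):
        """Per-frame contact environment of one position, all frames.

        Returns (partner_counts F x 20, burial F): partner_counts[f, t]
        counts contacting cross-chain partner residues of type t in
        frame f; burial is the saturating contact-count proxy.
        """
        topo = self._topology(ens)
        if position in topo["env"]:
            return topo["env"][position]
        groups, chains = topo["groups"], topo["chains"]
        aa_index = topo["aa_index"]
        own = ens.frames[:, groups[position], :]          # F x k x 3
        f = ens.n_frames
        n_contacts = np.zeros(f)
        partner_counts = np.zeros((f, 20))
        for q in range(ens.n_residues):
            if q == position:
                continue
            other = ens.frames[:, groups[q], :]           # F x m x 3
            d2 = ((own[:, :, None, :] - other[:, None, :, :]) ** 2
                  ).sum(axis=-1)
            in_contact = d2.min(axis=(1, 2)) <= self.cutoff ** 2
            n_contacts += in_contact
            partner_ok = (self.partner_chains is None
                          or chains[q] in self.partner_chains)
            if partner_ok and chains[q] != chains[position] \
                    and aa_index[q] >= 0:
                partner_counts[in_contact, aa_index[q]] += 1.0
        burial = np.minimum(1.0, n_contacts / self.burial_saturation)
        topo["env"][position] = (partner_counts, burial)
        return partner_counts, burial

    def score_position(self, ens: ConformationalEnsemble,
                       position: int) -> np.ndarray:
        """F x 20 matrix of per-frame scores for all substitutions."""
        wt = ens.reference.residue_one_letter()[position]
        w = AA_ORDER.index(wt)
        counts, burial = self._position_environment(ens, position)
        # pair term: (e_row(a) - e_row(wt)) . counts, per frame
        delta_e = self.pair_energy - self.pair_energy[w][None, :]  # 20x20
        pair = counts @ delta_e.T                                  # F x 20
        hydro = self.burial_weight * (self._h[w] - self._h)        # 20
        scores = pair + burial[:, None] * hydro[None, :]
        scores[:, w] = 0.0
        return scores

    def score(self, ens: ConformationalEnsemble, frame_index: int,
              position: int, target_aa: str) -> float:
        wt = ens.reference.residue_one_letter()[position]
        if target_aa == wt:
            return 0.0
        return float(
            self.score_position(ens, position)[frame_index,
                                               AA_ORDER.index(target_aa)]
        )


def builtin_contact_scorer(pair_energy_table: np.ndarray | None = None,
                           burial_weight: float = 0.0,
                           cutoff: float = 5.0,
                           partner_chains: set[str] | None = None
                           ) -> ContactScorer:
    """Construct the built-in contact scorer (see :class:`ContactScorer`)."""
    if pair_energy_table is None:
        pair_energy_table = default_pair_energy_table()
    return ContactScorer(
        pair_energy=pair_energy_table, burial_weight=burial_weight,
        cutoff=cutoff,
        partner_chains=frozenset(partner_chains) if partner_chains else None,
    )


#: Registry of named scorer factories for CLI / config lookup.
SCORER_REGISTRY: dict[str, Callable[..., SubstitutionScorer]] = {
    "builtin": builtin_contact_scorer,
}


@dataclass
class MutScanTable:
    """Positions x 20 matrix of ensemble-averaged ddG values (kcal/mol)."""

    residue_labels: list[str]
    aa_order: str
    ddg: np.ndarray
    ddg_se: np.ndarray
    n_samples: int
    wild_types: list[str]

    def __post_init__(self) -> None:
        self.ddg = np.asarray(self.ddg, dtype=float)
        self.ddg_se = np.asarray(self.ddg_se, dtype=float)
        p = len(self.residue_labels)
        if self.ddg.shape != (p, 20) or self.ddg_se.shape != (p, 20):
            raise ValueError("ddg tables must be positions x 20")
        if not np.all(np.isfinite(self.ddg)):
            raise ValueError("ddg values must be finite")
        for i, wt in enumerate(self.wild_types):
            col = self.aa_order.index(wt)
            if self.ddg[i, col] != 0.0:
                raise ValueError(
                    f"wild-type column must be exactly 0 at "
                    f"{self.residue_labels[i]}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ddg, index=self.residue_labels,
                            columns=list(self.aa_order))


def identify_interface_residues(ens: ConformationalEnsemble,
                                group_a: set[str], group_b: set[str],
                                cutoff: float = 5.0,
                                min_occupancy: float = 0.5) -> list[str]:
    """Residues of ``group_a`` chains in ensemble contact with ``group_b``.

    A residue qualifies if any of its heavy atoms comes within ``cutoff``
    angstrom of any heavy atom of the partner group in at least
    ``min_occupancy`` of the frames. Returned sorted by residue ordinal.
    """
    if group_a & group_b:
        raise ValueError("chain groups must be disjoint")
    if not group_a or not group_b:
        raise ValueError("chain groups must be non-empty")
    ref = ens.reference
    chains = ref.chain_of_residue()
    heavy = [
        np.array([i for i in ref.atoms_of_residue(r)
                  if not ref.atoms[i].is_hydrogen], dtype=int)
        for r in range(ref.n_residues)
    ]
    a_res = [r for r in range(ref.n_residues) if chains[r] in group_a]
    b_atoms = np.concatenate([
        heavy[r] for r in range(ref.n_residues) if chains[r] in group_b
    ] or [np.array([], dtype=int)])
    if b_atoms.size == 0:
        return []
    labels = ref.residue_labels
    partner = ens.frames[:, b_atoms, :]                  # F x B x 3
    out = []
    for r in a_res:
        if heavy[r].size == 0:
            continue
        own = ens.frames[:, heavy[r], :]                 # F x k x 3
        d2 = ((own[:, :, None, :] - partner[:, None, :, :]) ** 2
              ).sum(axis=-1)
        hits = (d2.min(axis=(1, 2)) <= cutoff ** 2).mean()
        if hits >= min_occupancy:
            out.append(labels[r])
    return out


def scan_mutations(ens: ConformationalEnsemble,
                   scorer: SubstitutionScorer,
                   positions: list[str],
                   n_samples: int = 1000,
                   scheme: str = "stride",
                   seed: int | None = None) -> MutScanTable:
    """Ensemble-averaged ddG of all 20 substitutions at each position.

    ``positions`` are residue labels (``chain:resnum``). ddG[p][a] is the
    mean over the selected frames of the per-frame scorer value, with the
    standard error of that mean. Stride selection makes the scan
    deterministic; the wild-type column is exactly zero by the scorer
    contract.
    """
    n_samples = min(n_samples, ens.n_frames)
    work = subsample(ens, n_samples, scheme=scheme, seed=seed) \
        if n_samples < ens.n_frames else ens
    labels = ens.reference.residue_labels
    label_to_ordinal = {lab: i for i, lab in enumerate(labels)}
    one_letter = ens.reference.residue_one_letter()
    bad = [p for p in positions
           if p not in label_to_ordinal
           or one_letter[label_to_ordinal[p]] not in AA_ORDER]
    if bad:
        raise ValueError(f"nonstandard or unknown positions: {bad}")
    ordinals = [label_to_ordinal[p] for p in positions]
    wild_types = [one_letter[o] for o in ordinals]

    f = work.n_frames
    ddg = np.zeros((len(positions), 20))
    se = np.zeros_like(ddg)
    for pi, (ordinal, wt) in enumerate(zip(ordinals, wild_types)):
        if hasattr(scorer, "score_position"):
            vals = np.asarray(scorer.score_position(work, ordinal))
            ddg[pi] = vals.mean(axis=0)
            if f > 1:
                se[pi] = vals.std(axis=0, ddof=1) / np.sqrt(f)
            ddg[pi, AA_ORDER.index(wt)] = 0.0
            se[pi, AA_ORDER.index(wt)] = 0.0
            continue
        for ai, aa in enumerate(AA_ORDER):
            if aa == wt:
                continue
            vals = np.array([
                scorer.score(work, fi, ordinal, aa) for fi in range(f)
            ])
            ddg[pi, ai] = vals.mean()
            se[pi, ai] = vals.std(ddof=1) / np.sqrt(f) if f > 1 else 0.0
    return MutScanTable(
        residue_labels=list(positions), aa_order=AA_ORDER,
        ddg=ddg, ddg_se=se, n_samples=f, wild_types=wild_types,
    )


@dataclass
class EnergyDecompositionTable:
    """Per-residue mean / standard error of binding-energy components."""

    residue_labels: list[str]
    mean: pd.DataFrame      # columns: total, vdw, elec
    se: pd.DataFrame
    n_samples: int

    def ranked(self) -> pd.DataFrame:
        """Residues ordered by mean total contribution (most favourable
        first)."""
        df = self.mean.copy()
        df.index = self.residue_labels
        return df.sort_values("total")


_COMPONENTS = ["total", "vdw", "elec"]


def aggregate_energy_decomposition(
        tables: list[pd.DataFrame] | list[str | Path]
) -> EnergyDecompositionTable:
    """Average per-residue energy-decomposition tables across samples.

    Each table needs a ``residue`` column and ``total``/``vdw``/``elec``
    component columns (e.g. exported from per-snapshot MM-GBSA
    decompositions); all tables must agree on residue labels.
    """
    if not tables:
        raise ValueError("no tables to aggregate")
    frames = []
    for t in tables:
        df = t if isinstance(t, pd.DataFrame) else pd.read_csv(t)
        missing = {"residue", *_COMPONENTS} - set(df.columns)
        if missing:
            raise ValueError(f"table missing columns: {sorted(missing)}")
        frames.append(df)
    labels = list(frames[0]["residue"].astype(str))
    for k, df in enumerate(frames[1:], start=2):
        got = list(df["residue"].astype(str))
        if got != labels:
            first = next(
                (a, b) for a, b in zip(labels + ["<end>"], got + ["<end>"])
                if a != b
            )
            raise ValueError(
                f"table {k} residue labels differ from table 1: "
                f"expected {first[0]!r}, got {first[1]!r}"
            )
    stack = np.stack([df[_COMPONENTS].to_numpy(float) for df in frames])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    se = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 \
        else np.zeros_like(mean)
    return EnergyDecompositionTable(
        residue_labels=labels,
        mean=pd.DataFrame(mean, columns=_COMPONENTS),
        se=pd.DataFrame(se, columns=_COMPONENTS),
        n_samples=n,
    )


def export_heatmap(table: MutScanTable, path: str | Path,
                   render_image: bool = False) -> None:
    """CSV in heatmap orientation: positions as columns, the 20
    substitutions as rows; optionally a rendered image with a diverging
    scale centred at 0."""
    df = table.to_frame().T  # 20 rows x positions
    df.index.name = "substitution"
    df.to_csv(path)
    if render_image:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.3 * len(table.residue_labels)), 6))
        lim = max(1e-9, np.abs(table.ddg).max())
        im = ax.imshow(df.to_numpy(), aspect="auto", cmap="RdBu_r",
                       vmin=-lim, vmax=lim)
        ax.set_yticks(range(20), list(table.aa_order))
        ax.set_xticks(range(len(table.residue_labels)),
                      table.residue_labels, rotation=90, fontsize=6)
        fig.colorbar(im, ax=ax, label="ddG (kcal/mol)")
        fig.tight_layout()
        fig.savefig(str(Path(path).with_suffix(".png")), dpi=150)
        plt.close(fig)


def read_heatmap(path: str | Path) -> pd.DataFrame:
    """Read a heatmap CSV back (rows substitutions, columns positions)."""
    return pd.read_csv(path, index_col=0)
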