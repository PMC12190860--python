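"""End-to-end pipeline orchestration.

Chains ingest -> superposition -> dynamics statistics (RMSD, RMSF,
DCCM, generalized correlation, contact occupancy) -> interface
detection and mutational scanning -> residue graph and betweenness ->
perturbation Z profile, writing every intermediate as CSV/TSV and a
manifest with configuration hash, package versions and per-stage
output checksums, so a run is a pure function of (inputs, config,
seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dynamics import (
    compute_contact_occupancy,
    compute_dccm,
    compute_generalized_correlation,
    compute_rmsd_series,
    compute_rmsf,
    subsample,
    superpose_frames,
)
from .ensemble_io import (
    read_coord_table,
    read_multimodel_pdb,
    write_labeled_matrix,
    write_profile,
)
from .mutscan import builtin_contact_scorer, export_heatmap, \
    identify_interface_residues, scan_mutations
from .network import build_residue_graph, compute_spc, export_graph
from .perturb import profile_perturbations, rank_hotspots

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative parameter registry for a full run.

    Defaults mirror the standard analysis constants: 5 A contact and
    interface cutoffs, occupancy threshold tau = 0.5, 1000 equilibrium
    samples, dynamics-only edge weights (lambda = 0).
    """

    out_dir: str = "run"
    # exactly one input source:
    ensemble_pdb: str | None = None
    coord_table: str | None = None
    topology: str | None = None
    synthetic: dict | None = None      # kwargs of synthetic.make_toy_complex
    target_chains: list[str] = field(default_factory=lambda: ["A"])
    partner_chains: list[str] = field(default_factory=lambda: ["B"])
    contact_cutoff: float = 5.0
    interface_cutoff: float = 5.0
    atom_mode: str = "sidechain_heavy"
    tau: float = 0.5
    lam: float = 0.0
    coupling: str = "generalized"      # or "dccm"
    n_samples: int = 1000
    burial_weight: float = 0.5
    perturb_mode: str = "remove"
    observable: str = "aspl"
    aggregation: str = "mean_square"
    z_min: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.tau <= 1:
            raise ValueError(f"tau must lie in [0, 1], got {self.tau}")
        if not 0 <= self.lam <= 1:
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")
        if self.contact_cutoff <= 0 or self.interface_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.coupling not in {"generalized", "dccm"}:
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.perturb_mode not in {"remove", "reweight"}:
            raise ValueError(f"unknown perturb_mode {self.perturb_mode!r}")
        if self.observable not in {"aspl", "node_spc"}:
            raise ValueError(f"unknown observable {self.observable!r}")
        if self.aggregation not in {"mean_square", "rms", "mean_abs"}:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.atom_mode not in {"sidechain_heavy", "all_heavy",
                                  "ca_only"}:
            raise ValueError(f"unknown atom_mode {self.atom_mode!r}")
        sources = [self.ensemble_pdb, self.coord_table, self.synthetic]
        if sum(s is not None for s in sources) != 1:
            raise ValueError(
                "exactly one of ensemble_pdb, coord_table, synthetic "
                "must be set"
            )
        if self.coord_table is not None and self.topology is None:
            raise ValueError("coord_table input requires a topology path")
        if set(self.target_chains) & set(self.partner_chains):
            raise ValueError("target and partner chains overlap")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_ensemble(config: PipelineConfig):
    if config.ensemble_pdb is not None:
        return read_multimodel_pdb(config.ensemble_pdb), None
    if config.coord_table is not None:
        return read_coord_table(config.coord_table, config.topology), None
    from .synthetic import make_toy_complex

    kwargs = dict(config.synthetic)
    kwargs.setdefault("seed", config.seed)
    ens, truth = make_toy_complex(**kwargs)
    return ens, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``<out_dir>/manifest.json``).

    Any stage failure is recorded in the manifest with a structured
    reason and later stages are skipped; the manifest is written in all
    cases.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "allonet": __version__,
            "numpy": np.__version__,
        },
        "stages": {},
        "outputs": {},
    }
    state: dict = {}

    def stage(name, fn):
        if any(s["status"] == "failed"
               for s in manifest["stages"].values()):
            manifest["stages"][name] = {"status": "skipped"}
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - reported in manifest
            manifest["stages"][name] = {
                "status": "failed",
                "error": f"{type(exc).__name__}: {exc}",
            }
            logger.exception("stage %s failed", name)
            return
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
        }

    def _ingest():
        ens, truth = _load_ensemble(config)
        if ens.n_frames > config.n_samples:
            ens = subsample(ens, config.n_samples, scheme="stride")
        state["ens"] = superpose_frames(ens)
        state["truth"] = truth

    def _dynamics():
        ens = state["ens"]
        labels = ens.reference.residue_labels
        rmsd = compute_rmsd_series(ens)
        np.savetxt(out / "rmsd.csv",
                   np.column_stack([np.arange(len(rmsd)), rmsd]),
                   delimiter=",", header="frame,rmsd", comments="",
                   fmt=["%d", "%.8f"])
        rmsf = compute_rmsf(ens)
        write_profile(labels, rmsf.values, out / "rmsf.csv", "rmsf")
        state["dccm"] = compute_dccm(ens)
        write_labeled_matrix(state["dccm"].values, labels,
                             out / "dccm.csv")
        state["gencorr"] = compute_generalized_correlation(ens)
        write_labeled_matrix(state["gencorr"].values, labels,
                             out / "gencorr.csv")
        state["occupancy"] = compute_contact_occupancy(
            ens, cutoff=config.contact_cutoff,
            atom_mode=config.atom_mode)
        write_labeled_matrix(state["occupancy"].values, labels,
                             out / "occupancy.csv")

    def _mutscan():
        ens = state["ens"]
        interface = identify_interface_residues(
            ens, set(config.target_chains), set(config.partner_chains),
            cutoff=config.interface_cutoff)
        state["interface"] = interface
        write_profile(interface, np.ones(len(interface)),
                      out / "interface.csv", "in_interface")
        if not interface:
            logger.info("no interface residues; mutational scan skipped")
            return
        scorer = builtin_contact_scorer(
            burial_weight=config.burial_weight,
            cutoff=config.interface_cutoff,
            partner_chains=set(config.partner_chains))
        table = scan_mutations(ens, scorer, interface,
                               n_samples=config.n_samples)
        state["mutscan"] = table
        export_heatmap(table, out / "mutscan_heatmap.csv")

    def _network():
        coupling = state["gencorr"] if config.coupling == "generalized" \
            else state["dccm"]
        ens = state["ens"]
        aa_map = dict(zip(ens.reference.residue_labels,
                          ens.reference.residue_one_letter()))
        graph = build_residue_graph(
            state["occupancy"], coupling, tau=config.tau,
            lam=config.lam, residue_aa=aa_map,
            chain_of=ens.reference.chain_of_residue())
        state["graph"] = graph
        export_graph(graph, out / "net.edges.tsv")
        spc = compute_spc(graph)
        write_profile(spc.residue_labels, spc.spc, out / "spc.csv", "spc")

    def _perturb():
        profile = profile_perturbations(
            state["graph"], mode=config.perturb_mode,
            observable=config.observable,
            aggregation=config.aggregation)
        state["profile"] = profile
        import pandas as pd

        pd.DataFrame({
            "residue": profile.residue_labels,
            "delta_L": profile.delta_L,
            "z": profile.z,
        }).to_csv(out / "zprofile.csv", index=False)
        hotspots = rank_hotspots(profile, z_min=config.z_min)
        (out / "hotspots.csv").write_text(
            "residue\n" + "".join(h + "\n" for h in hotspots))
        manifest["hotspots"] = hotspots

    stage("ingest", _ingest)
    stage("dynamics", _dynamics)
    stage("mutscan", _mutscan)
    stage("network", _network)
    stage("perturb", _perturb)

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def render_profiles(run_dir: str | Path) -> list[Path]:
    """Render bar/heatmap figures (PNG + SVG) from a run directory's CSVs.

    Missing profiles are skipped with a log entry. SVG output is
    deterministic for fixed inputs (fixed hash salt, no timestamp
    metadata).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    matplotlib.rcParams["svg.hashsalt"] = "allonet"
    run_dir = Path(run_dir)
    made: list[Path] = []

    def save(fig, stem: str) -> None:
        for ext in ("png", "svg"):
            target = run_dir / f"{stem}.{ext}"
            fig.savefig(str(target), metadata={"Date": None}
                        if ext == "svg" else None)
            made.append(target)
        plt.close(fig)

    def bar_chart(csv: str, column: str, stem: str, title: str) -> None:
        path = run_dir / csv
        if not path.exists():
            logger.info("missing %s; figure %s skipped", csv, stem)
            return
        df = pd.read_csv(path)
        fig, ax = plt.subplots(figsize=(10, 3))
        ax.bar(range(len(df)), df[column], color="orange", width=1.0)
        step = max(1, len(df) // 40)
        ax.set_xticks(range(0, len(df), step))
        ax.set_xticklabels(df["residue"][::step], rotation=90, fontsize=5)
        ax.set_ylabel(column)
        ax.set_title(title)
        fig.tight_layout()
        save(fig, stem)

    def heatmap(csv: str, stem: str, title: str, diverging: bool) -> None:
        path = run_dir / csv
        if not path.exists():
            logger.info("missing %s; figure %s skipped", csv, stem)
            return
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(float)
        fig, ax = plt.subplots(figsize=(6, 5))
        if diverging:
            lim = max(1e-9, np.abs(values).max())
            im = ax.imshow(values, cmap="RdBu_r", vmin=-lim, vmax=lim)
        else:
            im = ax.imshow(values, cmap="viridis")
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        save(fig, stem)

    bar_chart("rmsf.csv", "rmsf", "rmsf_profile", "C-alpha RMSF (A)")
    bar_chart("spc.csv", "spc", "spc_profile",
              "Shortest-path betweenness centrality")
    bar_chart("zprofile.csv", "z", "z_profile",
              "Network perturbation Z-score")
    heatmap("dccm.csv", "dccm_map", "Dynamic cross-correlation map",
            diverging=True)
    heatmap("mutscan_heatmap.csv", "mutscan_map",
            "Mutational scan ddG (kcal/mol)", diverging=True)
    return made
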