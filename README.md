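# allonet

Ensemble-based residue interaction network analysis for protein
complexes: from a conformational ensemble (molecular-dynamics
snapshots or any multi-model structure set) to per-residue dynamics
profiles, ensemble-averaged mutational ΔΔG maps, a dynamically
weighted residue communication network, and network-perturbation
Z-scores that flag allosteric hotspot residues.

It is written for structural bioinformaticians who have an ensemble of
a two-chain complex and want to know (a) which residues hold the
binding interface together energetically and (b) which residues —
interface or not — are load-bearing for long-range communication.
Every stage is exercised end-to-end on synthetic elastic-network
ensembles with analytic or planted ground truth, so the statistical
machinery is testable without any simulation data.

## The quantities computed

**Dynamics.** After least-squares superposition, per-frame RMSD,
per-residue RMSF, and the dynamic cross-correlation matrix over Cα
displacements about the ensemble mean,

    C_ij = ⟨Δr_i · Δr_j⟩ / (⟨Δr_i²⟩ ⟨Δr_j²⟩)^{1/2} ∈ [−1, 1],

plus the mutual-information-based generalized correlation
r_ij = sqrt(1 − exp(−2 I_ij / 3)) ∈ [0, 1] with I_ij the linear-Gaussian
mutual information of the two displacement vectors, and ensemble
contact-occupancy maps.

**Mutational scanning.** Every scanned position is mutated to all 20
amino acids; a pluggable scorer evaluates the per-frame binding
free-energy change and the table reports the ensemble mean ± standard
error over equilibrium samples (positive ΔΔG = destabilizing). The
built-in scorer is a documented residue-contact potential with an
optional burial-weighted hydrophobicity term.

**Network.** Residues are nodes; pairs whose side-chain contact
occupancy reaches τ (default 0.5 at 5 Å) are edges, weighted by a
coupling g ∈ (0, 1] (generalized correlation by default, optionally
mixed with coevolutionary mutual information) and given communication
distance d = −ln g. Shortest-path betweenness centrality,

    SPC(i) = Σ_{j<k, j≠i≠k} g_jk(i)/g_jk / [(N−1)(N−2)/2],

counts the fraction of all-pairs shortest paths through each residue,
normalized per connected component.

**Perturbation profiling.** Each node is perturbed by all 19
substitutions (node removal, or similarity-weighted edge reweighting);
the change of the characteristic path length (ASPL) gives
ΔL_i = ⟨|ΔL_i^{node j}|²⟩_j and the hotspot score
Z_i = (ΔL_i − ⟨ΔL⟩)/σ over nodes. High-Z residues are communication
bottlenecks whose mutation degrades global network integrity.

## Worked example

`examples/perturbation_hotspots.py` plants a known communication
bottleneck — two dense 6-node clusters joined by a single articulation
node — and asks the perturbation profiler to find it:

```
node            delta_L       Z
HUB             0.6765    2.34
C0:0            0.4867    1.53
C1:0            0.4806    1.51
C1:1            0.0001   -0.54

planted bottleneck : HUB
hotspots (Z >= 1)  : ['HUB', 'C0:0', 'C1:0']
```

`delta_L` is the mean squared ASPL change over the 19 substitutions at
each node and `Z` its standardization over nodes: removing the
articulation node (`HUB`) severs the clusters and collapses long-range
communication, so it tops the ranking; the two cluster gateways rank
next; interior nodes barely matter.

The other examples cover dynamics profiles against analytic GNM truth
(`dynamics_profiles.py`), interface detection plus ΔΔG scanning
(`mutational_scan.py`), graph construction, SPC and optimal paths
(`network_centrality.py`), and the full pipeline with figures
(`full_pipeline.py`). A thin CLI wraps the same functions:
`allonet run --config config.yaml`, with standalone `dynamics`,
`mutscan`, `network`, `perturb` and `simulate` subcommands.

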