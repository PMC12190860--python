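# Methods

## Scope and model

`allonet` treats a protein complex as a conformational ensemble — a
reference topology plus F coordinate frames — and derives three layers
of description from it: per-residue dynamics statistics, an
ensemble-averaged mutational ΔΔG table, and a weighted residue
communication network whose perturbation profile flags allosteric
hotspots. The package does not run molecular dynamics and does not
evaluate MM-GBSA energies; those are upstream producers whose outputs
(multi-model structures, per-snapshot energy-decomposition tables) it
ingests and analyses.

## Dynamics statistics

Frames are superposed onto the reference by the Kabsch least-squares
rotation over selected Cα atoms (all residues by default); the fit
requires at least three non-collinear Cα positions. All displacement
statistics are taken about the **ensemble-mean** Cα position, not the
reference: this is the standard definition of the cross-correlation
matrix and makes RMSF/DCCM invariant (to ~1e-8) under a global rigid
motion applied before superposition.

The signed DCCM is C_ij = ⟨Δr_i·Δr_j⟩ / (⟨Δr_i²⟩⟨Δr_j²⟩)^{1/2}.
Residues with exactly zero fluctuation would make this 0/0; their
rows/columns are set to 0 off-diagonal (1 on the diagonal) with a
warning rather than NaN, so downstream graph construction stays total.

The generalized correlation uses the linear-Gaussian mutual
information of the paired 3-vectors,
I_ij = ½ ln(det Σ_i · det Σ_j / det Σ_ij) from the 6×6 joint Cα
covariance, mapped through r_ij = sqrt(1 − exp(−2 I_ij / 3)). The
estimator the original correlation-network literature used is not
uniquely determined; the linear-Gaussian instantiation was chosen
because it is exactly testable against a closed form and reduces to
the |DCCM| signal for Gaussian ensembles (for which it provably
dominates the magnitude of the linear correlation — a property test
covers this). A singular 3×3 marginal yields r = 0 with a warning; a
singular joint with non-singular marginals is the perfect-coupling
limit and yields r = 1.

Contact occupancy counts, per residue pair, the fraction of frames
with any selected-atom pair within the cutoff. The default atom set is
`sidechain_heavy` (heavy atoms beyond the backbone, glycine falling
back to its Cα) because side-chain proximity is what defines
interaction-network edges; `all_heavy` and `ca_only` are provided for
sensitivity analysis. Occupancy is monotonically non-decreasing in the
cutoff by construction.

Subsampling to n equilibrium frames uses an even stride that always
includes the final frame (indices ⌈(k+1)F/n⌉−1); stride is the default
because it is deterministic, and random subsampling demands an
explicit seed.

## Mutational scanning

The scan mutates each listed position to all 20 amino acids and
averages a per-frame scorer over the selected frames — scoring each
frame and then averaging, never scoring a mean structure, because the
contact environment of a position fluctuates and the ensemble average
is the quantity of interest. The wild-type substitution scores exactly
0 by the scorer contract, making the ensemble average exactly linear
under ensemble concatenation and the standard error scale as 1/√n on
i.i.d. frames (both are tested).

The scorer is an interface. The built-in `ContactScorer` computes, for
wt→a at position p:

    Σ_{q in cross-chain contact of p} [e(a, aa_q) − e(wt, aa_q)]
    + burial_weight · (h(wt) − h(a)) · burial(p)

with contacts at ≤ 5 Å between heavy atoms. The default pair table is
a hydrophobicity-product contact potential, e(a,b) = −2·h′(a)·h′(b)
kcal/mol with h′ the Kyte–Doolittle scale rescaled to [0,1]: it
reproduces the dominant hydrophobic signal of knowledge-based contact
potentials, is generated in code rather than shipped as data, and any
symmetric 20×20 table can be substituted. Burial is a contact-count
proxy — the number of residues with heavy atoms within the cutoff,
saturating at 10 — rather than true SASA, which keeps the scorer free
of heavy geometry dependencies; the sign convention makes loss of
hydrophobicity at a buried position destabilizing. ΔΔG > 0 always
means binding is weakened.

Interface residues are those of the target chains whose heavy atoms
come within 5 Å of the partner chains in at least half the frames.
The 5 Å cutoff is the field's standard interface definition; the 0.5
occupancy threshold makes the rule deterministic and ensemble-aware
where a single-structure rule would be arbitrary about which frame to
trust.

Per-residue energy-decomposition tables (total / van-der-Waals /
electrostatic, one table per snapshot batch) are aggregated to means
and standard errors with strict label checking; the package does not
compute the underlying energies.

## Residue network and betweenness

Nodes are residues of both chains. Edges join pairs with contact
occupancy ≥ τ (default 0.5); consecutive residues of a chain are
always linked (backbone augmentation) because side-chain contact
edges alone can disconnect loop regions while physical communication
still propagates through the backbone, and betweenness presumes
meaningful path structure. Each edge carries a coupling
g = (1−λ)·g_dyn + λ·g_coev, with g_dyn the generalized correlation (or
|DCCM|) and g_coev min–max-normalized mutual information from an
alignment; λ defaults to 0 because a principled combination rule for
dynamics and coevolution is not settled, so mixing is an explicit,
documented option rather than a hidden default.

The communication distance is d = −ln g after clamping g to
[0.01, 1−1e-9]. −ln of a coupling in (0,1] is the standard
information-flow transform — strongly coupled pairs are "close" — and
is exactly invertible for round-trip tests; the floor caps any single
edge at ln 100 so decorrelated contacts cannot inject infinite
distances.

SPC is Brandes betweenness with weighted shortest paths, counting all
co-minimal paths with multiplicity, normalized by (N−1)(N−2)/2 within
each node's connected component (N = component size). With this
normalization a star center scores exactly 1 and leaves 0. Shortest
-path queries return one minimal path with lexicographic tie-breaking
(deterministic), and a disconnected pair is an explicit unreachable
result, not an exception. Co-minimality uses a relative tolerance of
1e-9 on path sums to absorb floating-point accumulation.

## Perturbation profiling

Two perturbation modes: `remove` deletes the node (all 19
substitutions coincide — the classic node-removal centrality), and
`reweight` multiplies each incident edge's coupling by a substitution
similarity s(wt, j) ∈ (0,1], so conservative substitutions perturb
communication less. The default similarity is derived from BLOSUM62 as
the normalized odds ratio 2^{(B(a,b) − (B(a,a)+B(b,b))/2)/2}, clipped
to (0,1] — it has unit diagonal by construction and makes the 19
substitutions distinguishable.

The default observable is the characteristic path length (ASPL), the
mean shortest-path distance over reachable pairs; after a removal that
disconnects the graph the mean is taken over the remaining reachable
pairs (logged), never infinite. The per-node statistic is
ΔL_i = ⟨|ΔL_i^{node j}|²⟩_j — the mean of **squared** changes, taken
literally; `rms` and `mean_abs` are offered as labelled alternatives
since the squared form and its root rank identically but differ in
scale. Z standardizes ΔL over nodes with the **population** standard
deviation: this is a standardization over a fixed finite node set, not
an inference, and σ = 0 yields an all-zero Z rather than NaN. Snapshot
-level profiles can be averaged (ΔL averaged node-wise, Z
re-standardized — Z is invariant under any affine rescaling of ΔL);
alternatively one profile can be computed from an occupancy-merged
graph, which is what the pipeline does by default.

The node-SPC observable is vector-valued; its per-perturbation change
is summarized as the RMS per-node SPC change over nodes present in
both graphs before aggregation.

ASPL computations run on a dense distance matrix through
`scipy.sparse.csgraph` Dijkstra (node removal = row/column masking);
tests verify exact agreement (1e-9) with a hand-written heap Dijkstra
and, for betweenness, with exhaustive DFS path enumeration on graphs
of up to 8 nodes.

## Synthetic data and what it does (not) show

The generator family emulates the *statistical structure* of MD-derived
ensembles with analytic ground truth:

- **Toy structures** are Cα-plus-pseudo-side-chain bead models
  (side-chain bead 1.5 Å off the local chain axis, so side-chain
  contact modes are exercisable); extended (3.8 Å spacing), helical,
  and dumbbell geometries; compact bodies are jittered cubic lattices
  (spacing 4.2 Å, ±0.2 Å seeded jitter) so the minimum-separation
  guarantee holds at any size.
- **GNM ensembles**: the Kirchhoff matrix over Cα pairs within 12 Å
  (sequence neighbours always linked), per-axis covariance
  kT/k · Γ⁺ with the null space removed by eigenvalue thresholding at
  1e-8 of the largest eigenvalue, three independent identical
  Cartesian blocks. The isotropic-GNM form (rather than a full
  anisotropic model) was chosen for its transparent analytic DCCM
  oracle: C_ij = Γ⁺_ij / sqrt(Γ⁺_ii Γ⁺_jj). Default kT/k = 0.5 Ų
  gives sub-ångström residue fluctuations typical of a folded protein
  core. Side-chain beads ride rigidly with their Cα.
- **Toy complexes** plant an exact interface: the K planted chain-A
  residues protrude toward chain B with heavy atoms within 4.5 Å,
  every other A residue stays beyond 6.5 Å, and the modest default
  fluctuation amplitude (kT = 0.1) keeps occupancy cleanly bimodal, so
  interface recovery has an exact expected answer. A zero-contact
  complex is two separate elastic bodies 20+ Å apart, sampled
  per-component.
- **Dumbbell graphs** join dense clusters through a single articulation
  node (intra-cluster couplings jittered ±0.05 so shortest paths are
  generically unique) — the planted answer for hotspot detection.
- **Coupled alignments** draw columns i.i.d. uniform except planted
  pairs, where the second column copies the first with probability s;
  the mixture's exact mutual information is returned as ground truth.

All generators are bit-reproducible given a seed. What passing these
tests shows is that the estimators, the graph machinery and the
perturbation statistics are correct on Gaussian, harmonic,
single-basin ensembles with clean planted signal. Real MD ensembles
are anharmonic and multi-basin, their contact occupancies are not
bimodal, side chains move independently of the backbone, and real
interfaces are not geometrically separable by construction — so these
tests validate the machinery, not the biological fidelity of any
particular scoring model.

## Pipeline, determinism, problem sizes

The pipeline chains ingest → superposition → dynamics → interface +
scan → network + SPC → perturbation Z, writes every intermediate as
CSV/TSV, and records a manifest with the configuration hash and
SHA-256 checksums of every output; a run is a pure function of
(inputs, config, seed) and repeat runs reproduce checksums bit for
bit. Figures are rendered from the CSVs only (no figure-only numbers),
with a fixed SVG hash salt and no timestamp metadata so re-rendering
unchanged inputs is byte-identical.

Validation problem sizes were chosen so the whole suite runs on a
laptop-class single core: DCCM accuracy at 50 residues × 5000 frames,
betweenness agreement on 100 random graphs of ≤ 8 nodes, bottleneck
recovery on 50 thirteen-node dumbbells, interface recovery on 20
complexes, and the end-to-end run at 170+120 residues × 1000 frames —
the scale of a small GTPase–binder complex with the snapshot count
typical of equilibrium-sample analyses.

## Known limitations

- The built-in ΔΔG scorer is a coarse contact potential: adequate for
  exercising the ensemble-averaging framework and for rank-ordering
  drastic substitutions, not a calibrated free-energy method.
- Burial is a contact-count proxy, not SASA.
- The generalized correlation is the linear-Gaussian estimator; truly
  nonlinear couplings in real ensembles would need a nonparametric MI
  estimator.
- Reweight-mode profiling recomputes the observable per substitution
  (19 N ASPL evaluations); on large graphs remove mode is the
  practical default.
- No mmCIF or compressed-trajectory ingest (multi-model PDB and the
  plain coordinate-table layout only); solvent and ions are dropped on
  ingest with a logged count.
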