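"""Per-residue dynamics from a synthetic elastic-network ensemble.

Samples a Gaussian ensemble from the GNM covariance of a 40-residue
helix and compares the estimated RMSF and DCCM with the analytic values
implied by that covariance: estimation error should shrink toward zero
as the frame count grows.
"""

import numpy as np

from allonet import (
    ENMSpec,
    build_toy_structure,
    compute_dccm,
    compute_rmsf,
    sample_enm_ensemble,
)

structure = build_toy_structure(40, "helix", seed=1)
ens, truth = sample_enm_ensemble(structure, ENMSpec(n_frames=5000, seed=2))

rmsf = compute_rmsf(ens)
n = ens.n_residues
analytic_rmsf = np.sqrt(
    np.einsum("idid->i", truth.covariance.reshape(n, 3, n, 3)))
dccm = compute_dccm(ens)
err = np.abs(dccm.values - truth.analytic_dccm).max()

print(f"ensemble: {ens.n_frames} frames, {n} residues")
print(f"mean RMSF (estimated) : {rmsf.values.mean():.3f} A")
print(f"mean RMSF (analytic)  : {analytic_rmsf.mean():.3f} A")
print(f"max |DCCM error|      : {err:.4f}")
print("Chain-end residues fluctuate most; the DCCM error is the "
      "worst-case deviation of the sampled correlation from the exact "
      "GNM prediction.")
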