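"""Ensemble-averaged mutational scanning of a synthetic interface.

Builds a two-chain complex with five planted interface residues,
detects the interface from ensemble contact occupancy, and scans all
20 substitutions at each interface position with the built-in contact
scorer. Positive ddG means the substitution weakens binding.
"""

import numpy as np

from allonet import (
    builtin_contact_scorer,
    identify_interface_residues,
    make_toy_complex,
    scan_mutations,
)

ens, truth = make_toy_complex(30, 20, 5, seed=7, n_frames=400)
interface = identify_interface_residues(ens, {"A"}, {"B"}, cutoff=5.0)
print(f"planted interface  : {truth.planted_interface}")
print(f"detected interface : {interface}")

scorer = builtin_contact_scorer(burial_weight=0.5, partner_chains={"B"})
table = scan_mutations(ens, scorer, interface, n_samples=400)

print(f"\nscan over {table.n_samples} frames "
      f"({len(interface)} positions x 20 substitutions)")
for i, label in enumerate(table.residue_labels):
    row = table.ddg[i].copy()
    row[table.aa_order.index(table.wild_types[i])] = -np.inf
    worst = int(np.argmax(row))
    print(f"  {label} ({table.wild_types[i]}): most destabilizing "
          f"{table.wild_types[i]}->{table.aa_order[worst]} "
          f"ddG = {table.ddg[i, worst]:+.2f} "
          f"+- {table.ddg_se[i, worst]:.2f} kcal/mol")
print("Hydrophobic wild types at the interface lose favourable "
      "cross-chain contacts when mutated to polar residues, giving the "
      "largest positive ddG.")
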