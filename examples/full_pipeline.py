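"""Full analysis pipeline on a realistically sized synthetic complex.

Runs ingest -> superposition -> dynamics -> interface + mutational scan
-> residue network + SPC -> perturbation Z profile on a 170+120-residue
two-chain complex sampled from an elastic network (1000 frames), then
renders the profile figures. Every output lands in ``scratch/demo_run``
with a manifest of checksums; rerunning with the same seed reproduces
them bit for bit.
"""

import json

from allonet import PipelineConfig, render_profiles, run_pipeline

config = PipelineConfig(
    out_dir="scratch/demo_run",
    synthetic={"n_a": 170, "n_b": 120, "n_interface_contacts": 12,
               "n_frames": 1000},
    n_samples=1000,
    seed=11,
)
manifest = run_pipeline(config)

print("stage status:")
for name, stage in manifest["stages"].items():
    extra = f" ({stage['seconds']} s)" if "seconds" in stage else ""
    print(f"  {name:<10}{stage['status']}{extra}")
print(f"\nhotspots (Z >= 1): {manifest['hotspots']}")
print(f"outputs: {len(manifest['outputs'])} files, e.g. "
      f"{sorted(manifest['outputs'])[:4]}")

figures = render_profiles(config.out_dir)
print(f"rendered {len(figures)} figure files")
print(json.dumps({"config_hash": manifest["config_hash"]}, indent=2))
print("The hotspot residues sit where the synthetic network is most "
      "fragile; with a real ensemble they would be candidate allosteric "
      "control points.")
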