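"""Generate the full synthetic nest dataset and validate its calibration.

Writes a bundle (baseline panel, clutch genotypes, nest metadata, ground
truth) mirroring the observed 18-clutch record, and checks the realised
baseline differentiation with the Weir–Cockerham estimator.
"""

import caretta as ct

cfg = ct.SimulationConfig(seed=3)
manifest = ct.simulate_nest_dataset(cfg, "scratch/example_bundle")

table = ct.read_genotype_table("scratch/example_bundle/clutches.csv")
panel = ct.BaselinePanel.from_table(
    ct.read_genotype_table("scratch/example_bundle/baseline.csv")
)
theta = ct.wc_fst(panel).theta

print(f"bundle written to scratch/example_bundle/")
print(f"clutches: {len(set(table.groups))}, samples: {len(table)}")
print(f"baseline: {panel.counts()} at {len(panel.loci)} loci")
print(f"realised Weir–Cockerham F_ST: {theta:.4f} (target {cfg.target_fst})")
print(
    "\nThe bundle mirrors the observed record (18 clutches, 121 samples,\n"
    "1–2 fathers per nest, Atlantic/Mediterranean/mixed origins) with every\n"
    "parent genotype and per-offspring sire recorded in truth.json."
)
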