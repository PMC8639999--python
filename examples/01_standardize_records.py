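"""Standardize a heterogeneous synthetic survey to common conventions.

Generates a noise-free balanced world, runs the harmonization chain
(density units -> winter season -> 0.01 m2 area -> 0-5 cm depth) and shows
that the recovered values match the generator's latent ground truth.
"""

import numpy as np

from globeseed import standardize, synth

cfg = synth.inversion_config(n_records=200)
records, predictors, truth = synth.generate_dataset(cfg, seed=1)
print(f"generated {len(records)} records across {len(cfg.biome_weights)} biomes")

result = standardize.run_standardization(records)
ratios = result.models.season_ratios.ratios["diversity"]
print("fitted winter ratios (diversity):",
      {s: round(r, 3) for s, r in ratios.items() if r is not None})
for biome, m in result.models.area_models.items():
    if biome != "pooled" and not m.insufficient_data:
        print(f"species-area fit {biome}: C={m.C:.2f} Z={m.Z:.3f} (n={m.n})")

rel_err = max(
    abs(r.value - truth["latent"][r.record_id]) / truth["latent"][r.record_id]
    for r in result.records
)
print(f"max relative error vs latent ground truth: {rel_err:.2e}")
# On this noise-free balanced design the chain inverts every distortion
# exactly (error at float precision), confirming the corrections are the
# inverse of the generating season/area/depth biases.
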