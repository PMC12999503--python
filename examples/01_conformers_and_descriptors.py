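"""From a conformer ensemble to a 756-value structure fingerprint.

Builds a synthetic conformer ensemble of a helical template (a stand-in for
an optimized transition-state structure), removes high-energy and duplicate
conformers, Boltzmann-weights the survivors and aggregates the full default
descriptor catalogue.
"""

from enantiokit import (
    SyntheticSpec,
    boltzmann_weights,
    dedup_by_rmsd,
    featurize_structure,
    filter_energy_window,
    gen_conformer_ensemble,
    make_default_catalogue,
    make_template_structure,
)

template = make_template_structure(24, stage_label="TSRC")
spec = SyntheticSpec(n_conformers=12, jitter_sd=0.04, seed=0)
ensemble = gen_conformer_ensemble(template, spec)
print(f"raw ensemble: {len(ensemble)} conformers")

windowed = filter_energy_window(ensemble, window=5.0)
unique = dedup_by_rmsd(windowed, threshold=0.05)
print(f"within 5 kcal/mol: {len(windowed)}; after RMSD dedup at 0.05 Å: {len(unique)}")

weights = boltzmann_weights(unique.free_energies, temperature=298.15)
print(f"Boltzmann weights (298.15 K): {[round(float(w), 3) for w in weights.weights]}")
# the lowest-energy conformer always dominates; weights sum to 1

catalogue = make_default_catalogue(grid_spacing=0.2)
features = featurize_structure(unique, catalogue, temperature=298.15, window=5.0)
series = features.as_series()
print(f"aggregated descriptor values: {len(series)} "
      f"({len(features.values)} descriptors x min/max/boltz/lowE)")
for name in ("d_1_2", "vbur_1_r4", "sterimol_B1_1_2", "hardness"):
    stats = features.values[name]
    print(f"  {name:>16}: boltz={stats['boltz']:.3f}  range=[{stats['min']:.3f}, {stats['max']:.3f}]")
# each descriptor carries its conformational spread, not just a point value
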