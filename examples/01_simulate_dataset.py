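"""Generate a venom-like compositional dataset and inspect its curation.

Builds the default study-like scenario — 52 species on a 60-My pure-birth
tree, 10 real toxin families plus 15 rare decoys, percent compositions
with structural zeros and sequencing-technology batches — then applies the
prevalence filter that defines the analyzed composition.
"""
import phylotox as pt

table, tree, truth = pt.simulate_venom_dataset(pt.SimulationScenario(seed=0))

print(f"tree: {tree.n_tips} tips, height {tree.height:.0f} My, "
      f"ultrametric={tree.is_ultrametric()}")
print(f"table: {len(table.species)} species x {len(table.components)} families, "
      f"rows sum to {table.values.sum(axis=1).iloc[0]:.1f}%")

prev = table.prevalence().sort_values(ascending=False)
print("\nmost / least prevalent families (fraction of species with the family):")
print(prev.head(4).round(2).to_string())
print("...")
print(prev.tail(3).round(2).to_string())

kept = pt.prevalence_filter(table, 0.5)
print(f"\nretained at >=50% prevalence: {len(kept.components)} of "
      f"{len(table.components)} -> {kept.components}")
print("the decoy families fall below the cutoff and drop out, mirroring how")
print("rare, noisily detected families are excluded before modeling.")
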