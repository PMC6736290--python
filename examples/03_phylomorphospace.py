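"""Project species into the venom phylomorphospace.

The eigenvectors of the posterior-mean PCOV define the axes along which
heritable venom variation is concentrated; the fraction of its trace on
the first two axes measures how low-dimensional the venom phenotype is.
Species scores are the projections of their scaled abundances onto those
axes.
"""
import phylotox as pt

table, tree, _ = pt.simulate_venom_dataset(
    pt.SimulationScenario(seed=2, n_tips=30, n_decoys=0)
)
config = pt.PGLMMConfig(n_iterations=20_000, burnin=4_000, thin=16, seed=0)
samples = pt.fit_pglmm(table, tree, config)
pcov = pt.posterior_pcov(samples)

pca = pt.pcov_pca(pcov.mean_G)
pca = pt.species_scores(samples.response, pca)

pct = 100 * pca.variance_fractions
print("variance captured per axis (%):", [f"{v:.1f}" for v in pct[:4]], "...")
print(f"PC1+PC2 jointly explain {pct[0] + pct[1]:.1f}% of the PCOV trace")

print("\nlargest-magnitude loadings:")
for axis in ("PC1", "PC2"):
    top = pca.loadings[axis].abs().sort_values(ascending=False).head(3)
    desc = ", ".join(f"{c} ({pca.loadings.loc[c, axis]:+.2f})" for c in top.index)
    print(f"  {axis}: {desc}")

print("\nfirst species scores (coordinates in the phylomorphospace):")
print(pca.scores.iloc[:5, :2].round(2).to_string())
print("nearby species share an envenomation strategy; distant clades that")
print("land close together are candidates for convergence.")
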