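"""Detect convergent adaptive regimes with the stepwise OU search.

Plants three regime shifts toward one shared optimum on a 50-tip tree,
runs the greedy forward (add shifts) and backward (merge regimes) phases
under AICc, and calibrates the observed convergence against a simulated
landscape with the same shifts but all-distinct optima.
"""
import numpy as np

import phylotox as pt

tree = pt.simulate_yule_tree(50, seed=7)
T = tree.height
alpha = 5.0 / T            # selection strength: alpha*T = 5
sigma2 = 2 * alpha         # stationary SD = 1 trait unit
# three clades shift to the same optimum, 8 stationary SDs from the base
truth = pt.RegimePainting(tree.n_nodes, ((4, 1), (26, 1), (11, 1)), 0)
traits = pt.simulate_ou_traits(
    tree, truth, alpha, sigma2, np.array([[0.0, 0.0], [8.0, 0.0]]), seed=42
)

fwd = pt.surface_forward(traits, tree)
result = pt.surface_backward(traits, tree, fwd)
m = result.metrics
print(f"forward phase accepted {len(fwd.painting.shifts)} shifts "
      f"(AICc {fwd.trace[0]['score']:.1f} -> {fwd.trace[-1]['score']:.1f})")
print(f"backward phase: k={m.k} placements collapse to k'={m.k_prime} regimes")
print(f"convergence: delta_k={m.delta_k}, c={m.c} convergent shifts "
      f"({m.n_convergent_regimes} convergent regime(s))")

null = pt.simulate_null(fwd.fit, tree, n_sim=50, seed=1, observed=result)
print(f"null (no true convergence, {null.n_sim} sims): "
      f"mean c = {null.c.mean():.1f}, p_c = {null.p_c:.3f}")
print("a small p_c says this much convergence rarely arises from a")
print("landscape whose regimes are all distinct.")
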