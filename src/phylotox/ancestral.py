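"""Maximum-likelihood ancestral state reconstruction under Brownian motion.

Each toxin family is reconstructed independently: tip abundances are
modeled as Brownian motion on the tree, and the state at every internal
node is the ML estimate obtained by re-rooting the tree at that node and
running the contrasts (pruning) algorithm — equivalently, the GLS
conditional expectation given the tips.  The implementation is a two-pass
Gaussian message-passing scheme, O(n) per trait:

* upward pass — each node receives from its subtree a value and an
  "extra branch length" (its conditional variance in branch-length units),
  folding children pairwise exactly as independent contrasts;
* downward pass — each node additionally receives the message from the
  rest of the tree through its parent; combining the two gives the
  re-rooted ML estimate and its variance.

The Brownian rate is the REML estimate from the standardized contrasts,
``sigma2 = sum(pic^2) / (n - 1)``.  The root-presence rule of the venom
analysis calls a toxin present at the root only when the root's 95% CI is
strictly positive.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import Phylogeny

__all__ = ["AncestralError", "AncestralStates", "ml_ancestral_states",
           "root_presence_call"]

#: Gaussian multiplier for the 95% confidence intervals
CI_Z = 1.959963984540054


class AncestralError(ValueError):
    """Invalid input for ancestral state reconstruction."""


@dataclass
class AncestralStates:
    """Per-internal-node ML estimates for one trait.

    ``table`` is indexed by internal node id with columns estimate,
    variance, ci_lower, ci_upper; ``sigma2`` is the contrasts (REML)
    estimate of the Brownian rate; ``root`` is the root node id.
    """

    table: pd.DataFrame
    sigma2: float
    root: int

    @property
    def root_estimate(self) -> float:
        return float(self.table.loc[self.root, "estimate"])

    @property
    def root_ci(self) -> tuple[float, float]:
        row = self.table.loc[self.root]
        return float(row["ci_lower"]), float(row["ci_upper"])


def _fold(v1, t1, v2, t2, eps):
    """Combine two independent Gaussian messages (value, length-variance)."""
    t1 = max(t1, eps)
    t2 = max(t2, eps)
    v = (v1 / t1 + v2 / t2) / (1.0 / t1 + 1.0 / t2)
    t = t1 * t2 / (t1 + t2)
    contrast = (v1 - v2) / np.sqrt(t1 + t2)
    return v, t, contrast


def ml_ancestral_states(tree: Phylogeny, values) -> AncestralStates:
    """Reconstruct one trait at every internal node.

    ``values`` maps tip labels to trait values (dict, Series, or array in
    tip order).  Raises :class:`AncestralError` when tips are missing.
    Zero-length branches are handled by the standard contrasts guard (a
    tiny effective length), so a zero-length cherry does not divide by
    zero.
    """
    tips = tree.tip_labels
    if isinstance(values, pd.Series):
        vmap = values.to_dict()
    elif isinstance(values, dict):
        vmap = values
    else:
        arr = np.asarray(values, dtype=float)
        if arr.size != len(tips):
            raise AncestralError("value vector length does not match tip count")
        vmap = dict(zip(tips, arr))
    missing = [t for t in tips if t not in vmap or pd.isna(vmap[t])]
    if missing:
        raise AncestralError(f"missing tip values: {missing}")
    n = tree.n_tips
    if n < 2:
        raise AncestralError("need at least 2 tips")

    eps = 1e-12 * max(tree.height, 1.0)
    N = tree.n_nodes
    up_val = np.zeros(N)
    up_t = np.zeros(N)  # conditional variance at the node, in branch-length units
    contrasts: list[float] = []

    for i in tree.postorder():
        i = int(i)
        if tree.is_tip(i):
            up_val[i] = vmap[tree.labels[i]]
            up_t[i] = 0.0
        else:
            kids = tree.children[i]
            v, t = up_val[kids[0]], up_t[kids[0]] + tree.lengths[kids[0]]
            for c in kids[1:]:
                v, t, u = _fold(v, t, up_val[c], up_t[c] + tree.lengths[c], eps)
                contrasts.append(u)
            up_val[i] = v
            up_t[i] = t

    sigma2 = float(np.sum(np.square(contrasts)) / (n - 1))

    # downward pass: message from the rest of the tree, measured at each node
    out_val = np.zeros(N)
    out_t = np.full(N, np.inf)
    for i in tree.preorder():
        i = int(i)
        for c in tree.children[i]:
            # combine at node i: messages from other children + i's own outside
            acc_val, acc_prec = 0.0, 0.0
            for s in tree.children[i]:
                if s == c:
                    continue
                t = max(up_t[s] + tree.lengths[s], eps)
                acc_val += up_val[s] / t
                acc_prec += 1.0 / t
            if np.isfinite(out_t[i]):
                t = max(out_t[i], eps)
                acc_val += out_val[i] / t
                acc_prec += 1.0 / t
            if acc_prec > 0:
                out_val[c] = acc_val / acc_prec
                out_t[c] = 1.0 / acc_prec + tree.lengths[c]

    rows = []
    index = []
    for i in range(N):
        if tree.is_tip(i):
            continue
        if i == tree.root or not np.isfinite(out_t[i]):
            est, tvar = up_val[i], up_t[i]
        else:
            below_t = max(up_t[i], eps)
            outside_t = max(out_t[i], eps)
            prec = 1.0 / below_t + 1.0 / outside_t
            est = (up_val[i] / below_t + out_val[i] / outside_t) / prec
            tvar = 1.0 / prec
        var = sigma2 * tvar
        half = CI_Z * np.sqrt(var)
        rows.append((est, var, est - half, est + half))
        index.append(i)
    table = pd.DataFrame(
        rows, index=index, columns=["estimate", "variance", "ci_lower", "ci_upper"]
    )
    table.index.name = "node"
    return AncestralStates(table=table, sigma2=sigma2, root=tree.root)


def root_presence_call(states: AncestralStates) -> bool:
    """A trait is called present at the root iff its CI is strictly positive."""
    lo, _ = states.root_ci
    return bool(lo > 0.0)
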