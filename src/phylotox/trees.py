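"""Rooted, time-calibrated phylogenies.

The analyses in this package all start from a rooted tree with branch
lengths in units of time (here millions of years, My).  The tree plays the
role of the pedigree in the animal model: the shared root-to-MRCA path
length between two species measures how much Brownian-motion history they
have in common, and the matrix of those shared paths is the phylogenetic
relatedness matrix ``A`` used by the mixed model, the OU machinery and the
ancestral-state reconstruction.

Newick parsing is delegated to :mod:`dendropy`; the in-memory container is
a small array-based structure so that traversals, pruning and covariance
matrices are cheap and deterministic.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeError",
    "Phylogeny",
    "parse_newick",
    "read_newick",
    "prune_to_taxa",
    "shared_time_matrix",
    "patristic_matrix",
    "phylo_vcv",
]


class TreeError(ValueError):
    """A tree violates a structural requirement (shape, labels, branch lengths)."""


class Phylogeny:
    """A rooted tree with branch lengths.

    Nodes are integers ``0 .. n_nodes-1`` with ``parent[i] < i`` for every
    non-root node; node 0 is the root.  ``lengths[i]`` is the length of the
    branch *above* node ``i`` (0 for the root).  Tips carry unique string
    labels; internal labels are optional and preserved.

    Polytomies are legal and never resolved.
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[str | None],
        validate: bool = True,
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                children[p].append(i)
        self.children = children
        if validate:
            if len(roots) != 1 or roots[0] != 0:
                raise TreeError("tree must have exactly one root, at node 0")
            if not (self.lengths.size == n and len(self.labels) == n):
                raise TreeError("parent, lengths and labels must have equal size")
            if np.any(self.parent[1:] >= np.arange(1, n)):
                raise TreeError("nodes must be numbered so that parent[i] < i")
            if np.any(self.lengths[1:] < 0):
                bad = int(np.nonzero(self.lengths[1:] < 0)[0][0]) + 1
                raise TreeError(f"negative branch length at node {bad}")
            tips = [self.labels[i] for i in range(n) if not children[i]]
            if any(t is None for t in tips):
                raise TreeError("every tip must carry a label")
            if len(set(tips)) != len(tips):
                dup = sorted({t for t in tips if tips.count(t) > 1})
                raise TreeError(f"duplicate tip labels: {dup}")
        self.root = 0
        self._cache: dict[str, object] = {}

    # ---------------------------------------------------------------- shape
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def tip_indices(self) -> np.ndarray:
        if "tips" not in self._cache:
            self._cache["tips"] = np.array(
                [i for i in range(self.n_nodes) if not self.children[i]], dtype=np.int64
            )
        return self._cache["tips"]  # type: ignore[return-value]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return self.tip_indices.size

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def preorder(self) -> np.ndarray:
        """Depth-first (root-first) node order, children visited in index order."""
        if "preorder" not in self._cache:
            order = np.empty(self.n_nodes, dtype=np.int64)
            stack = [self.root]
            k = 0
            while stack:
                i = stack.pop()
                order[k] = i
                k += 1
                stack.extend(reversed(self.children[i]))
            self._cache["preorder"] = order
        return self._cache["preorder"]  # type: ignore[return-value]

    def postorder(self) -> np.ndarray:
        return self.preorder()[::-1]

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (My)."""
        if "depths" not in self._cache:
            d = np.zeros(self.n_nodes)
            for i in range(1, self.n_nodes):
                d[i] = d[self.parent[i]] + self.lengths[i]
            self._cache["depths"] = d
        return self._cache["depths"]  # type: ignore[return-value]

    @property
    def height(self) -> float:
        """Maximum root-to-tip path length (tree age for an ultrametric tree)."""
        return float(self.depths()[self.tip_indices].max())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.depths()[self.tip_indices]
        return bool(np.ptp(d) <= rtol * max(d.max(), 1e-300))

    # ----------------------------------------------------------------- I/O
    def write_newick(self, precision: int = 12) -> str:
        fmt = f":{{:.{precision}g}}"

        def rec(i: int) -> str:
            if not self.children[i]:
                s = self.labels[i] or ""
            else:
                s = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
                s += self.labels[i] or ""
            if i != self.root:
                s += fmt.format(self.lengths[i])
            return s

        return rec(self.root) + ";"

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.lengths.copy(), list(self.labels))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Phylogeny {self.n_tips} tips, height {self.height:.4g}>"


def parse_newick(text: str) -> Phylogeny:
    """Parse a rooted Newick string with branch lengths.

    Branch lengths are required on every edge except the root edge.
    Internal node labels are optional and preserved.  Raises
    :class:`TreeError` for malformed strings, duplicate tip labels or
    missing branch lengths, naming the offending taxon where possible.
    """
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"Newick parse failed: {exc}") from None

    parent: list[int] = []
    lengths: list[float] = []
    labels: list[str | None] = []

    def visit(dnode, parent_id: int) -> None:
        i = len(parent)
        parent.append(parent_id)
        if parent_id < 0:
            lengths.append(0.0)
        else:
            if dnode.edge.length is None:
                who = dnode.taxon.label if dnode.taxon else (dnode.label or f"node {i}")
                raise TreeError(f"missing branch length above '{who}'")
            lengths.append(float(dnode.edge.length))
        kids = dnode.child_nodes()
        if kids:
            labels.append(dnode.label)
        else:
            if dnode.taxon is None or not dnode.taxon.label:
                raise TreeError(f"unlabeled tip (node {i})")
            labels.append(dnode.taxon.label)
        for k in kids:
            visit(k, i)

    visit(dtree.seed_node, -1)
    return Phylogeny(parent, lengths, labels)


def read_newick(path) -> Phylogeny:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def prune_to_taxa(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Restrict a tree to a subset of tips.

    Pairwise patristic distances among retained tips are preserved exactly:
    dropped subtrees are removed, degree-2 internal nodes are suppressed
    with their branch lengths summed, and the MRCA of the kept taxa becomes
    the new root.
    """
    keep = set(keep)
    missing = sorted(keep - set(tree.tip_labels))
    if missing:
        raise TreeError(f"taxa not in tree: {missing}")
    if len(keep) < 2:
        raise TreeError("need at least 2 taxa to prune to")

    marked = np.zeros(tree.n_nodes, dtype=bool)
    for i in tree.tip_indices:
        if tree.labels[i] in keep:
            j = int(i)
            while j >= 0 and not marked[j]:
                marked[j] = True
                j = int(tree.parent[j])

    def kept_children(i: int) -> list[int]:
        return [c for c in tree.children[i] if marked[c]]

    # new root = first node (from the old root) with >= 2 kept children
    r = tree.root
    while not tree.is_tip(r) and len(kept_children(r)) == 1:
        r = kept_children(r)[0]

    parent_l: list[int] = []
    length_l: list[float] = []
    label_l: list[str | None] = []

    def build(old: int, extra: float, newp: int) -> None:
        kids = kept_children(old)
        if len(kids) == 1:
            # suppress degree-2 node: pass its branch length down
            c = kids[0]
            build(c, extra + (tree.lengths[old] if newp >= 0 else 0.0), newp)
            return
        idx = len(parent_l)
        parent_l.append(newp)
        length_l.append(tree.lengths[old] + extra if newp >= 0 else 0.0)
        label_l.append(tree.labels[old])
        for c in kids:
            build(c, 0.0, idx)

    build(r, 0.0, -1)
    return Phylogeny(parent_l, length_l, label_l)


def shared_time_matrix(tree: Phylogeny) -> pd.DataFrame:
    """Root-to-MRCA path length for every pair of tips (diagonal: tip depth)."""
    tips = tree.tip_indices
    pos = {int(t): k for k, t in enumerate(tips)}
    n = tips.size
    depths = tree.depths()
    S = np.zeros((n, n))
    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder():
        node = int(node)
        if tree.is_tip(node):
            k = pos[node]
            S[k, k] = depths[node]
            tipsets[node] = [k]
        else:
            kid_sets = [tipsets.pop(c) for c in tree.children[node]]
            d = depths[node]
            for a in range(len(kid_sets)):
                for b in range(a + 1, len(kid_sets)):
                    ix = np.ix_(kid_sets[a], kid_sets[b])
                    S[ix] = d
                    S[np.ix_(kid_sets[b], kid_sets[a])] = d
            tipsets[node] = [k for s in kid_sets for k in s]
    labels = tree.tip_labels
    return pd.DataFrame(S, index=labels, columns=labels)


def patristic_matrix(tree: Phylogeny) -> pd.DataFrame:
    """Pairwise path length between tips (My)."""
    S = shared_time_matrix(tree)
    d = np.diag(S.to_numpy())
    D = d[:, None] + d[None, :] - 2.0 * S.to_numpy()
    return pd.DataFrame(D, index=S.index, columns=S.columns)


def phylo_vcv(tree: Phylogeny, scale: bool = True) -> pd.DataFrame:
    """Phylogenetic relatedness (shared-path-length) matrix.

    This is the ``A`` matrix of the animal model with the phylogeny standing
    in for the pedigree: ``A[i, j]`` is the root-to-MRCA path shared by tips
    ``i`` and ``j``, and the diagonal holds root-to-tip depths.  With
    ``scale=True`` (default) the matrix is divided by the tree height so
    that an ultrametric tree has unit diagonal; this keeps the phylogenetic
    and residual covariance components of the mixed model on a common scale
    and makes the per-trait signal ratio interpretable on [0, 1].
    """
    if tree.n_tips < 2:
        raise TreeError("phylo_vcv needs at least 2 tips")
    S = shared_time_matrix(tree)
    if scale:
        S = S / tree.height
    return S
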