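"""Phylomorphospace: eigen-analysis of the phylogenetic covariance matrix.

The posterior-mean PCOV describes how toxin families covary over
macroevolutionary time.  Its eigenvectors define the axes of the venom
phylomorphospace; projecting the (scaled) species abundances onto them
places each species in that space.  The fraction of trace captured by the
leading axes measures the dimensionality of the venom phenotype.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["PCAResult", "pcov_pca", "species_scores"]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    loadings: pd.DataFrame  # component x axis, orthonormal columns
    variance_fractions: np.ndarray  # eigenvalue / trace, sums to 1
    scores: pd.DataFrame | None = None  # species x axis

    @property
    def axes(self) -> list[str]:
        return list(self.loadings.columns)

    def cumulative_variance(self, k: int) -> float:
        """Fraction of total variance on the first ``k`` axes."""
        return float(self.variance_fractions[:k].sum())


def pcov_pca(G, components: list[str] | None = None) -> PCAResult:
    """Eigendecomposition of a symmetric PCOV matrix.

    Axes are ordered by decreasing eigenvalue and signed so that the
    largest-magnitude loading on each axis is positive (a deterministic
    convention so plots and tests are reproducible).
    """
    if isinstance(G, pd.DataFrame):
        components = list(G.columns)
        Gm = G.to_numpy(dtype=float)
    else:
        Gm = np.asarray(G, dtype=float)
        if components is None:
            components = [f"c{i+1}" for i in range(Gm.shape[0])]
    if Gm.ndim != 2 or Gm.shape[0] != Gm.shape[1] or Gm.shape[0] < 2:
        raise ValueError("G must be square with at least 2 components")
    asym = np.abs(Gm - Gm.T).max()
    if asym > 1e-8:
        raise ValueError(f"G is not symmetric (max asymmetry {asym:.3g})")

    w, V = np.linalg.eigh((Gm + Gm.T) / 2.0)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    axes = [f"PC{j+1}" for j in range(V.shape[1])]
    return PCAResult(
        eigenvalues=w,
        loadings=pd.DataFrame(V, index=components, columns=axes),
        variance_fractions=w / w.sum(),
    )


def species_scores(
    data: pd.DataFrame,
    result: PCAResult,
    tree=None,
    phylo_mean: bool = False,
) -> PCAResult:
    """Project species onto the PCOV axes.

    ``data`` holds the scaled abundances (species x component, columns
    matching the loadings).  Rows are centered on the cross-species
    arithmetic mean, or on the phylogenetically weighted (GLS) mean when
    ``phylo_mean=True`` and a tree is supplied.
    """
    comps = list(result.loadings.index)
    if set(data.columns) != set(comps):
        raise ValueError(
            f"data columns {sorted(data.columns)} do not match loadings {sorted(comps)}"
        )
    X = data[comps].to_numpy(dtype=float)
    if phylo_mean:
        if tree is None:
            raise ValueError("phylo_mean=True requires a tree")
        from .trees import phylo_vcv

        C = phylo_vcv(tree, scale=True).loc[data.index, data.index].to_numpy()
        ones = np.ones(len(data))
        w = np.linalg.solve(C, ones)
        mu = (w @ X) / (ones @ w)
    else:
        mu = X.mean(axis=0)
    scores = (X - mu) @ result.loadings.to_numpy()
    return replace(
        result,
        scores=pd.DataFrame(scores, index=data.index, columns=result.axes),
    )
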