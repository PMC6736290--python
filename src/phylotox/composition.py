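"""Compositional preprocessing of toxin-family abundance tables.

Venom transcriptome studies report toxin-family expression as percentages
of the toxin transcriptome, so each species is a composition: nonnegative
parts summing to 100, with structural zeros where a family is genuinely
absent.  This module provides the curation steps applied before any
phylogenetic modeling:

* :func:`percent_normalize` — convert raw (e.g. FPKM) values to percent.
* :func:`prevalence_filter` — keep families present in at least a given
  fraction of species (the study design keeps families in >= 50% of
  species) and re-close the composition.
* :func:`impute_zeros` — deterministic multiplicative replacement of
  structural zeros, needed before log-ratio transforms.
* :func:`clr_transform` — centered log-ratio transform (via scikit-bio),
  used to validate that results are robust to the sum constraint.

Values below ``TRACE_THRESHOLD`` (1e-6 percent) count as zeros throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompositionError",
    "ToxinAbundanceTable",
    "TRACE_THRESHOLD",
    "percent_normalize",
    "prevalence_filter",
    "impute_zeros",
    "clr_transform",
    "read_abundance_table",
]

#: abundances at or below this value (percent) are treated as structural zeros
TRACE_THRESHOLD = 1e-6


class CompositionError(ValueError):
    """Invalid compositional input (all-zero rows, nonpositive parts, ...)."""


@dataclass
class ToxinAbundanceTable:
    """Species x toxin-family percent abundances plus a per-species batch label.

    ``values`` is indexed by species (matching tree tip labels) with one
    column per toxin family; rows sum to 100.  ``batch`` optionally records
    a categorical covariate such as the sequencing technology of the source
    study, used downstream as a fixed effect.
    """

    values: pd.DataFrame
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.batch is not None:
            self.batch = self.batch.reindex(self.values.index)

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def components(self) -> list[str]:
        return list(self.values.columns)

    def presence(self) -> pd.DataFrame:
        return self.values > TRACE_THRESHOLD

    def prevalence(self) -> pd.Series:
        """Fraction of species in which each component is present."""
        return self.presence().mean(axis=0)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        if self.batch is not None:
            out["batch"] = self.batch
        out.to_csv(path, sep="\t", index_label="species")

    def copy(self) -> "ToxinAbundanceTable":
        return ToxinAbundanceTable(
            self.values.copy(), None if self.batch is None else self.batch.copy()
        )


def read_abundance_table(path) -> ToxinAbundanceTable:
    """Read a TSV/CSV table: first column species, optional 'batch' column."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    batch = None
    if "batch" in df.columns:
        batch = df.pop("batch").astype(str)
    return ToxinAbundanceTable(df.astype(float), batch)


def _as_frame(raw) -> pd.DataFrame:
    if isinstance(raw, ToxinAbundanceTable):
        return raw.values
    return pd.DataFrame(raw).astype(float)


def percent_normalize(raw, batch: pd.Series | None = None) -> ToxinAbundanceTable:
    """Convert nonnegative raw abundances (e.g. FPKM) to percent of row total.

    Zeros are preserved as zeros.  Raises :class:`CompositionError` naming
    the species if any row is all zero or contains a negative value.
    """
    df = _as_frame(raw)
    if isinstance(raw, ToxinAbundanceTable) and batch is None:
        batch = raw.batch
    if (df.to_numpy() < 0).any():
        bad = df.index[(df < 0).any(axis=1)].tolist()
        raise CompositionError(f"negative abundances for species: {bad}")
    totals = df.sum(axis=1)
    zero_rows = totals[totals <= 0].index.tolist()
    if zero_rows:
        raise CompositionError(f"all-zero abundance rows for species: {zero_rows}")
    return ToxinAbundanceTable(df.div(totals, axis=0) * 100.0, batch)


def prevalence_filter(
    table: ToxinAbundanceTable, threshold: float = 0.5
) -> ToxinAbundanceTable:
    """Keep components present in at least ``threshold`` of species (inclusive).

    Retained rows are re-normalized to sum to 100, so downstream analyses
    operate on a closed composition of the retained families.
    """
    if not 0 < threshold <= 1:
        raise CompositionError("threshold must be in (0, 1]")
    prev = table.prevalence()
    kept = prev.index[prev >= threshold].tolist()
    if not kept:
        raise CompositionError("prevalence filter removed every component")
    return percent_normalize(table.values[kept], table.batch)


def impute_zeros(
    table: ToxinAbundanceTable, delta: float | None = None
) -> ToxinAbundanceTable:
    """Replace structural zeros by a small constant, multiplicatively.

    Each zero cell receives ``delta`` (default: 0.65 x the smallest nonzero
    value in the table) and the nonzero cells of that row are scaled by
    ``1 - k * delta / 100`` (``k`` = zeros in the row), so the row still
    sums to 100.  A table without zeros is returned unchanged.
    """
    X = table.values.to_numpy(copy=True)
    zero = X <= TRACE_THRESHOLD
    if not zero.any():
        return table.copy()
    if delta is None:
        delta = 0.65 * X[~zero].min()
    k = zero.sum(axis=1)
    if np.any(k * delta >= 100.0):
        raise CompositionError("imputation value too large: would exceed row total")
    scale = 1.0 - k * delta / 100.0
    X = X * scale[:, None]
    X[zero] = delta
    return ToxinAbundanceTable(
        pd.DataFrame(X, index=table.values.index, columns=table.values.columns),
        table.batch,
    )


def clr_transform(table: ToxinAbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio transform of a strictly positive composition.

    Maps each row to log(part / geometric mean of the row); output rows sum
    to zero.  Structural zeros must be imputed first (:func:`impute_zeros`).
    """
    from skbio.stats.composition import clr

    df = _as_frame(table)
    if (df.to_numpy() <= 0).any():
        raise CompositionError(
            "clr requires strictly positive values; run impute_zeros first"
        )
    closed = df.to_numpy() / df.to_numpy().sum(axis=1, keepdims=True)
    return pd.DataFrame(clr(closed), index=df.index, columns=df.columns)
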