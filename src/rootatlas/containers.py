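"""Core data containers shared across the pipeline.

Matrices are stored gene-major (genes x cells) as dense integer / float
arrays: the synthetic scale this package targets (thousands of genes and
cells) comfortably fits in memory and dense arithmetic keeps downstream
code simple.  I/O round-trips through sparse Matrix Market (see
:mod:`rootatlas.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "ExpressionMatrix"]


@dataclass
class CountMatrix:
    """Integer gene x cell count matrix with cell and gene metadata.

    Parameters
    ----------
    counts
        ``(n_genes, n_cells)`` non-negative integer array.
    gene_ids, cell_ids
        Unique identifiers for rows / columns.
    cell_meta
        Indexed by ``cell_ids``; expected columns include ``sample`` and
        ``condition`` (extra columns are carried along untouched).
    gene_meta
        Indexed by ``gene_ids``; boolean flag columns such as ``is_mito``
        and ``is_chloroplast``.
    """

    counts: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame = field(default=None)
    gene_meta: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cell_ids)
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=self.gene_ids)
        self.validate()

    def validate(self) -> None:
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.gene_ids.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.cell_ids.has_duplicates:
            raise ValueError("duplicate cell identifiers")
        if not self.cell_meta.index.equals(self.cell_ids):
            raise ValueError("cell_meta index must equal cell_ids")
        if not self.gene_meta.index.equals(self.gene_ids):
            raise ValueError("gene_meta index must equal gene_ids")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def umi_totals(self) -> np.ndarray:
        """Per-cell UMI totals (column sums), recomputed on demand."""
        return self.counts.sum(axis=0)

    def gene_flags(self, column: str) -> np.ndarray:
        if column not in self.gene_meta.columns:
            return np.zeros(self.n_genes, dtype=bool)
        return self.gene_meta[column].to_numpy(dtype=bool)

    # ------------------------------------------------------------------
    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to the boolean/positional cell mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            counts=self.counts[:, keep],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[keep],
            cell_meta=self.cell_meta.iloc[keep],
            gene_meta=self.gene_meta,
        )

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            counts=self.counts[keep, :],
            gene_ids=self.gene_ids[keep],
            cell_ids=self.cell_ids,
            cell_meta=self.cell_meta,
            gene_meta=self.gene_meta.iloc[keep],
        )


@dataclass
class ExpressionMatrix:
    """Normalized (log-scale) gene x cell expression with provenance."""

    values: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            values=self.values[keep, :],
            gene_ids=self.gene_ids[keep],
            cell_ids=self.cell_ids,
            provenance=self.provenance,
        )
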