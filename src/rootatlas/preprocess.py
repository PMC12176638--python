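"""Cell quality filtering, gene-exclusion screens and normalization.

QC removes high-mitochondrial cells (fraction of counts in mito-flagged
genes above ``mito_max``) and then the top ``top_umi_frac`` of surviving
cells by UMI total.  Gene screens flag handling-induced (protoplasting)
genes from paired bulk profiles by absolute log2 fold change, and
mitochondrial / chloroplast / handling gene lists are excluded before
integration and differential expression.

Normalization substitutes the variance-stabilizing transform used by the
original workflow with per-cell scaling to the median UMI total followed
by log1p; the substitution is recorded in the matrix provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix

__all__ = [
    "QcThresholds",
    "qc_filter",
    "protoplast_gene_screen",
    "exclude_genes",
    "normalize",
]


@dataclass
class QcThresholds:
    mito_max: float = 0.05
    top_umi_frac: float = 0.01
    protoplast_abs_log2fc: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mito_max < 1.0:
            raise ValueError("mito_max must be in (0, 1)")
        if not 0.0 <= self.top_umi_frac < 1.0:
            raise ValueError("top_umi_frac must be in [0, 1)")
        if self.protoplast_abs_log2fc <= 0:
            raise ValueError("protoplast_abs_log2fc must be positive")


def qc_filter(counts: CountMatrix, thresholds: QcThresholds = None):
    """Remove high-mito cells, then the top UMI fraction of the remainder.

    Returns ``(filtered_matrix, report)`` where the report is a DataFrame
    with columns ``cell_id``, ``reason`` (``high_mito`` | ``top_umi``) and
    ``value`` (the offending statistic).  Raises if no mito flags are
    present or if filtering removes every cell.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    is_mito = counts.gene_flags("is_mito")
    if not is_mito.any():
        raise ValueError("no genes flagged is_mito; cannot run the mito filter")
    totals = counts.umi_totals().astype(float)
    if (totals == 0).any():
        raise ValueError("zero-count cells present; remove them first")
    mito_frac = counts.counts[is_mito, :].sum(axis=0) / totals

    removed = []
    keep = mito_frac <= thresholds.mito_max
    for i in np.flatnonzero(~keep):
        removed.append((counts.cell_ids[i], "high_mito", mito_frac[i]))

    surv_idx = np.flatnonzero(keep)
    n_top = ceil(thresholds.top_umi_frac * len(surv_idx))
    if n_top > 0 and len(surv_idx):
        # stable order: descending UMI total, ties by position
        order = surv_idx[np.argsort(-totals[surv_idx], kind="stable")]
        top = order[:n_top]
        for i in top:
            removed.append((counts.cell_ids[i], "top_umi", totals[i]))
        keep[top] = False

    if not keep.any():
        n_mito = sum(1 for r in removed if r[1] == "high_mito")
        n_top_r = sum(1 for r in removed if r[1] == "top_umi")
        raise ValueError(
            f"qc_filter removed all cells (high_mito={n_mito}, top_umi={n_top_r})"
        )
    report = pd.DataFrame(removed, columns=["cell_id", "reason", "value"])
    return counts.subset_cells(keep), report


def protoplast_gene_screen(
    bulk_a: pd.Series,
    bulk_b: pd.Series,
    thresholds: QcThresholds = None,
    pseudocount: float = 0.5,
) -> list:
    """Genes whose |log2((a+c)/(b+c))| meets the threshold (inclusive).

    ``bulk_a`` / ``bulk_b`` are mean-count or CPM profiles over a shared
    gene set (e.g. protoplasted vs intact tissue).  With ``pseudocount=0``
    genes with one-sided zeros yield infinite fold change (flagged) and
    0/0 is undefined (not flagged).
    """
    if thresholds is None:
        thresholds = QcThresholds()
    if not bulk_a.index.equals(bulk_b.index):
        if set(bulk_a.index) != set(bulk_b.index):
            raise ValueError("bulk profiles do not share a gene set")
        bulk_b = bulk_b.reindex(bulk_a.index)
    a = bulk_a.to_numpy(dtype=float) + pseudocount
    b = bulk_b.to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(a) - np.log2(b)
    hit = np.abs(lfc) >= thresholds.protoplast_abs_log2fc
    hit &= ~np.isnan(lfc)
    return list(bulk_a.index[hit])


def exclude_genes(
    matrix: CountMatrix,
    mito=(),
    chloroplast=(),
    protoplast=(),
):
    """Drop the union of the given gene lists, preserving gene order.

    Unknown identifiers are reported (returned) rather than fatal.  Returns
    ``(filtered_matrix, unknown_ids)``.
    """
    union = set(mito) | set(chloroplast) | set(protoplast)
    known = set(matrix.gene_ids)
    unknown = sorted(union - known)
    drop = matrix.gene_ids.isin(union)
    if drop.all():
        raise ValueError("gene exclusion would empty the matrix")
    return matrix.subset_genes(~drop), unknown


def normalize(counts: CountMatrix) -> ExpressionMatrix:
    """Median-library scaling followed by log1p.

    Each cell's counts are scaled so its total equals the median UMI total
    of the input, then log1p-transformed.  Cells with zero counts are an
    error (they cannot be scaled).
    """
    totals = counts.umi_totals().astype(float)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(
            f"cell {counts.cell_ids[zero[0]]!r} has zero counts; cannot normalize"
        )
    median = np.median(totals)
    scaled = counts.counts * (median / totals)[None, :]
    return ExpressionMatrix(
        values=np.log1p(scaled),
        gene_ids=counts.gene_ids,
        cell_ids=counts.cell_ids,
        provenance=f"median-library scaling (target={median:g}) + log1p",
    )
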