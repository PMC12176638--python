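"""Pseudobulk differential expression, DEG filters and enrichment.

Raw counts are summed per (sample, cell type) pair; pairs with fewer cells
than ``min_cells`` are flagged and excluded from testing.  The per-gene
test is a negative-binomial likelihood-ratio test of the condition effect
with library-size offsets: dispersion is estimated per gene by the method
of moments and shrunk toward the pooled common dispersion, then the
group-mean model is compared to the pooled-mean model by chi-square LRT.
Because the design is a plain two-group contrast the MLEs reduce to
one-parameter Newton solves, vectorized across genes.

A gene is a DEG when (inclusively) FDR <= fdr_max, |linear FC| >= fc_min
and detection frequency >= det_min in at least one condition; FDR is
Benjamini-Hochberg within cell type.  Term enrichment is the upper-tail
hypergeometric test with BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, hypergeom
from statsmodels.stats.multitest import multipletests

from .annotate import UNANNOTATED
from .containers import CountMatrix

__all__ = [
    "DeThresholds",
    "PseudobulkTable",
    "aggregate_pseudobulk",
    "nb_de_test",
    "detection_frequency",
    "detection_frequencies",
    "run_de",
    "filter_degs",
    "deg_summary",
    "hypergeom_enrich",
]

CPM_PSEUDOCOUNT = 0.5
DISPERSION_SHRINK = 0.85  # weight on the common dispersion
MIN_DISPERSION = 1e-6


@dataclass
class DeThresholds:
    fdr_max: float = 0.05
    fc_min: float = 1.5       # linear scale
    det_min: float = 0.10
    min_cells: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_max < 1.0:
            raise ValueError("fdr_max must be in (0, 1)")
        if self.fc_min < 1.0:
            raise ValueError("fc_min must be >= 1 (linear fold change)")
        if not 0.0 <= self.det_min <= 1.0:
            raise ValueError("det_min must be in [0, 1]")
        if self.min_cells < 1:
            raise ValueError("min_cells must be positive")


@dataclass
class PseudobulkTable:
    """Gene x (sample, cell type) integer raw-count sums."""

    counts: pd.DataFrame   # genes x pair-id columns
    pairs: pd.DataFrame    # index pair-id; sample, cell_type, condition, n_cells

    def usable(self, min_cells: int) -> pd.Index:
        return self.pairs.index[self.pairs["n_cells"] >= min_cells]


def aggregate_pseudobulk(counts: CountMatrix, labels) -> PseudobulkTable:
    """Sum raw counts per (sample, cell type); unannotated cells excluded."""
    types = labels.types if hasattr(labels, "types") else pd.Series(labels)
    types = types.reindex(counts.cell_ids)
    if types.isna().any():
        raise ValueError("labels do not cover all cells in the matrix")
    annotated = (types != UNANNOTATED).to_numpy()
    if not annotated.any():
        raise ValueError("no annotated cells to aggregate")
    sample = counts.cell_meta["sample"].to_numpy(dtype=object)
    condition = counts.cell_meta["condition"].to_numpy(dtype=object)
    keys = pd.DataFrame(
        {"sample": sample, "cell_type": types.to_numpy(), "condition": condition}
    )[annotated]
    grouped = keys.groupby(["sample", "cell_type"], sort=True)
    cols, meta = {}, []
    for (s, ct), sub in grouped:
        pid = f"{s}|{ct}"
        # sub.index holds positions in the full cell axis
        cols[pid] = counts.counts[:, sub.index.to_numpy()].sum(axis=1)
        meta.append((pid, s, ct, sub["condition"].iloc[0], len(sub)))
    pairs = pd.DataFrame(
        meta, columns=["pair", "sample", "cell_type", "condition", "n_cells"]
    ).set_index("pair")
    table = pd.DataFrame(cols, index=counts.gene_ids)
    return PseudobulkTable(counts=table, pairs=pairs)


# ----------------------------------------------------------------------
def _size_factors(y: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (robust to asymmetric DE), falling
    back to total-count factors when too few genes are always detected."""
    lib = y.sum(axis=0)
    always = np.all(y > 0, axis=1)
    if always.sum() >= 20:
        logs = np.log(y[always])
        ratios = logs - logs.mean(axis=1, keepdims=True)
        s = np.exp(np.median(ratios, axis=0))
    else:
        s = lib / np.exp(np.mean(np.log(lib)))
    return s / np.exp(np.mean(np.log(s)))


def _nb_loglik(y, mu, phi):
    """Elementwise NB log-likelihood, var = mu + phi mu^2 (phi > 0)."""
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-12)
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def _fit_nb_mean(y, s, phi, n_iter: int = 50, tol: float = 1e-10):
    """MLE of q in mu_ij = q_i * s_j for NB with per-gene dispersion phi.

    ``y``: genes x samples; ``s``: sample size factors; ``phi``: per-gene.
    Vectorized Newton on beta = log q.  Returns q (genes,).
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    tot = y.sum(axis=1)
    q = np.maximum(tot / s.sum(), 1e-12)
    beta = np.log(q)
    phi = np.asarray(phi, dtype=float)[:, None]
    for _ in range(n_iter):
        mu = np.exp(beta)[:, None] * s[None, :]
        denom = 1.0 + phi * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu * (1.0 + phi * y) / denom**2).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return np.exp(beta)


def _moment_dispersion(y, s, groups):
    """Method-of-moments per-gene dispersion pooled across groups.

    ``groups``: list of column-index arrays.  Size-factor-normalized counts
    z = y / s have E z = q and Var z ~ q / s_eff + phi q^2; we solve for phi
    within each group and pool by residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    num = np.zeros(y.shape[0])
    den = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        z = y[:, idx] / s[idx][None, :]
        m = z.mean(axis=1)
        v = z.var(axis=1, ddof=1)
        inv_s = np.mean(1.0 / s[idx])
        with np.errstate(invalid="ignore", divide="ignore"):
            phi_g = (v - m * inv_s) / m**2
        phi_g = np.where(np.isfinite(phi_g), phi_g, 0.0)
        phi_g = np.maximum(phi_g, 0.0)
        w = len(idx) - 1
        num += w * phi_g
        den += w
    if den == 0:
        return np.zeros(y.shape[0])
    return num / den


def nb_de_test(
    pb: PseudobulkTable,
    cell_type: str,
    cond_a: str,
    cond_b: str,
    thresholds: DeThresholds = None,
    shrink_weight: float = DISPERSION_SHRINK,
) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test of condition B vs A for one type.

    Returns a DataFrame indexed by gene with ``log2fc`` (B over A, CPM
    pseudocount 0.5) and ``p``.  Genes with zero counts in every usable
    pair get p = 1 and log2fc = 0.
    """
    if thresholds is None:
        thresholds = DeThresholds()
    usable = pb.usable(thresholds.min_cells)
    meta = pb.pairs.loc[usable]
    sel = meta["cell_type"] == cell_type
    meta = meta[sel]
    cols_a = meta.index[meta["condition"] == cond_a]
    cols_b = meta.index[meta["condition"] == cond_b]
    for cond, cols in [(cond_a, cols_a), (cond_b, cols_b)]:
        if len(cols) < 2:
            raise ValueError(
                f"condition {cond!r} has {len(cols)} usable pseudobulk pairs "
                f"for cell type {cell_type!r}; need >= 2"
            )
    cols = list(cols_a) + list(cols_b)
    y = pb.counts[cols].to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("pseudobulk pair with zero total counts")
    s = _size_factors(y)
    ia = np.arange(len(cols_a))
    ib = np.arange(len(cols_a), len(cols))

    phi_gene = _moment_dispersion(y, s, [ia, ib])
    expressed = y.sum(axis=1) > 0
    mean_norm = (y / s[None, :]).mean(axis=1)
    informative = mean_norm >= 1.0
    common = (
        float(np.mean(phi_gene[informative])) if informative.any() else 0.0
    )
    phi = (1.0 - shrink_weight) * phi_gene + shrink_weight * common
    phi = np.maximum(phi, MIN_DISPERSION)

    q_null = _fit_nb_mean(y, s, phi)
    q_a = _fit_nb_mean(y[:, ia], s[ia], phi)
    q_b = _fit_nb_mean(y[:, ib], s[ib], phi)

    mu_null = q_null[:, None] * s[None, :]
    mu_full = np.empty_like(y)
    mu_full[:, ia] = q_a[:, None] * s[ia][None, :]
    mu_full[:, ib] = q_b[:, None] * s[ib][None, :]
    ll_null = _nb_loglik(y, mu_null, phi[:, None]).sum(axis=1)
    ll_full = _nb_loglik(y, mu_full, phi[:, None]).sum(axis=1)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = chi2.sf(lrt, df=1)
    p = np.where(expressed, p, 1.0)

    # CPM on size-factor-adjusted counts (scaled by the geometric-mean
    # library so the pseudocount keeps its per-million meaning)
    ref_lib = np.exp(np.mean(np.log(lib)))
    cpm_a = (y[:, ia] / s[ia][None, :] / ref_lib * 1e6).mean(axis=1)
    cpm_b = (y[:, ib] / s[ib][None, :] / ref_lib * 1e6).mean(axis=1)
    log2fc = np.log2(cpm_b + CPM_PSEUDOCOUNT) - np.log2(cpm_a + CPM_PSEUDOCOUNT)
    log2fc = np.where(expressed, log2fc, 0.0)
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=pb.counts.index)


# ----------------------------------------------------------------------
def detection_frequency(
    counts: CountMatrix, labels, gene: str, cell_type: str, condition: str
) -> float:
    """Fraction of cells in the (type, condition) stratum with count > 0."""
    freqs = detection_frequencies(counts, labels, cell_type, condition)
    return float(freqs.loc[gene])


def detection_frequencies(
    counts: CountMatrix, labels, cell_type: str, condition: str
) -> pd.Series:
    types = labels.types if hasattr(labels, "types") else pd.Series(labels)
    types = types.reindex(counts.cell_ids)
    mask = (
        (types == cell_type).to_numpy()
        & (counts.cell_meta["condition"] == condition).to_numpy()
    )
    if not mask.any():
        raise ValueError(
            f"empty stratum: type={cell_type!r}, condition={condition!r}"
        )
    frac = (counts.counts[:, mask] > 0).mean(axis=1)
    return pd.Series(frac, index=counts.gene_ids)


def run_de(
    counts: CountMatrix,
    labels,
    cond_a: str,
    cond_b: str,
    thresholds: DeThresholds = None,
    cell_types=None,
    shrink_weight: float = DISPERSION_SHRINK,
) -> pd.DataFrame:
    """Full DE pass: pseudobulk, per-type NB test, detection, FDR, flags.

    Returns the DEResult table with one row per (gene, cell type), FDR
    computed by Benjamini-Hochberg within cell type, and ``passes_filters``
    applying the inclusive threshold rules.  Types lacking enough usable
    pairs in either condition are skipped.
    """
    if thresholds is None:
        thresholds = DeThresholds()
    pb = aggregate_pseudobulk(counts, labels)
    if cell_types is None:
        cell_types = sorted(pb.pairs["cell_type"].unique())
    frames = []
    for ct in cell_types:
        try:
            res = nb_de_test(
                pb, ct, cond_a, cond_b, thresholds, shrink_weight=shrink_weight
            )
        except ValueError:
            continue
        det_a = detection_frequencies(counts, labels, ct, cond_a)
        det_b = detection_frequencies(counts, labels, ct, cond_b)
        fdr = multipletests(res["p"].to_numpy(), method="fdr_bh")[1]
        frame = pd.DataFrame(
            {
                "gene": res.index,
                "cell_type": ct,
                "log2fc": res["log2fc"].to_numpy(),
                "p": res["p"].to_numpy(),
                "fdr": fdr,
                "det_a": det_a.to_numpy(),
                "det_b": det_b.to_numpy(),
            }
        )
        frames.append(frame)
    if not frames:
        raise ValueError("no cell type had enough pseudobulk pairs for testing")
    out = pd.concat(frames, ignore_index=True)
    out["passes_filters"] = _pass_mask(out, thresholds)
    return out


def _pass_mask(table: pd.DataFrame, thresholds: DeThresholds) -> np.ndarray:
    lfc_min = np.log2(thresholds.fc_min)
    return (
        (table["fdr"].to_numpy() <= thresholds.fdr_max)
        & (np.abs(table["log2fc"].to_numpy()) >= lfc_min - 1e-12)
        & (
            np.maximum(table["det_a"].to_numpy(), table["det_b"].to_numpy())
            >= thresholds.det_min
        )
    )


def filter_degs(results: pd.DataFrame, thresholds: DeThresholds = None) -> pd.DataFrame:
    """Rows passing all three DEG rules (inclusive comparisons)."""
    if thresholds is None:
        thresholds = DeThresholds()
    return results[_pass_mask(results, thresholds)].reset_index(drop=True)


def deg_summary(degs: pd.DataFrame):
    """Per-cell-type DEG counts and the fraction of single-type DEGs.

    Returns ``(counts, unique_fraction)``; the fraction is None when the
    table is empty (not applicable).
    """
    if len(degs) == 0:
        return pd.Series(dtype=int), None
    counts = degs.groupby("cell_type")["gene"].nunique().sort_values(
        ascending=False
    )
    per_gene = degs.groupby("gene")["cell_type"].nunique()
    unique_fraction = float((per_gene == 1).mean())
    return counts, unique_fraction


# ----------------------------------------------------------------------
def hypergeom_enrich(selected, term_map: dict, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with BH correction.

    p = P(X >= overlap) with population N = |universe|, successes
    K = |term ∩ universe|, draws n = |selected|.  The header notes that BH
    replaces the original tool-specific correction.
    """
    universe = set(universe)
    selected = set(selected)
    if not universe:
        raise ValueError("empty universe")
    if not selected:
        raise ValueError("empty selection")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    n = len(selected)
    N = len(universe)
    rows = []
    for term, genes in term_map.items():
        tg = set(genes) & universe
        K = len(tg)
        overlap = len(tg & selected)
        p = float(hypergeom.sf(overlap - 1, N, K, n))
        rows.append((term, overlap, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "overlap", "K", "n", "N", "p"])
    if len(out):
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["fdr"] = []
    out.attrs["correction"] = "benjamini-hochberg (substituted)"
    return out
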