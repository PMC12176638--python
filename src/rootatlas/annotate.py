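"""Dual-resolution consensus cell-type annotation and stage assignment.

The scheme: embed cells with PCA, cluster a shared-nearest-neighbour graph
with modularity-based community detection at a low and a high resolution,
label clusters by average marker-gene z-scores, keep cells whose two
labels agree (the consensus), average consensus cells into per-type
reference profiles, then re-annotate *every* cell by Pearson correlation
against those profiles.  Developmental stages are assigned per cell by
correlation against bulk zone profiles.

All ties are broken deterministically (marker count, then lexicographic
name) and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import igraph as ig
import leidenalg
from scipy.sparse import csr_matrix
from scipy.stats import spearmanr
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import ExpressionMatrix

__all__ = [
    "UNANNOTATED",
    "MarkerSet",
    "ClusterAssignment",
    "ConsensusLabels",
    "ReferenceProfiles",
    "embed_pca",
    "build_snn_graph",
    "cluster_cells",
    "choose_resolution",
    "score_clusters_by_markers",
    "consensus_annotation",
    "build_reference_profiles",
    "correlation_annotate",
    "stage_annotate",
    "sample_similarity",
    "annotate_pipeline",
]

UNANNOTATED = "unannotated"


@dataclass
class MarkerSet:
    """Cell type -> marker gene IDs; no marker may serve two types."""

    markers: dict

    def __post_init__(self) -> None:
        seen = {}
        for ct, genes in self.markers.items():
            for g in genes:
                if g in seen and seen[g] != ct:
                    raise ValueError(
                        f"marker {g!r} assigned to both {seen[g]!r} and {ct!r}"
                    )
                seen[g] = ct

    @property
    def types(self) -> list:
        return list(self.markers)

    def restrict_to(self, gene_ids) -> "MarkerSet":
        """Drop markers absent from the expression matrix; report them."""
        present = set(gene_ids)
        kept, missing = {}, []
        for ct, genes in self.markers.items():
            sub = [g for g in genes if g in present]
            missing.extend(g for g in genes if g not in present)
            if sub:
                kept[ct] = sub
        ms = MarkerSet(kept)
        ms.missing = missing
        return ms


@dataclass
class ClusterAssignment:
    resolution_label: str  # "low" | "high"
    membership: pd.Series  # cell -> cluster id (dense ints from 0)
    resolution: float = float("nan")

    def __post_init__(self) -> None:
        ids = np.unique(self.membership.to_numpy())
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("cluster ids must be dense from 0")

    @property
    def n_clusters(self) -> int:
        return int(self.membership.max()) + 1


@dataclass
class ConsensusLabels:
    """Per-cell type call with provenance and correlation, plus stage."""

    table: pd.DataFrame  # columns: type, source, r, stage, tie

    @property
    def types(self) -> pd.Series:
        return self.table["type"]

    def annotated_fraction(self) -> float:
        return float((self.table["type"] != UNANNOTATED).mean())


@dataclass
class ReferenceProfiles:
    profiles: pd.DataFrame  # genes x types

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.profiles.to_numpy())):
            raise ValueError("reference profiles must be finite")


# ----------------------------------------------------------------------
def embed_pca(expr: ExpressionMatrix, n_components: int = 50) -> np.ndarray:
    """Cells x n_components centered PCA scores.

    Component signs are fixed by convention: the largest-magnitude gene
    loading of each component is made positive.
    """
    if expr.n_cells < n_components:
        raise ValueError(
            f"fewer cells ({expr.n_cells}) than components ({n_components})"
        )
    X = expr.values.T  # cells x genes
    nonconst = X.std(axis=0) > 0
    if nonconst.sum() < n_components:
        raise ValueError("fewer non-constant genes than requested components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    flip = np.sign(
        pca.components_[np.arange(n_components),
                        np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    return scores * flip[None, :]


def build_snn_graph(embedding: np.ndarray, k: int = 15, prune: float = 1 / 15):
    """Shared-nearest-neighbour graph with Jaccard edge weights.

    k nearest neighbours (self included) per cell; edge weight between two
    cells is the Jaccard overlap of their neighbour sets, pruned below
    ``prune``.
    """
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    idx = nn.kneighbors(return_distance=False)
    # include self in the neighbour set
    rows = np.repeat(np.arange(n), k + 1)
    cols = np.concatenate([idx, np.arange(n)[:, None]], axis=1).ravel()
    A = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    A.data[:] = 1.0
    shared = A @ A.T
    shared = shared.tocoo()
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    jac = s / (2 * (k + 1) - s)
    keep = jac >= prune
    g = ig.Graph(
        n=n,
        edges=list(zip(r[keep].tolist(), c[keep].tolist())),
        edge_attrs={"weight": jac[keep].tolist()},
    )
    return g


def cluster_cells(
    embedding: np.ndarray,
    resolution: float,
    cell_ids=None,
    k: int = 15,
    seed: int = 0,
    label: str = "low",
    graph: ig.Graph = None,
) -> ClusterAssignment:
    """Partition the SNN graph by modularity community detection (Leiden).

    Deterministic for a fixed seed.  Pass a prebuilt ``graph`` to reuse it
    across resolutions.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if not np.all(np.isfinite(embedding)):
        raise ValueError("embedding must be finite")
    if graph is None:
        graph = build_snn_graph(embedding, k=k)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    memb = np.asarray(part.membership)
    # densify cluster ids in order of first appearance
    _, memb = np.unique(memb, return_inverse=True)
    if cell_ids is None:
        cell_ids = pd.RangeIndex(len(memb))
    return ClusterAssignment(
        resolution_label=label,
        membership=pd.Series(memb, index=cell_ids),
        resolution=resolution,
    )


DEFAULT_RESOLUTION_GRID = (
    0.05, 0.1, 0.2, 0.3, 0.5, 0.8, 1.0, 1.5, 2.0, 3.0, 5.0, 8.0, 12.0,
    20.0, 30.0, 50.0, 80.0, 120.0, 200.0, 300.0,
)


def choose_resolution(
    graph: ig.Graph,
    min_clusters: int,
    grid=DEFAULT_RESOLUTION_GRID,
    seed: int = 0,
) -> float:
    """Smallest grid resolution yielding at least ``min_clusters`` clusters."""
    for res in grid:
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=res,
            seed=seed,
            n_iterations=2,
        )
        if len(set(part.membership)) >= min_clusters:
            return res
    raise ValueError(
        f"no grid resolution produced >= {min_clusters} clusters"
    )


# ----------------------------------------------------------------------
@dataclass
class ClusterScores:
    labels: dict            # cluster id -> type or UNANNOTATED
    type_z: pd.DataFrame    # clusters x types, average marker z
    gene_z: pd.DataFrame    # genes x clusters, per-gene z across clusters
    ties: list = field(default_factory=list)


def score_clusters_by_markers(
    expr: ExpressionMatrix,
    clusters: ClusterAssignment,
    markers: MarkerSet,
    z_min: float = 0.5,
) -> ClusterScores:
    """Label clusters by average marker-gene z-scores.

    Per gene, the z-score of the cluster mean expression is taken across
    clusters; per cluster and type, the z-scores of that type's markers are
    averaged.  A cluster is labelled with the argmax type when the maximum
    average z reaches ``z_min``, otherwise ``unannotated``.  Ties are broken
    by marker count then type name, and recorded.
    """
    if not markers.markers:
        raise ValueError("empty marker set")
    if clusters.n_clusters < 2:
        raise ValueError("need at least 2 clusters to compute z-scores")
    markers = markers.restrict_to(expr.gene_ids)
    if not markers.markers:
        raise ValueError("no marker genes present in the expression matrix")

    memb = clusters.membership.to_numpy()
    n_clust = clusters.n_clusters
    # cluster means: genes x clusters
    sums = np.zeros((expr.n_genes, n_clust))
    counts = np.bincount(memb, minlength=n_clust).astype(float)
    np.add.at(sums.T, memb, expr.values.T)
    means = sums / counts[None, :]
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (means - mu) / sd
    z[~np.isfinite(z)] = 0.0
    gene_z = pd.DataFrame(
        z, index=expr.gene_ids, columns=[f"c{c}" for c in range(n_clust)]
    )

    gene_pos = pd.Series(np.arange(expr.n_genes), index=expr.gene_ids)
    types = sorted(markers.markers)
    type_z = np.zeros((n_clust, len(types)))
    n_markers = np.zeros(len(types), dtype=int)
    for j, ct in enumerate(types):
        pos = gene_pos[markers.markers[ct]].to_numpy()
        n_markers[j] = len(pos)
        type_z[:, j] = z[pos, :].mean(axis=0)
    type_z_df = pd.DataFrame(
        type_z, index=[f"c{c}" for c in range(n_clust)], columns=types
    )

    labels, ties = {}, []
    for c in range(n_clust):
        row = type_z[c]
        best = row.max()
        if best < z_min:
            labels[c] = UNANNOTATED
            continue
        cand = np.flatnonzero(np.isclose(row, best, rtol=0, atol=1e-12))
        if len(cand) > 1:
            # break by marker count, then lexicographic type name
            order = sorted(cand, key=lambda j: (-n_markers[j], types[j]))
            ties.append((c, [types[j] for j in cand]))
            cand = [order[0]]
        labels[c] = types[cand[0]]
    return ClusterScores(labels=labels, type_z=type_z_df, gene_z=gene_z, ties=ties)


def cells_from_clusters(
    clusters: ClusterAssignment, scores: ClusterScores
) -> pd.Series:
    """Propagate cluster labels to cells."""
    lab = np.array(
        [scores.labels[c] for c in range(clusters.n_clusters)], dtype=object
    )
    return pd.Series(
        lab[clusters.membership.to_numpy()], index=clusters.membership.index
    )


def consensus_annotation(labels_low: pd.Series, labels_high: pd.Series) -> ConsensusLabels:
    """Keep a cell's type only when both resolutions agree (and neither is
    unannotated); otherwise the cell is unannotated at this stage."""
    if not labels_low.index.equals(labels_high.index):
        if set(labels_low.index) != set(labels_high.index):
            raise ValueError("label maps cover different cell sets")
        labels_high = labels_high.reindex(labels_low.index)
    agree = (labels_low == labels_high) & (labels_low != UNANNOTATED)
    types = np.where(agree, labels_low, UNANNOTATED)
    table = pd.DataFrame(
        {
            "type": types,
            "source": np.where(agree, "consensus", UNANNOTATED),
            "r": np.nan,
            "stage": pd.NA,
            "tie": False,
        },
        index=labels_low.index,
    )
    return ConsensusLabels(table)


def build_reference_profiles(
    expr: ExpressionMatrix, consensus: ConsensusLabels
) -> ReferenceProfiles:
    """Per-type arithmetic mean expression over consensus cells."""
    types = consensus.table["type"]
    mask = types != UNANNOTATED
    if not mask.any():
        raise ValueError("no consensus cells; cannot build reference profiles")
    cols = {}
    for ct in sorted(types[mask].unique()):
        sel = (types == ct).to_numpy()
        cols[ct] = expr.values[:, sel].mean(axis=1)
    return ReferenceProfiles(pd.DataFrame(cols, index=expr.gene_ids))


def _pearson_matrix(X: np.ndarray, P: np.ndarray):
    """Columns of X (g x n) vs columns of P (g x m): Pearson r, n x m."""
    Xc = X - X.mean(axis=0, keepdims=True)
    Pc = P - P.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(Xc, axis=0)
    pn = np.linalg.norm(Pc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Pc) / np.outer(xn, pn)
    return r, xn == 0


def correlation_annotate(
    expr: ExpressionMatrix,
    profiles: ReferenceProfiles,
    genes=None,
    stages: pd.Series = None,
) -> ConsensusLabels:
    """Assign every cell the type whose reference profile it correlates
    with best (Pearson).

    Cells with constant expression over the gene set have undefined r and
    are left unannotated with the reason recorded.  Exact ties are broken
    lexicographically and flagged.
    """
    prof = profiles.profiles
    if prof.shape[1] < 2:
        raise ValueError("need at least 2 reference profiles")
    if genes is not None:
        genes = pd.Index(genes)
        missing = genes.difference(expr.gene_ids)
        if len(missing):
            raise ValueError(f"genes absent from matrix: {list(missing[:5])}...")
        gsel = expr.gene_ids.isin(genes)
    else:
        gsel = np.ones(expr.n_genes, dtype=bool)
    if not prof.index.equals(expr.gene_ids):
        raise ValueError("profile gene set does not match the expression matrix")
    X = expr.values[gsel, :]
    P = prof.to_numpy()[gsel, :]
    r, const = _pearson_matrix(X, P)
    types = np.asarray(prof.columns, dtype=object)
    out_type = np.empty(expr.n_cells, dtype=object)
    out_r = np.full(expr.n_cells, np.nan)
    tie = np.zeros(expr.n_cells, dtype=bool)
    for i in range(expr.n_cells):
        if const[i] or np.all(np.isnan(r[i])):
            out_type[i] = UNANNOTATED
            continue
        row = r[i]
        best = np.nanmax(row)
        cand = np.flatnonzero(np.isclose(row, best, rtol=0, atol=1e-12))
        if len(cand) > 1:
            tie[i] = True
        out_type[i] = types[cand[0]]  # columns sorted lexicographically upstream
        out_r[i] = best
    table = pd.DataFrame(
        {
            "type": out_type,
            "source": "correlation",
            "r": out_r,
            "stage": pd.NA if stages is None else stages.reindex(expr.cell_ids),
            "tie": tie,
        },
        index=expr.cell_ids,
    )
    return ConsensusLabels(table)


def stage_annotate(expr: ExpressionMatrix, zones) -> pd.DataFrame:
    """Per-cell argmax Pearson correlation against bulk zone profiles.

    Returns a DataFrame with columns ``stage``, ``r`` and ``tie``.
    """
    prof = zones.profiles if hasattr(zones, "profiles") else zones
    if prof.shape[1] < 2:
        raise ValueError("need at least 2 zone profiles")
    if not prof.index.equals(expr.gene_ids):
        raise ValueError("zone profile gene set does not match the matrix")
    r, const = _pearson_matrix(expr.values, prof.to_numpy())
    stages = np.asarray(prof.columns, dtype=object)
    best = np.nanargmax(np.where(np.isnan(r), -np.inf, r), axis=1)
    out = pd.DataFrame(
        {
            "stage": stages[best],
            "r": r[np.arange(expr.n_cells), best],
            "tie": [
                len(np.flatnonzero(np.isclose(r[i], r[i, best[i]], atol=1e-12))) > 1
                for i in range(expr.n_cells)
            ],
        },
        index=expr.cell_ids,
    )
    out.loc[const, "stage"] = UNANNOTATED
    return out


def sample_similarity(counts, sample_col: str = "sample") -> pd.DataFrame:
    """Spearman correlation matrix of per-sample pseudobulk gene sums."""
    samples = counts.cell_meta[sample_col]
    uniq = sorted(samples.unique())
    if len(uniq) < 2:
        raise ValueError("need at least 2 samples")
    sums = np.column_stack(
        [counts.counts[:, (samples == s).to_numpy()].sum(axis=1) for s in uniq]
    )
    rho = spearmanr(sums).statistic
    rho = np.atleast_2d(rho)
    return pd.DataFrame(rho, index=uniq, columns=uniq)


# ----------------------------------------------------------------------
def top_variable_genes(expr: ExpressionMatrix, n: int = 2000) -> pd.Index:
    var = expr.values.var(axis=1)
    order = np.argsort(-var, kind="stable")[: min(n, expr.n_genes)]
    return expr.gene_ids[np.sort(order)]


@dataclass
class AnnotationResult:
    labels: ConsensusLabels
    consensus: ConsensusLabels
    labels_low: pd.Series
    labels_high: pd.Series
    clusters_low: ClusterAssignment
    clusters_high: ClusterAssignment
    profiles: ReferenceProfiles
    res_low: float
    res_high: float


def annotate_pipeline(
    expr: ExpressionMatrix,
    markers: MarkerSet,
    zones=None,
    res_low: float = None,
    res_high: float = None,
    z_min: float = 0.5,
    n_components: int = 50,
    k: int = 15,
    n_hvg: int = 2000,
    seed: int = 0,
) -> AnnotationResult:
    """The full annotation chain on a normalized expression matrix.

    Resolutions default to the smallest grid values giving at least
    ``n_types`` (low) and ``3 * n_types`` (high) clusters.
    """
    n_components = min(n_components, expr.n_cells - 1, expr.n_genes - 1)
    emb = embed_pca(expr, n_components=n_components)
    graph = build_snn_graph(emb, k=k)
    n_types = len(markers.markers)
    if res_low is None:
        res_low = choose_resolution(graph, n_types, seed=seed)
    if res_high is None:
        res_high = choose_resolution(graph, 3 * n_types, seed=seed)
    cl_low = cluster_cells(
        emb, res_low, cell_ids=expr.cell_ids, k=k, seed=seed, label="low",
        graph=graph,
    )
    cl_high = cluster_cells(
        emb, res_high, cell_ids=expr.cell_ids, k=k, seed=seed, label="high",
        graph=graph,
    )
    sc_low = score_clusters_by_markers(expr, cl_low, markers, z_min=z_min)
    sc_high = score_clusters_by_markers(expr, cl_high, markers, z_min=z_min)
    lab_low = cells_from_clusters(cl_low, sc_low)
    lab_high = cells_from_clusters(cl_high, sc_high)
    consensus = consensus_annotation(lab_low, lab_high)
    profiles = build_reference_profiles(expr, consensus)
    marker_union = [g for genes in markers.markers.values() for g in genes]
    gene_set = pd.Index(sorted(set(marker_union))).union(
        top_variable_genes(expr, n_hvg)
    ).intersection(expr.gene_ids)
    stage_tab = stage_annotate(expr, zones)["stage"] if zones is not None else None
    final = correlation_annotate(expr, profiles, genes=gene_set, stages=stage_tab)
    return AnnotationResult(
        labels=final,
        consensus=consensus,
        labels_low=lab_low,
        labels_high=lab_high,
        clusters_low=cl_low,
        clusters_high=cl_high,
        profiles=profiles,
        res_low=res_low,
        res_high=res_high,
    )
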