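"""Seeded synthetic data generators.

Every downstream stage of the pipeline is exercised against data produced
here, with full ground truth: cell types arranged along an ordered
developmental-stage gradient, type-restricted marker genes, planted
condition-specific differential expression concentrated in designated cell
types, mitochondrial / chloroplast / handling-induced gene sets, per-cell
library-size variation, negative-binomial overdispersion and logistic
dropout.

The count law is NB parameterized by mean and dispersion
(``var = mu + phi * mu^2``) with dropout applied as a logistic thinning of
the mean before sampling, so planted moments remain computable in closed
form (:meth:`AtlasConfig.expected_means`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .waterloss import DecayFit, WaterLossSeries, evaluate_remaining

__all__ = [
    "AtlasConfig",
    "TruthAnnotation",
    "BulkProfileSet",
    "generate_atlas",
    "generate_bulk_zones",
    "simulate_null_pseudobulk",
    "generate_protoplast_profiles",
    "generate_waterloss",
    "generate_phonon_map",
]

DEFAULT_STAGES = ("meristem", "elongation", "maturation1", "maturation2")
DEFAULT_CONDITIONS = ("gel", "noncompacted", "compacted")


@dataclass
class AtlasConfig:
    """Parameters of the synthetic single-cell atlas.

    ``planted_degs`` maps a condition pair ``(cond_a, cond_b)`` to a mapping
    ``cell type -> list of (gene_id, log2FC)``; the shift is applied to
    cells of that type in ``cond_b``.
    """

    n_genes: int = 1500
    n_cells: int = 2000
    cell_types: tuple = (
        "atrichoblast",
        "trichoblast",
        "exodermis",
        "sclerenchyma",
        "cortex",
        "endodermis",
        "stele",
        "phloem",
    )
    stages: tuple = DEFAULT_STAGES
    markers_per_type: int = 5
    marker_log2_effect: float = 2.0
    marker_baseline_log2: float = 2.0
    samples_per_condition: int = 3
    conditions: tuple = DEFAULT_CONDITIONS
    planted_degs: dict = field(default_factory=dict)
    allow_marker_degs: bool = False
    frac_mito: float = 0.02
    frac_chloroplast: float = 0.01
    mito_high_cells: float = 0.05
    mito_high_log2_boost: float = 4.0
    protoplast_genes: int = 20
    protoplast_log2_shift: float = 3.0
    baseline_log2_mean: float = 0.5
    baseline_log2_sd: float = 1.0
    stage_slope_sd: float = 0.5
    type_effect_sd: float = 0.35
    libsize_lognormal_params: tuple = (0.0, 0.25)
    nb_dispersion: float = 0.2
    dropout_midpoint: float = -4.0
    dropout_slope: float = 1.0
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_cells <= 0:
            raise ValueError("n_genes and n_cells must be positive")
        if len(self.cell_types) == 0 or len(self.stages) == 0:
            raise ValueError("cell_types and stages must be non-empty")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("cell_types must be unique")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stages must be unique (order is meaningful)")
        for frac, name in [
            (self.frac_mito, "frac_mito"),
            (self.frac_chloroplast, "frac_chloroplast"),
            (self.mito_high_cells, "mito_high_cells"),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.markers_per_type < 0:
            raise ValueError("markers_per_type must be non-negative")
        n_reserved = (
            self.markers_per_type * len(self.cell_types)
            + self.protoplast_genes
        )
        if n_reserved > self.n_genes:
            raise ValueError("more reserved genes than n_genes")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.samples_per_condition <= 0:
            raise ValueError("samples_per_condition must be positive")
        # marker/DEG disjointness is enforced in generate_atlas where the
        # gene layout is materialized

    # gene layout ------------------------------------------------------
    def gene_ids(self) -> pd.Index:
        return pd.Index([f"g{i:05d}" for i in range(self.n_genes)], name="gene")

    def marker_table(self) -> pd.DataFrame:
        """Deterministic marker layout: the first ``markers_per_type`` genes
        per type, in declared type order."""
        rows = []
        i = 0
        for ct in self.cell_types:
            for _ in range(self.markers_per_type):
                rows.append((f"g{i:05d}", ct))
                i += 1
        return pd.DataFrame(rows, columns=["gene", "cell_type"])

    def marker_sets(self) -> dict:
        tab = self.marker_table()
        return {
            ct: list(sub["gene"]) for ct, sub in tab.groupby("cell_type", sort=False)
        }

    def protoplast_gene_ids(self) -> list:
        """Handling-induced genes: the block right after the markers."""
        start = self.markers_per_type * len(self.cell_types)
        return [f"g{i:05d}" for i in range(start, start + self.protoplast_genes)]

    def free_gene_ids(self) -> list:
        """Genes not reserved as markers or protoplast-induced."""
        start = self.markers_per_type * len(self.cell_types) + self.protoplast_genes
        return [f"g{i:05d}" for i in range(start, self.n_genes)]

    def with_planted_degs(
        self, pair: tuple, per_type: dict, log2fc: float = 2.0
    ) -> "AtlasConfig":
        """Return a copy with DEGs planted in free (non-marker) genes.

        ``per_type`` maps cell type -> number of DEGs to plant.  Genes are
        taken deterministically from the free block, disjoint across types.
        """
        free = self.free_gene_ids()
        need = sum(per_type.values())
        if need > len(free):
            raise ValueError("not enough free genes to plant the requested DEGs")
        planted = dict(self.planted_degs)
        mapping = {}
        i = 0
        for ct, n in per_type.items():
            if ct not in self.cell_types:
                raise ValueError(f"unknown cell type {ct!r}")
            mapping[ct] = [(free[i + j], log2fc) for j in range(n)]
            i += n
        planted[pair] = mapping
        cfg = AtlasConfig(**{**asdict_compat(self), "planted_degs": planted})
        return cfg

    # expectation model ------------------------------------------------
    def _gene_params(self, rng: np.random.Generator):
        """Per-gene baseline log2 mean, stage slope, diffuse per-type
        effects and flags."""
        base = rng.normal(self.baseline_log2_mean, self.baseline_log2_sd, self.n_genes)
        slope = rng.normal(0.0, self.stage_slope_sd, self.n_genes)
        marker_tab = self.marker_table()
        n_marker = len(marker_tab)
        base[:n_marker] = self.marker_baseline_log2
        # mito / chloroplast flags drawn from the free block to keep them
        # disjoint from markers and protoplast genes
        free_start = n_marker + self.protoplast_genes
        n_mito = int(round(self.frac_mito * self.n_genes))
        n_chl = int(round(self.frac_chloroplast * self.n_genes))
        free = np.arange(free_start, self.n_genes)
        if n_mito + n_chl > len(free):
            raise ValueError("not enough free genes for mito/chloroplast flags")
        flagged = rng.choice(free, size=n_mito + n_chl, replace=False)
        is_mito = np.zeros(self.n_genes, dtype=bool)
        is_chl = np.zeros(self.n_genes, dtype=bool)
        is_mito[flagged[:n_mito]] = True
        is_chl[flagged[n_mito:]] = True
        # diffuse per-type expression structure on non-marker, non-organelle
        # genes (markers carry their own dedicated effect)
        type_effect = rng.normal(
            0.0, self.type_effect_sd, size=(self.n_genes, len(self.cell_types))
        )
        type_effect[:n_marker, :] = 0.0
        type_effect[is_mito | is_chl, :] = 0.0
        return base, slope, is_mito, is_chl, type_effect

    def expected_means(
        self,
        base: np.ndarray,
        slope: np.ndarray,
        is_mito: np.ndarray,
        cell_type: np.ndarray,
        stage_idx: np.ndarray,
        condition: np.ndarray,
        lib_factor: np.ndarray,
        mito_high: np.ndarray,
        type_effect: np.ndarray = None,
        protoplasted: bool = False,
        apply_dropout: bool = True,
    ) -> np.ndarray:
        """Noise-free expected counts (genes x cells) under the full model."""
        genes = self.gene_ids()
        gene_pos = pd.Series(np.arange(self.n_genes), index=genes)
        s_center = (len(self.stages) - 1) / 2.0
        log2mu = base[:, None] + slope[:, None] * (stage_idx[None, :] - s_center)
        if type_effect is not None:
            type_idx = pd.Series(
                np.arange(len(self.cell_types)), index=list(self.cell_types)
            )[cell_type].to_numpy()
            log2mu += type_effect[:, type_idx]
        marker_tab = self.marker_table()
        for gid, ct in marker_tab.itertuples(index=False):
            gi = gene_pos[gid]
            log2mu[gi, cell_type == ct] += self.marker_log2_effect
        for (ca, cb), per_type in self.planted_degs.items():
            for ct, entries in per_type.items():
                in_cells = (cell_type == ct) & (condition == cb)
                if not in_cells.any():
                    continue
                for gid, lfc in entries:
                    log2mu[gene_pos[gid], in_cells] += lfc
        if mito_high.any():
            log2mu[np.ix_(is_mito, mito_high)] += self.mito_high_log2_boost
        if protoplasted and self.protoplast_genes:
            ppos = [gene_pos[g] for g in self.protoplast_gene_ids()]
            log2mu[ppos, :] += self.protoplast_log2_shift
        log2mu += np.log2(lib_factor)[None, :]
        mu = np.exp2(log2mu)
        if apply_dropout:
            mu *= self._keep_prob_log2(log2mu)
        return mu

    def _keep_prob_log2(self, log2mu: np.ndarray) -> np.ndarray:
        """Logistic thinning of the mean: P(keep) as a function of log2 mu."""
        from scipy.special import expit

        return expit(self.dropout_slope * (log2mu - self.dropout_midpoint))


def asdict_compat(cfg: AtlasConfig) -> dict:
    d = asdict(cfg)
    return d


@dataclass
class TruthAnnotation:
    """Ground truth companion of a synthetic :class:`CountMatrix`."""

    cells: pd.DataFrame  # true_type, true_stage, sample, condition, is_mito_high
    genes: pd.DataFrame  # marker_for, is_mito, is_chloroplast, is_protoplast_induced
    planted_lfc: dict    # (cond pair) -> {cell type: [(gene, lfc), ...]}

    def validate_against(self, cm: CountMatrix) -> None:
        if not self.cells.index.equals(cm.cell_ids):
            raise ValueError("truth cells do not match count matrix cells")
        if not self.genes.index.equals(cm.gene_ids):
            raise ValueError("truth genes do not match count matrix genes")


@dataclass
class BulkProfileSet:
    """Zone name -> per-gene mean expression profile (normalized scale)."""

    profiles: pd.DataFrame  # genes x zones

    def __post_init__(self) -> None:
        vals = self.profiles.to_numpy()
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("bulk profiles must be finite and non-negative")

    @property
    def zones(self) -> list:
        return list(self.profiles.columns)


# ----------------------------------------------------------------------
def _assign_cells(config: AtlasConfig, rng: np.random.Generator):
    n = config.n_cells
    types = np.asarray(config.cell_types, dtype=object)
    cell_type = types[rng.integers(0, len(types), size=n)]
    for ct in config.cell_types:
        if not (cell_type == ct).any():
            raise ValueError(f"no cells drawn for declared cell type {ct!r}")
    stage_idx = rng.integers(0, len(config.stages), size=n)
    cond_idx = rng.integers(0, len(config.conditions), size=n)
    condition = np.asarray(config.conditions, dtype=object)[cond_idx]
    rep = rng.integers(0, config.samples_per_condition, size=n)
    sample = np.array(
        [f"{c}_s{r + 1}" for c, r in zip(condition, rep)], dtype=object
    )
    mito_high = rng.random(n) < config.mito_high_cells
    return cell_type, stage_idx, condition, sample, mito_high


def generate_atlas(config: AtlasConfig):
    """Generate a synthetic count matrix plus ground-truth annotation.

    Deterministic for a fixed ``config.seed``.  Raises if the random cell
    assignment leaves a declared type empty or if planted DEG genes collide
    with marker genes (unless ``allow_marker_degs``).
    """
    config.validate()
    marker_genes = set(config.marker_table()["gene"])
    for pair, per_type in config.planted_degs.items():
        for ct, entries in per_type.items():
            for gid, _ in entries:
                if gid in marker_genes and not config.allow_marker_degs:
                    raise ValueError(
                        f"planted DEG {gid!r} is a marker gene; set "
                        "allow_marker_degs=True to permit this"
                    )
    rng = np.random.default_rng(config.seed)
    base, slope, is_mito, is_chl, type_effect = config._gene_params(rng)
    cell_type, stage_idx, condition, sample, mito_high = _assign_cells(config, rng)
    lmu, lsd = config.libsize_lognormal_params
    lib_factor = rng.lognormal(lmu, lsd, size=config.n_cells)

    mu = config.expected_means(
        base, slope, is_mito, cell_type, stage_idx, condition,
        lib_factor, mito_high, type_effect=type_effect,
    )
    phi = config.nb_dispersion
    if phi > 0:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
    else:
        counts = rng.poisson(mu).astype(np.int64)

    genes = config.gene_ids()
    cells = pd.Index([f"cell{i:05d}" for i in range(config.n_cells)], name="cell")
    marker_for = pd.Series(pd.NA, index=genes, dtype=object)
    for gid, ct in config.marker_table().itertuples(index=False):
        marker_for[gid] = ct
    is_proto = pd.Series(False, index=genes)
    is_proto[config.protoplast_gene_ids()] = True

    gene_meta = pd.DataFrame(
        {
            "is_mito": is_mito,
            "is_chloroplast": is_chl,
        },
        index=genes,
    )
    cell_meta = pd.DataFrame(
        {"sample": sample, "condition": condition}, index=cells
    )
    cm = CountMatrix(counts, genes, cells, cell_meta, gene_meta)

    truth_cells = pd.DataFrame(
        {
            "true_type": cell_type,
            "true_stage": np.asarray(config.stages, dtype=object)[stage_idx],
            "sample": sample,
            "condition": condition,
            "is_mito_high": mito_high,
        },
        index=cells,
    )
    truth_genes = pd.DataFrame(
        {
            "marker_for": marker_for,
            "is_mito": is_mito,
            "is_chloroplast": is_chl,
            "is_protoplast_induced": is_proto.to_numpy(),
        },
        index=genes,
    )
    truth = TruthAnnotation(truth_cells, truth_genes, dict(config.planted_degs))
    # stash per-gene model parameters for moment-recovery checks
    truth.gene_model = pd.DataFrame(
        {"baseline_log2": base, "stage_slope": slope}, index=genes
    )
    truth.lib_factor = pd.Series(lib_factor, index=cells)
    return cm, truth


def generate_bulk_zones(config: AtlasConfig, per_type: bool = False) -> BulkProfileSet:
    """Noise-free expected normalized expression per developmental zone.

    Profiles are the expected counts of cells at each stage (baseline
    condition, reference library size, no dropout), averaged over cell
    types unless ``per_type``; scaled to CPM and log1p'd to match
    :func:`rootatlas.preprocess.normalize` output scale.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    base, slope, is_mito, _, type_effect = config._gene_params(rng)
    genes = config.gene_ids()
    cols = {}
    for si, stage in enumerate(config.stages):
        profs = []
        for ct in config.cell_types:
            mu = config.expected_means(
                base, slope, is_mito,
                cell_type=np.array([ct], dtype=object),
                stage_idx=np.array([si]),
                condition=np.array([config.conditions[0]], dtype=object),
                lib_factor=np.ones(1),
                mito_high=np.zeros(1, dtype=bool),
                type_effect=type_effect,
                apply_dropout=False,
            )[:, 0]
            profs.append(mu)
        if per_type:
            for ct, mu in zip(config.cell_types, profs):
                cpm = mu / mu.sum() * 1e6
                cols[f"{stage}:{ct}"] = np.log1p(cpm)
        else:
            mu = np.mean(profs, axis=0)
            cpm = mu / mu.sum() * 1e6
            cols[stage] = np.log1p(cpm)
    return BulkProfileSet(pd.DataFrame(cols, index=genes))


def generate_protoplast_profiles(config: AtlasConfig):
    """Noise-free bulk CPM profiles of protoplasted vs intact tissue.

    Returns ``(protoplasted, intact)`` as pandas Series over the gene set;
    the planted handling-induced genes carry a ``protoplast_log2_shift``
    log2 shift in the protoplasted profile.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    base, slope, is_mito, _, type_effect = config._gene_params(rng)
    genes = config.gene_ids()
    mid_stage = np.array([len(config.stages) // 2])
    common = dict(
        cell_type=np.array([config.cell_types[0]], dtype=object),
        stage_idx=mid_stage,
        condition=np.array([config.conditions[0]], dtype=object),
        lib_factor=np.ones(1),
        mito_high=np.zeros(1, dtype=bool),
        type_effect=type_effect,
        apply_dropout=False,
    )
    intact = config.expected_means(base, slope, is_mito, **common)[:, 0]
    proto = config.expected_means(
        base, slope, is_mito, protoplasted=True, **common
    )[:, 0]
    intact = pd.Series(intact / intact.sum() * 1e6, index=genes, name="intact")
    proto = pd.Series(proto / proto.sum() * 1e6, index=genes, name="protoplasted")
    return proto, intact


# ----------------------------------------------------------------------
def simulate_null_pseudobulk(
    n_genes: int = 2000,
    reps: int = 3,
    phi: float = 0.2,
    seed: int = 0,
    mean_log: float = 3.0,
    mean_sd: float = 1.5,
    lib_sd: float = 0.3,
):
    """Global-null pseudobulk table: identical NB means in both conditions.

    Used for DE calibration studies.  Returns a
    :class:`rootatlas.diffexpr.PseudobulkTable` with ``reps`` pairs per
    condition (conditions ``a`` and ``b``) for a single cell type ``T``.
    """
    from .diffexpr import PseudobulkTable

    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean_log, mean_sd, n_genes)
    lib = rng.lognormal(0.0, lib_sd, 2 * reps)
    mu = base[:, None] * lib[None, :]
    r = 1.0 / phi
    y = rng.negative_binomial(r, r / (r + mu))
    cols = [f"a_s{i}|T" for i in range(reps)] + [f"b_s{i}|T" for i in range(reps)]
    counts = pd.DataFrame(
        y, columns=cols, index=pd.Index([f"g{i}" for i in range(n_genes)])
    )
    pairs = pd.DataFrame(
        {
            "sample": [c.split("|")[0] for c in cols],
            "cell_type": "T",
            "condition": ["a"] * reps + ["b"] * reps,
            "n_cells": 100,
        },
        index=pd.Index(cols, name="pair"),
    )
    return PseudobulkTable(counts=counts, pairs=pairs)


# ----------------------------------------------------------------------
def generate_waterloss(
    decay: DecayFit,
    n_points: int,
    dt: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    root_length: float = 0.03,
    root_diameter: float = 0.001,
    total_water: float = 0.05,
) -> WaterLossSeries:
    """Sample a cumulative water-loss curve from a two-phase decay model.

    ``noise_sd`` is in percent-of-total-water units, added as i.i.d.
    Gaussian noise on the cumulative loss.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_points < 4:
        raise ValueError("need at least 4 time points")
    rng = np.random.default_rng(seed)
    times = np.arange(n_points) * dt
    w0 = decay.plateau + decay.span_fast + decay.span_slow
    remaining = evaluate_remaining(decay, times)
    loss = (w0 - remaining)
    if noise_sd > 0:
        loss = loss + rng.normal(0.0, noise_sd, size=n_points)
    return WaterLossSeries(
        times=times,
        cumulative_loss=loss,
        root_length=root_length,
        root_diameter=root_diameter,
        total_water=total_water,
    )


# ----------------------------------------------------------------------
def generate_phonon_map(means, covs, weights, grid, seed: int = 0):
    """Draw a synthetic (dfb, ab) pixel map from a two-component mixture.

    Returns a :class:`rootatlas.phonon.PhononMap` with per-pixel truth
    labels (component indices).
    """
    from .phonon import PhononMap  # local import to avoid cycle

    means = [np.asarray(m, dtype=float) for m in means]
    covs = [np.asarray(c, dtype=float) for c in covs]
    weights = np.asarray(weights, dtype=float)
    if len(means) != 2 or len(covs) != 2 or weights.shape != (2,):
        raise ValueError("exactly two components required")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    for c in covs:
        if c.shape != (2, 2) or not np.allclose(c, c.T):
            raise ValueError("covariances must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(c) <= 0):
            raise ValueError("covariances must be positive definite")
    rows, cols = grid
    n = rows * cols
    rng = np.random.default_rng(seed)
    labels = rng.choice(2, size=n, p=weights)
    xy = np.empty((n, 2))
    for k in range(2):
        mask = labels == k
        if mask.any():
            xy[mask] = rng.multivariate_normal(means[k], covs[k], size=int(mask.sum()))
    return PhononMap(
        dfb=xy[:, 0].reshape(rows, cols),
        ab=xy[:, 1].reshape(rows, cols),
        truth=labels.reshape(rows, cols),
    )
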