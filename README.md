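# rootatlas

A tested, reusable re-implementation of a root single-cell analysis
pipeline, together with the quantitative wet-lab analyses that accompany
it.  Six modules:

- **`rootatlas.synthetic`** — seeded generators for every input the
  pipeline consumes: single-cell count matrices with full ground truth
  (cell types on a developmental-stage gradient, type-restricted markers,
  planted condition-specific DEGs, mitochondrial / chloroplast /
  protoplasting-induced gene sets, NB overdispersion, logistic dropout,
  library-size variation), bulk zone and protoplasting profiles,
  water-loss time series, and two-component phonon pixel maps.
- **`rootatlas.preprocess`** — cell QC (5% mitochondrial threshold, top-1%
  UMI trimming), the protoplasting gene screen (|log2FC| >= 2 on paired
  bulk profiles), gene-list exclusion, and median-library log1p
  normalization.
- **`rootatlas.annotate`** — dual-resolution consensus annotation: PCA,
  SNN-graph Leiden clustering at a low and a high resolution, cluster
  labelling by average marker z-scores, consensus of the two labelings,
  reference profiles from consensus cells, correlation re-annotation of
  every cell, and developmental-stage assignment against bulk zone
  profiles.
- **`rootatlas.diffexpr`** — pseudobulk differential expression: raw-count
  aggregation per (sample, cell type), a vectorized negative-binomial
  likelihood-ratio test with moment dispersion shrunk toward a common
  value, detection frequencies, the inclusive DEG filter
  (FDR <= 0.05, |FC| >= 1.5, detection >= 10%), DEG summaries, and
  hypergeometric term enrichment with BH correction.
- **`rootatlas.waterloss`** — two-phase exponential decay fitting of
  cumulative radial water-loss curves, time-to-half-loss, and conversion
  of mass-loss rates to radial flux (umol m^-2 s^-1).
- **`rootatlas.phonon`** — Brillouin-shift (f_B = 2nv/lambda) and
  longitudinal-modulus (M = rho v^2) formulas, two-component Gaussian
  mixture segmentation of (frequency shift, attenuation) maps by EM with
  an asserted monotone log-likelihood, Mahalanobis/chi-square confidence
  regions, and Yuen's trimmed-mean t-test.

## CLI

The `rootatlas` entry point exposes one subcommand per stage:

```bash
rootatlas simulate --n-genes 1500 --n-cells 2000 --seed 1 --out atlas/
rootatlas qc atlas/ --mito-max 0.05 --top-umi-frac 0.01 --out qc/
rootatlas annotate qc/ --markers atlas/markers.tsv \
    --zones atlas/bulk_zones.tsv --out labels.tsv
rootatlas de qc/ --labels labels.tsv --cond-a gel --cond-b compacted \
    --out de.tsv
rootatlas enrich --degs de.tsv --terms terms.gmt --universe universe.txt \
    --out enrich.tsv
rootatlas waterloss series.csv --interpolate-t50 --out fit.json
rootatlas phonon --dfb dfb.csv --ab ab.csv --level 0.70 --out phonon/
```

Count matrices are exchanged as 10x-style Matrix Market triplets
(`matrix.mtx`, `genes.tsv`, `barcodes.tsv`) with metadata columns for gene
flags and cell sample/condition; everything else is plain TSV/CSV/JSON.

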