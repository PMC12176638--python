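"""Plain-text I/O: 10x-style Matrix Market triplets, marker and profile
TSVs, water-loss CSVs and phonon CSV grids.

The triplet layout follows the droplet convention — ``matrix.mtx`` with
genes as rows, ``genes.tsv`` and ``barcodes.tsv`` — extended with optional
metadata columns (gene flags; cell sample/condition) that round-trip
through :func:`write_10x` / :func:`read_10x`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy.sparse import coo_matrix

from .containers import CountMatrix
from .waterloss import WaterLossSeries

__all__ = [
    "write_10x",
    "read_10x",
    "write_markers",
    "read_markers",
    "write_profiles",
    "read_profiles",
    "write_labels",
    "write_waterloss_csv",
    "read_waterloss_csv",
    "write_phonon_csv",
    "read_phonon_csv",
    "read_gmt",
]


def write_10x(cm: CountMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"), coo_matrix(cm.counts), field="integer")
    genes = cm.gene_meta.reset_index()
    genes.columns = ["gene"] + list(cm.gene_meta.columns)
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    cells = cm.cell_meta.reset_index()
    cells.columns = ["barcode"] + list(cm.cell_meta.columns)
    cells.to_csv(outdir / "barcodes.tsv", sep="\t", index=False)


def read_10x(indir) -> CountMatrix:
    indir = Path(indir)
    mat = spio.mmread(str(indir / "matrix.mtx")).toarray().astype(np.int64)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t")
    gene_ids = pd.Index(genes["gene"], name="gene")
    cell_ids = pd.Index(cells["barcode"].astype(str), name="cell")
    gene_meta = genes.drop(columns=["gene"]).set_index(gene_ids)
    cell_meta = cells.drop(columns=["barcode"]).set_index(cell_ids)
    return CountMatrix(mat, gene_ids, cell_ids, cell_meta, gene_meta)


def write_markers(markers: dict, path) -> None:
    rows = [(ct, g) for ct, genes in markers.items() for g in genes]
    pd.DataFrame(rows, columns=["cell_type", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_markers(path) -> dict:
    tab = pd.read_csv(path, sep="\t")
    return {
        ct: list(sub["gene"])
        for ct, sub in tab.groupby("cell_type", sort=False)
    }


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.rename_axis("gene").to_csv(path, sep="\t")


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_labels(table: pd.DataFrame, path) -> None:
    table.rename_axis("cell").to_csv(path, sep="\t")


# ----------------------------------------------------------------------
def write_waterloss_csv(series: WaterLossSeries, path) -> None:
    """CSV with a JSON metadata header line (prefixed '#')."""
    meta = {
        "root_length_m": series.root_length,
        "root_diameter_m": series.root_diameter,
        "total_water_g": series.total_water,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        pd.DataFrame(
            {"time_min": series.times, "cumulative_loss_pct": series.cumulative_loss}
        ).to_csv(fh, index=False)


def read_waterloss_csv(path) -> WaterLossSeries:
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
        tab = pd.read_csv(fh)
    return WaterLossSeries(
        times=tab["time_min"].to_numpy(),
        cumulative_loss=tab["cumulative_loss_pct"].to_numpy(),
        root_length=meta.get("root_length_m", 0.03),
        root_diameter=meta.get("root_diameter_m", 0.001),
        total_water=meta.get("total_water_g", 0.05),
    )


# ----------------------------------------------------------------------
def write_phonon_csv(pmap, dfb_path, ab_path) -> None:
    np.savetxt(dfb_path, pmap.dfb, delimiter=",")
    np.savetxt(ab_path, pmap.ab, delimiter=",")


def read_phonon_csv(dfb_path, ab_path):
    from .phonon import PhononMap

    return PhononMap(
        dfb=np.atleast_2d(np.loadtxt(dfb_path, delimiter=",")),
        ab=np.atleast_2d(np.loadtxt(ab_path, delimiter=",")),
    )


def read_gmt(path) -> dict:
    """GMT-style TSV: term, description, gene, gene, ..."""
    terms = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = [g for g in parts[2:] if g]
    return terms
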