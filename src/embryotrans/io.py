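"""Readers and writers for the pipeline's on-disk formats.

Counts travel as MatrixMarket MTX (genes x cells) with genes.tsv /
barcodes.tsv sidecars plus a cell-metadata CSV, or as a dense CSV; grade
tables, barcode profiles and DE results are plain CSV/TSV; z-stacks are
multi-page TIFF (one file per channel); gene sets are JSON and ground truth
is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .scores import GeneSetDefinition

__all__ = [
    "write_counts",
    "read_counts",
    "read_counts_csv",
    "write_zstack",
    "read_zstack",
    "read_gene_set",
    "write_gene_set",
    "write_json",
]


def write_counts(adata: ad.AnnData, outdir) -> None:
    """Write counts as MTX (genes x cells) + genes/barcodes TSV + metadata CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X
    if not sparse.issparse(x):
        x = sparse.csr_matrix(np.asarray(x))
    spio.mmwrite(str(outdir / "matrix.mtx"), x.T.tocoo())  # genes x cells
    pd.Series(adata.var_names).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    adata.obs.to_csv(outdir / "metadata.csv")


def read_counts(indir) -> ad.AnnData:
    """Read an MTX + TSV + metadata directory written by :func:`write_counts`."""
    indir = Path(indir)
    x = spio.mmread(str(indir / "matrix.mtx")).T.tocsr()  # back to cells x genes
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.read_csv(indir / "metadata.csv", index_col=0)
    obs = obs.reindex(barcodes.values)
    return ad.AnnData(
        X=np.asarray(x.todense()),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes.values, name="gene")),
    )


def read_counts_csv(path) -> ad.AnnData:
    """Read a dense genes-by-cells CSV (gene ids in the first column)."""
    df = pd.read_csv(path, index_col=0)
    return ad.AnnData(
        X=df.T.to_numpy(),
        obs=pd.DataFrame(index=pd.Index(df.columns, name="cell")),
        var=pd.DataFrame(index=pd.Index(df.index, name="gene")),
    )


def write_zstack(stack, outdir, prefix: str = "stack") -> list[Path]:
    """Write each channel as a multi-page TIFF; returns the written paths."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in stack.channels.items():
        path = outdir / f"{prefix}_{name}.tiff"
        tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))
        paths.append(path)
    return paths


def read_zstack(paths: dict, slice_height_um: float = 1.675):
    """Assemble a ZStack from {channel name: TIFF path}."""
    import tifffile

    from .imaging import ZStack

    channels = {
        name: np.asarray(tifffile.imread(path), dtype=float)
        for name, path in paths.items()
    }
    return ZStack(channels=channels, slice_height_um=slice_height_um)


def read_gene_set(path) -> GeneSetDefinition:
    """Read a gene set from JSON: {"name": ..., "genes": [...]}."""
    with open(path) as fh:
        data = json.load(fh)
    return GeneSetDefinition(name=data["name"], genes=tuple(data["genes"]))


def write_gene_set(gene_set: GeneSetDefinition, path) -> None:
    with open(path, "w") as fh:
        json.dump({"name": gene_set.name, "genes": list(gene_set.genes)}, fh, indent=2)


def write_json(obj, path) -> None:
    """JSON writer tolerant of numpy scalar types."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
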