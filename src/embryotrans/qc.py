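"""Cell-level quality control, normalization and annotation.

Cells are kept when at most 25% of their reads are mitochondrial and their
detected unique gene count lies in [500, 8000]; the mitochondrial bound is
deliberately permissive so that genes encoded by the mitochondrial genome
remain comparable across groups.  Expression is then library-size scaled,
log-transformed, and the per-cell ribosomal expression fraction is regressed
out gene-by-gene to remove its confounding effect.  Finally each cell is
annotated as trophectoderm (TE) or inner cell mass (ICM) from marker-panel
means, and as male or female/indeterminate from Y-chromosome marker
detection (male markers are the only confident call at E4.5; everything else
is female/indeterminate).

The in-memory container is an :class:`anndata.AnnData` with cells as
observations and genes as variables; raw counts live in ``X`` and the
normalized matrix in ``layers["normalized"]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .scores import MITO_GENES

__all__ = [
    "QCThresholds",
    "MarkerPanel",
    "DEFAULT_PANEL",
    "compute_mito_fraction",
    "compute_qc_metrics",
    "filter_cells",
    "normalize",
    "annotate_cell_type",
    "classify_sex",
]

MALE = "male"
FEMALE_INDET = "female/indeterminate"
TE = "TE"
ICM = "ICM"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class QCThresholds:
    """Retention bounds: mito fraction <= max, gene count within [min, max]."""

    max_mito_fraction: float = 0.25
    min_genes: int = 500
    max_genes: int = 8000

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must be <= max_genes")


@dataclass(frozen=True)
class MarkerPanel:
    """Marker genes for cell-type and sex annotation of E4.5 blastomeres."""

    te_markers: tuple[str, ...] = (
        "Krt8", "Gata2", "Gata3", "Wnt7b", "Cdx2", "Elf5", "Eomes",
    )
    icm_markers: tuple[str, ...] = ("Pou5f1", "Sox2", "Nanog")
    male_markers: tuple[str, ...] = ("Eif2s3y", "Usp9y", "Kdm5d")

    def __post_init__(self) -> None:
        panels = [set(self.te_markers), set(self.icm_markers), set(self.male_markers)]
        for i in range(len(panels)):
            for j in range(i + 1, len(panels)):
                if panels[i] & panels[j]:
                    raise ValueError("marker panels must be disjoint")


DEFAULT_PANEL = MarkerPanel()


def _counts(adata: ad.AnnData) -> np.ndarray:
    x = adata.X
    if hasattr(x, "toarray"):
        x = x.toarray()
    return np.asarray(x)


def compute_mito_fraction(adata: ad.AnnData, mito_genes=MITO_GENES) -> pd.Series:
    """Per-cell fraction of counts on mitochondrial genes.

    Mitochondrial genes are given explicitly (default: the 13 mtDNA
    protein-coding genes); no name-prefix inference is done.  Cells with
    zero total counts are an error.
    """
    counts = _counts(adata)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = list(adata.obs_names[np.asarray(totals == 0)])[:5]
        raise ValueError(f"cells with zero total counts: {bad}")
    mito_idx = adata.var_names.isin(mito_genes)
    mito_sum = counts[:, mito_idx].sum(axis=1) if mito_idx.any() else np.zeros(adata.n_obs)
    return pd.Series(mito_sum / totals, index=adata.obs_names, name="mito_fraction")


def compute_qc_metrics(
    adata: ad.AnnData, mito_genes=MITO_GENES, ribo_genes=()
) -> ad.AnnData:
    """Attach ``mito_fraction``, ``ribo_fraction`` and ``n_genes_detected``.

    Modifies ``adata.obs`` in place and returns the same object.  Which
    genes count as ribosomal is caller-supplied.
    """
    counts = _counts(adata)
    totals = counts.sum(axis=1)
    adata.obs["mito_fraction"] = compute_mito_fraction(adata, mito_genes).values
    ribo_idx = adata.var_names.isin(ribo_genes)
    ribo_sum = counts[:, ribo_idx].sum(axis=1) if ribo_idx.any() else np.zeros(adata.n_obs)
    adata.obs["ribo_fraction"] = ribo_sum / totals
    adata.obs["n_genes_detected"] = (counts > 0).sum(axis=1)
    return adata


def filter_cells(
    adata: ad.AnnData, thresholds: QCThresholds = QCThresholds()
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Filter cells by mito fraction and detected-gene bounds.

    A cell is retained iff ``mito_fraction <= max_mito_fraction`` and
    ``min_genes <= n_genes_detected <= max_genes`` — all bounds inclusive on
    the retain side (exclusion requires *more than* 25% mitochondrial reads).

    Returns the filtered copy and a per-cell report with a ``retained``
    flag and a semicolon-joined ``reasons`` string for every excluded cell.
    """
    for col in ("mito_fraction", "n_genes_detected"):
        if col not in adata.obs:
            raise ValueError(f"run compute_qc_metrics first: obs lacks {col!r}")
    mito = adata.obs["mito_fraction"].to_numpy()
    ngenes = adata.obs["n_genes_detected"].to_numpy()
    reasons = []
    for m, g in zip(mito, ngenes):
        r = []
        if m > thresholds.max_mito_fraction:
            r.append(f"mito_fraction>{thresholds.max_mito_fraction}")
        if g < thresholds.min_genes:
            r.append(f"n_genes_detected<{thresholds.min_genes}")
        if g > thresholds.max_genes:
            r.append(f"n_genes_detected>{thresholds.max_genes}")
        reasons.append(";".join(r))
    report = pd.DataFrame(
        {
            "retained": [r == "" for r in reasons],
            "reasons": reasons,
        },
        index=adata.obs_names,
    )
    kept = adata[report["retained"].to_numpy()].copy()
    return kept, report


def normalize(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Library-size scale, log-transform, and regress out ribosomal fraction.

    Each cell's counts are scaled to ``target_sum`` total, log(1+x)
    transformed (stored as ``layers["lognorm"]``), then each gene is
    linearly regressed on the per-cell ``ribo_fraction`` covariate and the
    residuals plus the gene mean are stored as ``layers["normalized"]``.
    A zero-variance covariate leaves the log-normalized values unchanged.

    This is a transparent stand-in for variance-stabilizing normalization:
    downstream analyses only require a monotone stabilized scale with the
    ribosomal covariate removed.
    """
    counts = _counts(adata).astype(float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = list(adata.obs_names[np.asarray(totals == 0)])[:5]
        raise ValueError(f"cells with zero total counts: {bad}")
    lognorm = np.log1p(counts / totals[:, None] * target_sum)
    adata.layers["lognorm"] = lognorm
    ribo = adata.obs.get("ribo_fraction")
    if ribo is None:
        ribo = np.zeros(adata.n_obs)
    ribo = np.asarray(ribo, dtype=float)
    xc = ribo - ribo.mean()
    var_x = float((xc**2).sum())
    if var_x == 0.0:
        adata.layers["normalized"] = lognorm.copy()
        return adata
    # per-gene OLS slope on the centered covariate; residual + gene mean
    beta = xc @ lognorm / var_x
    adata.layers["normalized"] = lognorm - np.outer(xc, beta)
    return adata


def annotate_cell_type(
    adata: ad.AnnData, panel: MarkerPanel = DEFAULT_PANEL, layer: str = "normalized"
) -> pd.Series:
    """Assign TE / ICM / unassigned from marker-panel means.

    Each cell goes to the panel (TE or ICM) with the higher mean normalized
    marker expression, provided that mean is positive; exact ties or two
    zero means leave the cell unassigned.  The labels are written to
    ``obs["cell_type"]`` and returned.
    """
    if layer not in adata.layers:
        raise ValueError(f"layer {layer!r} missing; run normalize first")
    te = [g for g in panel.te_markers if g in adata.var_names]
    icm = [g for g in panel.icm_markers if g in adata.var_names]
    if not te or not icm:
        raise ValueError("no TE or no ICM marker gene found in the matrix")
    x = np.asarray(adata.layers[layer])
    te_mean = x[:, adata.var_names.get_indexer(te)].mean(axis=1)
    icm_mean = x[:, adata.var_names.get_indexer(icm)].mean(axis=1)
    labels = np.where(
        (te_mean > icm_mean) & (te_mean > 0),
        TE,
        np.where((icm_mean > te_mean) & (icm_mean > 0), ICM, UNASSIGNED),
    )
    out = pd.Series(labels, index=adata.obs_names, name="cell_type")
    adata.obs["cell_type"] = out.values
    return out


def classify_sex(adata: ad.AnnData, panel: MarkerPanel = DEFAULT_PANEL) -> pd.Series:
    """Male iff any Y-chromosome marker has a raw count > 0.

    Few sex-specific genes are expressed at E4.5, so only male cells
    (expressing Eif2s3y, Usp9y or Kdm5d) can be called confidently; all
    others are "female/indeterminate".  Written to ``obs["sex_class"]``.
    """
    male = [g for g in panel.male_markers if g in adata.var_names]
    if not male:
        raise ValueError("no male marker gene found in the matrix")
    counts = _counts(adata)
    any_male = (counts[:, adata.var_names.get_indexer(male)] > 0).any(axis=1)
    out = pd.Series(
        np.where(any_male, MALE, FEMALE_INDET), index=adata.obs_names, name="sex_class"
    )
    adata.obs["sex_class"] = out.values
    return out
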