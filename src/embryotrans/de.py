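"""Two-part (hurdle) differential expression between cell groups.

Single-cell expression is zero-inflated: a gene can differ between groups in
how often it is detected, in how strongly it is expressed when detected, or
both.  The hurdle test therefore combines

* part 1 — a Fisher exact test on the 2x2 detection table
  (count > 0 vs count == 0, group A vs group B), and
* part 2 — a two-sided Mann-Whitney rank-sum test on the normalized values
  of the detected (positive-count) cells,

via Fisher's method; a part with no data contributes p = 1.  A gene
undetected in both groups gets p = 1 by convention.  Effect size is the
log2 ratio of group means of normalized expression with a small
pseudocount, computed on the de-logged (normalized-count) scale — the
usual convention for single-cell average fold changes — so a planted
4-fold mean shift reads as a log2 FC near 2.
A gene is called significant when |log2 FC| > 1 (strict) and raw p <= 0.05;
Benjamini-Hochberg adjusted p-values over all tested genes are reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEThresholds",
    "ComparisonSpec",
    "log2_fold_change",
    "hurdle_test",
    "select_cells",
    "run_de",
]

#: Default pseudocount on the normalized-expression scale for fold changes.
DEFAULT_PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class DEThresholds:
    """Significance cuts: |log2 FC| > lfc_cut (strict) and p <= p_cut."""

    lfc_cut: float = 1.0
    p_cut: float = 0.05

    def __post_init__(self) -> None:
        if self.lfc_cut <= 0:
            raise ValueError("lfc_cut must be positive")
        if not 0.0 < self.p_cut < 1.0:
            raise ValueError("p_cut must be in (0, 1)")


@dataclass(frozen=True)
class ComparisonSpec:
    """Two disjoint cell selections to compare (A vs B).

    Each selector is a dict over obs columns, e.g.
    ``{"group": "HFDM", "generation": "F2"}`` with optional ``cell_type``
    and ``sex_class`` keys.
    """

    label: str
    cells_a: dict
    cells_b: dict


def log2_fold_change(expr_a, expr_b, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2((mean_A + pc) / (mean_B + pc)); positive when A > B."""
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    # normalized values can dip slightly negative after covariate regression;
    # means are floored at zero so the ratio stays defined
    mean_a = max(float(a.mean()), 0.0)
    mean_b = max(float(b.mean()), 0.0)
    return float(np.log2((mean_a + pseudocount) / (mean_b + pseudocount)))


def hurdle_test(values_a, values_b, detected_a=None, detected_b=None) -> float:
    """Two-part hurdle p-value for one gene.

    ``values_a``/``values_b`` are normalized expression values per cell;
    ``detected_a``/``detected_b`` are boolean detection masks (default:
    value > 0, which matches raw-count detection when values are
    log-normalized counts).  Returns a p-value in (0, 1].
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    da = np.asarray(detected_a, dtype=bool) if detected_a is not None else a > 0
    db = np.asarray(detected_b, dtype=bool) if detected_b is not None else b > 0
    ka, kb = int(da.sum()), int(db.sum())
    if ka == 0 and kb == 0:
        return 1.0

    # part 1: detection proportions
    table = [[ka, a.size - ka], [kb, b.size - kb]]
    p_detect = float(stats.fisher_exact(table, alternative="two-sided")[1])

    # part 2: location among detected cells
    pos_a, pos_b = a[da], b[db]
    if pos_a.size > 0 and pos_b.size > 0 and np.ptp(np.concatenate([pos_a, pos_b])) > 0:
        p_loc = float(
            stats.mannwhitneyu(pos_a, pos_b, alternative="two-sided").pvalue
        )
    else:
        p_loc = 1.0

    p_detect = min(max(p_detect, 1e-300), 1.0)
    p_loc = min(max(p_loc, 1e-300), 1.0)
    combined = float(stats.combine_pvalues([p_detect, p_loc], method="fisher")[1])
    return min(max(combined, 1e-300), 1.0)


def select_cells(adata, selector: dict) -> np.ndarray:
    """Boolean mask over cells matching every (obs column, value) pair."""
    mask = np.ones(adata.n_obs, dtype=bool)
    for col, value in selector.items():
        if col not in adata.obs:
            raise ValueError(f"unknown obs column in selector: {col!r}")
        mask &= (adata.obs[col] == value).to_numpy()
    return mask


def run_de(
    adata,
    spec: ComparisonSpec,
    thresholds: DEThresholds = DEThresholds(),
    layer: str = "normalized",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene hurdle DE between the two cell selections of ``spec``.

    Genes detected (raw count > 0) in no cell of either selection are
    skipped.  Returns a frame with columns ``gene``, ``p_value``,
    ``log2_fc``, ``p_adjusted`` (Benjamini-Hochberg over tested genes),
    ``direction`` and ``significant``, sorted by p-value.

    Raises
    ------
    ValueError
        If the selections overlap or either is empty.
    """
    mask_a = select_cells(adata, spec.cells_a)
    mask_b = select_cells(adata, spec.cells_b)
    if not mask_a.any() or not mask_b.any():
        raise ValueError(f"empty cell selection in comparison {spec.label!r}")
    if (mask_a & mask_b).any():
        raise ValueError(f"overlapping cell selections in comparison {spec.label!r}")

    counts = adata.X
    if hasattr(counts, "toarray"):
        counts = counts.toarray()
    counts = np.asarray(counts)
    values = np.asarray(adata.layers[layer]) if layer in adata.layers else counts

    det_a = counts[mask_a] > 0
    det_b = counts[mask_b] > 0
    vals_a = values[mask_a]
    vals_b = values[mask_b]

    tested = np.flatnonzero(det_a.any(axis=0) | det_b.any(axis=0))
    # fold changes are taken on the de-logged normalized-count scale
    expr_a = np.expm1(vals_a)
    expr_b = np.expm1(vals_b)
    records = []
    for j in tested:
        p = hurdle_test(vals_a[:, j], vals_b[:, j], det_a[:, j], det_b[:, j])
        lfc = log2_fold_change(expr_a[:, j], expr_b[:, j], pseudocount)
        records.append((adata.var_names[j], p, lfc))
    result = pd.DataFrame(records, columns=["gene", "p_value", "log2_fc"])
    if len(result):
        result["p_adjusted"] = multipletests(result["p_value"], method="fdr_bh")[1]
    else:
        result["p_adjusted"] = pd.Series(dtype=float)
    result["direction"] = np.where(result["log2_fc"] > 0, "up", "down")
    result["significant"] = (
        (result["log2_fc"].abs() > thresholds.lfc_cut)
        & (result["p_value"] <= thresholds.p_cut)
    )
    result = result.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    result.attrs["comparison"] = spec.label
    result.attrs["pseudocount"] = pseudocount
    result.attrs["n_cells_a"] = int(mask_a.sum())
    result.attrs["n_cells_b"] = int(mask_b.sum())
    return result
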