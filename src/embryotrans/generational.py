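"""Cross-generation analyses of differential-expression results.

Embryos from different generations were collected years apart, so genes that
differ between the two *control* generations (CON F2e vs CON F3e) are
treated as environmental/batch confounders and removed from every other
comparison's DEG set.  The remaining DEGs are then examined for:

* directionality across generations — whether a gene up- or downregulated
  in F2e (vs its generational control) stays that way, flips, or is no
  longer significant (NS) in F3e;
* conservation in a mitochondrial catalog (genes present in both the mouse
  and human sets, labeled with one of seven functional categories);
* pathway over-representation, scored as fold enrichment
  (k/n)/(K/N) with a hypergeometric upper-tail p-value and
  Benjamini-Hochberg adjustment across pathways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .de import ComparisonSpec, DEThresholds, run_de

__all__ = [
    "MITO_CATEGORIES",
    "DIRECTIONALITY_CATEGORIES",
    "build_confounder_blacklist",
    "apply_confounder_filter",
    "classify_directionality",
    "load_mito_catalog",
    "mito_categorize",
    "fold_enrichment_test",
]

#: The seven functional categories of the conserved mitochondrial catalog.
MITO_CATEGORIES: tuple[str, ...] = (
    "metabolism",
    "mitoribosomes and biosynthesis",
    "cell signaling and cell fate",
    "oxidative phosphorylation",
    "oxidative repair",
    "dynamism (fission/fusion)",
    "structure/other",
)

DIRECTIONALITY_CATEGORIES: tuple[str, ...] = (
    "Up->Up", "Up->Down", "Up->NS",
    "Down->Down", "Down->Up", "Down->NS",
    "NS->Up", "NS->Down",
)


def build_confounder_blacklist(
    adata,
    thresholds: DEThresholds = DEThresholds(),
    control_group: str = "CON",
    generations: tuple[str, str] = ("F2", "F3"),
    layer: str = "normalized",
) -> set[str]:
    """Genes significantly different between the two control generations.

    Runs the hurdle DE between CON cells of the two generations and returns
    genes with |log2 FC| >= lfc_cut and p <= p_cut.  (The blacklist uses an
    inclusive fold-change bound, the printed definition of the confounder
    condition; the main DEG call is strict.)

    Raises
    ------
    ValueError
        If either control generation has no cells.
    """
    spec = ComparisonSpec(
        label=f"{control_group}-{generations[0]}_vs_{control_group}-{generations[1]}",
        cells_a={"group": control_group, "generation": generations[0]},
        cells_b={"group": control_group, "generation": generations[1]},
    )
    result = run_de(adata, spec, thresholds, layer=layer)
    hit = (result["log2_fc"].abs() >= thresholds.lfc_cut) & (
        result["p_value"] <= thresholds.p_cut
    )
    return set(result.loc[hit, "gene"])


def apply_confounder_filter(degs: pd.DataFrame, blacklist: set[str]) -> pd.DataFrame:
    """Drop blacklisted genes from a DE result; all other rows unchanged."""
    if len(degs) == 0 or not blacklist:
        return degs.copy()
    return degs[~degs["gene"].isin(blacklist)].reset_index(drop=True)


def _state(row, thresholds: DEThresholds) -> str:
    sig = (abs(row["log2_fc"]) > thresholds.lfc_cut) and (
        row["p_value"] <= thresholds.p_cut
    )
    if not sig:
        return "NS"
    return "Up" if row["log2_fc"] > 0 else "Down"


def classify_directionality(
    f2: pd.DataFrame,
    f3: pd.DataFrame,
    thresholds: DEThresholds = DEThresholds(),
) -> pd.DataFrame:
    """Classify each gene's DE pattern across the two generations.

    ``f2`` and ``f3`` are DE results of the within-generation exposure
    comparisons (HF+DM vs CON in F2e, and in F3e).  Every gene significant
    in at least one generation receives exactly one category such as
    ``Up->Down`` (upregulated in F2e, downregulated in F3e) or ``Up->NS``
    (no longer significant in F3e).  Genes significant in neither are
    omitted.
    """
    f2i = f2.set_index("gene")
    f3i = f3.set_index("gene")
    records = []
    for gene in sorted(set(f2i.index) | set(f3i.index)):
        s2 = _state(f2i.loc[gene], thresholds) if gene in f2i.index else "NS"
        s3 = _state(f3i.loc[gene], thresholds) if gene in f3i.index else "NS"
        if s2 == "NS" and s3 == "NS":
            continue
        records.append(
            {
                "gene": gene,
                "f2_log2fc": float(f2i.loc[gene, "log2_fc"]) if gene in f2i.index else np.nan,
                "f2_significant": s2 != "NS",
                "f3_log2fc": float(f3i.loc[gene, "log2_fc"]) if gene in f3i.index else np.nan,
                "f3_significant": s3 != "NS",
                "category": f"{s2}->{s3}",
            }
        )
    out = pd.DataFrame(
        records,
        columns=[
            "gene", "f2_log2fc", "f2_significant",
            "f3_log2fc", "f3_significant", "category",
        ],
    )
    assert set(out["category"]) <= set(DIRECTIONALITY_CATEGORIES)
    return out


def load_mito_catalog(path) -> pd.DataFrame:
    """Read a mitochondrial catalog TSV: columns gene, species, category.

    Species is ``mouse`` or ``human``; category must be one of the seven
    fixed labels.
    """
    catalog = pd.read_csv(path, sep="\t")
    return validate_mito_catalog(catalog)


def validate_mito_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    missing = {"gene", "species", "category"} - set(catalog.columns)
    if missing:
        raise ValueError(f"catalog lacks columns: {sorted(missing)}")
    bad = set(catalog["category"]) - set(MITO_CATEGORIES)
    if bad:
        raise ValueError(f"unknown mitochondrial categories: {sorted(bad)}")
    bad_sp = set(catalog["species"]) - {"mouse", "human"}
    if bad_sp:
        raise ValueError(f"unknown catalog species: {sorted(bad_sp)}")
    return catalog


def mito_categorize(degs: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Match DEGs to the conserved mitochondrial catalog.

    A DEG matches only when present in *both* the mouse and the human set.
    Matched genes carry their functional category; if the mouse and human
    entries disagree the row is flagged (``category_conflict``) rather than
    silently resolved, with the mouse category reported.
    """
    validate_mito_catalog(catalog)
    mouse = catalog[catalog["species"] == "mouse"].set_index("gene")["category"]
    human = catalog[catalog["species"] == "human"].set_index("gene")["category"]
    records = []
    for _, row in degs.iterrows():
        gene = row["gene"]
        if gene in mouse.index and gene in human.index:
            m_cat, h_cat = mouse[gene], human[gene]
            records.append(
                {
                    "gene": gene,
                    "category": m_cat,
                    "category_conflict": m_cat != h_cat,
                    "direction": row.get("direction", ""),
                    "log2_fc": row.get("log2_fc", np.nan),
                }
            )
    return pd.DataFrame(
        records,
        columns=["gene", "category", "category_conflict", "direction", "log2_fc"],
    )


def fold_enrichment_test(
    deg_genes,
    pathways: dict,
    universe,
) -> pd.DataFrame:
    """Pathway over-representation by fold enrichment and hypergeometric p.

    For each pathway: k = DEGs in the pathway, n = number of DEGs,
    K = pathway genes in the universe, N = universe size;
    fold_enrichment = (k/n)/(K/N) and the p-value is the hypergeometric
    upper tail P(X >= k).  Adjusted p is Benjamini-Hochberg across
    pathways.  The universe defaults in callers to all tested genes.

    Raises
    ------
    ValueError
        If the universe or DEG set is empty, or DEGs fall outside the
        universe.
    """
    universe = set(universe)
    deg_genes = set(deg_genes)
    if not universe:
        raise ValueError("empty gene universe")
    if not deg_genes:
        raise ValueError("empty DEG set")
    if not deg_genes <= universe:
        raise ValueError("DEG set must be a subset of the universe")
    n = len(deg_genes)
    N = len(universe)
    records = []
    for name, genes in pathways.items():
        in_universe = set(genes) & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(deg_genes & in_universe)
        fe = (k / n) / (K / N)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        records.append(
            {"pathway": name, "k": k, "n": n, "K": K, "N": N,
             "fold_enrichment": fe, "p_value": min(p, 1.0)}
        )
    out = pd.DataFrame(
        records,
        columns=["pathway", "k", "n", "K", "N", "fold_enrichment", "p_value"],
    )
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
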