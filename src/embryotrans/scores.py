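"""Per-cell gene-set expression scores.

A gene-set score is the unweighted mean of normalized expression over the
set's genes, computed per cell.  Three sets are packaged:

* ``mito`` — the 13 protein-coding genes of the mitochondrial genome, used
  as a proxy for mitochondrial quantity;
* ``stress`` — 11 antioxidant-response genes (superoxide dismutases,
  thioredoxin reductases, peroxiredoxins, glutathione peroxidases/reductase);
* ``repair`` — 7 base-excision-repair genes handling oxidized bases.

Scores are compared across experimental groups with the same rank-based
tests used for embryo scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grading import GroupComparison, compare_score_groups as _compare_groups

__all__ = [
    "GeneSetDefinition",
    "ScoreResult",
    "GENE_SETS",
    "MITO_GENES",
    "STRESS_GENES",
    "REPAIR_GENES",
    "gene_set_score",
    "compare_score_groups",
]

MITO_GENES: tuple[str, ...] = (
    "Mt-nd1", "Mt-nd2", "Mt-nd3", "Mt-nd4", "Mt-nd4l", "Mt-nd5", "Mt-nd6",
    "Mt-co1", "Mt-co2", "Mt-co3", "Mt-atp6", "Mt-atp8", "Mt-cyb",
)

STRESS_GENES: tuple[str, ...] = (
    "Sod1", "Sod2", "Txnrd1", "Txnrd2", "Prdx1", "Prdx2", "Prdx3", "Prdx5",
    "Gpx1", "Gpx2", "Gsr",
)

REPAIR_GENES: tuple[str, ...] = (
    "Mutyh", "Ogg1", "Nthl1", "Ung", "Tdg", "Mpg", "Polb",
)


@dataclass(frozen=True)
class GeneSetDefinition:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate ids")


#: Packaged default gene sets (mitochondrial quantity, oxidative-stress
#: response, base-excision repair).
GENE_SETS: dict[str, GeneSetDefinition] = {
    "mito": GeneSetDefinition("mito", MITO_GENES),
    "stress": GeneSetDefinition("stress", STRESS_GENES),
    "repair": GeneSetDefinition("repair", REPAIR_GENES),
}


@dataclass(frozen=True)
class ScoreResult:
    """Per-cell gene-set scores plus the set genes that were missing."""

    set_name: str
    scores: pd.Series  # indexed by cell id
    genes_used: tuple[str, ...]
    genes_missing: tuple[str, ...]


def gene_set_score(adata, gene_set: GeneSetDefinition, layer: str = "normalized") -> ScoreResult:
    """Per-cell mean normalized expression over a gene set.

    Set genes absent from the matrix are skipped with a warning (absence is
    a detection artifact, not zero biology) and reported in the result.

    Raises
    ------
    ValueError
        If no set gene is present in the matrix.
    """
    present = [g for g in gene_set.genes if g in adata.var_names]
    missing = tuple(g for g in gene_set.genes if g not in adata.var_names)
    if not present:
        raise ValueError(
            f"no gene of set {gene_set.name!r} is present in the matrix"
        )
    if missing:
        warnings.warn(
            f"gene set {gene_set.name!r}: {len(missing)} gene(s) absent from "
            f"matrix and skipped: {missing}",
            stacklevel=2,
        )
    x = adata[:, present].layers[layer] if layer in adata.layers else adata[:, present].X
    x = np.asarray(x)
    scores = pd.Series(x.mean(axis=1), index=adata.obs_names, name=gene_set.name)
    return ScoreResult(
        set_name=gene_set.name,
        scores=scores,
        genes_used=tuple(present),
        genes_missing=missing,
    )


def compare_score_groups(result: ScoreResult, grouping) -> GroupComparison:
    """Rank-based comparison of per-cell scores across groups.

    ``grouping`` is a label per cell, aligned with ``result.scores``.  Two
    groups use the Mann-Whitney U test, more use Kruskal-Wallis; per-group
    medians and quartiles are reported.
    """
    grouping = pd.Series(np.asarray(grouping), index=result.scores.index)
    by_group = {
        str(lab): result.scores[grouping == lab].to_numpy()
        for lab in grouping.unique()
    }
    return _compare_groups(by_group)
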