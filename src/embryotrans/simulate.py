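"""Synthetic data generators emulating the study's structure.

Every pipeline stage can be exercised without any download: this module
fabricates grade cohorts, blinded rater pairs, barnyard mapping-rate
profiles, structured count matrices with known planted effects, small
mitochondrial catalogs / pathway annotations, and 3-channel voxel stacks —
each paired with its ground truth.

The count simulator draws negative-binomial counts (gamma-Poisson, NB
dispersion theta so that var = mu + mu^2/theta) with independent Bernoulli
dropout, over a gene universe that contains the TE/ICM/male marker panels,
the three packaged gene sets, a block of ribosomal genes and filler genes.
Marker genes are elevated in their own cell type; male markers are strictly
zero outside male cells so the presence/absence sex rule is exercisable;
planted group x generation effects act multiplicatively on the mean
(log2 scale).  All randomness flows from a single integer seed and the same
seed reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .grading import ALL_GRADES, parse_grade
from .qc import DEFAULT_PANEL
from .scores import MITO_GENES, REPAIR_GENES, STRESS_GENES
from .generational import MITO_CATEGORIES

__all__ = [
    "SimDesign",
    "PlantedEffect",
    "CountsTruth",
    "ZStackTruth",
    "DEFAULT_GROUPS",
    "generate_grade_cohort",
    "generate_rater_pairs",
    "generate_barnyard",
    "generate_counts",
    "generate_zstack",
    "make_mito_catalog",
    "make_pathways",
]

DEFAULT_GROUPS: tuple[tuple[str, str], ...] = (
    ("CON", "F2"), ("CON", "F3"), ("HFDM", "F2"), ("HFDM", "F3"),
)

RIBO_GENES: tuple[str, ...] = tuple(f"Rps{i}" for i in range(1, 11)) + tuple(
    f"Rpl{i}" for i in range(1, 11)
)


@dataclass(frozen=True)
class PlantedEffect:
    """A multiplicative log2 expression effect planted in one population.

    Cells of ``(group, generation)`` get their mean expression of ``genes``
    multiplied by ``2**log2_effect`` relative to every other population.
    """

    label: str
    genes: tuple[str, ...]
    group: str
    generation: str
    log2_effect: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2_effect):
            raise ValueError("planted log2 effect must be finite")


@dataclass(frozen=True)
class SimDesign:
    """Design of a synthetic count matrix.

    Defaults emulate the study's scale at desk size: four populations
    (CON/HFDM x F2/F3), ~70% trophectoderm cells, ~30% male-marker-positive
    cells, NB counts with moderate dispersion and dropout.
    """

    n_cells_per_group: int = 200
    groups: tuple[tuple[str, str], ...] = DEFAULT_GROUPS
    n_genes: int = 2000
    frac_te: float = 0.7
    frac_male: float = 0.3
    planted_effects: tuple[PlantedEffect, ...] = ()
    dispersion: float = 2.0
    dropout_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_te", "frac_male", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_cells_per_group < 0 or self.n_genes <= 0:
            raise ValueError("cell and gene counts must be positive")


@dataclass(frozen=True)
class CountsTruth:
    """Ground truth of a simulated count matrix.

    ``gene_effects`` has one row per (gene, population) planted effect;
    ``cells`` records every cell's true type and sex exactly once.
    """

    gene_effects: pd.DataFrame  # gene, group, generation, log2_effect
    cells: pd.DataFrame  # cell, group, generation, cell_type, sex


def gene_universe(n_genes: int) -> list[str]:
    """Named gene universe: markers, gene sets, ribosomal block, filler."""
    panel = DEFAULT_PANEL
    named = (
        list(panel.te_markers)
        + list(panel.icm_markers)
        + list(panel.male_markers)
        + list(MITO_GENES)
        + list(STRESS_GENES)
        + list(REPAIR_GENES)
        + list(RIBO_GENES)
    )
    if n_genes < len(named):
        raise ValueError(
            f"n_genes must be at least {len(named)} to hold the named genes"
        )
    filler = [f"Gene{i:05d}" for i in range(n_genes - len(named))]
    return named + filler


def generate_counts(design: SimDesign) -> tuple[ad.AnnData, CountsTruth]:
    """Simulate a gene x cell count matrix with known structure.

    Returns an AnnData (cells x genes, raw counts in ``X``, population and
    true-label metadata in ``obs``) plus the ground truth.  Marker genes are
    elevated 8-fold in their own cell type and suppressed 4-fold in the
    other; male markers are strictly zero in non-male cells; planted
    contrasts are realized in expectation.
    """
    rng = np.random.default_rng(design.seed)
    genes = gene_universe(design.n_genes)
    gene_idx = {g: j for j, g in enumerate(genes)}
    for eff in design.planted_effects:
        unknown = [g for g in eff.genes if g not in gene_idx]
        if unknown:
            raise ValueError(
                f"planted effect {eff.label!r} references unknown genes: {unknown[:5]}"
            )
        if (eff.group, eff.generation) not in design.groups:
            raise ValueError(
                f"planted effect {eff.label!r} targets unknown population "
                f"{(eff.group, eff.generation)}"
            )

    # cells
    obs_rows = []
    for group, generation in design.groups:
        for i in range(design.n_cells_per_group):
            obs_rows.append((f"{group}-{generation}-{i:04d}", group, generation))
    obs = pd.DataFrame(obs_rows, columns=["cell", "group", "generation"]).set_index("cell")
    n_cells = len(obs)
    obs["cell_type_true"] = np.where(
        rng.random(n_cells) < design.frac_te, "TE", "ICM"
    )
    obs["sex_true"] = np.where(
        rng.random(n_cells) < design.frac_male, "male", "female/indeterminate"
    )

    # per-gene baseline means; ribosomal genes a bit higher so the ribo
    # fraction covariate has realistic spread
    base_mu = rng.lognormal(mean=np.log(2.0), sigma=0.8, size=design.n_genes)
    ribo_j = [gene_idx[g] for g in RIBO_GENES]
    base_mu[ribo_j] *= 3.0

    mu = np.tile(base_mu, (n_cells, 1))
    te_cells = (obs["cell_type_true"] == "TE").to_numpy()
    male_cells = (obs["sex_true"] == "male").to_numpy()
    te_j = [gene_idx[g] for g in DEFAULT_PANEL.te_markers]
    icm_j = [gene_idx[g] for g in DEFAULT_PANEL.icm_markers]
    male_j = [gene_idx[g] for g in DEFAULT_PANEL.male_markers]
    mu[np.ix_(te_cells, te_j)] *= 8.0
    mu[np.ix_(~te_cells, te_j)] *= 0.25
    mu[np.ix_(~te_cells, icm_j)] *= 8.0
    mu[np.ix_(te_cells, icm_j)] *= 0.25
    mu[np.ix_(male_cells, male_j)] = 3.0
    mu[np.ix_(~male_cells, male_j)] = 0.0

    effect_rows = []
    for eff in design.planted_effects:
        target = (
            (obs["group"] == eff.group) & (obs["generation"] == eff.generation)
        ).to_numpy()
        cols = [gene_idx[g] for g in eff.genes]
        mu[np.ix_(target, cols)] *= 2.0**eff.log2_effect
        for g in eff.genes:
            effect_rows.append((g, eff.group, eff.generation, eff.log2_effect))

    # gamma-Poisson mixture = NB(mu, theta); strict zeros stay zero
    theta = design.dispersion
    lam = np.zeros_like(mu)
    positive = mu > 0
    lam[positive] = rng.gamma(shape=theta, scale=mu[positive] / theta)
    counts = rng.poisson(lam)
    if design.dropout_rate > 0:
        counts[rng.random(counts.shape) < design.dropout_rate] = 0
    # sex is defined by Y-marker presence, so every male cell keeps at
    # least one marker transcript (sampling noise must not erase its sex)
    male_counts = counts[np.ix_(male_cells, male_j)]
    silent = ~(male_counts > 0).any(axis=1)
    male_counts[silent, 0] = 1
    counts[np.ix_(male_cells, male_j)] = male_counts

    adata = ad.AnnData(
        X=counts.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    truth = CountsTruth(
        gene_effects=pd.DataFrame(
            effect_rows, columns=["gene", "group", "generation", "log2_effect"]
        ),
        cells=obs.reset_index().rename(
            columns={"cell_type_true": "cell_type", "sex_true": "sex"}
        ),
    )
    return adata, truth


def generate_grade_cohort(
    n_litters: int,
    litter_size_mean: float,
    grade_probs: dict,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-embryo grade tables for litters assigned to groups.

    ``grade_probs`` maps each group label to a distribution over valid
    grade strings (probabilities summing to 1).  Litter sizes are Poisson
    with the given mean (zero-size litters are redrawn as 1).  Pre- and
    post-culture grades are drawn from the same distribution, and an embryo
    is flagged ``changed_in_culture`` when its grade changed or (for
    unchanged grades) with probability 0.5, modeling cell-count changes that
    grading cannot see.

    Returns the embryo table and a per-litter ground-truth table of
    non-viable counts (unchanged 1CC embryos).
    """
    rng = np.random.default_rng(seed)
    for group, dist in grade_probs.items():
        for g in dist:
            parse_grade(g)  # raises on invalid support
        total = float(sum(dist.values()))
        if not np.isclose(total, 1.0):
            raise ValueError(
                f"grade probabilities for group {group!r} sum to {total}, not 1"
            )
    groups = list(grade_probs)
    rows = []
    truth_rows = []
    for litter in range(n_litters):
        group = groups[litter % len(groups)]
        size = max(1, int(rng.poisson(litter_size_mean)))
        dist = grade_probs[group]
        support = list(dist)
        probs = np.array([dist[g] for g in support], dtype=float)
        probs /= probs.sum()
        n_nonviable = 0
        for e in range(size):
            pre = support[rng.choice(len(support), p=probs)]
            post = support[rng.choice(len(support), p=probs)]
            changed = pre != post or bool(rng.random() < 0.5)
            if post == "1CC" and not changed:
                n_nonviable += 1
            rows.append(
                {
                    "litter_id": f"L{litter:03d}",
                    "embryo_id": f"L{litter:03d}-E{e:02d}",
                    "group": group,
                    "grade_pre": pre,
                    "grade_post": post,
                    "changed_in_culture": changed,
                }
            )
        truth_rows.append(
            {
                "litter_id": f"L{litter:03d}",
                "group": group,
                "n_embryos": size,
                "n_nonviable": n_nonviable,
            }
        )
    columns = [
        "litter_id", "embryo_id", "group", "grade_pre", "grade_post",
        "changed_in_culture",
    ]
    return (
        pd.DataFrame(rows, columns=columns),
        pd.DataFrame(
            truth_rows, columns=["litter_id", "group", "n_embryos", "n_nonviable"]
        ),
    )


def generate_rater_pairs(n: int, agreement: float, seed: int = 0) -> pd.DataFrame:
    """Paired embryo scores from two simulated blinded raters.

    Rater 1 scores uniformly over the 3-9 embryo-score scale; rater 2
    repeats rater 1's score with probability ``agreement`` and otherwise
    draws an independent uniform score.  ``agreement=1`` gives perfect
    concordance; ``agreement=0`` gives independence (kappa ~ 0).
    """
    if not 0.0 <= agreement <= 1.0:
        raise ValueError("agreement must be in [0, 1]")
    rng = np.random.default_rng(seed)
    scale = np.arange(3, 10)
    a = rng.choice(scale, size=n)
    b = np.where(rng.random(n) < agreement, a, rng.choice(scale, size=n))
    return pd.DataFrame({"rater_a": a, "rater_b": b})


def generate_barnyard(
    n_rat: int,
    n_human: int,
    separation: float = 0.8,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate dual-genome mapping-rate profiles for a species mixture.

    Rat barcodes map at ~``0.5 + separation/2`` to rat and
    ~``0.5 - separation/2`` to human (Gaussian noise ``noise_sd``, clipped
    to [0, 1]); human barcodes are the mirror image.  Returns a frame with
    ``barcode``, ``rate_rat``, ``rate_human`` and the ground-truth
    ``species_true``.
    """
    if n_rat < 0 or n_human < 0:
        raise ValueError("barcode counts must be non-negative")
    rng = np.random.default_rng(seed)
    hi = 0.5 + separation / 2.0
    lo = 0.5 - separation / 2.0
    n = n_rat + n_human
    species = np.array(["rat"] * n_rat + ["human"] * n_human)
    own = rng.normal(hi, noise_sd, size=n)
    other = rng.normal(lo, noise_sd, size=n)
    rate_rat = np.where(species == "rat", own, other).clip(0.0, 1.0)
    rate_human = np.where(species == "rat", other, own).clip(0.0, 1.0)
    return pd.DataFrame(
        {
            "barcode": [f"BC{i:05d}" for i in range(n)],
            "rate_rat": rate_rat,
            "rate_human": rate_human,
            "species_true": species,
        }
    )


@dataclass(frozen=True)
class ZStackTruth:
    """Ground truth of a synthetic voxel stack."""

    channel_sums: dict
    n_nuclei: int
    nucleus_centers: tuple
    nucleus_radius: int


def generate_zstack(
    shape: tuple[int, int, int] = (12, 64, 64),
    n_nuclei: int = 5,
    channel_means: dict | None = None,
    slice_height_um: float = 1.675,
    seed: int = 0,
    nucleus_radius: int = 3,
    nucleus_value: float = 200.0,
):
    """Synthetic 3-channel stack with disjoint solid nuclei.

    Nuclei are solid spheres of ``nucleus_radius`` placed by rejection
    sampling so that no two overlap (an impossible packing raises).  The
    remaining channels are Poisson noise fields at the given means.
    Returns the :class:`~embryotrans.imaging.ZStack` and a
    :class:`ZStackTruth` recording the rendered per-channel voxel sums,
    the nucleus count and centers.
    """
    from .imaging import ZStack

    if channel_means is None:
        channel_means = {"mito": 20.0, "ros": 10.0}
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    r = nucleus_radius

    def draw_axis(dim: int) -> int:
        # thin axes (e.g. few z slices) center the nucleus and clip it,
        # as real stacks clip nuclei at the first/last slice
        if dim > 2 * r:
            return int(rng.integers(r, dim - r))
        return dim // 2

    # rejection sampling with whole-configuration restarts, so one badly
    # placed early nucleus cannot wedge the packing
    min_sep2 = (2 * r + 2) ** 2  # one-voxel gap even under 26-connectivity
    centers: list[tuple[int, int, int]] = []
    for _ in range(200):
        centers = []
        for _ in range(200 * max(n_nuclei, 1)):
            c = (draw_axis(nz), draw_axis(ny), draw_axis(nx))
            if all(
                (c[0] - o[0]) ** 2 + (c[1] - o[1]) ** 2 + (c[2] - o[2]) ** 2
                >= min_sep2
                for o in centers
            ):
                centers.append(c)
            if len(centers) == n_nuclei:
                break
        if len(centers) == n_nuclei:
            break
    if len(centers) < n_nuclei:
        raise ValueError(
            f"cannot pack {n_nuclei} disjoint nuclei of radius {r} "
            f"into shape {shape}"
        )

    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    nuclei = np.zeros(shape, dtype=float)
    for cz, cy, cx in centers:
        inside = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        nuclei[inside] = nucleus_value

    channels = {"nuclei": nuclei}
    for name, mean in channel_means.items():
        channels[name] = rng.poisson(mean, size=shape).astype(float)

    stack = ZStack(channels=channels, slice_height_um=slice_height_um)
    truth = ZStackTruth(
        channel_sums={name: float(arr.sum()) for name, arr in channels.items()},
        n_nuclei=len(centers),
        nucleus_centers=tuple(centers),
        nucleus_radius=r,
    )
    return stack, truth


def make_mito_catalog(
    conserved_genes=MITO_GENES,
    mouse_only=("Gene00001",),
    seed: int = 0,
    conflict_genes=(),
) -> pd.DataFrame:
    """Small synthetic stand-in for a curated mitochondrial gene catalog.

    Conserved genes appear under both the mouse and human sets with the same
    functional category (drawn deterministically from the seven labels);
    ``mouse_only`` genes appear only in the mouse set; ``conflict_genes``
    get deliberately disagreeing categories so conflict flagging is
    exercisable.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in conserved_genes:
        cat = MITO_CATEGORIES[int(rng.integers(len(MITO_CATEGORIES)))]
        rows.append({"gene": g, "species": "mouse", "category": cat})
        rows.append({"gene": g, "species": "human", "category": cat})
    for g in mouse_only:
        cat = MITO_CATEGORIES[int(rng.integers(len(MITO_CATEGORIES)))]
        rows.append({"gene": g, "species": "mouse", "category": cat})
    for g in conflict_genes:
        rows.append({"gene": g, "species": "mouse", "category": MITO_CATEGORIES[0]})
        rows.append({"gene": g, "species": "human", "category": MITO_CATEGORIES[1]})
    return pd.DataFrame(rows, columns=["gene", "species", "category"])


def make_pathways(universe, n_pathways: int = 10, size: int = 30, seed: int = 0) -> dict:
    """Random disjoint-ish pathway annotation over a gene universe."""
    rng = np.random.default_rng(seed)
    universe = list(universe)
    return {
        f"PW{i:03d}": tuple(
            rng.choice(universe, size=min(size, len(universe)), replace=False)
        )
        for i in range(n_pathways)
    }
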