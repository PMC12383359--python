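"""Confounder blacklist, directionality, mito catalog, fold enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from embryotrans.de import ComparisonSpec, DEThresholds, run_de
from embryotrans.generational import (
    MITO_CATEGORIES,
    apply_confounder_filter,
    build_confounder_blacklist,
    classify_directionality,
    fold_enrichment_test,
    mito_categorize,
    validate_mito_catalog,
)
from embryotrans.qc import compute_qc_metrics, normalize
from embryotrans.simulate import (
    PlantedEffect,
    RIBO_GENES,
    SimDesign,
    gene_universe,
    generate_counts,
    make_mito_catalog,
)


@pytest.fixture(scope="module")
def batch_effect_data():
    """Counts with 20 genes planted as a control-generation batch effect."""
    genes = [g for g in gene_universe(400) if g.startswith("Gene")][:20]
    effects = (
        PlantedEffect("batch", tuple(genes), "CON", "F3", log2_effect=2.0),
        # the same batch shift affects HFDM F3 cells (collection-year effect)
        PlantedEffect("batch_hf", tuple(genes), "HFDM", "F3", log2_effect=2.0),
    )
    adata, _ = generate_counts(
        SimDesign(n_cells_per_group=100, n_genes=400, planted_effects=effects, seed=21)
    )
    compute_qc_metrics(adata, ribo_genes=RIBO_GENES)
    normalize(adata)
    return adata, genes


class TestConfounderBlacklist:
    def test_recovers_planted_batch_genes(self, batch_effect_data):
        adata, genes = batch_effect_data
        blacklist = build_confounder_blacklist(adata)
        recovered = len(blacklist & set(genes)) / len(genes)
        assert recovered >= 0.9

    def test_filtered_outputs_contain_no_blacklisted_gene(self, batch_effect_data):
        adata, genes = batch_effect_data
        blacklist = build_confounder_blacklist(adata)
        for gen in ("F2", "F3"):
            res = run_de(
                adata,
                ComparisonSpec(
                    f"hf_{gen}",
                    {"group": "HFDM", "generation": gen},
                    {"group": "CON", "generation": gen},
                ),
            )
            filtered = apply_confounder_filter(res, blacklist)
            assert not set(filtered["gene"]) & blacklist

    def test_identical_control_populations_give_empty_blacklist(self):
        adata, _ = generate_counts(
            SimDesign(n_cells_per_group=50, n_genes=200, seed=5)
        )
        # copy CON-F2 cells over CON-F3 so the two controls are identical
        con_f2 = (
            (adata.obs["group"] == "CON") & (adata.obs["generation"] == "F2")
        ).to_numpy()
        con_f3 = (
            (adata.obs["group"] == "CON") & (adata.obs["generation"] == "F3")
        ).to_numpy()
        x = adata.X.copy()
        x[con_f3] = x[con_f2]
        adata.X = x
        compute_qc_metrics(adata, ribo_genes=RIBO_GENES)
        normalize(adata)
        assert build_confounder_blacklist(adata) == set()

    def test_missing_control_generation_errors(self):
        adata, _ = generate_counts(
            SimDesign(
                n_cells_per_group=30,
                n_genes=150,
                groups=(("CON", "F2"), ("HFDM", "F2")),
                seed=6,
            )
        )
        compute_qc_metrics(adata, ribo_genes=RIBO_GENES)
        normalize(adata)
        with pytest.raises(ValueError):
            build_confounder_blacklist(adata)


class TestApplyFilter:
    @staticmethod
    def degs():
        return pd.DataFrame(
            {
                "gene": ["a", "b", "c"],
                "p_value": [0.01, 0.02, 0.03],
                "log2_fc": [2.0, -2.0, 1.5],
            }
        )

    def test_empty_blacklist_identity(self):
        out = apply_confounder_filter(self.degs(), set())
        pd.testing.assert_frame_equal(out, self.degs())

    def test_superset_blacklist_empties(self):
        out = apply_confounder_filter(self.degs(), {"a", "b", "c", "d"})
        assert len(out) == 0

    def test_exact_removal(self):
        out = apply_confounder_filter(self.degs(), {"b"})
        assert list(out["gene"]) == ["a", "c"]


def de_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "log2_fc", "p_value"])


class TestDirectionality:
    def test_category_examples(self):
        f2 = de_frame([("g1", 2.0, 0.001), ("g2", 2.0, 0.001), ("g3", 1.5, 0.001)])
        f3 = de_frame([("g1", -1.5, 0.001), ("g2", 0.5, 0.5), ("g3", 2.0, 0.001)])
        out = classify_directionality(f2, f3).set_index("gene")
        assert out.loc["g1", "category"] == "Up->Down"
        assert out.loc["g2", "category"] == "Up->NS"
        assert out.loc["g3", "category"] == "Up->Up"

    def test_totality_and_exclusion(self):
        f2 = de_frame([("a", 2.0, 0.01), ("b", 0.2, 0.9), ("c", -3.0, 0.001)])
        f3 = de_frame([("b", -2.0, 0.01), ("c", 0.1, 0.8), ("d", 0.1, 0.9)])
        out = classify_directionality(f2, f3)
        # a: Up->NS, b: NS->Down, c: Down->NS; d significant nowhere -> absent
        assert sorted(out["gene"]) == ["a", "b", "c"]
        assert out["gene"].is_unique
        assert set(out["category"]) == {"Up->NS", "NS->Down", "Down->NS"}

    def test_flags_consistent(self):
        f2 = de_frame([("a", 2.0, 0.01)])
        f3 = de_frame([("a", 2.0, 0.01)])
        out = classify_directionality(f2, f3)
        assert out.loc[0, "f2_significant"] and out.loc[0, "f3_significant"]


class TestMitoCategorize:
    def test_conserved_gene_matched_with_category(self):
        catalog = pd.DataFrame(
            [
                {"gene": "Acadm", "species": "mouse", "category": "metabolism"},
                {"gene": "Acadm", "species": "human", "category": "metabolism"},
            ]
        )
        degs = pd.DataFrame({"gene": ["Acadm"], "direction": ["up"], "log2_fc": [2.0]})
        out = mito_categorize(degs, catalog)
        assert list(out["gene"]) == ["Acadm"]
        assert out.loc[0, "category"] == "metabolism"
        assert not out.loc[0, "category_conflict"]

    def test_mouse_only_gene_not_matched(self):
        catalog = pd.DataFrame(
            [{"gene": "OnlyMouse", "species": "mouse", "category": "metabolism"}]
        )
        degs = pd.DataFrame({"gene": ["OnlyMouse"]})
        assert len(mito_categorize(degs, catalog)) == 0

    def test_empty_deg_list(self):
        catalog = make_mito_catalog()
        out = mito_categorize(pd.DataFrame({"gene": []}), catalog)
        assert len(out) == 0

    def test_conflicting_categories_flagged(self):
        catalog = make_mito_catalog(conflict_genes=("Weird",))
        degs = pd.DataFrame({"gene": ["Weird"]})
        out = mito_categorize(degs, catalog)
        assert out.loc[0, "category_conflict"]

    def test_unknown_category_errors(self):
        catalog = pd.DataFrame(
            [{"gene": "x", "species": "mouse", "category": "not-a-category"}]
        )
        with pytest.raises(ValueError, match="unknown"):
            validate_mito_catalog(catalog)

    def test_seven_categories(self):
        assert len(MITO_CATEGORIES) == 7


def enumeration_hypergeom_tail(k, N, K, n):
    """P(X >= k) by exhaustive summation of the hypergeometric pmf."""
    total = 0
    for i in range(k, min(n, K) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / math.comb(N, n)


class TestFoldEnrichment:
    @staticmethod
    def run(k, n, K, N):
        universe = [f"u{i}" for i in range(N)]
        pathway = universe[:K]
        degs = pathway[:k] + universe[K : K + (n - k)]
        return fold_enrichment_test(degs, {"pw": pathway}, universe).iloc[0]

    def test_closed_form_ten(self):
        row = self.run(k=5, n=50, K=100, N=10000)
        assert row["fold_enrichment"] == pytest.approx(10.0)

    def test_zero_overlap(self):
        row = self.run(k=0, n=10, K=20, N=100)
        assert row["fold_enrichment"] == 0.0
        assert row["p_value"] == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_hypergeometric_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(10, 51))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        # draw k within the feasible hypergeometric support
        k_min = max(0, n - (N - K))
        k_max = min(n, K)
        k = int(rng.integers(k_min, k_max + 1))
        row = self.run(k=k, n=n, K=K, N=N)
        if k == 0:
            assert row["p_value"] == 1.0
        else:
            assert row["p_value"] == pytest.approx(
                enumeration_hypergeom_tail(k, N, K, n), rel=1e-9
            )

    def test_exhaustive_partition_sums_to_n(self):
        universe = [f"u{i}" for i in range(60)]
        pathways = {
            "a": universe[:20],
            "b": universe[20:45],
            "c": universe[45:],
        }
        degs = universe[5:30]
        res = fold_enrichment_test(degs, pathways, universe)
        assert int(res["k"].sum()) == len(degs)

    def test_errors(self):
        with pytest.raises(ValueError):
            fold_enrichment_test([], {"p": ["a"]}, ["a"])
        with pytest.raises(ValueError):
            fold_enrichment_test(["a"], {"p": ["a"]}, [])
        with pytest.raises(ValueError, match="subset"):
            fold_enrichment_test(["zzz"], {"p": ["a"]}, ["a"])
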