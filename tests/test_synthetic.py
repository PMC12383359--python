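"""The synthetic-data generators: determinism, calibration, ground truth."""

import numpy as np
import pandas as pd
import pytest

from embryotrans.grading import score_grade, weighted_kappa
from embryotrans.simulate import (
    PlantedEffect,
    SimDesign,
    generate_barnyard,
    generate_counts,
    generate_grade_cohort,
    generate_rater_pairs,
    generate_zstack,
)

GRADE_PROBS = {
    "CON": {"4AA": 0.5, "3AB": 0.3, "1CC": 0.2},
    "HFDM": {"4AA": 0.4, "3AB": 0.3, "1CC": 0.3},
}


class TestDeterminism:
    def test_counts_bit_identical(self):
        d = SimDesign(n_cells_per_group=40, n_genes=120, seed=3)
        a1, t1 = generate_counts(d)
        a2, t2 = generate_counts(d)
        np.testing.assert_array_equal(a1.X, a2.X)
        pd.testing.assert_frame_equal(a1.obs, a2.obs)
        pd.testing.assert_frame_equal(t1.gene_effects, t2.gene_effects)

    def test_grades_bit_identical(self):
        t1, _ = generate_grade_cohort(6, 8, GRADE_PROBS, seed=1)
        t2, _ = generate_grade_cohort(6, 8, GRADE_PROBS, seed=1)
        pd.testing.assert_frame_equal(t1, t2)

    def test_barnyard_bit_identical(self):
        b1 = generate_barnyard(30, 10, seed=2)
        b2 = generate_barnyard(30, 10, seed=2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_zstack_bit_identical(self):
        s1, t1 = generate_zstack(shape=(5, 16, 16), n_nuclei=2, seed=4)
        s2, t2 = generate_zstack(shape=(5, 16, 16), n_nuclei=2, seed=4)
        for name in s1.channels:
            np.testing.assert_array_equal(s1.channels[name], s2.channels[name])
        assert t1.nucleus_centers == t2.nucleus_centers


class TestGradeCohort:
    def test_degenerate_all_1cc(self):
        probs = {"CON": {"1CC": 1.0}}
        table, _ = generate_grade_cohort(4, 6, probs, seed=0)
        assert (table["grade_post"].map(score_grade) == 3).all()

    def test_zero_litters_empty_table(self):
        table, truth = generate_grade_cohort(0, 6, GRADE_PROBS, seed=0)
        assert len(table) == 0 and len(truth) == 0

    def test_invalid_grade_in_support(self):
        with pytest.raises(ValueError):
            generate_grade_cohort(2, 5, {"CON": {"5ZZ": 1.0}}, seed=0)

    def test_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            generate_grade_cohort(2, 5, {"CON": {"4AA": 0.5}}, seed=0)

    def test_truth_counts_match_table(self):
        table, truth = generate_grade_cohort(8, 10, GRADE_PROBS, seed=9)
        for _, row in truth.iterrows():
            litter = table[table["litter_id"] == row["litter_id"]]
            assert len(litter) == row["n_embryos"]
            nonviable = (
                (litter["grade_post"] == "1CC") & ~litter["changed_in_culture"]
            ).sum()
            assert nonviable == row["n_nonviable"]


class TestRaterPairs:
    def test_perfect_agreement_gives_kappa_one(self):
        pairs = generate_rater_pairs(113, agreement=1.0, seed=0)
        assert weighted_kappa(pairs["rater_a"], pairs["rater_b"]).kappa == 1.0

    def test_independent_raters_near_zero_kappa(self):
        pairs = generate_rater_pairs(5000, agreement=0.0, seed=1)
        kappa = weighted_kappa(pairs["rater_a"], pairs["rater_b"]).kappa
        assert abs(kappa) < 0.05

    def test_moderate_agreement_between_zero_and_one(self):
        pairs = generate_rater_pairs(113, agreement=0.7, seed=2)
        kappa = weighted_kappa(pairs["rater_a"], pairs["rater_b"]).kappa
        assert 0.0 < kappa < 1.0

    def test_agreement_out_of_range(self):
        with pytest.raises(ValueError):
            generate_rater_pairs(10, agreement=1.5)


class TestBarnyard:
    def test_no_humans_all_rat(self):
        b = generate_barnyard(25, 0, seed=0)
        assert (b["species_true"] == "rat").all()

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            generate_barnyard(-1, 10)

    def test_zero_separation_chance_recovery(self):
        from embryotrans.demux import demux_batch

        b = generate_barnyard(500, 500, separation=0.0, noise_sd=0.05, seed=3)
        called, _ = demux_batch(b)
        decided = called[called["call"] != "ambiguous"]
        recovery = (decided["call"] == decided["species_true"]).mean()
        assert recovery == pytest.approx(0.5, abs=0.1)


class TestCounts:
    def test_design_validation(self):
        with pytest.raises(ValueError):
            SimDesign(frac_te=1.5)
        with pytest.raises(ValueError):
            SimDesign(dispersion=0.0)
        with pytest.raises(ValueError):
            PlantedEffect("e", ("g",), "CON", "F2", float("inf"))

    def test_unknown_planted_gene_errors(self):
        eff = PlantedEffect("e", ("NotAGene",), "CON", "F2", 1.0)
        with pytest.raises(ValueError, match="unknown genes"):
            generate_counts(SimDesign(n_genes=120, planted_effects=(eff,)))

    def test_ground_truth_covers_every_cell_once(self):
        adata, truth = generate_counts(SimDesign(n_cells_per_group=30, n_genes=120, seed=4))
        assert sorted(truth.cells["cell"]) == sorted(adata.obs_names)
        assert truth.cells["cell"].is_unique

    def test_male_markers_strictly_zero_in_nonmale(self):
        adata, _ = generate_counts(SimDesign(n_cells_per_group=50, n_genes=120, seed=5))
        male_cols = adata.var_names.get_indexer(["Eif2s3y", "Usp9y", "Kdm5d"])
        nonmale = (adata.obs["sex_true"] != "male").to_numpy()
        assert (adata.X[np.ix_(nonmale, male_cols)] == 0).all()

    def test_marker_genes_elevated_in_own_type(self):
        adata, _ = generate_counts(SimDesign(n_cells_per_group=100, n_genes=150, seed=6))
        te = (adata.obs["cell_type_true"] == "TE").to_numpy()
        cdx2 = adata.X[:, adata.var_names.get_loc("Cdx2")]
        pou = adata.X[:, adata.var_names.get_loc("Pou5f1")]
        assert cdx2[te].mean() > cdx2[~te].mean()
        assert pou[~te].mean() > pou[te].mean()

    def test_nb_marginal_calibration(self):
        """Without dropout, empirical moments match NB(mu, theta) at n=10,000."""
        design = SimDesign(
            n_cells_per_group=2500,  # 4 groups -> 10,000 cells
            n_genes=80,
            dropout_rate=0.0,
            dispersion=2.0,
            seed=7,
        )
        adata, _ = generate_counts(design)
        gene = "Gene00000"  # filler gene: no markers, no planted effects
        x = adata.X[:, adata.var_names.get_loc(gene)].astype(float)
        mu_hat = x.mean()
        var_hat = x.var()
        theta = design.dispersion
        expected_var = mu_hat + mu_hat**2 / theta
        assert abs(var_hat - expected_var) / expected_var < 0.1
        # zero fraction matches the NB mass at zero for the fitted mean
        p0 = (theta / (theta + mu_hat)) ** theta
        assert (x == 0).mean() == pytest.approx(p0, abs=0.03)

    def test_planted_fraction_of_males(self):
        adata, _ = generate_counts(
            SimDesign(n_cells_per_group=250, n_genes=100, frac_male=0.3, seed=8)
        )
        n_male = (adata.obs["sex_true"] == "male").sum()
        assert n_male == pytest.approx(300, abs=50)


class TestZStackGeneration:
    def test_truth_sums_match_channels(self):
        stack, truth = generate_zstack(shape=(6, 20, 20), n_nuclei=2, seed=0)
        for name, arr in stack.channels.items():
            assert truth.channel_sums[name] == float(np.asarray(arr).sum())

    def test_nuclei_disjoint(self):
        from skimage import measure

        stack, truth = generate_zstack(shape=(16, 48, 48), n_nuclei=6, seed=1)
        labels = measure.label(stack.channel("nuclei") > 50.0, connectivity=3)
        assert labels.max() == truth.n_nuclei == 6

    def test_impossible_packing_errors(self):
        with pytest.raises(ValueError):
            generate_zstack(shape=(8, 10, 10), n_nuclei=100, seed=2)
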