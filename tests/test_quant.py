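import math

import numpy as np
import pandas as pd
import pytest

from salimet.errors import DegenerateInputError
from salimet.lca import LCAAssignment
from salimet.proteingroups import SampleDesign
from salimet.quant import (
    anova_screen,
    bh_adjust,
    biomass_partition,
    cluster_rows,
    compare_taxa,
    impute_row_mean,
    log2_and_impute,
    mannwhitney,
    pca_scores,
    quantile_normalize,
    taxon_abundance,
)


def asg(gid, taxid, rank, kingdom):
    return LCAAssignment(gid, taxid, rank, kingdom)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_two_columns_map_to_row_sorted_means(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_permuted_column_keeps_ranks_and_shares_sorted_values(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [10.0, 30.0, 20.0]})
        out = quantile_normalize(m)
        assert sorted(out["a"]) == sorted(out["b"])
        assert out["a"].rank().tolist() == m["a"].rank().tolist()
        assert out["b"].rank().tolist() == m["b"].rank().tolist()

    def test_missing_cells_stay_missing(self):
        m = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        assert out["a"].isna().tolist() == [False, True, False]

    def test_all_missing_column_names_the_sample(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "bad": [np.nan, np.nan]})
        with pytest.raises(DegenerateInputError, match="bad"):
            quantile_normalize(m)

    def test_complete_columns_share_sorted_values(self, cohort):
        from salimet.proteingroups import intensity_matrix

        # rows with full detection -> every column is complete
        m = intensity_matrix(cohort.groups, cohort.design).dropna().iloc[:400]
        out = quantile_normalize(m)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for c in out.columns[1:]:
            np.testing.assert_allclose(np.sort(out[c].to_numpy()), ref, atol=1e-9)

    def test_total_of_column_means_preserved(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.lognormal(3, 1, size=(50, 6)))
        out = quantile_normalize(m)
        assert math.isclose(out.mean().sum(), m.mean().sum(), rel_tol=1e-9)


class TestLog2Impute:
    def test_log2_of_observed(self):
        m = pd.DataFrame({"a": [2.0 ** 20]})
        assert log2_and_impute(m)["a"].iloc[0] == 20.0

    def test_missing_gets_floor_constant_when_imputing(self):
        m = pd.DataFrame({"a": [np.nan], "b": [2.0]})
        assert log2_and_impute(m).loc[0, "a"] == 19.0

    def test_missing_stays_missing_without_imputation(self):
        m = pd.DataFrame({"a": [np.nan], "b": [2.0]})
        assert np.isnan(log2_and_impute(m, impute=False).loc[0, "a"])

    def test_non_positive_observed_is_error(self):
        with pytest.raises(DegenerateInputError):
            log2_and_impute(pd.DataFrame({"a": [-1.0]}))


class TestBiomass:
    def test_toy_fractions(self):
        m = pd.DataFrame({"s": [95.0, 3.0, 2.0]}, index=[0, 1, 2])
        a = [asg(0, 9606, "species", "human"), asg(1, 5, "species", "bacteria"),
             asg(2, 6, "species", "other")]
        assert biomass_partition(m, a) == {"human": 0.95, "bacteria": 0.03, "other": 0.02}

    def test_single_kingdom_is_total(self):
        m = pd.DataFrame({"s": [1.0, 2.0]}, index=[0, 1])
        a = [asg(0, 5, "species", "bacteria"), asg(1, 6, "species", "bacteria")]
        assert biomass_partition(m, a) == {"bacteria": 1.0}

    def test_zero_total_is_error(self):
        m = pd.DataFrame({"s": [np.nan]}, index=[0])
        with pytest.raises(DegenerateInputError):
            biomass_partition(m, [asg(0, 5, "species", "bacteria")])


class TestTaxonAbundance:
    def test_two_genera_split(self, tree):
        m = pd.DataFrame({"s": [70.0, 30.0]}, index=[0, 1])
        a = [asg(0, 1304, "species", "bacteria"), asg(1, 28132, "species", "bacteria")]
        ab = taxon_abundance(m, a, tree, "genus")
        assert ab.loc[1301, "s"] == pytest.approx(0.7)  # Streptococcus
        assert ab.loc[838, "s"] == pytest.approx(0.3)   # Prevotella

    def test_family_level_group_excluded_from_genus_matrix(self, tree):
        m = pd.DataFrame({"s": [50.0, 50.0]}, index=[0, 1])
        a = [asg(0, 1304, "species", "bacteria"), asg(1, 1300, "family", "bacteria")]
        ab = taxon_abundance(m, a, tree, "genus")
        assert list(ab.index) == [1301]
        assert ab.loc[1301, "s"] == pytest.approx(1.0)

    def test_top_five_genus_share_recovered(self, tree, cohort):
        """The five most predominant genera carry ~70% of bacterial mass."""
        from salimet.lca import assign_all
        from salimet.proteingroups import intensity_matrix

        a = assign_all(cohort.groups, cohort.taxmap, tree, "second_iteration")
        ab = taxon_abundance(intensity_matrix(cohort.groups, cohort.design), a, tree, "genus")
        # Streptococcus, Prevotella, Veillonella, Rothia, Neisseria
        top5 = [1301, 838, 29465, 32207, 482]
        share = float(ab.mean(axis=1).loc[top5].sum())
        assert abs(share - 0.70) <= 0.05

    def test_columns_sum_to_one(self, tree, cohort):
        from salimet.lca import assign_all
        from salimet.proteingroups import intensity_matrix

        a = assign_all(cohort.groups, cohort.taxmap, tree, "second_iteration")
        m = intensity_matrix(cohort.groups, cohort.design)
        for rank in ("genus", "species"):
            ab = taxon_abundance(m, a, tree, rank)
            np.testing.assert_allclose(ab.sum(axis=0), 1.0, atol=1e-9)


class TestMannWhitneyBH:
    def test_identical_distributions_give_p_one(self):
        u, p = mannwhitney([1.0] * 5, [1.0] * 5)
        assert p == 1.0

    def test_complete_separation_exact_p(self):
        u, p = mannwhitney(np.arange(10.0), np.arange(10.0) + 100)
        assert u == 0.0
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)  # ~1.08e-5

    @pytest.mark.parametrize(
        "p_in,q_out",
        [
            ([0.04], [0.04]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_bh_worked_examples(self, p_in, q_out):
        np.testing.assert_allclose(bh_adjust(p_in), q_out)

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_compare_taxa_invariant_to_relabeling_within_groups(self, two_group_design):
        rng = np.random.default_rng(5)
        ab = pd.DataFrame(
            rng.random((4, 20)), columns=two_group_design.samples
        )
        res1 = compare_taxa(ab, two_group_design, [("caries", "healthy")])
        # permute sample columns within each group
        perm = (
            list(rng.permutation(two_group_design.members("caries")))
            + list(rng.permutation(two_group_design.members("healthy")))
        )
        res2 = compare_taxa(ab[perm], two_group_design, [("caries", "healthy")])
        assert [r.p for r in res1] == [r.p for r in res2]

    def test_compare_taxa_needs_two_samples_per_group(self):
        design = SampleDesign(["a", "b", "c"], {"a": "caries", "b": "healthy", "c": "healthy"})
        ab = pd.DataFrame(np.ones((2, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            compare_taxa(ab, design, [("caries", "healthy")])


@pytest.fixture()
def three_group_design():
    samples = [f"{g}{i}" for g in "pch" for i in range(10)]
    labels = {
        s: {"p": "periodontitis", "c": "caries", "h": "healthy"}[s[0]] for s in samples
    }
    return SampleDesign(samples, labels)


class TestAnova:
    def test_degenerate_protein_skipped(self, three_group_design):
        m = pd.DataFrame(
            [[5.0] * 30, list(np.arange(30.0))],
            columns=three_group_design.samples,
            index=["flat", "ok"],
        )
        res = anova_screen(m, three_group_design)
        assert [r.feature for r in res] == ["ok"]

    def test_insufficient_observations_skipped(self, three_group_design):
        row = [np.nan] * 9 + [1.0] + list(np.arange(20.0))
        m = pd.DataFrame([row], columns=three_group_design.samples, index=["sparse"])
        assert anova_screen(m, three_group_design) == []

    def test_null_type_one_error_near_nominal(self, three_group_design):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(1000, 30)), columns=three_group_design.samples)
        res = anova_screen(m, three_group_design)
        frac = np.mean([r.p < 0.05 for r in res])
        assert 0.03 <= frac <= 0.07


class TestPCA:
    def test_collinear_data_explained_by_one_component(self):
        m = pd.DataFrame([[1.0, 2, 3, 4], [2.0, 4, 6, 8]], index=["x", "y"])
        res = pca_scores(m)
        assert res.explained[0] == pytest.approx(1.0)

    def test_isotropic_noise_spreads_variance(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(200, 10)))
        res = pca_scores(m)
        assert res.explained[0] < 0.25

    def test_constant_matrix_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pca_scores(pd.DataFrame(np.ones((5, 4))))

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.normal(size=(20, 8)))
        res = pca_scores(m)
        for c in res.loadings.columns:
            v = res.loadings[c].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0


class TestClustering:
    def test_identical_rows_merge_first_at_distance_zero(self):
        m = pd.DataFrame([[1.0, 2, 3], [1.0, 2, 3], [9.0, 1, 5]], index=list("aab"))
        res = cluster_rows(m)
        assert res.row_linkage[0, 2] == 0.0
        assert set(res.row_linkage[0, :2]) == {0.0, 1.0}

    def test_constant_offset_rows_coincide_after_centering(self):
        m = pd.DataFrame([[1.0, 2, 3], [11.0, 12, 13], [5.0, 1, 9]])
        res = cluster_rows(m)
        assert res.row_linkage[0, 2] == 0.0

    def test_requires_two_rows(self):
        with pytest.raises(DegenerateInputError):
            cluster_rows(pd.DataFrame([[1.0, 2.0]]))

    def test_row_mean_imputation_is_neutral_after_centering(self):
        m = pd.DataFrame([[1.0, np.nan, 3.0]])
        filled = impute_row_mean(m)
        assert filled.iloc[0, 1] == 2.0
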