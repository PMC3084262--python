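"""Target classification, recruiter-count bins, scaling, derepression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from corecruit import cooccupancy as co
from corecruit.errors import (
    DegenerateRegressorError,
    EmptyGroupError,
    EmptyJoinError,
    InsufficientGenesError,
    UnscalableProfileError,
)
from corecruit.simulate import (
    GeneratorConfig,
    default_gene_map,
    generate_dataset,
    generate_deletion_profile,
    generate_expression,
)


class TestClassify:
    def test_rule_application(self):
        pvals = pd.DataFrame({"TF1": [0.0005, 0.02, np.nan]},
                             index=["t1", "t2", "t3"])
        out = co.classify_targets(["t1", "t2", "t3"], pvals, p_bind=0.001)
        assert list(out["status"]) == ["co-occupied", "not-co-occupied",
                                       "no-data"]
        assert out.loc[0, "cofactors_bound"] == "TF1"
        assert out.loc[1, "cofactors_bound"] == ""

    def test_threshold_limit_everything_with_data_cooccupied(self):
        pvals = pd.DataFrame({"TF1": [0.99, np.nan]}, index=["t1", "t2"])
        out = co.classify_targets(["t1", "t2"], pvals, p_bind=1.0)
        assert list(out["status"]) == ["co-occupied", "no-data"]

    def test_partition_conserved(self, small_dataset):
        _, occ, _ = small_dataset
        targets = list(occ.ratios.index[:100])
        out = co.classify_targets(targets, occ.recruiter_pvalues)
        assert out["status"].value_counts().sum() == len(targets)

    def test_disjoint_tables_rejected(self):
        pvals = pd.DataFrame({"TF1": [0.5]}, index=["x"])
        with pytest.raises(EmptyJoinError):
            co.classify_targets(["y"], pvals)


class TestCountBins:
    def test_mean_increases_with_recruiter_count(self, default_dataset):
        _, occ, _ = default_dataset
        bins = co.bin_by_recruiter_count(
            occ.corepressor_values, occ.pvalues, occ.factors)
        sub = bins[bins["k"] <= 3]
        assert (np.diff(sub["mean_z"]) > 0).all()

    def test_single_member_bin_flagged_with_zero_se(self):
        z = pd.Series([1.0], index=["r1"])
        pvals = pd.DataFrame({"A": [0.0001]}, index=["r1"])
        bins = co.bin_by_recruiter_count(z, pvals, ["A"])
        assert bins.loc[0, "se_z"] == 0.0
        assert bool(bins.loc[0, "single_member"])

    def test_all_unbound_collapse_to_zero_bin(self):
        z = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        pvals = pd.DataFrame({"A": [0.9, 0.8, 0.7]}, index=list("abc"))
        bins = co.bin_by_recruiter_count(z, pvals, ["A"])
        assert len(bins) == 1
        assert bins.loc[0, "k"] == 0 and bins.loc[0, "n_targets"] == 3


class TestRegressOnCount:
    def test_exact_linear_gives_r2_one(self):
        counts = np.arange(10)
        slope, icpt, r2, p = co.regress_on_count(2.0 * counts + 1, counts)
        assert r2 == pytest.approx(1.0)

    def test_hand_computed_five_points(self):
        # x=(0..4), y=(1,2,3,5,4): Sxy=9, Sxx=10, SST=10 -> slope 0.9,
        # R^2 = 81/100
        slope, icpt, r2, _ = co.regress_on_count(
            [1, 2, 3, 5, 4], [0, 1, 2, 3, 4])
        assert slope == pytest.approx(0.9, abs=1e-9)
        assert r2 == pytest.approx(0.81, abs=1e-9)

    def test_permuted_counts_have_no_signal(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 5, 1000)
        z = counts + rng.normal(0, 1, 1000)
        perm = rng.permutation(counts)
        _, _, r2, _ = co.regress_on_count(z, perm)
        assert r2 < 0.02

    def test_constant_counts_rejected(self):
        with pytest.raises(DegenerateRegressorError):
            co.regress_on_count([1.0, 2.0, 3.0], [2, 2, 2])

    def test_bound_target_regression_stronger_than_all_regions(self):
        """Regression of co-repressor Z on true-recruiter counts over its
        own targets beats regression on total factor counts (recruiters
        plus decoys) over all regions."""
        from corecruit.simulate import DEFAULT_WEIGHTS
        recruiters = list(DEFAULT_WEIGHTS)
        decoys = [f"DEC{i:02d}" for i in range(30)]
        cfg = GeneratorConfig(n_regions=6000,
                              factors=recruiters + decoys, seed=15)
        _, occ, truth = generate_dataset(cfg)
        z = occ.corepressor_values
        counts = co.count_bound_recruiters(occ.pvalues, recruiters)
        targets = sorted(truth.planted_target_ids)
        _, _, r2_bound, _ = co.regress_on_count(z.loc[targets],
                                                counts.loc[targets])
        counts_all = co.count_bound_recruiters(occ.pvalues, occ.factors)
        _, _, r2_all, _ = co.regress_on_count(z, counts_all)
        assert r2_bound > r2_all


class TestScaleToReference:
    def test_identical_profiles_unit_factors(self):
        p = pd.Series([1.0, 2.0], index=["a", "b"])
        out = co.scale_to_reference({"wt": p, "d1": p.copy()}, ["a", "b"],
                                    "wt")
        assert np.allclose(out["d1"], p)

    def test_proportional_profile_halved(self):
        ref = pd.Series([1.0, 3.0], index=["a", "b"])
        out = co.scale_to_reference({"wt": ref, "d1": 2 * ref}, ["a", "b"],
                                    "wt")
        assert np.allclose(out["d1"], ref)

    def test_bound_means_equal_after_scaling(self):
        rng = np.random.default_rng(7)
        idx = [f"r{i}" for i in range(100)]
        profs = {k: pd.Series(rng.normal(1, 0.5, 100), index=idx)
                 for k in ["wt", "d1", "d2"]}
        out = co.scale_to_reference(profs, idx[:40], "wt")
        means = [out[k].loc[idx[:40]].mean() for k in out]
        assert np.allclose(means, means[0], atol=1e-9)

    def test_positive_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        idx = [f"r{i}" for i in range(50)]
        wt = pd.Series(rng.normal(1, 0.5, 50), index=idx)
        d1 = pd.Series(rng.normal(1, 0.5, 50), index=idx)
        a = co.scale_to_reference({"wt": wt, "d1": d1}, idx[:20], "wt")
        b = co.scale_to_reference({"wt": wt, "d1": 7.3 * d1}, idx[:20], "wt")
        assert np.allclose(a["d1"], b["d1"])

    def test_zero_mean_profile_rejected(self):
        wt = pd.Series([1.0, 1.0], index=["a", "b"])
        bad = pd.Series([1.0, -1.0], index=["a", "b"])
        with pytest.raises(UnscalableProfileError):
            co.scale_to_reference({"wt": wt, "d1": bad}, ["a", "b"], "wt")


class TestGroupComparison:
    def test_identical_profiles_not_significant(self):
        idx = [f"r{i}" for i in range(20)]
        wt = pd.Series(np.arange(20.0), index=idx)
        out = co.group_comparison(wt, wt.copy(), {"g": idx})
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(9)
        idx = [f"r{i}" for i in range(50)]
        wt = pd.Series(rng.normal(3, 0.5, 50), index=idx)
        out = co.group_comparison(wt, wt - 2.0, {"g": idx})
        assert out.loc[0, "p_value"] < 1e-10

    def test_single_member_group_reports_means_without_test(self):
        wt = pd.Series([1.0], index=["a"])
        out = co.group_comparison(wt, wt * 2, {"g": ["a"]})
        assert out.loc[0, "mean_wt"] == 1.0
        assert np.isnan(out.loc[0, "p_value"])

    def test_fully_redundant_deletion_changes_nothing_significant(self):
        cfg = GeneratorConfig(n_regions=3000, seed=12)
        _, occ, truth = generate_dataset(cfg)
        wt = occ.corepressor_values
        dl = generate_deletion_profile(occ, truth, "NRG1", redundancy=1.0,
                                       seed=77)
        pvals = occ.pvalues["NRG1"]
        bound = list(pvals.index[(pvals < 0.001).fillna(False)])
        scaled = co.scale_to_reference(
            {"wt": wt, "del": dl}, bound, "wt")
        out = co.group_comparison(scaled["wt"], scaled["del"],
                                  {"nrg1_bound": bound})
        pooled_se = np.hypot(out.loc[0, "se_wt"], out.loc[0, "se_del"])
        diff = abs(out.loc[0, "mean_wt"] - out.loc[0, "mean_del"])
        assert diff < 2 * pooled_se


class TestDerepression:
    def test_shifted_bound_group_detected(self):
        rng = np.random.default_rng(10)
        regions = [f"r{i}" for i in range(1100)]
        gm = pd.DataFrame({"gene_id": [f"g{i}" for i in range(1100)],
                           "region_id": regions})
        expr = pd.Series(rng.normal(0, 1, 1100), index=gm["gene_id"])
        expr.iloc[:100] += 1.0
        mb, mu, sb, su, p = co.derepression_test(
            expr, regions[:100], regions[100:], gm)
        assert p < 1e-5
        assert mb > mu

    def test_empty_group_rejected(self):
        gm = pd.DataFrame({"gene_id": ["g1", "g2"],
                           "region_id": ["r1", "r2"]})
        expr = pd.Series([0.1, 0.2], index=["g1", "g2"])
        with pytest.raises(EmptyGroupError):
            co.derepression_test(expr, [], ["r1", "r2"], gm)

    def test_null_split_not_significant(self):
        rng = np.random.default_rng(11)
        regions = [f"r{i}" for i in range(2000)]
        gm = pd.DataFrame({"gene_id": [f"g{i}" for i in range(2000)],
                           "region_id": regions})
        expr = pd.Series(rng.normal(0, 1, 2000), index=gm["gene_id"])
        mb, mu, sb, su, p = co.derepression_test(
            expr, regions[:1000], regions[1000:], gm)
        assert abs(mb - mu) < 3 * np.hypot(sb, su)

    def test_bound_regions_derepressed_in_synthetic_run(self):
        cfg = GeneratorConfig(n_regions=3000, seed=13)
        regions, occ, truth = generate_dataset(cfg)
        gm = default_gene_map(regions)
        expr = generate_expression(occ, truth, gm, seed=13)
        p_tup1 = occ.pvalues[occ.corepressor]
        bound = list(p_tup1.index[p_tup1 < 0.001])
        unbound = list(p_tup1.index[p_tup1 > 0.05])
        mb, mu, *_, p = co.derepression_test(expr, bound, unbound, gm)
        assert mb > mu and p < 1e-4


class TestDecileBinning:
    def test_perfectly_coupled_bins_increase(self):
        regions = [f"r{i}" for i in range(20)]
        gm = pd.DataFrame({"gene_id": [f"g{i}" for i in range(20)],
                           "region_id": regions})
        z = pd.Series(np.arange(20.0), index=regions)
        expr = pd.Series(np.arange(20.0), index=gm["gene_id"])
        out = co.decile_binning(expr, z, gm, n_bins=10)
        assert (np.diff(out["mean_chip_z"]) > 0).all()

    def test_one_gene_per_bin_in_expression_order(self):
        regions = [f"r{i}" for i in range(10)]
        gm = pd.DataFrame({"gene_id": [f"g{i}" for i in range(10)],
                           "region_id": regions})
        z = pd.Series([5, 1, 4, 0, 9, 2, 8, 3, 7, 6.0], index=regions)
        expr = pd.Series([5, 1, 4, 0, 9, 2, 8, 3, 7, 6.0],
                         index=gm["gene_id"])
        out = co.decile_binning(expr, z, gm, n_bins=10)
        assert list(out["mean_chip_z"]) == sorted(z)

    def test_independent_expression_gives_flat_bins(self):
        rng = np.random.default_rng(14)
        regions = [f"r{i}" for i in range(5000)]
        gm = pd.DataFrame({"gene_id": [f"g{i}" for i in range(5000)],
                           "region_id": regions})
        z = pd.Series(rng.normal(0, 1, 5000), index=regions)
        expr = pd.Series(rng.normal(0, 1, 5000), index=gm["gene_id"])
        out = co.decile_binning(expr, z, gm, n_bins=10)
        se = 1.0 / np.sqrt(500)
        assert out["mean_chip_z"].max() - out["mean_chip_z"].min() < 4 * se

    def test_fewer_genes_than_bins_rejected(self):
        gm = pd.DataFrame({"gene_id": ["g1"], "region_id": ["r1"]})
        z = pd.Series([1.0], index=["r1"])
        expr = pd.Series([1.0], index=["g1"])
        with pytest.raises(InsufficientGenesError):
            co.decile_binning(expr, z, gm, n_bins=10)
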