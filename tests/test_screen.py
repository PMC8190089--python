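"""Count-based screening: normalisation, NB test, screen, clusters, overlap."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from heatmem import (CountMatrix, DEResult, bh_adjust,
                     call_fold_change_regions, cluster_profiles,
                     cpm_normalize, default_screen_design,
                     estimate_common_dispersion, gen_count_matrix,
                     hypergeom_overlap, nb_lrt, screen_memory_genes)
from heatmem.screen import read_bed


def two_group_matrix(wt, mut, libsize=1e6):
    """1-gene CountMatrix: WT and mutant replicate counts at t=4 h."""
    samples = [f"WT_r{i}" for i in range(len(wt))] + \
        [f"jmjq_r{i}" for i in range(len(mut))]
    counts = pd.DataFrame([list(wt) + list(mut)], index=["g1"],
                          columns=samples)
    design = pd.DataFrame({
        "genotype": ["WT"] * len(wt) + ["jmjq"] * len(mut),
        "time_h": 4, "replicate": list(range(len(wt))) + list(range(len(mut))),
    }, index=samples)
    libs = pd.Series(libsize, index=samples)
    return CountMatrix(counts, design, lib_sizes=libs)


class TestCpm:
    def test_definition(self):
        cm = two_group_matrix([5, 5], [5, 5], libsize=1e6)
        assert np.all(cpm_normalize(cm).to_numpy() == 5.0)

    def test_all_zero_gene(self):
        cm = two_group_matrix([0, 0], [0, 0])
        assert np.all(cpm_normalize(cm).to_numpy() == 0.0)

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s1": [10, 90], "s2": [20, 180]},
                              index=["g1", "g2"])
        out = cpm_normalize(counts)
        np.testing.assert_allclose(out["s1"], out["s2"])

    def test_zero_libsize_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            cpm_normalize(counts, lib_sizes=pd.Series({"s1": 0.0}))


class TestDispersion:
    def test_poisson_counts_near_zero(self):
        cm, _ = gen_count_matrix(n_genes=2000, n_memory=0, dispersion=0.0,
                                 design=default_screen_design(4), seed=1)
        assert estimate_common_dispersion(cm) <= 0.01

    def test_nb_dispersion_recovered(self):
        cm, _ = gen_count_matrix(n_genes=2000, n_memory=0, dispersion=0.1,
                                 design=default_screen_design(4), seed=2)
        assert 0.05 <= estimate_common_dispersion(cm) <= 0.2

    def test_constant_counts_clip_to_zero(self):
        cm = two_group_matrix([7, 7, 7], [7, 7, 7])
        assert estimate_common_dispersion(cm) == 0.0

    def test_unreplicated_design_rejected(self):
        cm = two_group_matrix([7], [9])
        with pytest.raises(ValueError, match="replicated"):
            estimate_common_dispersion(cm)


class TestNbLrt:
    def test_poisson_limit_closed_form(self):
        """dispersion 0, {10,10} vs {20,20}, equal libsizes: the statistic is
        the closed-form Poisson LRT (~6.80, p ~ 0.0091)."""
        from scipy.stats import chi2
        cm = two_group_matrix([10, 10], [20, 20])
        res = nb_lrt(cm, 4, dispersion=0.0)
        closed = 2 * (20 * np.log(10 / 15) + 40 * np.log(20 / 15))
        assert res.table["stat"].iloc[0] == pytest.approx(closed, abs=1e-9)
        assert res.table["stat"].iloc[0] == pytest.approx(6.80, abs=0.01)
        assert res.table["pvalue"].iloc[0] == pytest.approx(
            chi2.sf(closed, 1), abs=1e-12)

    def test_identical_groups_null(self):
        cm = two_group_matrix([15, 15], [15, 15])
        res = nb_lrt(cm, 4, dispersion=0.1)
        assert res.table["stat"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert res.table["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_label_swap_flips_log2fc(self):
        cm1 = two_group_matrix([10, 10], [20, 20])
        cm2 = two_group_matrix([20, 20], [10, 10])
        r1 = nb_lrt(cm1, 4, dispersion=0.05)
        r2 = nb_lrt(cm2, 4, dispersion=0.05)
        assert r1.table["log2fc"].iloc[0] == pytest.approx(
            -r2.table["log2fc"].iloc[0])
        assert r1.table["pvalue"].iloc[0] == pytest.approx(
            r2.table["pvalue"].iloc[0], rel=1e-9)

    def test_nb_statistic_below_poisson(self):
        """Extra-Poisson variance discounts the same count difference."""
        cm = two_group_matrix([10, 10], [20, 20])
        s0 = nb_lrt(cm, 4, dispersion=0.0).table["stat"].iloc[0]
        s1 = nb_lrt(cm, 4, dispersion=0.2).table["stat"].iloc[0]
        assert s1 < s0

    def test_negative_dispersion_rejected(self):
        cm = two_group_matrix([10, 10], [20, 20])
        with pytest.raises(ValueError):
            nb_lrt(cm, 4, dispersion=-0.1)


class TestBhAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_order_preserving(self, ps):
        q = bh_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)


def de_from_q(qs, lfcs=None):
    genes = [f"g{i}" for i in range(len(qs))]
    lfcs = lfcs if lfcs is not None else np.ones(len(qs))
    table = pd.DataFrame({"log2fc": lfcs, "stat": 1.0,
                          "pvalue": np.asarray(qs) / 2, "qvalue": qs},
                         index=genes)
    return DEResult(table=table, contrast_time=0)


class TestScreen:
    @pytest.mark.parametrize("qs, selected", [
        ((0.5, 0.01, 0.2), True),    # flat at 0 h, hit at 4 h
        ((0.01, 0.001, 0.001), False),  # already different at 0 h
        ((0.5, 0.2, 0.3), False),    # never different
    ])
    def test_selection_criterion(self, qs, selected):
        res = screen_memory_genes(de_from_q([qs[0]]), de_from_q([qs[1]]),
                                  de_from_q([qs[2]]))
        assert (len(res.genes) == 1) is selected

    def test_direction_from_earliest_qualifying_time(self):
        de0 = de_from_q([0.5])
        de4 = de_from_q([0.01], lfcs=[-2.0])
        de24 = de_from_q([0.01], lfcs=[+2.0])
        res = screen_memory_genes(de0, de4, de24)
        assert res.table["direction"].iloc[0] == "down"
        assert res.table["qualifying_times"].iloc[0] == (4, 24)

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universes"):
            screen_memory_genes(de_from_q([0.5, 0.5]), de_from_q([0.5]),
                                de_from_q([0.5]))


class TestClusterProfiles:
    def _planted(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        a = np.array([0.0, 0.1, 3.0, 0.0, 0.1, 3.1])
        b = np.array([2.0, 0.0, 0.0, 2.1, 0.0, 0.0])
        rows = [a + rng.normal(0, 0.05, 6) for _ in range(n // 2)] + \
               [b + rng.normal(0, 0.05, 6) for _ in range(n // 2)]
        labels = [0] * (n // 2) + [1] * (n // 2)
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(n)]), labels

    def test_recovers_planted_groups(self):
        expr, truth = self._planted()
        assign = cluster_profiles(expr, k=2, seed=1)
        assert adjusted_rand_score(truth, assign.to_numpy()) == 1.0

    def test_duplicated_rows_same_cluster(self):
        expr, _ = self._planted()
        expr2 = pd.concat([expr, expr.iloc[[0]].rename(index={"g0": "dup"})])
        assign = cluster_profiles(expr2, k=2, seed=1)
        assert assign["dup"] == assign["g0"]

    def test_deterministic_given_seed(self):
        expr, _ = self._planted()
        a1 = cluster_profiles(expr, k=2, seed=7)
        a2 = cluster_profiles(expr, k=2, seed=7)
        pd.testing.assert_series_equal(a1, a2)

    def test_constant_rows_dropped_with_warning(self):
        expr, _ = self._planted()
        expr.loc["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            assign = cluster_profiles(expr, k=2, seed=0)
        assert "flat" not in assign.index

    def test_k_larger_than_genes_rejected(self):
        expr, _ = self._planted(n=4)
        with pytest.raises(ValueError):
            cluster_profiles(expr, k=10, seed=0)


def hypergeom_enumeration(n_A, n_B, n_overlap, n_universe):
    """Brute-force upper tail by counting draws (independent oracle)."""
    total = comb(n_universe, n_A)
    hits = sum(comb(n_B, k) * comb(n_universe - n_B, n_A - k)
               for k in range(n_overlap, min(n_A, n_B) + 1))
    return hits / total


class TestHypergeomOverlap:
    def test_worked_example(self):
        assert hypergeom_overlap(4, 5, 3, 10) == pytest.approx(55 / 210)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_overlap(4, 5, 0, 10) == 1.0

    def test_forced_total_overlap(self):
        assert hypergeom_overlap(6, 6, 6, 6) == pytest.approx(1.0)

    def test_matches_enumeration_small_universes(self):
        for M in range(1, 13):
            for nA in range(0, M + 1):
                for nB in range(0, M + 1):
                    k_min = max(0, nA + nB - M)
                    for k in range(k_min, min(nA, nB) + 1):
                        assert hypergeom_overlap(nA, nB, k, M) == \
                            pytest.approx(hypergeom_enumeration(nA, nB, k, M),
                                          rel=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(4, 5, 6, 10)
        with pytest.raises(ValueError):
            hypergeom_overlap(11, 5, 2, 10)


class TestFoldChangeRegions:
    def test_toy_triple(self):
        res = call_fold_change_regions([100, 100, 150], [160, 100, 100],
                                       1e6, 1e6)
        assert list(res.table["call"]) == ["hyper", "none", "hypo"]
        assert res.table["ratio"].iloc[0] == pytest.approx(160.5 / 100.5)
        assert res.table["ratio"].iloc[2] == pytest.approx(100.5 / 150.5)

    def test_bed_regions_and_errors(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t0\t100\tgeneA\nchr1\t200\t300\tgeneB\n")
        res = call_fold_change_regions([10, 10], [10, 10], 1e6, 1e6,
                                       bed_path=bed)
        assert list(res.table.index) == ["geneA", "geneB"]
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t0\t100\tok\nchr1\t300\t200\tbroken\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(bad)

    def test_zero_libsize_rejected(self):
        with pytest.raises(ValueError):
            call_fold_change_regions([1], [1], 0.0, 1e6)


class TestPlantedScreenRecovery:
    def test_screen_then_overlap_composition(self):
        """Screen + hypermethylation overlap: a planted coupling between
        down-genes and hyper regions is detected, and the overlap p-value
        falls as the universe grows (fixed overlap counts)."""
        p_small = hypergeom_overlap(80, 100, 44, 1000)
        p_large = hypergeom_overlap(80, 100, 44, 5000)
        assert p_large < p_small < 1e-6
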