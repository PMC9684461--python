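"""Kis scoring, classification, binning and buffering tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kisflux import gro, kis, simulate
from kisflux.simulate import ConditionSpec, MeasurementConfig


def noiseless_kinetics(truth, cond_name, beta=1.0):
    cond = ConditionSpec.from_name(cond_name, beta=beta)
    profile = simulate.apply_condition(truth, cond)
    sample = simulate.simulate_gro(profile, MeasurementConfig(1, 0.0, 1.0, 0))
    return gro.build_kinetics_table(sample, cond_name)


class TestComputeKisValues:
    def test_sum_of_the_two_ratios(self, toy_kinetics):
        wt, mut = toy_kinetics
        table = kis.compute_kis_values(wt, mut).set_index("gene_id")
        # g1: HL doubles and TR halves -> 2 + 2 = 4
        assert table.loc["g1", "kis_value"] == pytest.approx(4.0)
        # g2: untouched -> 1 + 1 = 2
        assert table.loc["g2", "kis_value"] == pytest.approx(2.0)

    def test_wt_vs_itself_scores_two(self, toy_kinetics):
        wt, _ = toy_kinetics
        table = kis.compute_kis_values(wt, wt)
        np.testing.assert_allclose(table["kis_value"], 2.0)

    def test_headline_noiseless_median_is_five(self, headline_truth):
        """With perfect buffering both terms equal the true fold-change r,
        so the median Kis value is 2 * median(r) = 5; the brute-force
        oracle recomputes it from the generator's ground truth."""
        wt = noiseless_kinetics(headline_truth, "WT")
        mut = noiseless_kinetics(headline_truth, "dNLS12")
        table = kis.compute_kis_values(wt, mut)
        f = simulate.kis_fraction(headline_truth).to_numpy()
        oracle = np.median(2.0 / (1.0 - f))  # 2r per gene
        assert table["kis_value"].median() == pytest.approx(oracle, rel=1e-12)

    def test_genes_missing_in_either_table_dropped(self, toy_kinetics):
        wt, mut = toy_kinetics
        table = kis.compute_kis_values(wt, mut.iloc[:2])
        assert set(table["gene_id"]) == {"g1", "g2"}

    def test_undefined_hl_excluded(self, toy_kinetics):
        wt, mut = toy_kinetics
        mut = mut.copy()
        mut.loc[0, "HL"] = np.nan
        table = kis.compute_kis_values(wt, mut)
        assert "g1" not in set(table["gene_id"])


class TestClassifyKis:
    def test_boundary_is_inclusive(self):
        table = pd.DataFrame(
            {"gene_id": ["a", "b"], "hl_ratio": [2.0, 3.0], "tr_ratio_inv": [2.0, 1.9]}
        )
        table["kis_value"] = table["hl_ratio"] + table["tr_ratio_inv"]
        cls = kis.classify_kis(table)
        assert cls.kis_genes == {"a"}  # both exactly 2-fold counts; b fails TR
        assert cls.hl_affected == {"a", "b"}

    def test_perfect_buffering_sets_coincide(self, headline_truth):
        wt = noiseless_kinetics(headline_truth, "WT")
        mut = noiseless_kinetics(headline_truth, "dNLS12")
        cls = kis.classify_kis(kis.compute_kis_values(wt, mut))
        assert cls.hl_affected == cls.tr_affected == cls.kis_genes
        # both criteria reduce to r >= 2 against the generator truth
        f = simulate.kis_fraction(headline_truth)
        r = 1.0 / (1.0 - f)
        assert len(cls.kis_genes) == int((r >= 2.0 - 1e-12).sum())

    def test_threshold_must_exceed_one(self):
        table = pd.DataFrame(
            {"gene_id": ["a"], "hl_ratio": [2.0], "tr_ratio_inv": [2.0], "kis_value": [4.0]}
        )
        with pytest.raises(ValueError):
            kis.classify_kis(table, threshold=1.0)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        """Scaling both strains' units by any constant leaves the
        classification unchanged (ratios cancel units)."""
        wt = pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"], "TR": [10.0, 4.0, 2.0],
             "RA": [10.0, 8.0, 2.0], "HL": [1.0, 2.0, 1.0]}
        )
        mut = pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"], "TR": [5.0, 4.0, 1.0],
             "RA": [10.0, 8.0, 3.0], "HL": [2.0, 2.0, 3.0]}
        )
        base = kis.classify_kis(kis.compute_kis_values(wt, mut))
        wt2 = wt.assign(TR=wt["TR"] * scale, RA=wt["RA"] * scale, HL=wt["HL"])
        mut2 = mut.assign(TR=mut["TR"] * scale, RA=mut["RA"] * scale, HL=mut["HL"])
        scaled = kis.classify_kis(kis.compute_kis_values(wt2, mut2))
        assert base.kis_genes == scaled.kis_genes


class TestOverlapSignificance:
    def test_identical_sets_closed_form(self):
        # A == B, |A| = 5, N = 10: P(full overlap) = 1/C(10,5)
        a = set(range(5))
        p = kis.overlap_significance(a, a, 10)
        assert p == pytest.approx(1.0 / math.comb(10, 5), rel=1e-12)

    def test_zero_overlap_is_certain(self):
        assert kis.overlap_significance({1, 2}, {3, 4}, 10) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        """Small universes: compare against enumerating every possible
        draw of B from the universe."""
        rng = np.random.default_rng(seed)
        n = 10
        universe = list(range(n))
        a = set(rng.choice(universe, size=4, replace=False).tolist())
        b = set(rng.choice(universe, size=5, replace=False).tolist())
        k = len(a & b)
        hits = sum(
            1 for draw in itertools.combinations(universe, len(b))
            if len(a & set(draw)) >= k
        )
        oracle = hits / math.comb(n, len(b))
        assert kis.overlap_significance(a, b, n) == pytest.approx(oracle, rel=1e-12)

    def test_rejects_oversized_sets(self):
        with pytest.raises(ValueError):
            kis.overlap_significance(set(range(5)), set(), 3)


class TestAssignBins:
    @staticmethod
    def table(values, ids=None):
        ids = ids or [f"g{i:02d}" for i in range(len(values))]
        return pd.DataFrame({"gene_id": ids, "hl_ratio": 1.0, "tr_ratio_inv": 1.0,
                             "kis_value": values})

    def test_rank_partition(self):
        out = kis.assign_bins(self.table(list(range(1, 13))), 6)
        assert out.groupby("bin").size().tolist() == [2] * 6
        bin1 = set(out[out["bin"] == 1]["kis_value"])
        assert bin1 == {12, 11}  # bin 1 holds the highest Kis values

    def test_single_bin(self):
        out = kis.assign_bins(self.table([3.0, 1.0]), 1)
        assert (out["bin"] == 1).all()

    def test_remainder_rule_100_genes_6_bins(self):
        out = kis.assign_bins(self.table(list(np.linspace(0, 5, 100))), 6)
        assert out.groupby("bin").size().tolist() == [17, 17, 17, 17, 16, 16]

    def test_concatenating_bins_reproduces_sorted_order(self, rng):
        values = rng.lognormal(size=57)
        out = kis.assign_bins(self.table(list(values)), 7)
        resorted = out.sort_values("bin", kind="stable")
        assert (resorted["kis_value"].to_numpy() == np.sort(values)[::-1]).all()

    def test_permutation_invariance_with_ties(self):
        """Shuffling input rows never changes any gene's bin; ties are
        broken by gene_id."""
        tbl = self.table([2.0, 3.0, 2.0, 3.0, 1.0, 1.0])
        a = kis.assign_bins(tbl, 3).set_index("gene_id")["bin"]
        b = kis.assign_bins(tbl.sample(frac=1, random_state=5), 3).set_index("gene_id")["bin"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_lowest_first_flag(self):
        out = kis.assign_bins(self.table([1.0, 2.0, 3.0, 4.0]), 2, highest_first=False)
        assert set(out[out["bin"] == 1]["kis_value"]) == {1.0, 2.0}

    def test_invalid_bin_count(self):
        with pytest.raises(ValueError):
            kis.assign_bins(self.table([1.0, 2.0]), 3)


class TestBinSummary:
    def test_single_bin_median(self):
        out = kis.bin_summary(np.log2([1.0, 2.0, 4.0]), [1, 1, 1])
        assert out["median"].iloc[0] == pytest.approx(1.0)
        assert out["n_genes"].iloc[0] == 3

    def test_headline_bins_grade_monotonically(self, headline_truth):
        """Ranked by Kis value, per-bin median log2 HL ratios must fall
        strictly from bin 1 (most import-sensitive) to bin 6."""
        wt = noiseless_kinetics(headline_truth, "WT")
        mut = noiseless_kinetics(headline_truth, "dNLS12")
        table = kis.assign_bins(kis.compute_kis_values(wt, mut), 6)
        summary = kis.bin_summary(np.log2(table["hl_ratio"]), table["bin"])
        med = summary.sort_values("bin")["median"].to_numpy()
        assert (np.diff(med) < 0).all()

    def test_xrn1_null_bins_are_near_uniform(self, headline_truth):
        """Deleting the nuclease stabilizes all bins alike: the spread of
        per-bin medians stays under 0.5 log2 units."""
        wt = noiseless_kinetics(headline_truth, "WT")
        kis_mut = noiseless_kinetics(headline_truth, "dNLS12")
        xrn1 = noiseless_kinetics(headline_truth, "dXRN1")
        binned = kis.assign_bins(kis.compute_kis_values(wt, kis_mut), 6)
        xtable = kis.compute_kis_values(wt, xrn1).set_index("gene_id")
        aligned = xtable.loc[binned["gene_id"], "hl_ratio"].to_numpy()
        summary = kis.bin_summary(np.log2(aligned), binned["bin"].to_numpy())
        med = summary["median"].to_numpy()
        assert med.max() - med.min() < 0.5
        assert (med > 0).all()  # every bin stabilized


class TestBufferingTest:
    def test_identical_vectors(self, rng):
        ra = rng.lognormal(size=100)
        res = kis.buffering_test(ra, ra)
        assert res.median_wt == res.median_mut
        assert res.pvalue == pytest.approx(1.0)

    def test_perfect_buffering_identical_abundance(self, headline_truth):
        wt = noiseless_kinetics(headline_truth, "WT")
        mut = noiseless_kinetics(headline_truth, "dNLS12")
        np.testing.assert_allclose(wt["RA"], mut["RA"])

    def test_broken_buffering_detected(self):
        """beta=0: stabilization without transcriptional compensation
        raises mutant abundance, and the rank-sum test sees it."""
        truth = simulate.generate_truth(5000, "headline", seed=31)
        wt = noiseless_kinetics(truth, "WT", beta=1.0)
        mut = noiseless_kinetics(truth, "dNLS12", beta=0.0)
        res = kis.buffering_test(wt["RA"], mut["RA"])
        assert res.median_mut > res.median_wt
        assert res.pvalue < 0.01

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            kis.buffering_test([], [1.0])


class TestCorrelateLogRatios:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert kis.correlate_log_ratios(x, x) == pytest.approx(1.0)
        assert kis.correlate_log_ratios(x, 1.0 / x) == pytest.approx(-1.0)

    def test_matches_textbook_covariance_formula(self, rng):
        x = rng.lognormal(size=300)
        y = x ** 0.7 * rng.lognormal(sigma=0.3, size=300)
        lx, ly = np.log2(x), np.log2(y)
        oracle = np.mean((lx - lx.mean()) * (ly - ly.mean())) / (lx.std() * ly.std())
        assert kis.correlate_log_ratios(x, y) == pytest.approx(oracle, rel=1e-9)

    def test_noisy_headline_hl_tr_coupling(self):
        """Buffering couples the two fold-changes: with moderate noise the
        log HL-ratio vs log inverse-TR-ratio correlation stays above 0.5."""
        truth = simulate.generate_truth(3000, "headline", seed=41)
        cond = ConditionSpec.from_name("dNLS12")
        wt_p = simulate.apply_condition(truth, ConditionSpec.from_name("WT"))
        mut_p = simulate.apply_condition(truth, cond)
        wt = gro.build_kinetics_table(
            simulate.simulate_gro(wt_p, MeasurementConfig(3, 0.3, 1.0, 42)), "WT"
        )
        mut = gro.build_kinetics_table(
            simulate.simulate_gro(mut_p, MeasurementConfig(3, 0.3, 1.0, 43)), "dNLS12"
        )
        table = kis.compute_kis_values(wt, mut)
        r = kis.correlate_log_ratios(table["hl_ratio"], table["tr_ratio_inv"])
        assert r > 0.5
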