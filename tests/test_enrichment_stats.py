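"""The statistical battery: contingency, goodness-of-fit, rank tests, SMA."""

import itertools

import numpy as np
import pytest

import poiarray as pa
from poiarray.enrichment_stats import (
    chisq_gof, chromosome_table, contingency_test, direction_bias,
    mannwhitney_shift, sma_fit, spearman_corr,
)


class TestContingency:
    @pytest.mark.parametrize("table,odds,p", [
        ((161, 1103, 205, 1002), 0.71, 0.0032),   # all genes
        ((38, 308, 141, 722), 0.63, 0.0196),      # excl. tissue-specific
        ((10, 126, 57, 265), 0.37, 0.0036),       # active-chromatin subset
    ])
    def test_printed_direction_tables(self, table, odds, p):
        rep = contingency_test(*table)
        assert rep.statistic["odds_ratio"] == pytest.approx(odds, abs=0.005)
        assert rep.p == pytest.approx(p, abs=5e-5)

    def test_degenerate_row_gives_undefined_or(self):
        rep = contingency_test(80, 495, 0, 10)
        assert rep.statistic["odds_ratio"] is None
        assert rep.p == pytest.approx(0.372, abs=5e-4)

    def test_balanced_table(self):
        rep = contingency_test(5, 5, 5, 5)
        assert rep.statistic["odds_ratio"] == pytest.approx(1.0)
        assert rep.p == pytest.approx(1.0)

    def test_or_invariant_to_double_swap_and_p_to_transpose(self):
        a, b, c, d = 12, 30, 7, 51
        r1 = contingency_test(a, b, c, d)
        r2 = contingency_test(d, c, b, a)   # both rows and both columns
        assert r1.statistic["odds_ratio"] == pytest.approx(
            r2.statistic["odds_ratio"])
        r3 = contingency_test(a, c, b, d)   # transpose
        assert r1.p == pytest.approx(r3.p)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            contingency_test(-1, 2, 3, 4)


class TestChisqGof:
    def test_perfect_fit(self):
        rep = chisq_gof([50, 50], [0.5, 0.5])
        assert rep.statistic["chi2"] == 0.0 and rep.p == pytest.approx(1.0)

    def test_x_deficit_two_category(self):
        # 366 X-linked of 2480 mapped DE genes vs the 16.8% array share
        rep = chisq_gof([366, 2114], [0.16801, 0.83199])
        assert rep.statistic["chi2"] == pytest.approx(7.41, abs=0.02)
        assert rep.p == pytest.approx(0.0065, abs=2e-4)

    def test_sixty_forty(self):
        rep = chisq_gof([60, 40], [0.5, 0.5])
        assert rep.statistic["chi2"] == pytest.approx(4.0)
        assert rep.p == pytest.approx(0.0455, abs=1e-4)

    def test_yates_correction_reduces_statistic(self):
        plain = chisq_gof([60, 40], [0.5, 0.5])
        corrected = chisq_gof([60, 40], [0.5, 0.5], yates=True)
        assert corrected.statistic["chi2"] < plain.statistic["chi2"]

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            chisq_gof([10, 10], [0.6, 0.6])


class TestMannWhitney:
    def test_brute_force_oracle_small_instance(self):
        """Exact two-sided p for {1,2,3} vs {4,5,6} by enumerating all 20
        rank assignments."""
        group, rest = [1, 2, 3], [4, 5, 6]
        pooled = group + rest

        def u_stat(g):
            return sum(1 for a in g for b in pooled if b not in g and a > b)

        observed = u_stat(group)
        us = [u_stat(list(c)) for c in itertools.combinations(pooled, 3)]
        mean_u = np.mean(us)
        extreme = sum(1 for u in us if abs(u - mean_u) >= abs(observed - mean_u))
        p_exact = extreme / len(us)
        rep = mannwhitney_shift(group, rest)
        assert rep.statistic["U"] == 0.0
        assert rep.p == pytest.approx(p_exact)
        assert p_exact == pytest.approx(0.1)

    def test_identical_groups_zero_shift(self):
        rep = mannwhitney_shift([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.statistic["median_difference"] == 0.0

    def test_constant_offset_reported(self):
        rest = np.linspace(0, 1, 30)
        rep = mannwhitney_shift(rest + 0.25, rest)
        assert rep.statistic["median_difference"] == pytest.approx(0.25)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mannwhitney_shift([], [1.0])


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        assert spearman_corr(x, x ** 3).statistic["rho"] == pytest.approx(1.0)
        assert spearman_corr(x, -x).statistic["rho"] == pytest.approx(-1.0)

    def test_hand_computed_ranks(self):
        rep = spearman_corr([1, 2, 3, 4], [2, 1, 4, 3])
        assert rep.statistic["rho"] == pytest.approx(0.6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSma:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        rep = sma_fit(x, 2 * x)
        assert rep.statistic["slope"] == pytest.approx(2.0)
        assert rep.statistic["intercept"] == pytest.approx(0.0)

    def test_worked_example(self):
        rep = sma_fit([0.0, 1.0, 2.0], [1.0, 3.0, 4.0])
        assert rep.statistic["slope"] == pytest.approx(1.5275, abs=5e-5)

    def test_geometric_mean_identity(self):
        """|SMA slope| equals the geometric mean of the y-on-x slope and
        the inverse of the x-on-y slope."""
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2, 200)
        y = 1.4 * x + rng.normal(0, 1, 200)
        rep = sma_fit(x, y)
        b_yx = np.polyfit(x, y, 1)[0]
        b_xy = np.polyfit(y, x, 1)[0]
        assert abs(rep.statistic["slope"]) == pytest.approx(
            np.sqrt(b_yx / b_xy))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            sma_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestChromosomeTable:
    @staticmethod
    def _annotation(counts):
        genes, arms = [], []
        for arm, k in counts.items():
            for i in range(k):
                genes.append(f"{arm}_{i}")
                arms.append(arm)
        import pandas as pd
        return pd.DataFrame({"gene_id": genes, "arm": arms})

    def test_mapped_only_percentages(self):
        # the printed all-spots row: X share of mapped = 16.8%
        counts = {"X": 2719, "2L": 2992, "2R": 3225, "3L": 3235,
                  "3R": 3915, "4": 98, "Other": 514}
        ann = self._annotation(counts)
        table, _ = chromosome_table(ann["gene_id"], ann["gene_id"], ann)
        row = table.set_index("arm")
        assert row.loc["X", "pct_all_mapped"] == pytest.approx(16.8, abs=0.05)
        mapped = table[table["arm"] != "Other"]
        assert mapped["pct_all_mapped"].sum() == pytest.approx(100.0, abs=0.1)

    def test_de_equals_background_flags_nothing(self):
        counts = {"X": 170, "2L": 180, "2R": 200, "3L": 200, "3R": 230,
                  "4": 6, "Other": 30}
        ann = self._annotation(counts)
        table, reports = chromosome_table(ann["gene_id"], ann["gene_id"], ann)
        assert not table["flagged"].any()
        for rep in reports:
            assert rep.statistic["chi2"] == pytest.approx(0.0)

    def test_empty_de_set(self):
        ann = self._annotation({"X": 5, "2L": 5})
        table, reports = chromosome_table([], ann["gene_id"], ann)
        assert table["n_de"].sum() == 0 and reports == []


class TestDirectionBias:
    @staticmethod
    def _results(fcs, qs):
        import pandas as pd
        return pd.DataFrame({
            "log2fc": fcs, "q": qs,
            "testable": [True] * len(fcs),
        })

    def test_ten_of_ten_down(self):
        res = self._results([0.5] * 10 + [0.1] * 10,
                            [0.01] * 10 + [0.5] * 10)
        rep = direction_bias(res, [True] * 10 + [False] * 10)
        assert rep.statistic["k_down"] == 10
        assert rep.p == pytest.approx(2 * 0.5 ** 10)

    def test_five_of_ten_down(self):
        fcs = [0.5] * 5 + [-0.5] * 5
        res = self._results(fcs, [0.01] * 10)
        rep = direction_bias(res, [True] * 10)
        assert rep.p == pytest.approx(1.0)

    def test_absent_class_reports_na(self):
        res = self._results([0.5, -0.5], [0.01, 0.01])
        rep = direction_bias(res, [False, False])
        assert rep.p is None and "NA" in rep.notes


def test_planted_direction_bias_recovered(default_run):
    """Significant testis-class genes are overwhelmingly downregulated in
    the paternal-X genotype, and the class-vs-rest Fisher test is
    decisive."""
    contrast = default_run["contrast"]
    truth = default_run["truth"]
    member = (truth.tissue_class.reindex(contrast.index) == "testis")
    rep = direction_bias(contrast, member.to_numpy())
    assert rep.statistic["frac_down"] > 0.90
    assert rep.statistic["fisher_p"] < 1e-4
    mid = (truth.tissue_class.reindex(contrast.index) == "midgut")
    rep_mid = direction_bias(contrast, mid.to_numpy())
    assert rep_mid.statistic["frac_down"] < 0.10  # midgut genes go up
    assert rep_mid.statistic["fisher_p"] < 1e-4
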