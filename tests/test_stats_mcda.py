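"""ANOVA, Tukey HSD, Wilcoxon signed-rank, Bonferroni and TOPSIS."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from kapurseg.benchmarks import (ANOVA_DF_BETWEEN, ANOVA_DF_WITHIN,
                                 ANOVA_SS_BETWEEN, ANOVA_SS_WITHIN,
                                 benchmark_decision_matrix)
from kapurseg.stats_mcda import (DecisionMatrix, bonferroni, one_way_anova,
                                 topsis, tukey_hsd, wilcoxon_signed_rank)


def wilcoxon_exact_reference(x, y):
    """Brute-force two-sided p over all 2^n sign assignments (no ties)."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w_obs = min(w_plus, w_minus)
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, n * (n + 1) / 2 - w) <= w_obs:
            count += 1
    return count / 2 ** n


class TestAnova:
    def test_identical_means_give_zero_between(self, rng):
        base = rng.normal(0, 3, size=50)
        shuffled = rng.permutation(base)  # same mean, different spread order
        t = one_way_anova([base, shuffled])
        assert t.ss_between == pytest.approx(0.0, abs=1e-9)
        assert t.f_stat == pytest.approx(0.0, abs=1e-12)

    def test_sum_of_squares_additivity(self, rng):
        groups = [rng.normal(m, 2, size=30) for m in (0, 1, 5)]
        t = one_way_anova(groups)
        assert t.ss_total == pytest.approx(t.ss_between + t.ss_within, rel=1e-9)
        assert t.ms_between == pytest.approx(t.ss_between / t.df_between)
        assert t.f_stat == pytest.approx(t.ms_between / t.ms_within)

    def test_label_permutation_preserves_total(self, rng):
        groups = [rng.normal(m, 1, size=20) for m in (0, 2, 4)]
        t1 = one_way_anova(groups)
        t2 = one_way_anova(groups[::-1])
        assert t1.ss_total == pytest.approx(t2.ss_total)

    def test_published_dsc_table_reconstruction(self):
        """Mean squares and F from the printed sums of squares/df of the
        10-method x 100-slice DSC comparison."""
        ms_b = ANOVA_SS_BETWEEN / ANOVA_DF_BETWEEN
        ms_w = ANOVA_SS_WITHIN / ANOVA_DF_WITHIN
        assert ms_b == pytest.approx(881.9255, rel=2e-5)
        assert ms_w == pytest.approx(164.4308, rel=2e-5)
        assert ms_b / ms_w == pytest.approx(5.3635, abs=5e-4)

    def test_degenerate_all_identical_warns(self):
        with pytest.warns(UserWarning):
            t = one_way_anova([np.ones(5), np.ones(5)])
        assert t.f_stat == 0.0


class TestTukey:
    def test_identical_groups_not_significant(self, rng):
        g = rng.normal(0, 1, size=10)
        out = tukey_hsd([g, g.copy()])
        assert not out["significant"].any()

    def test_extreme_separation_significant(self, rng):
        g1 = rng.normal(0, 1, size=10)
        g2 = g1 + 100 * np.std(g1)
        out = tukey_hsd([g1, g2])
        assert out["significant"].all()

    def test_matches_statsmodels_oracle(self, rng):
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        groups = [rng.normal(m, 1.5, size=10) for m in (0.0, 0.8, 3.0)]
        mine = tukey_hsd(groups, alpha=0.05)
        data = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], 10)
        ref = statsmodels.pairwise_tukeyhsd(data, labels, alpha=0.05)
        assert list(mine["significant"]) == list(ref.reject)

    def test_unbalanced_rejected(self, rng):
        with pytest.raises(ValueError):
            tukey_hsd([rng.normal(size=5), rng.normal(size=7)])


class TestWilcoxon:
    def test_identical_samples(self, rng):
        x = rng.normal(size=12)
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank(x, x) == 1.0

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert wilcoxon_signed_rank(x, y) == pytest.approx(
            wilcoxon_signed_rank(y, x))

    def test_matches_exhaustive_null_enumeration(self, rng):
        x = rng.normal(0.4, 1, size=10)
        y = rng.normal(0.0, 1, size=10)
        assert wilcoxon_signed_rank(x, y) == pytest.approx(
            wilcoxon_exact_reference(x, y), rel=1e-9)


class TestBonferroni:
    def test_published_adjustments(self):
        assert bonferroni(0.05, 8) == pytest.approx(0.00625)
        assert bonferroni(0.05, 9) == pytest.approx(0.005556, abs=5e-6)

    def test_single_comparison_unchanged(self):
        assert bonferroni(0.05, 1) == 0.05

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)


class TestTopsis:
    def _dm(self, values, benefit=None, weights=None):
        df = pd.DataFrame(values)
        benefit = benefit or {c: True for c in df.columns}
        return DecisionMatrix(values=df, is_benefit=benefit, weights=weights)

    def test_dominant_alternative_ranked_first(self, rng):
        vals = {"a": [9, 5, 4], "b": [8, 3, 2]}
        out = topsis(self._dm(vals))
        assert out.loc[0, "rank"] == 1

    def test_single_criterion_orders_by_value(self):
        out = topsis(self._dm({"a": [1.0, 3.0, 2.0]}))
        assert list(out.sort_index()["rank"]) == [3, 1, 2]
        out_cost = topsis(self._dm({"a": [1.0, 3.0, 2.0]}, benefit={"a": False}))
        assert list(out_cost.sort_index()["rank"]) == [1, 3, 2]

    def test_scale_invariance_of_ranking(self, rng):
        vals = pd.DataFrame(rng.random((6, 4)) + 0.1, columns=list("wxyz"))
        benefit = {"w": True, "x": True, "y": False, "z": True}
        base = topsis(DecisionMatrix(vals, benefit)).sort_index()["rank"]
        scaled = vals.copy()
        scaled["x"] *= 37.0
        again = topsis(DecisionMatrix(scaled, benefit)).sort_index()["rank"]
        assert list(base) == list(again)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError):
            topsis(self._dm({"a": [0.0, 0.0], "b": [1.0, 2.0]},
                            benefit={"a": True, "b": True}))

    def test_published_benchmark_ranks_gtorbl_first(self):
        out = topsis(benchmark_decision_matrix())
        assert out.loc["GTORBL", "rank"] == 1
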