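"""Model-comparison statistics: exact oracles, null calibration, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import wilcoxon_exact_p
from prostseg.compare import (
    CohortResults,
    coefficient_of_variation,
    compare_to_best,
    covariate_association,
    kruskal_wallis,
    merge_sparse_categories,
    rank_models,
    spearman,
    volume_bias,
    wilcoxon_signed_rank,
    worst_cases,
)
from prostseg.metrics import ScoreRecord


def _results(score_map):
    """score_map: model -> list of (dice, arvd, msd, hd95) per patient."""
    res = CohortResults()
    for model, rows in score_map.items():
        for i, (d, a, m, h) in enumerate(rows):
            pid = f"P{i:03d}"
            res.add(pid, model, ScoreRecord(pid, d, a, m, h))
    return res


class TestWilcoxon:
    def test_identical_pairs_degenerate_flag(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.pvalue == 1.0

    def test_all_positive_differences_matches_exact_enumeration(self):
        a = [5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        b = [1.0, 2.0, 3.0, 3.5, 4.0, 4.5]
        res = wilcoxon_signed_rank(a, b)
        assert res.pvalue == pytest.approx(wilcoxon_exact_p(np.subtract(a, b)), abs=1e-12)
        assert res.pvalue == pytest.approx(2 / 64, abs=1e-12)

    def test_mirrored_inputs_give_identical_p(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        assert wilcoxon_signed_rank(a, b).pvalue == wilcoxon_signed_rank(b, a).pvalue

    @pytest.mark.parametrize("seed", range(4))
    def test_small_n_matches_sign_flip_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=9)
        b = a + rng.normal(0.4, 1.0, size=9)
        got = wilcoxon_signed_rank(a, b).pvalue
        assert got == pytest.approx(wilcoxon_exact_p(a - b), abs=1e-12)


class TestKruskal:
    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(1000):
            groups = [rng.normal(size=12) for _ in range(3)]
            ps.append(kruskal_wallis(groups))
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_two_groups_consistent_with_mannwhitney(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(0.8, 1, size=40)
        p_kw = kruskal_wallis([a, b])
        p_mw = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p_kw == pytest.approx(p_mw, rel=0.15)

    def test_maximal_separation_small_n(self):
        assert kruskal_wallis([[1, 2, 3], [101, 102, 103]]) < 0.1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0], []])


class TestSpearman:
    def test_monotone_relationships(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x)).statistic == pytest.approx(1.0)
        assert spearman(x, -(x**3)).statistic == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_with_ties(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [3.0, 1.0, 2.0, 2.0, 5.0]
        rho = spearman(x, y).statistic
        expected = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning):
            res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.degenerate


class TestVolumeBias:
    def test_perfect_volumes(self):
        res = volume_bias([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert res.mean_relative_volume == pytest.approx(1.0)
        assert res.p_value == 1.0

    def test_uniform_inflation_detected(self):
        gt = np.linspace(20, 80, 12)
        res = volume_bias(1.3 * gt, gt)
        assert res.mean_relative_volume == pytest.approx(1.30, abs=1e-12)
        assert res.p_value == pytest.approx(2 / 2**12, abs=1e-12)  # minimal exact p

    def test_unbiased_noise_rarely_significant(self):
        rng = np.random.default_rng(42)
        hits = 0
        reps = 40
        for _ in range(reps):
            gt = rng.uniform(20, 80, size=50)
            pred = gt * np.exp(rng.normal(0, 0.05, size=50))
            if volume_bias(pred, gt).p_value <= 0.05:
                hits += 1
        assert hits / reps <= 0.10

    def test_nonpositive_gt_rejected(self):
        with pytest.raises(ValueError):
            volume_bias([1.0], [0.0])


class TestRanking:
    def test_dominant_model_gets_rank_one(self):
        res = _results({
            "good": [(0.95, 0.05, 1.0, 2.0)] * 4,
            "bad": [(0.80, 0.20, 3.0, 6.0)] * 4,
        })
        ranks = rank_models(res)
        assert ranks["good"] == 1.0 and ranks["bad"] == 2.0

    def test_tied_models_share_midrank(self):
        rows = [(0.9, 0.1, 2.0, 3.0)] * 3
        ranks = rank_models(_results({"a": rows, "b": list(rows)}))
        assert ranks["a"] == ranks["b"] == 1.5

    def test_three_model_table_matches_hand_ranking(self):
        res = _results({
            "m1": [(0.90, 0.10, 2.0, 4.0)] * 2,
            "m2": [(0.95, 0.30, 1.0, 3.0)] * 2,
            "m3": [(0.85, 0.05, 3.0, 5.0)] * 2,
        })
        ranks = rank_models(res)
        # dice: m2<m1<m3 -> (2,1,3); arvd: (2,3,1); msd: (2,1,3); hd95: (2,1,3)
        assert ranks["m1"] == pytest.approx((2 + 2 + 2 + 2) / 4)
        assert ranks["m2"] == pytest.approx((1 + 3 + 1 + 1) / 4)
        assert ranks["m3"] == pytest.approx((3 + 1 + 3 + 3) / 4)

    def test_incomplete_table_rejected(self):
        res = _results({"a": [(0.9, 0.1, 1.0, 2.0)] * 3})
        res.add("P099", "b", ScoreRecord("P099", 0.8, 0.2, 2.0, 3.0))
        with pytest.raises(ValueError, match="missing"):
            rank_models(res)


class TestCvAndWorstCases:
    def test_constant_scores_have_zero_cv(self):
        assert coefficient_of_variation([0.9] * 5) == 0.0

    def test_two_point_closed_form(self):
        # sd(ddof=1) of {1,3} is sqrt(2), mean 2
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2)

    def test_scale_invariance(self, rng):
        x = rng.uniform(0.7, 1.0, 20)
        assert coefficient_of_variation(3.7 * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-12)

    def test_injected_catastrophe_ranks_first_everywhere(self):
        rows = [(0.9, 0.1, 2.0, 3.0)] * 6
        rows[3] = (0.2, 0.9, 9.0, 15.0)
        res = _results({"m": rows})
        for metric in ("dice", "arvd", "msd", "hd95"):
            worst = worst_cases(res, metric, k=1)
            assert worst.iloc[0]["patient_id"] == "P003"

    def test_k_equals_n_returns_full_sorted_table(self, rng):
        vals = rng.uniform(0.5, 1.0, 8)
        rows = [(v, 0.1, 1.0, 2.0) for v in vals]
        table = worst_cases(_results({"m": rows}), "dice", k=8)
        assert list(table["dice"]) == sorted(vals)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            worst_cases(_results({"m": [(0.9, 0.1, 1, 2)] * 3}), "dice", k=4)


class TestCompareToBest:
    def test_best_model_excluded_and_pvalues_present(self, rng):
        good = [(0.95 + 0.01 * rng.standard_normal(), 0.05, 1.0, 2.0) for _ in range(10)]
        bad = [(0.80 + 0.01 * rng.standard_normal(), 0.2, 3.0, 5.0) for _ in range(10)]
        table = compare_to_best(_results({"good": good, "bad": bad}), "dice")
        assert list(table["model"]) == ["bad"]
        assert table.iloc[0]["p_value"] < 0.05


class TestCovariateAssociation:
    @staticmethod
    def _cov_frame(n, rng):
        return pd.DataFrame({
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "age": rng.normal(70, 7, n),
            "prostate_volume_ml": rng.uniform(20, 80, n),
            "ipsa": rng.lognormal(2, 0.5, n),
            "isup": rng.integers(1, 6, n),
            "ece": rng.integers(0, 4, n),
            "pirads": rng.integers(2, 6, n),
        })

    def test_sparse_categories_merge_to_nearest_neighbour(self):
        vals = [1, 1, 2, 2, 2, 2, 3, 3, 3]  # category 1 has 2 members -> join 2
        merged = merge_sparse_categories(vals, min_count=3)
        assert set(merged) == {2.0, 3.0}
        assert (merged == 2.0).sum() == 6

    def test_monotone_score_in_volume_detected(self, rng):
        n = 50
        cov = self._cov_frame(n, rng)
        rows = [(0.9, 0.1, 1.0 + 0.05 * v + 0.01 * rng.standard_normal(), 2.0)
                for v in cov["prostate_volume_ml"]]
        table = covariate_association(_results({"m": rows}), cov)
        row = table[(table.covariate == "prostate_volume_ml") & (table.metric == "msd")]
        assert row.iloc[0]["p_value"] < 0.05

    def test_independent_covariates_yield_uniform_pvalues(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(300):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            ps.append(spearman(x, y).pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_missing_covariates_listed(self, rng):
        cov = self._cov_frame(3, rng)
        rows = [(0.9, 0.1, 1.0, 2.0)] * 5
        with pytest.raises(ValueError, match="P003"):
            covariate_association(_results({"m": rows}), cov)

    def test_order_invariance(self, rng):
        n = 20
        cov = self._cov_frame(n, rng)
        rows = [(0.8 + 0.01 * i, 0.1, 1.0 + 0.1 * i, 2.0) for i in range(n)]
        res = _results({"m": rows})
        t1 = covariate_association(res, cov)
        t2 = covariate_association(res, cov.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(t1, t2)
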