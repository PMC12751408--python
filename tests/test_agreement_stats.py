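import math

import numpy as np
import pandas as pd
import pytest

from nephroscore import agreement_stats as ag


def kappa_from_table(counts, weighting="linear"):
    """Independent hand-style evaluation of weighted kappa on a confusion table."""
    counts = np.asarray(counts, float)
    n = counts.sum()
    k = counts.shape[0]
    po = pe = 0.0
    row = counts.sum(axis=1) / n
    col = counts.sum(axis=0) / n
    for i in range(k):
        for j in range(k):
            d = abs(i - j) / (k - 1)
            w = 1 - d if weighting == "linear" else 1 - d ** 2
            po += w * counts[i, j] / n
            pe += w * row[i] * col[j]
    return (po - pe) / (1 - pe)


def ratings_from_table(counts):
    x, y = [], []
    for i, row in enumerate(counts):
        for j, c in enumerate(row):
            x += [i] * c
            y += [j] * c
    return np.array(x), np.array(y)


class TestWeightedKappa:
    def test_perfect_agreement(self):
        x = np.array([1, 2, 3, 1, 2, 3, 2])
        res = ag.weighted_kappa(x, x)
        assert res.kappa == pytest.approx(1.0)

    def test_toy_table_matches_hand_formula_and_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        counts = [[20, 5, 1], [4, 30, 6], [2, 3, 25]]
        x, y = ratings_from_table(counts)
        for weighting in ("linear", "quadratic"):
            res = ag.weighted_kappa(x, y, weighting=weighting)
            assert res.kappa == pytest.approx(
                kappa_from_table(counts, weighting), abs=1e-12)
            assert res.kappa == pytest.approx(
                cohen_kappa_score(x, y, weights=weighting), abs=1e-12)
            assert res.ci95[0] <= res.kappa <= res.ci95[1]
            assert res.se > 0

    def test_symmetric_in_raters(self):
        rng = np.random.default_rng(0)
        x = rng.integers(1, 4, 200)
        y = np.clip(x + rng.integers(-1, 2, 200), 1, 3)
        a = ag.weighted_kappa(x, y)
        b = ag.weighted_kappa(y, x)
        assert a.kappa == pytest.approx(b.kappa, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)

    def test_two_categories_linear_equals_quadratic(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 300)
        y = rng.integers(0, 2, 300)
        lin = ag.weighted_kappa(x, y, weighting="linear")
        quad = ag.weighted_kappa(x, y, weighting="quadratic")
        assert lin.kappa == pytest.approx(quad.kappa, abs=1e-12)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.integers(1, 5, 10000)
        y = rng.integers(1, 5, 10000)
        assert abs(ag.weighted_kappa(x, y).kappa) < 0.05

    def test_constant_ratings_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            ag.weighted_kappa([2, 2, 2], [2, 2, 2])

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="not in categories"):
            ag.weighted_kappa([1, 2], [1, 4], categories=[1, 2, 3])


class TestCompareGroups:
    def test_complete_separation(self):
        # U statistic is 0 under complete separation; note a two-sided
        # test cannot reach p < 0.05 with only 3 observations per group
        res = ag.compare_groups([1, 2, 3, 101, 102, 103],
                                ["a", "a", "a", "b", "b", "b"])
        assert res.test == "mann-whitney-u"
        assert res.statistic == 0.0
        assert res.medians["a"] == 2 and res.medians["b"] == 102
        res5 = ag.compare_groups([1, 2, 3, 4, 5, 101, 102, 103, 104, 105],
                                 ["a"] * 5 + ["b"] * 5)
        assert res5.statistic == 0.0 and res5.p_value < 0.05

    def test_all_identical_is_degenerate(self):
        res = ag.compare_groups([5.0] * 9, ["a", "b", "c"] * 3)
        assert res.p_value == 1.0
        assert "DEGENERATE_ALL_IDENTICAL" in res.flags

    def test_three_groups_run_kruskal_and_dunn(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30),
                               rng.normal(4, 1, 30)])
        labs = np.repeat(["a", "b", "c"], 30)
        res = ag.compare_groups(vals, labs)
        assert res.test == "kruskal-wallis"
        assert len(res.posthoc) == 3
        assert res.p_value < 0.01

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, 90)
        labs = np.repeat(["a", "b", "c"], 30)
        p1 = ag.compare_groups(vals, labs).p_value
        p2 = ag.compare_groups(np.exp(vals), labs).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_dunn_adjusted_at_least_raw(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 120)
        labs = np.repeat(["a", "b", "c", "d"], 30)
        groups = ["a", "b", "c", "d"]
        raw = dict(((a, b), p) for a, b, p
                   in ag.dunn_posthoc(vals, labs, groups, correction=None))
        for corr in ("holm", "bonferroni"):
            for a, b, p in ag.dunn_posthoc(vals, labs, groups, correction=corr):
                assert p >= raw[(a, b)] - 1e-15

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ag.compare_groups([1.0, 2.0], ["a", "a"])


class TestOutcomeTable:
    def _cohort(self, totals, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i, total in enumerate(totals):
            stratum_shift = {True: 0.0}  # placeholder
            rows.append({"case_id": f"c{i}", "score": total})
        scores = pd.DataFrame(rows)
        # outcome increases with the score: strata separate cleanly
        outcomes = pd.DataFrame({
            "case_id": scores["case_id"],
            "wit_min": np.asarray(totals) * 3.0 + rng.normal(0, 1.0, len(totals)),
        })
        return scores, outcomes

    def test_counts_row_formatting(self):
        totals = [5] * 46 + [8] * 39 + [11] * 15
        scores, outcomes = self._cohort(totals)
        table = ag.outcome_table(scores, outcomes, mode="renal")
        assert table["n_pct"] == {"low": "46(46%)", "moderate": "39(39%)",
                                  "high": "15(15%)"}

    def test_shifted_outcomes_give_monotone_medians_and_significance(self):
        rng = np.random.default_rng(6)
        totals = list(rng.integers(4, 7, 40)) + list(rng.integers(7, 10, 40)) \
            + list(rng.integers(10, 13, 20))
        scores, outcomes = self._cohort(totals, seed=6)
        table = ag.outcome_table(scores, outcomes, mode="renal")
        entry = table["outcomes"]["wit_min"]
        meds = [entry["per_stratum"][g]["median"]
                for g in ("low", "moderate", "high")]
        assert meds[0] < meds[1] < meds[2]
        assert entry["p_value"] < 0.05
        assert entry["test"] == "kruskal-wallis"

    def test_single_stratum_flagged(self):
        scores, outcomes = self._cohort([5, 5, 6, 6, 4])
        table = ag.outcome_table(scores, outcomes, mode="renal")
        assert "ONLY_ONE_STRATUM" in table["flags"]
        assert table["outcomes"]["wit_min"]["test"] is None

    def test_missing_values_complete_case(self):
        scores, outcomes = self._cohort([5, 5, 8, 8, 11, 11])
        outcomes.loc[1, "wit_min"] = np.nan
        table = ag.outcome_table(scores, outcomes, mode="renal")
        assert table["outcomes"]["wit_min"]["n_excluded_missing"] == 1

    def test_csa_mode_uses_20_threshold(self):
        scores = pd.DataFrame({"case_id": ["a", "b", "c", "d"],
                               "score": [10.0, 19.9, 20.0, 30.0]})
        outcomes = pd.DataFrame({"case_id": ["a", "b", "c", "d"],
                                 "loss_ml": [10.0, 20.0, 50.0, 60.0]})
        table = ag.outcome_table(scores, outcomes, mode="csa")
        assert table["n"] == {"low": 2, "high": 2}

    def test_unknown_mode_rejected(self):
        scores, outcomes = self._cohort([5, 8])
        with pytest.raises(ValueError, match="mode"):
            ag.outcome_table(scores, outcomes, mode="padua")

    def test_table_flattens_to_frame(self):
        scores, outcomes = self._cohort([5, 5, 8, 8, 11, 11])
        table = ag.outcome_table(scores, outcomes, mode="renal")
        frame = ag.outcome_table_frame(table)
        assert "low_median" in frame.columns and len(frame) == 1
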