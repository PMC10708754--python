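"""Engagement, ICC(1) agreement, paired comparisons, endorsement and USE scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from edaprompt import (
    aggregate_children,
    correlation_matrix,
    endorsement_table,
    engagement,
    icc1,
    paired_comparison,
    study_engagement,
    use_scores,
)
from edaprompt.analytics import render_endorsement
from edaprompt.survey import EMOTIONS, TABLE_LABEL_ALIASES


def _log(rows):
    return pd.DataFrame(rows, columns=["member_id", "role", "kind", "emotion",
                                       "activity", "status"])


def _member_rows(member, role, kind, n_complete, n_other, status_other="missed"):
    rows = [[member, role, kind, "happy", "relaxing", "complete"]] * n_complete
    rows += [[member, role, kind, "", "", status_other]] * n_other
    return rows


class TestEngagement:
    def test_eight_of_ten_is_eighty_percent(self):
        log = _log(_member_rows("m1", "mother", "random", 8, 2))
        s = {x.kind: x for x in engagement(log)}
        assert s["random"].rate_pct == 80.0
        assert s["random"].n_received == 10
        assert s["overall"].rate_pct == 80.0

    def test_zero_received_is_flagged_undefined_not_zero(self):
        log = _log(_member_rows("m1", "mother", "random", 3, 0))
        dev = [x for x in engagement(log) if x.kind == "deviation"][0]
        assert not dev.defined
        assert np.isnan(dev.rate_pct)

    def test_incomplete_counts_as_non_complete(self):
        log = _log(_member_rows("m1", "father", "random", 5, 5, status_other="incomplete"))
        s = {x.kind: x for x in engagement(log)}
        assert s["random"].rate_pct == 50.0

    def test_pending_log_rejected(self):
        log = _log([["m1", "mother", "random", "", "", "pending"]])
        with pytest.raises(ValueError, match="pending"):
            engagement(log)

    def test_pooled_rate_invariant_under_member_duplication(self):
        log = _log(
            _member_rows("m1", "mother", "random", 8, 2)
            + _member_rows("m2", "father", "random", 4, 6)
        )
        doubled = pd.concat(
            [log, log.assign(member_id=log["member_id"] + "_copy")], ignore_index=True
        )
        assert study_engagement(log) == pytest.approx(study_engagement(doubled))

    def test_simulated_binomial_rate_recovers_probability(self):
        rng = np.random.default_rng(0)
        statuses = np.where(rng.uniform(size=1000) < 0.8, "complete", "missed")
        log = _log([["m1", "child", "random", "", "", s] for s in statuses])
        rate = study_engagement(log, kind="random")
        assert 76.0 <= rate <= 84.0


def icc_oracle(pairs):
    """Independent route: one-way ANOVA F via scipy, ICC = (F-1)/(F+k-1)."""
    arr = np.asarray(pairs, dtype=float)
    f = stats.f_oneway(*list(arr)).statistic  # groups = families
    k = arr.shape[1]
    return (f - 1.0) / (f + k - 1.0)


class TestIcc1:
    def test_identical_twins_with_family_spread_give_unity(self):
        res = icc1([(1, 1), (2, 2), (3, 3)])
        assert res.icc1 == pytest.approx(1.0)
        assert res.band == "very strong"
        assert res.aggregate

    def test_equal_family_means_give_negative_icc(self):
        res = icc1([(1, 2), (2, 1), (1, 2)])
        assert res.icc1 < 0
        assert res.band == "lack"
        assert not res.aggregate

    def test_zero_total_variance_flagged_undefined(self):
        res = icc1([(5, 5), (5, 5), (5, 5)])
        assert not res.defined
        assert np.isnan(res.icc1)

    def test_unbalanced_families_rejected(self):
        with pytest.raises(ValueError, match="exactly 2"):
            icc1(np.ones((4, 3)))
        with pytest.raises(ValueError, match="3 families"):
            icc1([(1, 2), (3, 4)])

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_anova_oracle_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 20))
        fam = rng.normal(0, rng.uniform(0.2, 2.0), size=n)
        pairs = fam[:, None] + rng.normal(0, rng.uniform(0.2, 2.0), size=(n, 2))
        res = icc1(pairs)
        assert res.icc1 == pytest.approx(icc_oracle(pairs), abs=1e-9)

    def test_unity_iff_within_variance_zero_with_between_spread(self):
        rng = np.random.default_rng(1)
        pairs = np.repeat(rng.normal(size=6)[:, None], 2, axis=1)
        assert icc1(pairs).icc1 == pytest.approx(1.0)
        noisy = pairs + rng.normal(0, 0.1, size=pairs.shape)
        assert icc1(noisy).icc1 < 1.0


class TestAggregateChildren:
    def test_high_agreement_takes_family_means(self):
        res = icc1([(60, 70), (20, 22), (80, 84)])
        vals, did = aggregate_children([(60, 70), (20, 22), (80, 84)], res)
        assert did
        assert vals[0] == pytest.approx(65.0)

    def test_low_agreement_keeps_children_separate(self):
        from edaprompt import AgreementResult
        low = AgreementResult(icc1=0.40, band="weak", aggregate=False)
        pairs = [(60, 70), (20, 22), (80, 84)]
        vals, did = aggregate_children(pairs, low)
        assert not did
        assert vals.shape == (3, 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_aggregation_equals_brute_force_family_mean(self, seed):
        rng = np.random.default_rng(seed)
        pairs = rng.normal(50, 10, size=(8, 2))
        res = icc1(pairs)
        vals, did = aggregate_children(pairs, res)
        if did:
            assert np.allclose(vals, [(a + b) / 2 for a, b in pairs])
            assert res.icc1 >= 0.51
        else:
            assert res.icc1 < 0.51 or not res.defined


class TestPairedComparison:
    def test_identical_series_give_null_result(self):
        res = paired_comparison([1, 2, 3], [1, 2, 3])
        assert (res.t_stat, res.cohens_d, res.p_two_sided) == (0.0, 0.0, 1.0)

    def test_constant_nonzero_difference_flagged(self):
        res = paired_comparison([2, 3, 4], [1, 2, 3])
        assert not res.defined
        assert np.isnan(res.t_stat)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_scipy_ttest_rel(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        a = rng.normal(size=n)
        b = a + rng.normal(0.3, 1.0, size=n)
        res = paired_comparison(a, b)
        ref = stats.ttest_rel(a, b)
        assert res.t_stat == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-9)
        assert res.df == n - 1
        d = a - b
        assert res.cohens_d == pytest.approx(np.mean(d) / np.std(d, ddof=1), abs=1e-12)

    @pytest.mark.parametrize(
        "shift, label",
        [(0.05, "negligible"), (0.3, "small"), (0.6, "medium"), (2.0, "large")],
    )
    def test_effect_size_benchmarks(self, shift, label):
        rng = np.random.default_rng(3)
        noise = rng.normal(size=200)
        noise = (noise - noise.mean()) / noise.std(ddof=1)
        a = np.arange(200, dtype=float)
        res = paired_comparison(a + shift + noise, a)
        assert res.interpretation == label


class TestEndorsement:
    def _log(self):
        rows = []
        for role, kind, emo, n in [
            ("mother", "random", "happy", 3),
            ("mother", "random", "relaxed", 1),
            ("mother", "deviation", "frustrated", 2),
            ("child", "random", "excited", 5),
        ]:
            rows += [[role, role, kind, emo, "relaxing", "complete"]] * n
        return _log(rows)

    def test_single_survey_gives_hundred_percent_and_dashes(self):
        log = _log([["m1", "mother", "random", "happy", "relaxing", "complete"]])
        with pytest.warns(UserWarning):
            table = endorsement_table(log, EMOTIONS, "emotion")
        col = table[("mother", "random")]
        assert col["happy"] == 100.0
        assert col.drop("happy").isna().all()
        rendered = render_endorsement(table)
        assert rendered[("mother", "random")]["sad"] == "-"

    def test_columns_sum_to_one_hundred(self):
        with pytest.warns(UserWarning):
            table = endorsement_table(self._log(), EMOTIONS, "emotion")
        sums = table.sum(axis=0, skipna=True)
        assert np.allclose(sums.to_numpy(float), 100.0, atol=0.1)

    def test_alias_map_relabels_rows_for_presentation(self):
        with pytest.warns(UserWarning):
            table = endorsement_table(self._log(), EMOTIONS, "emotion",
                                      aliases=TABLE_LABEL_ALIASES)
        assert "content" in table.index and "relaxed" not in table.index
        assert "afraid/scared" in table.index
        assert table[("mother", "random")]["content"] == pytest.approx(25.0)


class TestUseScores:
    def test_all_sevens_score_seven(self):
        res = use_scores([7] * 11, [7] * 4)
        assert res.ease_of_use == 7.0 and res.satisfaction == 7.0

    @pytest.mark.parametrize("x", [1, 7])
    def test_items_seven_and_eight_are_excluded(self, x):
        items = [4, 4, 4, 4, 4, 4, x, x, 4, 4, 4]
        res = use_scores(items, [4, 4, 4, 4])
        assert res.ease_of_use == 4.0
        assert res.ease_items_used == 9

    def test_out_of_scale_item_rejected(self):
        with pytest.raises(ValueError, match="1–7"):
            use_scores([8] + [4] * 10, [4] * 4)

    def test_missing_item_uses_available_mean_with_flag(self):
        res = use_scores([None] + [4] * 10, [4, 4, None, 4])
        assert res.ease_of_use == 4.0 and res.satisfaction == 4.0
        assert res.has_missing
        assert res.ease_items_used == 8 and res.satisfaction_items_used == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_mean_over_retained_items(self, seed):
        rng = np.random.default_rng(seed)
        ease = [int(v) for v in rng.integers(1, 8, size=11)]
        sat = [int(v) for v in rng.integers(1, 8, size=4)]
        res = use_scores(ease, sat)
        retained = [v for i, v in enumerate(ease, start=1) if i not in (7, 8)]
        assert res.ease_of_use == pytest.approx(sum(retained) / 9)
        assert res.satisfaction == pytest.approx(sum(sat) / 4)


class TestCorrelationMatrix:
    def test_diagonal_is_unity_and_constant_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2]})
        r, ann = correlation_matrix(df)
        assert r.loc["a", "a"] == 1.0
        assert np.isnan(r.loc["a", "b"])
        assert ann.loc["a", "b"] == "undef"

    def test_matches_scipy_pearson(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["x", "y", "z"])
        r, ann = correlation_matrix(df)
        for a in df.columns:
            for b in df.columns:
                if a == b:
                    continue
                ref, p = stats.pearsonr(df[a], df[b])
                assert r.loc[a, b] == pytest.approx(ref, abs=1e-9)
                if p < 0.01:
                    assert "**" in ann.loc[a, b]

    def test_pairwise_complete_with_missing_values(self):
        df = pd.DataFrame({
            "x": [1.0, 2, 3, 4, 5, np.nan],
            "y": [2.0, 1, 4, 3, 6, 5],
        })
        r, _ = correlation_matrix(df)
        ref, _ = stats.pearsonr(df["x"][:5], df["y"][:5])
        assert r.loc["x", "y"] == pytest.approx(ref, abs=1e-12)
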