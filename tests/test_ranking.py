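"""Subsample-voting feature ranking and threshold selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from restpredict.ranking import (
    EmptySelectionError,
    VoteTable,
    rank_features,
    select_features,
    welch_ttest_pvalues,
)
from restpredict.synthdata import simulate_feature_cohort


def _vote_table(votes: dict, n_iterations=100) -> VoteTable:
    return VoteTable(
        votes=pd.Series(votes), n_iterations=n_iterations, fraction=0.8,
        alpha=0.05, seed=0,
    )


class TestWelchTTest:
    def test_matches_scipy_columnwise(self, rng):
        a = rng.standard_normal((15, 50))
        b = rng.standard_normal((20, 50)) + 0.5
        a[3, 7] = np.nan
        ours = welch_ttest_pvalues(a, b)
        ref = stats.ttest_ind(a, b, axis=0, equal_var=False, nan_policy="omit").pvalue
        np.testing.assert_allclose(ours, np.asarray(ref), rtol=1e-10)

    def test_too_few_values_gives_nan(self, rng):
        a = np.full((10, 1), np.nan)
        a[0, 0] = 1.0
        assert np.isnan(welch_ttest_pvalues(a, rng.standard_normal((10, 1)))[0])


class TestRankFeatures:
    def test_saturated_feature_reaches_100(self):
        vals, labels, _ = simulate_feature_cohort(
            120, n_noise_features=50, n_effect_features=1, effect_size=4.0, seed=5
        )
        table = rank_features(vals, labels, seed=0)
        assert table.votes[vals.columns[0]] == 100

    def test_votes_bounded(self):
        vals, labels, _ = simulate_feature_cohort(60, 30, 5, 1.0, seed=2)
        table = rank_features(vals, labels, seed=1)
        assert table.votes.between(0, 100).all()

    def test_null_votes_mean_near_100_alpha(self):
        """Null features earn ~alpha votes per iteration: the mean vote count
        over 50 seeds lies in [2, 8] (binomial oracle around 100*0.05,
        subsample dependence notwithstanding)."""
        means = []
        for seed in range(50):
            vals, labels, _ = simulate_feature_cohort(
                120, n_noise_features=1, seed=1000 + seed
            )
            table = rank_features(vals, labels, seed=seed)
            means.append(float(table.votes.iloc[0]))
        assert 2.0 <= np.mean(means) <= 8.0

    def test_deterministic_given_seed(self):
        vals, labels, _ = simulate_feature_cohort(80, 20, 2, 1.0, seed=7)
        t1 = rank_features(vals, labels, seed=42)
        t2 = rank_features(vals, labels, seed=42)
        pd.testing.assert_series_equal(t1.votes, t2.votes)

    def test_adding_noise_feature_leaves_votes_unchanged(self):
        vals, labels, _ = simulate_feature_cohort(80, 10, 2, 1.5, seed=3)
        before = rank_features(vals, labels, seed=9).votes
        wider = vals.copy()
        wider["noise|extra"] = np.random.default_rng(1).standard_normal(len(vals))
        after = rank_features(wider, labels, seed=9).votes
        pd.testing.assert_series_equal(before, after[before.index])

    def test_label_permutation_destroys_votes(self):
        # Under true labels every d=2 feature saturates at 100; permuting the
        # labels collapses them to near-zero votes.  (Note: because votes are
        # strongly dependent across subsample iterations, a *null* feature
        # whose full-sample t-test is extreme by chance can still score high,
        # so the collapse is asserted on the known effect features and on the
        # bulk of the distribution, not on the maximum.)
        vals, labels, _ = simulate_feature_cohort(120, 100, 10, 2.0, seed=4)
        effect_cols = [c for c in vals.columns if c.startswith("effect")]
        true_table = rank_features(vals, labels, seed=0)
        assert (true_table.votes[effect_cols] == 100).all()

        permuted = pd.Series(
            np.random.default_rng(0).permutation(labels.to_numpy()),
            index=labels.index,
        )
        table = rank_features(vals, permuted, seed=0)
        assert int(table.votes[effect_cols].max()) < 50
        assert float(table.votes.median()) <= 10

    def test_all_missing_feature_dropped(self):
        vals, labels, _ = simulate_feature_cohort(60, 5, seed=6)
        vals["noise|dead"] = np.nan
        table = rank_features(vals, labels, seed=0)
        assert "noise|dead" not in table.votes.index

    def test_single_class_rejected(self):
        vals, labels, _ = simulate_feature_cohort(40, 5, seed=8)
        labels[:] = "responder"
        with pytest.raises(ValueError, match="both outcome classes"):
            rank_features(vals, labels)


class TestSelectFeatures:
    def test_threshold_inclusive(self):
        table = _vote_table({"a": 61, "b": 60, "c": 59})
        assert set(select_features(table, 60)) == {"a", "b"}

    def test_zero_threshold_selects_all(self):
        table = _vote_table({"a": 0, "b": 5})
        assert set(select_features(table, 0)) == {"a", "b"}

    def test_empty_selection_raises_with_advice(self):
        table = _vote_table({"a": 10, "b": 20})
        with pytest.raises(EmptySelectionError, match="lower"):
            select_features(table, 60)

    def test_selection_monotone_in_threshold(self):
        vals, labels, _ = simulate_feature_cohort(120, 50, 10, 1.0, seed=11)
        table = rank_features(vals, labels, seed=0)
        sizes = []
        for threshold in (0, 20, 40, 60, 80, 100):
            try:
                sizes.append(len(select_features(table, threshold)))
            except EmptySelectionError:
                sizes.append(0)
        assert all(a >= b for a, b in zip(sizes[:-1], sizes[1:]))

    def test_out_of_range_threshold(self):
        table = _vote_table({"a": 10})
        with pytest.raises(ValueError, match="threshold"):
            select_features(table, 150)


def test_vote_table_csv_round_trip(tmp_path):
    table = _vote_table({"mse|C3|17": 88, "spectral|O1|theta": 12})
    table.to_csv(tmp_path / "votes.csv")
    back = VoteTable.from_csv(tmp_path / "votes.csv")
    pd.testing.assert_series_equal(
        back.votes.sort_index(), table.votes.sort_index(), check_names=False
    )
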