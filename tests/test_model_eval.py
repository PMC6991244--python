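"""RBF-SVM training, cross-validation, and leave-one-site-out evaluation."""

import numpy as np
import pandas as pd
import pytest

from restpredict.model_eval import (
    ModelSpec,
    balanced_accuracy,
    cross_validate,
    leave_one_site_out,
    train_classifier,
)
from restpredict.synthdata import simulate_feature_cohort

FAST = ModelSpec(
    C_grid=(0.1, 1.0, 10.0), gamma_grid=(0.01, 0.1), inner_folds=3, vote_threshold=0
)


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "sens, spec, expected",
        [(67.3, 91.0, 79.15), (79.2, 85.5, 82.35), (50.0, 50.0, 50.0)],
    )
    def test_mean_of_rates(self, sens, spec, expected):
        assert balanced_accuracy(sens, spec) == pytest.approx(expected)

    def test_identity_when_equal(self):
        for x in (0.0, 33.3, 100.0):
            assert balanced_accuracy(x, x) == x

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            balanced_accuracy(110.0, 50.0)


class TestTrainClassifier:
    def test_separable_clouds_fit_perfectly(self):
        vals, labels, _ = simulate_feature_cohort(
            100, n_noise_features=0, n_effect_features=5, effect_size=6.0, seed=0
        )
        model = train_classifier(vals, labels, FAST)
        pred = model.predict(vals.to_numpy())
        truth = (labels == "responder").to_numpy().astype(int)
        assert np.array_equal(pred, truth)

    def test_duplicated_columns_same_predictions(self):
        # duplicating a z-scored feature only rescales the RBF distance by a
        # constant, which the gamma grid absorbs; decisions are unchanged
        vals, labels, _ = simulate_feature_cohort(80, 2, 3, 2.0, seed=1)
        doubled = pd.concat(
            [vals, vals.add_suffix("|copy")], axis=1
        )
        grids = ModelSpec(
            C_grid=(1.0,), gamma_grid=(0.1,), inner_folds=3, vote_threshold=0
        )
        half_gamma = ModelSpec(
            C_grid=(1.0,), gamma_grid=(0.05,), inner_folds=3, vote_threshold=0
        )
        m1 = train_classifier(vals, labels, grids)
        m2 = train_classifier(doubled, labels, half_gamma)
        np.testing.assert_array_equal(
            m1.predict(vals.to_numpy()), m2.predict(doubled.to_numpy())
        )

    def test_deterministic_given_seed(self):
        vals, labels, _ = simulate_feature_cohort(60, 10, 2, 1.0, seed=2)
        m1 = train_classifier(vals, labels, FAST)
        m2 = train_classifier(vals, labels, FAST)
        assert m1.best_params_ == m2.best_params_
        np.testing.assert_array_equal(
            m1.predict(vals.to_numpy()), m2.predict(vals.to_numpy())
        )

    def test_single_class_rejected(self):
        vals, labels, _ = simulate_feature_cohort(30, 5, seed=3)
        labels[:] = "nonresponder"
        with pytest.raises(ValueError, match="both outcome classes"):
            train_classifier(vals, labels, FAST)


class TestCrossValidate:
    def test_report_structure_and_count_consistency(self):
        vals, labels, _ = simulate_feature_cohort(60, 10, 5, 2.0, seed=4)
        report = cross_validate(vals, labels, FAST, k=5, seed=0)
        folds = report.table.drop(index="pooled")
        assert len(folds) == 5
        # pooled counts equal the sum over folds
        for c in ("tp", "fp", "tn", "fn"):
            assert report.pooled[c] == folds[c].sum()
        assert folds["n"].sum() == 60
        # balanced accuracy always recomputable from the rates
        row = report.pooled
        assert row["balanced_accuracy"] == pytest.approx(
            balanced_accuracy(row["sensitivity"], row["specificity"])
        )

    def test_strong_effect_learnable(self):
        vals, labels, _ = simulate_feature_cohort(80, 20, 10, 2.5, seed=5)
        report = cross_validate(
            vals, labels,
            ModelSpec(C_grid=(1.0, 10.0), gamma_grid=(0.01, 0.1), inner_folds=3,
                      vote_threshold=60),
            k=5, seed=0,
        )
        assert report.balanced_accuracy_pct >= 75.0

    def test_too_few_subjects_rejected(self):
        vals, labels, _ = simulate_feature_cohort(12, 5, seed=6)
        with pytest.raises(ValueError, match="at least"):
            cross_validate(vals, labels, FAST, k=10)

    def test_no_leakage_canary(self):
        """An oracle feature that encodes the label only in held-out rows
        must not lift accuracy: selection/scaling/training never see it as
        informative if the pipeline is leak-free."""
        vals, labels, sites = simulate_feature_cohort(
            80, n_noise_features=20, site_sizes=(40, 40), seed=7
        )
        oracle = np.random.default_rng(0).standard_normal(80)
        test_site = sites == "S2"
        oracle[test_site.to_numpy()] = np.where(
            (labels[test_site] == "responder").to_numpy(), 10.0, -10.0
        )
        vals["noise|oracle"] = oracle
        report = leave_one_site_out(
            vals, labels, sites, FAST, seed=0, min_per_class=5
        )
        ba = report.table.loc["S2", "balanced_accuracy"]
        assert 25.0 <= ba <= 75.0  # chance band, not oracle-perfect


class TestLeaveOneSiteOut:
    def test_one_row_per_site_with_sizes(self):
        vals, labels, sites = simulate_feature_cohort(
            90, 20, 10, 2.5, site_sizes=(40, 30, 20), seed=8
        )
        report = leave_one_site_out(
            vals, labels, sites,
            ModelSpec(C_grid=(1.0, 10.0), gamma_grid=(0.01, 0.1), inner_folds=3,
                      vote_threshold=60),
            seed=0,
        )
        body = report.table.drop(index="pooled")
        assert sorted(body.index) == ["S1", "S2", "S3"]
        assert body.loc["S1", "n"] == 40
        assert body.loc["S3", "n"] == 20

    def test_degenerate_site_flagged(self):
        vals, labels, sites = simulate_feature_cohort(
            70, 10, 5, 3.0, site_sizes=(35, 25, 10), seed=9
        )
        labels[sites == "S3"] = "nonresponder"  # no responders to detect
        report = leave_one_site_out(vals, labels, sites, FAST, seed=0, min_per_class=5)
        row = report.table.loc["S3"]
        assert bool(row["degenerate"])
        assert np.isnan(row["sensitivity"])
        assert np.isnan(row["balanced_accuracy"])

    def test_single_site_rejected(self):
        vals, labels, sites = simulate_feature_cohort(40, 5, seed=10)
        with pytest.raises(ValueError, match="2 sites"):
            leave_one_site_out(vals, labels, sites, FAST)
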