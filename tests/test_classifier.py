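"""Split, forest scoring, sensitivity-at-specificity and ROC behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from serumpanel import (
    ForestSpec,
    GroupSpec,
    MarkerSpec,
    SingleClassError,
    evaluate_panels,
    generate_cohort,
    make_fixture,
    roc_curve,
    score_cohort,
    sensitivity_at_specificity,
    split_cohort,
    train_forest,
    with_split,
)

from conftest import tiny_table


def _case_control(n_healthy, n_early, markers, seed):
    groups = [
        GroupSpec("healthy", {"mdacc": n_healthy // 2, "fhcc": n_healthy - n_healthy // 2}),
        GroupSpec("early", {"mdacc": n_early // 2, "fhcc": n_early - n_early // 2}),
    ]
    return generate_cohort(groups, markers, seed)


class TestSplitCohort:
    def test_study_split_yields_125_validation_cases(self, edrn_cohort):
        split = split_cohort(edrn_cohort, fraction=0.5, seed=0)
        cs = with_split(edrn_cohort, split)
        val_cases = cs[(cs["split"] == "validation") & cs["group"].isin(("early", "late"))]
        assert len(val_cases) == 125

    def test_even_stratum_splits_in_half(self):
        cohort = tiny_table(["early"] * 10, range(10))
        split = split_cohort(cohort, 0.5, seed=1)
        assert (split == "train").sum() == 5
        assert (split == "validation").sum() == 5

    def test_deterministic_under_seed(self, edrn_cohort):
        a = split_cohort(edrn_cohort, 0.5, seed=7)
        b = split_cohort(edrn_cohort, 0.5, seed=7)
        c = split_cohort(edrn_cohort, 0.5, seed=8)
        pd.testing.assert_series_equal(a, b)
        assert (a != c).any()

    def test_per_stratum_balance(self, edrn_cohort):
        split = split_cohort(edrn_cohort, 0.5, seed=2)
        cs = with_split(edrn_cohort, split)
        for _, grp in cs.groupby("group"):
            n_train = (grp["split"] == "train").sum()
            assert abs(n_train - 0.5 * len(grp)) <= 1

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 2.0])
    def test_fraction_outside_unit_interval_rejected(self, bad, edrn_cohort):
        with pytest.raises(ValueError):
            split_cohort(edrn_cohort, fraction=bad, seed=0)


class TestTrainForest:
    def test_separable_features_give_near_perfect_auc(self):
        markers = [
            MarkerSpec("a", {"healthy": 0.0, "early": 6.0}, {"healthy": 1.0}),
            MarkerSpec("b", {"healthy": 0.0, "early": 6.0}, {"healthy": 1.0}),
        ]
        cohort = _case_control(100, 100, markers, seed=0)
        split = split_cohort(cohort, 0.5, seed=0)
        model = train_forest(
            cohort, split, ForestSpec(n_trees=100, seed=0, feature_columns=("a", "b"))
        )
        cs = with_split(cohort, split)
        val = cs[cs["split"] == "validation"]
        curve = roc_curve(model.vote_scores(val), val["group"] == "early")
        assert curve.auc >= 0.99

    def test_permuted_labels_give_chance_auc(self):
        markers = [MarkerSpec("a", {"healthy": 0.0, "early": 1.5}, {"healthy": 1.0})]
        aucs = []
        for seed in range(20):
            cohort = _case_control(80, 80, markers, seed=seed)
            rng = np.random.default_rng(seed)
            cohort["group"] = rng.permutation(cohort["group"].to_numpy())
            split = split_cohort(cohort, 0.5, seed=seed)
            model = train_forest(
                cohort, split, ForestSpec(n_trees=100, seed=seed, feature_columns=("a",))
            )
            cs = with_split(cohort, split)
            val = cs[cs["split"] == "validation"]
            aucs.append(roc_curve(model.vote_scores(val), val["group"] == "early").auc)
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_constant_feature_gives_chance_level_sensitivity(self):
        markers = [MarkerSpec("a", {"healthy": 0.0, "early": 2.0}, {"healthy": 1.0})]
        cohort = _case_control(100, 50, markers, seed=1)
        cohort["flat"] = 1.0
        split = split_cohort(cohort, 0.5, seed=1)
        model = train_forest(
            cohort, split, ForestSpec(n_trees=100, seed=1, feature_columns=("flat",))
        )
        cs = with_split(cohort, split)
        val = cs[cs["split"] == "validation"]
        res = sensitivity_at_specificity(
            model.vote_scores(val), val["group"] == "early", 0.98
        )
        assert res.sensitivity <= 0.10

    def test_single_class_training_rejected(self):
        cohort = tiny_table(["healthy"] * 10, range(10))
        split = split_cohort(cohort, 0.5, seed=0)
        with pytest.raises(SingleClassError):
            train_forest(cohort, split, ForestSpec(n_trees=10, feature_columns=("m",)))

    def test_deterministic_scores_under_seed(self):
        markers = [MarkerSpec("a", {"healthy": 0.0, "early": 1.0}, {"healthy": 1.0})]
        cohort = _case_control(40, 40, markers, seed=2)
        split = split_cohort(cohort, 0.5, seed=2)
        spec = ForestSpec(n_trees=50, seed=9, feature_columns=("a",))
        s1 = score_cohort(train_forest(cohort, split, spec), cohort)
        s2 = score_cohort(train_forest(cohort, split, spec), cohort)
        pd.testing.assert_series_equal(s1, s2)


class TestSensitivityAtSpecificity:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(50), np.ones(10)]
        labels = np.r_[np.zeros(50), np.ones(10)].astype(bool)
        assert sensitivity_at_specificity(scores, labels, 0.99).sensitivity == 1.0

    def test_identical_scores_give_zero_sensitivity(self):
        scores = np.full(30, 0.5)
        labels = np.r_[np.zeros(20), np.ones(10)].astype(bool)
        assert sensitivity_at_specificity(scores, labels, 0.9).sensitivity == 0.0

    def test_enumeration_example(self):
        scores = np.r_[np.arange(10) / 10, 0.85, 0.95]
        labels = np.r_[np.zeros(10), np.ones(2)].astype(bool)
        res = sensitivity_at_specificity(scores, labels, 0.95)
        assert res.threshold == pytest.approx(0.9)
        assert res.sensitivity == 0.5

    def test_achieved_specificity_never_below_request(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(5, 200)
            scores = np.r_[rng.normal(0, 1, n), rng.normal(1, 1, 20)]
            labels = np.r_[np.zeros(n), np.ones(20)].astype(bool)
            target = rng.uniform(0.5, 0.99)
            res = sensitivity_at_specificity(scores, labels, target)
            assert res.achieved_specificity >= target

    def test_sensitivity_monotone_in_specificity(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.normal(0, 1, 300), rng.normal(1.5, 1, 100)]
        labels = np.r_[np.zeros(300), np.ones(100)].astype(bool)
        sens = [
            sensitivity_at_specificity(scores, labels, s).sensitivity
            for s in (0.5, 0.8, 0.9, 0.95, 0.98)
        ]
        assert sens == sorted(sens, reverse=True)

    def test_empty_class_rejected(self):
        with pytest.raises(SingleClassError):
            sensitivity_at_specificity([0.1, 0.2], [True, True], 0.9)


class TestROC:
    def test_separable_scores_pass_through_top_left(self):
        scores = np.r_[np.zeros(20), np.ones(20)]
        labels = np.r_[np.zeros(20), np.ones(20)]
        curve = roc_curve(scores, labels)
        assert any((f == 0.0) and (t == 1.0) for f, t in zip(curve.fpr, curve.tpr))
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1

    def test_random_scores_have_half_area(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(size=4000)
        labels = rng.integers(0, 2, size=4000)
        assert abs(roc_curve(scores, labels).auc - 0.5) < 0.05

    def test_sign_reversal_complements_area(self):
        rng = np.random.default_rng(6)
        scores = np.r_[rng.normal(0, 1, 100), rng.normal(1, 1, 50)]
        labels = np.r_[np.zeros(100), np.ones(50)]
        a = roc_curve(scores, labels).auc
        b = roc_curve(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_auc_equals_mann_whitney_u_statistic(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n0, n1 = rng.integers(5, 50, size=2)
            scores = np.r_[rng.normal(0, 1, n0), rng.normal(0.7, 1.3, n1)]
            labels = np.r_[np.zeros(n0), np.ones(n1)]
            auc = roc_curve(scores, labels).auc
            u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
            assert auc == pytest.approx(u / (n0 * n1))

    def test_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        curve = roc_curve(scores, labels)
        assert (np.diff(curve.fpr) >= 0).all()
        assert (np.diff(curve.tpr) >= 0).all()


class TestEvaluatePanels:
    def test_baseline_against_itself_has_zero_deltas(self):
        cohort = make_fixture("complementary", seed=0)
        split = split_cohort(cohort, 0.5, seed=0)
        report = evaluate_panels(
            cohort, split, {"p": ["A"], "q": ["A"]}, baseline="p",
            n_trees=50, seed=0,
        )
        assert (report["delta_vs_baseline"].abs() < 1e-12).all()

    def test_complementary_marker_lifts_panel_sensitivity(self):
        wins = 0
        for seed in range(20):
            cohort = make_fixture("complementary", seed=seed)
            split = split_cohort(cohort, 0.5, seed=seed)
            report = evaluate_panels(
                cohort, split, {"ab": ["A", "B"], "a": ["A"]}, baseline="a",
                n_trees=100, seed=seed,
            )
            sens = report[report["group"] == "all_cases"].set_index("panel")["sensitivity"]
            wins += sens["ab"] > sens["a"]
        assert wins >= 18

    def test_pure_noise_marker_does_not_move_sensitivity(self):
        # needs the large control pool: with few evaluation controls the
        # vote-score ceiling ties make single-feature operating points
        # unstable regardless of the added feature
        deltas = []
        for seed in range(20):
            cohort = make_fixture("edrn_like", seed=seed)
            rng = np.random.default_rng(1000 + seed)
            cohort["N"] = np.exp(rng.normal(size=len(cohort)))
            split = split_cohort(cohort, 0.5, seed=seed)
            report = evaluate_panels(
                cohort, split, {"a": ["CA125"], "an": ["CA125", "N"]},
                baseline="a", n_trees=500, seed=seed,
            )
            row = report[(report["panel"] == "an") & (report["group"] == "all_cases")]
            deltas.append(float(row["delta_vs_baseline"].iloc[0]))
        assert abs(np.mean(deltas)) < 0.04

    def test_unknown_feature_rejected(self):
        cohort = make_fixture("tiny", seed=0)
        split = split_cohort(cohort, 0.5, seed=0)
        with pytest.raises(KeyError, match="nope"):
            evaluate_panels(cohort, split, {"p": ["nope"]}, n_trees=10)
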