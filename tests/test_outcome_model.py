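import numpy as np
import pytest
from scipy import stats

import hfonet
from hfonet.outcome_model import (
    SurgicalOutcomeModel,
    apply_to_heldout,
    bootstrap_auc_test,
    calibration_curve,
    hanley_mcneil_ci,
    hotelling_t2,
    loo_naive_bayes,
    permutation_ppv_test,
    ppv_at_threshold,
    roc_auc,
)


def separated_cohort(rng, n_pos=12, n_neg=5, gap=10.0, sd=0.1, d=1):
    X = np.vstack([rng.normal(gap, sd, (n_pos, d)), rng.normal(0.0, sd, (n_neg, d))])
    y = np.array([True] * n_pos + [False] * n_neg)
    return X, y


class TestRocAuc:
    def test_perfectly_ordered(self):
        pts, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_perfectly_reversed(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert auc == 0.0

    def test_matches_pair_count_oracle_with_ties(self, rng):
        scores = rng.integers(0, 5, 30).astype(float)  # many ties
        labels = rng.random(30) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        _, auc = roc_auc(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        u = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
        assert auc == pytest.approx(u / (len(pos) * len(neg)))

    def test_negation_complements_auc(self, rng):
        scores = rng.standard_normal(20)  # continuous, tie-free
        labels = np.arange(20) < 8
        _, a = roc_auc(scores, labels)
        _, b = roc_auc(-scores, labels)
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestHanleyMcneil:
    def test_symmetric_at_half(self):
        lo, hi = hanley_mcneil_ci(0.5, 10, 10)
        assert lo + hi == pytest.approx(1.0)

    def test_degenerate_at_one(self):
        assert hanley_mcneil_ci(1.0, 12, 5) == (1.0, 1.0)

    def test_matches_independent_formula_on_grid(self):
        z = stats.norm.ppf(0.975)
        for a in (0.55, 0.7, 10 / 12, 0.95):
            for n_pos, n_neg in ((12, 5), (30, 30), (8, 20)):
                q1 = a / (2 - a)
                q2 = 2 * a * a / (1 + a)
                se = np.sqrt((a * (1 - a) + (n_pos - 1) * (q1 - a * a)
                              + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg))
                lo, hi = hanley_mcneil_ci(a, n_pos, n_neg)
                assert lo == pytest.approx(a - z * se, abs=1e-12)
                assert hi == pytest.approx(a + z * se, abs=1e-12)

    def test_bounds_not_clamped(self):
        # strong AUCs at small n produce intervals extending past 1
        _, hi = hanley_mcneil_ci(0.83, 12, 5)
        assert hi > 1.0


class TestBootstrapAucTest:
    def test_separated_scores_significant(self, rng):
        X, y = separated_cohort(rng)
        p = bootstrap_auc_test(X[:, 0], y, n_boot=2000, seed=0)
        assert p < 0.05

    def test_seeded_determinism(self, rng):
        s = rng.standard_normal(17)
        y = np.arange(17) < 12
        assert bootstrap_auc_test(s, y, 500, seed=3) == \
               bootstrap_auc_test(s, y, 500, seed=3)

    def test_null_p_values_roughly_uniform(self):
        """Scores independent of labels give approximately uniform p."""
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(200):
            s = rng.standard_normal(17)
            y = rng.permutation(np.arange(17) < 12)
            ps.append(bootstrap_auc_test(s, y, n_boot=200, seed=0))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPpv:
    def test_nine_of_nine(self):
        post = np.array([0.9] * 9 + [0.3] * 8)
        labels = np.array([True] * 9 + [False] * 8)
        assert ppv_at_threshold(post, labels, 0.8) == (1.0, 9, 9)

    def test_twelve_of_seventeen(self):
        post = np.ones(17)
        labels = np.array([True] * 12 + [False] * 5)
        ppv, tp, n = ppv_at_threshold(post, labels, 0.8)
        assert (tp, n) == (12, 17)
        assert ppv == pytest.approx(12 / 17)

    def test_no_predictions_flagged_undefined(self):
        ppv, tp, n = ppv_at_threshold([0.1, 0.2], [True, False], 0.8)
        assert np.isnan(ppv) and n == 0


class TestPermutationPpvTest:
    def test_identical_rules_give_p_one(self):
        pred = np.array([1, 1, 0, 1, 0], bool)
        y = np.array([1, 0, 0, 1, 1], bool)
        assert permutation_ppv_test(pred, pred, y, n_perm=200, seed=0) == \
               pytest.approx(1.0)

    def test_perfect_vs_chance_significant(self, rng):
        y = np.arange(17) < 12
        perfect = y.copy()
        chance = rng.random(17) < 0.5
        p = permutation_ppv_test(perfect, chance, y, n_perm=2000, seed=1)
        assert p < 0.05

    def test_seeded_determinism(self, rng):
        a, b = rng.random(10) < 0.5, rng.random(10) < 0.5
        y = rng.random(10) < 0.6
        assert permutation_ppv_test(a, b, y, 300, seed=7) == \
               permutation_ppv_test(a, b, y, 300, seed=7)


class TestHotelling:
    def test_identical_groups_give_zero(self, rng):
        A = rng.standard_normal((10, 3))
        res = hotelling_t2(A, A.copy())
        assert res.t2 == pytest.approx(0.0, abs=1e-10)
        assert res.p_global == pytest.approx(1.0)
        assert res.per_feature == []

    def test_univariate_equals_t_squared(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(5) + 1.0
        res = hotelling_t2(a[:, None], b[:, None])
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert res.t2 == pytest.approx(t * t, abs=1e-10)

    def test_post_hoc_only_when_significant(self, rng):
        A = rng.standard_normal((12, 4)) + 3.0
        B = rng.standard_normal((5, 4))
        res = hotelling_t2(A, B)
        assert res.p_global < 0.05
        assert len(res.per_feature) == 4

    def test_dimension_guard(self, rng):
        with pytest.raises(ValueError):
            hotelling_t2(rng.standard_normal((3, 5)), rng.standard_normal((3, 5)))


class TestCalibration:
    def test_all_certain_and_correct(self):
        assert calibration_curve([1.0, 1.0], [True, True]) == [(1.0, 1.0)]

    def test_single_bin_is_mean_and_prevalence(self, rng):
        post = rng.random(50)
        y = rng.random(50) < 0.5
        [(mp, op)] = calibration_curve(post, y, n_bins=1)
        assert mp == pytest.approx(post.mean())
        assert op == pytest.approx(y.mean())

    def test_well_calibrated_posteriors_track_diagonal(self):
        rng = np.random.default_rng(0)
        post = rng.random(2000)
        y = rng.random(2000) < post
        for mp, op in calibration_curve(post, y, n_bins=5):
            se = np.sqrt(mp * (1 - mp) / 400)
            assert abs(op - mp) < 3 * se + 0.05


class TestLooNaiveBayes:
    def test_separated_cohort_gives_auc_one(self, rng):
        X, y = separated_cohort(rng)
        res, models = loo_naive_bayes(X, y, n_boot=200)
        assert res.auc == 1.0
        assert len(models) == 17

    def test_permuted_labels_never_optimistic(self):
        """Under the label-permutation null the pooled leave-one-out AUC is
        conservative: each held-out patient's own class loses one training
        member, which systematically depresses that patient's posterior, so
        the pooled AUC sits below — never above — chance at this sample
        size (n = 17, 12/5 split)."""
        rng = np.random.default_rng(7)
        aucs = []
        for _ in range(200):
            X = rng.standard_normal((17, 4))
            y = rng.permutation(np.arange(17) < 12)
            res, _ = loo_naive_bayes(X, y, n_boot=10)
            aucs.append(res.auc)
        assert 0.2 < np.mean(aucs) < 0.55

    def test_one_per_class_rejected(self):
        with pytest.raises(ValueError):
            loo_naive_bayes(np.array([[0.0], [1.0]]), [True, False])

    def test_row_order_invariance(self, rng):
        X, y = separated_cohort(rng, gap=1.0, sd=1.0, d=3)
        res1, _ = loo_naive_bayes(X, y, n_boot=10)
        perm = rng.permutation(len(y))
        res2, _ = loo_naive_bayes(X[perm], y[perm], n_boot=10)
        assert np.allclose(res1.posteriors[perm], res2.posteriors)


class TestApplyToHeldout:
    def test_identical_models_give_zero_sd(self, rng):
        X, y = separated_cohort(rng, gap=1.0, sd=1.0)
        _, models = loo_naive_bayes(X, y, n_boot=10)
        scores = apply_to_heldout([models[0]] * 5, rng.standard_normal((3, 1)))
        assert all(sd == 0.0 for _, sd in scores)

    def test_heldout_at_positive_centroid_scores_high(self, rng):
        X, y = separated_cohort(rng, gap=10.0, sd=0.5)
        _, models = loo_naive_bayes(X, y, n_boot=10)
        [(mean, sd)] = apply_to_heldout(models, np.array([[10.0]]))
        assert mean > 0.5

    def test_one_score_per_fold(self, rng):
        X, y = separated_cohort(rng, gap=1.0, sd=1.0)
        _, models = loo_naive_bayes(X, y, n_boot=10)
        scores = np.empty((2, len(models)))
        for k, m in enumerate(models):
            scores[:, k] = m.predict_proba(np.zeros((2, 1)))[:, 1]
        assert scores.shape[1] == 17

    def test_dimension_mismatch_rejected(self, rng):
        X, y = separated_cohort(rng)
        _, models = loo_naive_bayes(X, y, n_boot=10)
        with pytest.raises(ValueError):
            apply_to_heldout(models, np.zeros((2, 3)))


class TestModelSurface:
    def test_fit_summary_and_accessors(self, rng):
        X, y = separated_cohort(rng, gap=2.0, sd=1.0, d=4)
        model = SurgicalOutcomeModel(X, y, feature_names=[f"f{i}" for i in range(4)])
        res = model.fit(n_boot=100, seed=0)
        text = res.summary()
        assert "AUC" in text and "Hotelling" in text
        assert 0.0 <= res.auc <= 1.0
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1] + 1e-12

    def test_from_dataframe_excludes_class2(self, rng):
        import pandas as pd
        n = 20
        df = pd.DataFrame({
            "HFO-RATE_CReP30": rng.random(n),
            "class_group": ["Class-1"] * 9 + ["Class-3+"] * 7 + ["Class-2"] * 4,
        })
        model = SurgicalOutcomeModel.from_dataframe(df)
        assert model.features.shape == (16, 1)

    def test_auc_increases_with_link_effect_size(self):
        """End-to-end: stronger outcome links give higher recovered AUC."""
        from hfonet.features import build_feature_table
        mean_aucs = []
        for slope in (0.0, 4.0, 16.0):
            aucs = []
            for seed in range(25):
                cfg = hfonet.CohortSimConfig(
                    n_patients=40, seed=seed,
                    outcome_link={"slope": slope, "center": 0.5})
                table = build_feature_table(hfonet.make_feature_cohort(cfg))
                counts = table["class_group"].value_counts()
                if counts.get("Class-1", 0) < 2 or counts.get("Class-3+", 0) < 2:
                    continue
                m = SurgicalOutcomeModel.from_dataframe(table)
                res, _ = loo_naive_bayes(m.features, m.labels, n_boot=10)
                aucs.append(res.auc)
            mean_aucs.append(np.mean(aucs))
        assert mean_aucs[0] < mean_aucs[1] < mean_aucs[2]
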