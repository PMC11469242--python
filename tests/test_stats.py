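"""Cohort statistics: test gates, ZIP model, SMOTE+CV, agreement."""

import numpy as np
import pandas as pd
import pytest

from fazmetrics.errors import DataError, ParameterError
from fazmetrics.stats import (bland_altman, dice_jaccard, dunn_test, fit_zip,
                              group_difference_tests, intergrader, predict_cv,
                              smote)


def make_table(rng, n_per_group=60, shift=0.0, metric="m"):
    rows = []
    for g in (0, 1, 2):
        vals = rng.normal(g * shift, 1.0, n_per_group)
        for v in vals:
            rows.append({metric: v, "ternary_group": g})
    return pd.DataFrame(rows)


class TestGroupDifferences:
    def test_parametric_pathway_on_gaussian_data(self):
        rng = np.random.default_rng(0)
        out = group_difference_tests(make_table(rng), "m")
        assert out["pathway"].iloc[0] == "anova_tukey"
        assert len(out) == 3  # three pairwise comparisons

    def test_rank_pathway_on_skewed_data(self):
        rng = np.random.default_rng(1)
        t = make_table(rng)
        t["m"] = np.exp(t["m"] * 2)  # lognormal: fails Shapiro
        out = group_difference_tests(t, "m")
        assert out["pathway"].iloc[0] == "kruskal_dunn_holm"

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(2)
        out = group_difference_tests(make_table(rng, shift=1.0), "m")
        assert (out["p_adj"] < 0.01).all()

    def test_null_type_one_rate_controlled(self):
        rejections = 0
        n_reps = 120
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            out = group_difference_tests(make_table(rng, n_per_group=40), "m")
            rejections += int((out["p_adj"] < 0.05).any())
        # familywise rate should be near alpha; allow binomial slack
        assert rejections / n_reps <= 0.10

    def test_bonferroni_factor_multiplies(self):
        rng = np.random.default_rng(3)
        t = make_table(rng)
        p1 = group_difference_tests(t, "m", bonferroni_factor=1)
        p9 = group_difference_tests(t, "m", bonferroni_factor=9)
        np.testing.assert_allclose(
            p9["p_adj_bonferroni"], np.minimum(1.0, p1["p_adj_bonferroni"] * 9))

    def test_dunn_matches_kruskal_direction(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        g = np.repeat([0, 1], 50)
        out = dunn_test(x, g)
        assert out["p_adj"].iloc[0] < 1e-6

    def test_tiny_group_rejected(self):
        t = pd.DataFrame({"m": [1.0, 2.0, 3.0], "ternary_group": [0, 1, 1]})
        with pytest.raises(DataError):
            group_difference_tests(t, "m")


def simulate_zip_table(rng, n=800, beta_metric=0.5, gamma_metric=0.8):
    metric = rng.normal(0, 1, n)
    age = rng.normal(0, 1, n)
    sex = rng.integers(0, 2, n)
    diabetes = rng.integers(0, 2, n)
    eta_count = 2.0 + beta_metric * metric + 0.1 * age - 0.2 * sex + 0.3 * diabetes
    eta_infl = -1.0 + gamma_metric * metric + 0.2 * age
    p_zero = 1.0 / (1.0 + np.exp(-eta_infl))
    gs = np.where(rng.uniform(size=n) < p_zero, 0, rng.poisson(np.exp(eta_count)))
    return pd.DataFrame({"m": metric, "age_y": age, "sex": sex,
                         "diabetes": diabetes, "gs": gs})


class TestZip:
    def test_recovers_known_coefficients(self):
        # coverage-style check: the 2-SE interval should capture the truth
        # in most replicates (a single draw misses ~5% of the time)
        hits_count, hits_infl = 0, 0
        n_reps = 5
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            coefs = fit_zip(simulate_zip_table(rng, n=1500), "m")
            count_m = coefs[(coefs.part == "count") & (coefs.term == "m")].iloc[0]
            infl_m = coefs[(coefs.part == "inflate") & (coefs.term == "m")].iloc[0]
            hits_count += int(abs(count_m.coef - 0.5) <= 2 * count_m.se)
            hits_infl += int(abs(infl_m.coef - 0.8) <= 2 * infl_m.se)
        assert hits_count >= n_reps - 1
        assert hits_infl >= n_reps - 1

    def test_all_zero_outcome_falls_back_to_poisson(self):
        rng = np.random.default_rng(11)
        t = simulate_zip_table(rng, n=100)
        t["gs"] = np.maximum(t["gs"], 1)  # no zeros at all
        with pytest.warns(UserWarning, match="plain Poisson"):
            coefs = fit_zip(t, "m")
        assert set(coefs["part"]) == {"count"}

    def test_constant_metric_is_uninformative(self):
        rng = np.random.default_rng(12)
        t = simulate_zip_table(rng, n=600, beta_metric=0.5)
        t["m"] = 1.0
        coefs = fit_zip(t, "m")
        row = coefs[(coefs.part == "count") & (coefs.term == "m")].iloc[0]
        assert abs(row.coef) < 3 * max(row.se, 1e-3) or not np.isfinite(row.se)

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(DataError):
            fit_zip(simulate_zip_table(rng, n=10), "m")


def make_cv_table(rng, n=240, signal=0.0):
    gs = np.where(rng.uniform(size=n) < 0.4, 0.0, rng.poisson(30, n).astype(float))
    binary = np.where(gs <= 3, 0, np.where(gs > 14, 1, -1))
    ternary = np.where(gs <= 3, 0, np.where(gs <= 31, 1, 2))
    return pd.DataFrame({
        "age_y": rng.normal(60, 10, n),
        "sex": rng.integers(0, 2, n),
        "m": rng.normal(0, 1, n) + signal * ternary,
        "binary_group": binary,
        "ternary_group": ternary,
        "gs": gs,
    })


class TestPredictCv:
    def test_null_metric_auc_near_chance(self):
        aucs = [predict_cv(make_cv_table(np.random.default_rng(100 + s)),
                           "m", task="binary", seed=s).mean_auc
                for s in range(8)]
        assert 0.4 < np.mean(aucs) < 0.6

    def test_separable_metric_reaches_perfect_auc(self):
        rng = np.random.default_rng(20)
        t = make_cv_table(rng)
        t["m"] = 2.0 ** t["ternary_group"]  # noiseless monotone transform
        res = predict_cv(t, "m", task="ternary", seed=0)
        assert all(a == pytest.approx(1.0) for a in res.fold_aucs)

    def test_smote_points_never_in_test_folds(self):
        rng = np.random.default_rng(21)
        t = make_cv_table(rng, signal=0.5)
        res = predict_cv(t, "m", task="binary", seed=3)
        sub = t[t["binary_group"].isin([0, 1])]
        all_test = [i for d in res.fold_details for i in d["test_indices"]]
        assert sorted(all_test) == sorted(sub.index)  # partition of originals
        assert len(set(all_test)) == len(all_test)
        assert any(d["n_train_synthetic"] > 0 for d in res.fold_details)
        for d in res.fold_details:
            assert d["n_test"] + d["n_train_original"] == len(sub)

    def test_deterministic_per_seed(self):
        t = make_cv_table(np.random.default_rng(22), signal=0.3)
        r1 = predict_cv(t, "m", task="binary", seed=5)
        r2 = predict_cv(t, "m", task="binary", seed=5)
        assert r1.fold_aucs == r2.fold_aucs

    def test_metric_model_beats_baseline_on_signal(self):
        wins = 0
        t = make_cv_table(np.random.default_rng(23), signal=1.0)
        for s in range(10):
            with_m = predict_cv(t, "m", task="binary", seed=s).mean_auc
            base = predict_cv(t, None, task="binary", seed=s).mean_auc
            wins += int(with_m > base)
        assert wins >= 9

    def test_ordinal_variants_both_run(self):
        t = make_cv_table(np.random.default_rng(24), signal=0.8)
        for variant in ("cumulative", "immediate_threshold"):
            res = predict_cv(t, "m", task="ternary", seed=1,
                             ordinal_variant=variant)
            assert 0.5 < res.mean_auc <= 1.0

    def test_small_class_rejected(self):
        t = make_cv_table(np.random.default_rng(25), n=20)
        with pytest.raises(DataError):
            predict_cv(t, "m", task="ternary", seed=0)


class TestSmote:
    def test_balances_classes(self):
        rng = np.random.default_rng(30)
        X = rng.normal(size=(60, 3))
        y = np.array([0] * 50 + [1] * 10)
        Xr, yr, n_orig = smote(X, y, rng=rng)
        assert n_orig == 60
        assert (yr == 0).sum() == (yr == 1).sum() == 50
        np.testing.assert_array_equal(Xr[:60], X)  # originals kept in place

    def test_synthetic_points_in_minority_convex_hull_segments(self):
        rng = np.random.default_rng(31)
        X = np.column_stack([np.linspace(0, 1, 20), np.zeros(20)])
        y = np.array([0] * 15 + [1] * 5)
        Xr, yr, _ = smote(X, y, rng=rng)
        synth = Xr[20:]
        assert np.all(synth[:, 1] == 0)  # stays on the minority segment
        assert synth[:, 0].min() >= X[15:, 0].min() - 1e-12
        assert synth[:, 0].max() <= X[15:, 0].max() + 1e-12


class TestIntergrader:
    def test_identity_masks(self):
        m = np.zeros((32, 32), bool)
        m[8:20, 8:20] = True
        out = intergrader(m, m, [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["dice"] == 1.0 and out["jaccard"] == 1.0
        assert out["bland_altman"]["bias"] == 0.0

    def test_disjoint_masks(self):
        a = np.zeros((16, 16), bool)
        b = np.zeros((16, 16), bool)
        a[:4, :4] = True
        b[8:, 8:] = True
        dice, jaccard = dice_jaccard(a, b)
        assert dice == 0.0 and jaccard == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_dice_jaccard_algebraic_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(size=(40, 40)) > 0.5
        b = rng.uniform(size=(40, 40)) > 0.5
        dice, jaccard = dice_jaccard(a, b)
        assert dice == pytest.approx(2 * jaccard / (1 + jaccard), rel=1e-9)

    def test_mismatched_frames_rejected(self):
        with pytest.raises(DataError):
            dice_jaccard(np.zeros((4, 4), bool), np.zeros((5, 5), bool))

    def test_bland_altman_known_values(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.5, 2.5, 3.5, 4.5])
        out = bland_altman(a, b)
        assert out["bias"] == pytest.approx(-0.5)
        assert out["loa_low"] == pytest.approx(-0.5)  # zero spread
        assert out["loa_high"] == pytest.approx(-0.5)
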