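"""PLSR engine, repeated CV, permutation inference, covariate control, CPM."""

import numpy as np
import pytest

import connpredict as cp
from connpredict.exceptions import (
    CollinearityError,
    DegenerateTargetError,
    InsufficientDataError,
    InvalidParameterError,
    NoFeaturesError,
)
from connpredict.prediction import PermutationResult, _simpls


class TestSimpls:
    def test_univariate_equals_ols(self, rng):
        x = rng.standard_normal(40)
        y = 2.0 * x + rng.standard_normal(40)
        coef, intercept, _ = _simpls(x[:, None], y, 1)
        slope, b0 = np.polyfit(x, y, 1)
        assert np.isclose(coef[0], slope)
        assert np.isclose(intercept, b0)

    def test_exact_linear_recovery(self, rng):
        X = rng.standard_normal((30, 2))
        y = 2.0 * X[:, 0] - X[:, 1]
        res = cp.fit_plsr(X, y, 2)
        rmse = np.sqrt(np.mean((res.predict(X) - y) ** 2))
        assert rmse < 1e-8

    def test_matches_sklearn_nipals(self, rng):
        """SIMPLS and NIPALS PLS1 coincide for a single response."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((50, 20))
        y = X[:, :5].sum(axis=1) + rng.standard_normal(50)
        for a in (1, 4, 7):
            coef, intercept, _ = _simpls(X, y, a)
            sk = PLSRegression(n_components=a, scale=False).fit(X, y[:, None])
            assert np.allclose(coef, sk.coef_.ravel(), atol=1e-10)

    def test_component_bounds_and_constant_target(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(InvalidParameterError):
            _simpls(X, rng.standard_normal(10), 0)
        with pytest.raises(InvalidParameterError):
            _simpls(X, rng.standard_normal(10), 11)
        with pytest.raises(DegenerateTargetError):
            _simpls(X, np.ones(10), 1)

    def test_recovers_planted_signs(self, cohort60):
        """Fitted coefficients agree in sign with the planted loadings."""
        spec, phen, edges = cohort60
        model = cp.ConnectomePLS.from_dataframe(phen, edges, "age")
        res = model.fit()  # default inner-CV component selection
        beta_age = spec.edge_effect_map[:, 0]
        effect = beta_age != 0
        agree = np.mean(np.sign(res.params[effect]) == np.sign(beta_age[effect]))
        assert agree >= 0.8


class TestAccuracyMetrics:
    def test_identity_prediction(self):
        r, r2, rmse = cp.accuracy_metrics([1, 2, 3, 4], [1, 2, 3, 4])
        assert (r, r2, rmse) == (1.0, 1.0, 0.0)

    def test_mean_predictor_has_zero_r2(self):
        actual = np.array([1.0, 2.0, 3.0, 4.0])
        _, r2, _ = cp.accuracy_metrics(actual, np.full(4, actual.mean()))
        assert np.isclose(r2, 0.0)

    def test_hand_computed_example(self):
        r, r2, rmse = cp.accuracy_metrics(
            [1, 2, 3, 4], [1.5, 1.5, 3.5, 3.5]
        )
        assert np.isclose(r, 2 / np.sqrt(5), atol=1e-3)  # ≈ 0.894
        assert np.isclose(r2, 0.8)
        assert np.isclose(rmse, 0.5)

    def test_constant_actual_rejected(self):
        with pytest.raises(DegenerateTargetError):
            cp.accuracy_metrics([1, 1, 1], [1, 2, 3])


class TestRepeatedCV:
    def test_fold_map_count(self, rng):
        X = rng.standard_normal((60, 15))
        y = X[:, 0] + rng.standard_normal(60)
        cv = cp.ConnectomePLS(y, X).fit_repeated_cv(
            folds=10, reps=20, n_components=2, seed=0
        )
        assert cv.fold_weight_maps.shape == (200, 15)
        assert cv.rep_r.shape == (20,)

    def test_null_target_gives_near_zero_accuracy(self, rng):
        X = rng.standard_normal((200, 30))
        y = rng.standard_normal(200)  # independent of X
        cv = cp.ConnectomePLS(y, X).fit_repeated_cv(
            folds=10, reps=10, n_components=3, seed=1
        )
        assert abs(cv.mean_r) < 0.1

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((40, 10))
        y = X[:, 0] + rng.standard_normal(40)
        m = cp.ConnectomePLS(y, X)
        a = m.fit_repeated_cv(folds=5, reps=3, n_components=2, seed=42)
        b = m.fit_repeated_cv(folds=5, reps=3, n_components=2, seed=42)
        assert np.array_equal(a.rep_r, b.rep_r)
        assert np.array_equal(a.fold_weight_maps, b.fold_weight_maps)

    def test_insufficient_subjects(self, rng):
        X = rng.standard_normal((15, 5))
        y = rng.standard_normal(15)
        with pytest.raises(InsufficientDataError):
            cp.ConnectomePLS(y, X).fit_repeated_cv(folds=10, reps=1)

    def test_training_untouched_by_test_fold_targets(self, rng):
        """Leakage guard: shuffling a held-out fold's targets cannot change
        the coefficients learned on the training folds."""
        X = rng.standard_normal((50, 8))
        y = X[:, 0] + rng.standard_normal(50)
        test_idx = np.arange(10)
        train_idx = np.arange(10, 50)
        coef1, _, _ = _simpls(X[train_idx], y[train_idx], 2)
        y_mod = y.copy()
        y_mod[test_idx] = rng.permutation(y_mod[test_idx])
        coef2, _, _ = _simpls(X[train_idx], y_mod[train_idx], 2)
        assert np.array_equal(coef1, coef2)

    def test_accuracy_improves_as_noise_vanishes(self, atlas40):
        rs = []
        for noise in (1.0, 0.25, 0.0):
            spec = cp.default_spec(atlas40, 100, noise_sd=noise, seed=3)
            phen, edges = cp.simulate_cohort(spec)
            cv = cp.ConnectomePLS.from_dataframe(phen, edges, "age").fit_repeated_cv(
                folds=5, reps=2, n_components=5, seed=0
            )
            rs.append(cv.mean_r)
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] > 0.999


class TestPermutation:
    def test_p_floor_formula(self):
        res = PermutationResult(
            observed=1.0, null_values=np.zeros(5000), n_perm=5000, reps_per_perm=1
        )
        assert res.p_value == 1 / 5001
        assert res.p_value <= 2.0e-4

    def test_p_is_one_when_observed_below_all_nulls(self):
        res = PermutationResult(
            observed=-1.0, null_values=np.zeros(100), n_perm=100, reps_per_perm=1
        )
        assert res.p_value == 1.0

    def test_p_counting(self):
        null = np.concatenate([np.full(49, 2.0), np.full(950, -1.0)])
        res = PermutationResult(
            observed=1.0, null_values=null, n_perm=999, reps_per_perm=1
        )
        assert np.isclose(res.p_value, 0.05)

    def test_signal_detected(self, rng):
        X = rng.standard_normal((80, 10))
        y = X[:, 0] * 2 + rng.standard_normal(80) * 0.3
        perm = cp.ConnectomePLS(y, X).permutation_test(
            n_perm=99, folds=5, n_components=2, seed=0
        )
        assert perm.p_value == 1 / 100

    def test_nperm_validation(self, rng):
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        with pytest.raises(InvalidParameterError):
            cp.ConnectomePLS(y, X).permutation_test(n_perm=0)


class TestPartialAccuracy:
    def test_orthogonal_covariate_leaves_r_unchanged(self, rng):
        n = 400
        a = rng.standard_normal(n)
        b = a + rng.standard_normal(n)
        c = rng.standard_normal(n)
        # orthogonalize the covariate against both vectors exactly
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), a, b]))
        c = c - q @ (q.T @ c)
        r_plain = np.corrcoef(a, b)[0, 1]
        r_part, _ = cp.partial_accuracy(a, b, c)
        assert abs(r_part - r_plain) < 1e-10

    def test_fully_explained_prediction(self, rng):
        n = 50
        cov = rng.standard_normal(n)
        actual = rng.standard_normal(n)
        r, p = cp.partial_accuracy(actual, cov.copy(), cov)
        assert abs(r) < 1e-6

    def test_matches_two_stage_residual_oracle(self):
        actual = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 4.0])
        predicted = np.array([1.2, 1.8, 1.9, 2.5, 3.0, 3.6])
        cov = np.array([0.1, 0.4, 0.3, 0.9, 0.7, 1.0])
        design = np.column_stack([np.ones(6), cov])

        def resid(v):
            beta, *_ = np.linalg.lstsq(design, v, rcond=None)
            return v - design @ beta

        oracle = np.corrcoef(resid(actual), resid(predicted))[0, 1]
        r, _ = cp.partial_accuracy(actual, predicted, cov)
        assert abs(r - oracle) < 1e-12

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n = 60
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(n),
                "y": rng.standard_normal(n),
                "c": rng.standard_normal(n),
            }
        )
        ref = pingouin.partial_corr(df, x="x", y="y", covar="c")
        r, p = cp.partial_accuracy(df.x, df.y, df.c)
        assert np.isclose(r, ref["r"].iloc[0], atol=1e-10)
        assert np.isclose(p, ref["p_val"].iloc[0], atol=1e-8)

    def test_rank_deficient_covariates_rejected(self, rng):
        v = rng.standard_normal(20)
        cov = np.column_stack([v, v])
        with pytest.raises(CollinearityError):
            cp.partial_accuracy(rng.standard_normal(20),
                                rng.standard_normal(20), cov)


class TestCovariateScreen:
    def test_covariate_duplicate_edge_excluded(self, rng):
        n = 200
        cov = rng.standard_normal(n)
        y = cov + rng.standard_normal(n)
        X = np.column_stack([
            cov,                               # pure covariate copy
            rng.standard_normal(n) + 0.8 * y,  # genuine signal
        ])
        mask = cp.screen_out_covariate_edges(X, y, cov, alpha=0.05)
        assert not mask[0]
        assert mask[1]

    def test_planted_cog_edge_retained(self):
        emap = np.zeros((cp.n_edges(4), 2))
        emap[1, 1] = 0.5
        spec = cp.SyntheticSpec(
            n_subjects=300, n_nodes=4, network_sizes=(2, 2),
            edge_effect_map=emap, confound_slope=0.0, noise_sd=0.5, seed=6,
        )
        phen, edges = cp.simulate_cohort(spec)
        mask = cp.screen_out_covariate_edges(
            edges, phen.gF.to_numpy(), phen.age.to_numpy()
        )
        assert mask[1]

    def test_vacuous_alpha_keeps_everything(self, rng):
        X = rng.standard_normal((50, 6))
        y = rng.standard_normal(50)
        mask = cp.screen_out_covariate_edges(X, y, rng.standard_normal(50),
                                             alpha=1.0)
        assert mask.all()

    def test_no_features_is_an_error(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        with pytest.raises(NoFeaturesError):
            cp.screen_out_covariate_edges(X, y, rng.standard_normal(30),
                                          alpha=1e-12)


class TestCPM:
    def test_single_informative_edge(self, rng):
        n = 100
        x = rng.standard_normal(n)
        y = 2 * x + rng.standard_normal(n) * 0.1
        X = np.column_stack([x, rng.standard_normal(n)])
        res = cp.cpm_fit_predict(X[:80], y[:80], X[80:], p_threshold=0.01)
        assert res.positive_edges.tolist() == [0]
        assert res.negative_edges.size == 0
        assert np.corrcoef(res.predictions, y[80:])[0, 1] > 0.9

    def test_vacuous_threshold_partitions_by_sign(self, rng):
        n = 40
        x = rng.standard_normal(n)
        y = x + rng.standard_normal(n) * 0.5
        X = np.column_stack([x, -x + rng.standard_normal(n) * 0.2])
        res = cp.cpm_fit_predict(X, y, X, p_threshold=1.0)
        assert set(res.positive_edges) | set(res.negative_edges) == {0, 1}
        assert set(res.positive_edges) & set(res.negative_edges) == set()

    def test_selected_signs_match_planted_effects(self, cohort60):
        spec, phen, edges = cohort60
        y = phen.age.to_numpy()
        res = cp.cpm_fit_predict(edges[:250], y[:250], edges[250:],
                                 p_threshold=0.01)
        beta_age = spec.edge_effect_map[:, 0]
        sel = np.concatenate([res.positive_edges, res.negative_edges])
        sel_signs = np.concatenate([
            np.ones_like(res.positive_edges),
            -np.ones_like(res.negative_edges),
        ])
        nonzero = beta_age[sel] != 0
        agree = np.mean(np.sign(beta_age[sel][nonzero]) == sel_signs[nonzero])
        assert agree >= 0.8

    def test_no_feature_error(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        with pytest.raises(NoFeaturesError):
            cp.cpm_fit_predict(X, y, X, p_threshold=1e-10)

    def test_cpm_and_plsr_agree_at_network_level(self, cohort60, atlas60):
        """The two model families highlight the same network pattern: their
        network-level weight summaries correlate positively."""
        from connpredict.interpretation import WeightMap

        _, phen, edges = cohort60
        y = phen.age.to_numpy()
        plsr = cp.ConnectomePLS.from_dataframe(phen, edges, "age").fit(
            n_components=1
        )
        res = cp.cpm_fit_predict(edges, y, edges, p_threshold=0.01)
        cpm_map = np.zeros(edges.shape[1])
        cpm_map[res.positive_edges] = 1.0
        cpm_map[res.negative_edges] = -1.0
        _, plsr_net = cp.network_summary(
            WeightMap("connection", plsr.params), atlas60
        )
        _, cpm_net = cp.network_summary(
            WeightMap("connection", cpm_map), atlas60
        )
        assert np.corrcoef(plsr_net.values, cpm_net.values)[0, 1] > 0.5


class TestMotionFilter:
    def test_strict_inequality(self):
        import pandas as pd

        df = pd.DataFrame({"subject_id": list("abc"),
                           "mean_fd": [0.1, 0.15, 0.3]})
        out = cp.filter_by_motion(df, 0.15)
        assert out.subject_id.tolist() == ["a"]

    def test_infinite_threshold_is_identity(self, cohort60):
        _, phen, _ = cohort60
        out = cp.filter_by_motion(phen, np.inf)
        assert out.equals(phen)

    def test_median_split_count(self, cohort60):
        _, phen, _ = cohort60
        med = phen.mean_fd.median()
        out = cp.filter_by_motion(phen, med)
        assert len(out) in (len(phen) // 2, (len(phen) + 1) // 2)

    def test_empty_result_warns(self):
        import pandas as pd

        df = pd.DataFrame({"subject_id": ["a"], "mean_fd": [0.5]})
        with pytest.warns(UserWarning):
            cp.filter_by_motion(df, 0.1)
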