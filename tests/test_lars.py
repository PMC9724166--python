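"""LARS-lasso path solver: closed-form, oracle and property checks."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Lasso

from beachcast.lars import LarsPath, LarsStep, lars_fit, mallows_cp, select_min_cp

from conftest import orthonormal_design, standardized_design


def soft_threshold(ols: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(ols) * np.maximum(np.abs(ols) - thr, 0.0)


class TestPathStructure:
    def test_single_covariate_gives_null_then_ols(self):
        X = standardized_design(0, 25, 1)
        rng = np.random.default_rng(1)
        y = 3.0 + 0.8 * X[:, 0] + rng.normal(0, 0.1, 25)
        path = lars_fit(X, y)
        assert len(path.steps) == 2
        assert path.steps[0].active == []
        ols = float(np.linalg.lstsq(X, y - y.mean(), rcond=None)[0][0])
        assert path.steps[1].coef[0] == pytest.approx(ols, abs=1e-10)

    def test_active_set_changes_by_one_and_rss_non_increasing(self):
        X = standardized_design(3, 50, 8)
        rng = np.random.default_rng(4)
        y = X[:, 0] - 0.5 * X[:, 1] + rng.normal(0, 0.3, 50)
        path = lars_fit(X, y)
        for prev, cur in zip(path.steps, path.steps[1:]):
            assert len(set(prev.active) ^ set(cur.active)) == 1
            assert cur.rss <= prev.rss + 1e-10

    def test_first_entrant_has_largest_absolute_correlation(self):
        X = standardized_design(5, 60, 6)
        rng = np.random.default_rng(6)
        y = 0.9 * X[:, 4] + rng.normal(0, 0.5, 60)
        path = lars_fit(X, y)
        cors = np.abs(X.T @ (y - y.mean()))
        assert path.steps[1].active == [str(int(np.argmax(cors)))]

    def test_final_step_equals_ols_when_overdetermined(self):
        X = standardized_design(8, 45, 7)
        rng = np.random.default_rng(9)
        y = X @ rng.normal(0, 1, 7) + rng.normal(0, 0.4, 45)
        path = lars_fit(X, y)
        ols = np.linalg.lstsq(X, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(path.steps[-1].coef, ols, atol=1e-8)

    def test_sign_consistency_along_path(self):
        """Each active coefficient's sign matches its residual correlation."""
        X = standardized_design(11, 80, 6)
        rng = np.random.default_rng(12)
        y = X @ np.array([1.0, -0.8, 0.5, 0, 0, 0]) + rng.normal(0, 0.4, 80)
        path = lars_fit(X, y)
        yc = y - y.mean()
        for prev, cur in zip(path.steps[:-1], path.steps[1:]):
            # evaluate mid-segment, where strict sign agreement holds
            mid = (prev.coef + cur.coef) / 2
            c = X.T @ (yc - X @ mid)
            for j in np.nonzero(mid)[0]:
                assert np.sign(mid[j]) == np.sign(c[j])

    def test_rejects_non_standardized_input(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 3)) * 5 + 2
        with pytest.raises(ValueError, match="not standardized"):
            lars_fit(X, rng.standard_normal(20))

    def test_duplicate_column_skipped_with_warning(self, caplog):
        X = standardized_design(2, 30, 3)
        X = np.column_stack([X, X[:, 0]])  # exact duplicate -> singular Gram
        y = 1.0 * X[:, 0] + np.random.default_rng(3).normal(0, 0.2, 30)
        with caplog.at_level("WARNING", logger="beachcast.lars"):
            path = lars_fit(X, y, check_standardized=False)
        assert any("rank-deficient" in r.message for r in caplog.records)
        assert all(np.isfinite(s.rss) for s in path.steps)


class TestSoftThresholdEquivalence:
    def test_orthonormal_path_matches_closed_form(self):
        """On an orthogonal design the lasso is coordinatewise
        soft-thresholding of OLS at the current correlation level."""
        n, p = 40, 5
        X = orthonormal_design(13, n, p)
        rng = np.random.default_rng(14)
        y = X @ np.array([1.0, -0.7, 0.4, 0.15, 0.0]) + rng.normal(0, 0.3, n)
        yc = y - y.mean()
        ols = X.T @ yc / (n - 1)
        path = lars_fit(X, y)
        for step in path.steps[1:]:
            r = yc - X @ step.coef
            C = np.abs(X.T @ r).max()
            np.testing.assert_allclose(
                step.coef, soft_threshold(ols, C / (n - 1)), atol=1e-10
            )


class TestCoordinateDescentOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_interior_steps_match_cd_lasso_at_same_penalty(self, seed):
        """At every path breakpoint the KKT conditions pin the penalty
        level; an independent coordinate-descent solver at that penalty
        must return the same coefficients."""
        n, p = 30, 6
        X = standardized_design(100 + seed, n, p)
        rng = np.random.default_rng(200 + seed)
        y = X @ rng.normal(0, 1, p) + rng.normal(0, 0.5, n)
        yc = y - y.mean()
        path = lars_fit(X, y)
        for step in path.steps[1:-1]:
            C = np.abs(X.T @ (yc - X @ step.coef)).max()
            cd = Lasso(alpha=C / n, fit_intercept=False, tol=1e-14, max_iter=500000)
            cd.fit(X, yc)
            np.testing.assert_allclose(step.coef, cd.coef_, atol=1e-6)
            assert abs(np.abs(step.coef).sum() - np.abs(cd.coef_).sum()) < 1e-6


class TestMallowsCp:
    def test_full_model_cp_equals_p_plus_one(self):
        X = standardized_design(21, 50, 6)
        rng = np.random.default_rng(22)
        y = X @ rng.normal(0, 1, 6) + rng.normal(0, 0.5, 50)
        path = lars_fit(X, y)
        assert len(path.steps[-1].active) == 6
        assert path.steps[-1].cp == pytest.approx(7.0, abs=1e-8)

    def test_null_step_cp_expectation_near_one(self):
        """With the exact noise variance, E[Cp] of the null model is
        (n-1) - n + 2 = 1; Monte-Carlo over 10000 pure-noise draws
        (per-draw sd of Cp is sqrt(2(n-1)) ~ 6.9, so the mean carries a
        standard error of ~0.07; the bound is ~3.5 standard errors)."""
        rng = np.random.default_rng(30)
        n, sigma2 = 25, 1.0
        cps = []
        for _ in range(10000):
            y = rng.normal(0, np.sqrt(sigma2), n)
            rss0 = float(np.sum((y - y.mean()) ** 2))
            path = LarsPath(
                steps=[LarsStep(active=[], coef=np.zeros(1), rss=rss0)],
                sigma2_hat=sigma2, column_names=["x"], y_mean=float(y.mean()), n=n,
            )
            cps.append(mallows_cp(path, sigma2)[0])
        assert np.mean(cps) == pytest.approx(1.0, abs=0.25)

    def test_scaling_sigma2_scales_rss_term(self):
        X = standardized_design(23, 40, 4)
        y = X[:, 0] + np.random.default_rng(24).normal(0, 0.5, 40)
        path = lars_fit(X, y)
        cp1 = mallows_cp(path, 1.0).copy()
        cp2 = mallows_cp(path, 2.0)
        n = 40
        for s, a, b in zip(path.steps, cp1, cp2):
            df = len(s.active) + 1
            assert (a + n - 2 * df) == pytest.approx(2 * (b + n - 2 * df), rel=1e-10)


class TestSelection:
    def test_strictly_decreasing_cp_selects_last_step(self):
        path = LarsPath(
            steps=[LarsStep([], np.zeros(2), 10.0, cp=5.0),
                   LarsStep(["a"], np.array([1.0, 0]), 5.0, cp=3.0),
                   LarsStep(["a", "b"], np.array([1.0, 0.5]), 2.0, cp=1.0)],
            sigma2_hat=1.0, column_names=["a", "b"], y_mean=0.0, n=10,
        )
        assert path.selected_step == 2

    def test_cp_tie_breaks_toward_sparser_step(self):
        path = LarsPath(
            steps=[LarsStep([], np.zeros(1), 10.0, cp=2.0),
                   LarsStep(["a"], np.array([1.0]), 5.0, cp=2.0)],
            sigma2_hat=1.0, column_names=["a"], y_mean=0.0, n=10,
        )
        model = select_min_cp(path)
        assert path.selected_step == 0
        assert model.active_set == []
        assert (model.coefficients == 0).all()

    def test_inactive_coefficients_are_exact_zeros(self):
        X = standardized_design(31, 60, 8)
        rng = np.random.default_rng(32)
        y = 2.0 * X[:, 2] + rng.normal(0, 1.5, 60)
        model = select_min_cp(lars_fit(X, y))
        off = model.coefficients.drop(labels=model.active_set)
        assert (off == 0.0).all()

    def test_strong_signal_support_always_contained(self):
        """Minimum-Cp selection retains every strong true covariate."""
        hits = 0
        for seed in range(30):
            X = standardized_design(1000 + seed, 200, 10)
            rng = np.random.default_rng(3000 + seed)
            beta = np.zeros(10)
            beta[:3] = 1.0
            y = X @ beta + rng.normal(0, 0.2, 200)
            model = select_min_cp(lars_fit(X, y))
            hits += {"0", "1", "2"} <= set(model.active_set)
        assert hits == 30

    def test_pure_noise_null_model_modal_and_matches_independent_selector(self):
        """On pure noise the null model is the single most frequent
        minimum-Cp outcome, at the same rate as an independent lasso-path
        information-criterion selector run on the identical replicates."""
        from collections import Counter

        from sklearn.linear_model import LassoLarsIC

        sizes = []
        sk_null = 0
        for seed in range(60):
            X = standardized_design(2000 + seed, 200, 10)
            y = np.random.default_rng(4000 + seed).normal(0, 1.0, 200)
            sizes.append(len(select_min_cp(lars_fit(X, y)).active_set))
            sk_null += bool((LassoLarsIC(criterion="aic").fit(X, y).coef_ == 0).all())
        counts = Counter(sizes)
        assert counts[0] == max(counts.values())
        assert counts[0] >= 0.45 * len(sizes)
        assert counts[0] == sk_null  # agreement with the independent selector
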