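"""Stepwise selection, MANCOVA, CCA, k-means elbow, ANOVA/Tukey, BH."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.multivariate.manova import MANOVA

from facediet.stats import (
    anova_eta_squared,
    anova_tukey,
    bh_adjust,
    canonical_analysis,
    kmeans_elbow,
    mancova,
    partial_eta_squared,
    stepwise_select,
)


class TestStepwise:
    def test_perfect_predictor(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 3)), columns=["a", "b", "c"])
        fit = stepwise_select(X["b"].to_numpy(), X, alpha_in=0.05)
        assert fit.selected[0] == "b"
        assert fit.coefficients["b"] == pytest.approx(1.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_response_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 2)))
        with pytest.raises(ValueError, match="zero-variance"):
            stepwise_select(np.ones(20), X)

    def test_entry_pvalues_below_threshold(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 4)))
        y = X[0] * 0.8 + X[2] * 0.5 + rng.standard_normal(60) * 0.3
        fit = stepwise_select(y.to_numpy(), X, alpha_in=0.05)
        assert (fit.entry_pvalues < 0.05).all()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_selection_path_matches_exhaustive_oracle(self, seed):
        """At every forward step the entered term equals the best single
        addition found by exhaustive OLS refits."""
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.standard_normal((35, 3)), columns=list("abc"))
        y = 0.6 * X["a"].to_numpy() + 0.4 * X["c"].to_numpy() + rng.standard_normal(35)
        fit = stepwise_select(y, X, alpha_in=0.05)

        selected: list[str] = []
        while True:
            best, best_p = None, np.inf
            for col in X.columns:
                if col in selected:
                    continue
                design = sm.add_constant(X[selected + [col]])
                res = sm.OLS(y, design).fit()
                p = res.pvalues[col]
                if p < best_p:
                    best, best_p = col, p
            if best is None or best_p >= 0.05:
                break
            selected.append(best)
        assert fit.selected == selected


class TestMancova:
    def test_printed_effect_size_identity(self):
        assert partial_eta_squared(0.79, 1) == pytest.approx(0.21)

    def test_perfect_fit_limit(self, rng):
        X = rng.standard_normal((30, 2))
        Y = X @ (rng.standard_normal((2, 2)) + 2 * np.eye(2))
        res = mancova(Y + rng.standard_normal(Y.shape) * 1e-8, X)
        assert res.wilks_lambda < 1e-10

    def test_null_predictors_lambda_one(self, rng):
        Y = rng.standard_normal((25, 2))
        res = mancova(Y, np.zeros((25, 1)) + rng.standard_normal((25, 1)) * 0)
        # a zero predictor explains nothing in-sample
        assert res.wilks_lambda == pytest.approx(1.0, abs=1e-10)

    def test_wilks_matches_eigen_oracle(self, rng):
        """Wilks' lambda on a 12-row fixture equals the product
        1/(1+theta_i) over the eigenvalues of E^-1 H."""
        n, p, q = 12, 2, 2
        X = rng.standard_normal((n, q))
        Y = X @ np.array([[0.5, -0.2], [0.1, 0.4]]) + rng.standard_normal((n, p))
        res = mancova(Y, X)
        D = np.column_stack([np.ones(n), X])
        B = np.linalg.lstsq(D, Y, rcond=None)[0]
        E = (Y - D @ B).T @ (Y - D @ B)
        Yc = Y - Y.mean(axis=0)
        H = Yc.T @ Yc - E
        theta = np.linalg.eigvals(np.linalg.inv(E) @ H)
        lam = float(np.prod(1.0 / (1.0 + theta.real)))
        assert res.wilks_lambda == pytest.approx(lam, abs=1e-10)

    def test_per_predictor_matches_statsmodels(self, rng):
        n = 20
        X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["x1", "x2"])
        Y = pd.DataFrame(
            X.to_numpy() @ rng.standard_normal((2, 3)) * 0.5 + rng.standard_normal((n, 3)),
            columns=["y1", "y2", "y3"],
        )
        res = mancova(Y, X)
        mv = MANOVA(Y.to_numpy(), sm.add_constant(X).to_numpy())
        for j, name in enumerate(["x1", "x2"]):
            L = np.zeros((1, 3))
            L[0, j + 1] = 1.0
            tbl = mv.mv_test(hypotheses=[(name, L, None)])
            stat = tbl.results[name]["stat"]
            lam_sm = float(stat.loc["Wilks' lambda", "Value"])
            p_sm = float(stat.loc["Wilks' lambda", "Pr > F"])
            assert res.per_predictor.loc[name, "wilks_lambda"] == pytest.approx(lam_sm, abs=1e-8)
            assert res.per_predictor.loc[name, "p_value"] == pytest.approx(p_sm, abs=1e-8)

    def test_lambda_in_unit_interval(self, rng):
        Y = rng.standard_normal((30, 3))
        X = rng.standard_normal((30, 2))
        res = mancova(Y, X)
        assert 0 < res.wilks_lambda <= 1


class TestCanonical:
    def test_self_correlation(self, rng):
        X = rng.standard_normal((25, 3))
        res = canonical_analysis(X, X.copy())
        assert res.correlations[0] == pytest.approx(1.0, abs=1e-8)

    def test_bivariate_reduction(self, rng):
        x = rng.standard_normal(40)
        y = 0.6 * x + rng.standard_normal(40)
        res = canonical_analysis(x[:, None], y[:, None])
        assert res.correlations[0] == pytest.approx(abs(np.corrcoef(x, y)[0, 1]), abs=1e-10)

    def test_matches_eigen_oracle(self, rng):
        """Canonical correlations on a 12-row, 3x2 fixture equal the
        square roots of the eigenvalues of Sxx^-1 Sxy Syy^-1 Syx."""
        n = 12
        X = rng.standard_normal((n, 3))
        Y = X[:, :2] * 0.7 + rng.standard_normal((n, 2))
        res = canonical_analysis(X, Y)
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        Sxx, Syy = Xc.T @ Xc / (n - 1), Yc.T @ Yc / (n - 1)
        Sxy = Xc.T @ Yc / (n - 1)
        M = np.linalg.inv(Sxx) @ Sxy @ np.linalg.inv(Syy) @ Sxy.T
        r_oracle = np.sort(np.sqrt(np.clip(np.linalg.eigvals(M).real, 0, 1)))[::-1][:2]
        np.testing.assert_allclose(res.correlations, r_oracle, atol=1e-8)

    def test_affine_invariance(self, rng):
        X = rng.standard_normal((30, 3))
        Y = rng.standard_normal((30, 2))
        base = canonical_analysis(X, Y)
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        B = rng.standard_normal((2, 2)) + 3 * np.eye(2)
        trans = canonical_analysis(X @ A + 5.0, Y @ B - 2.0)
        np.testing.assert_allclose(base.correlations, trans.correlations, atol=1e-8)

    def test_canonical_scores_uncorrelated(self, rng):
        X = rng.standard_normal((50, 4))
        Y = rng.standard_normal((50, 3))
        res = canonical_analysis(X, Y)
        U = (X - X.mean(0)) @ res.x_weights
        C = np.corrcoef(U.T)
        np.testing.assert_allclose(C - np.diag(np.diag(C)), 0.0, atol=1e-8)

    def test_correlations_sorted_and_bounded(self, rng):
        X = rng.standard_normal((40, 5))
        Y = rng.standard_normal((40, 3))
        r = canonical_analysis(X, Y).correlations
        assert np.all(np.diff(r) <= 1e-12)
        assert np.all((r >= 0) & (r <= 1))


class TestKMeansElbow:
    def test_three_point_masses(self):
        centers = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        X = np.repeat(centers, 10, axis=0)
        res = kmeans_elbow(X, k_candidates=range(1, 6), seed=0)
        assert res.k == 3
        assert res.wss_curve[3] == pytest.approx(0.0, abs=1e-12)
        codes = res.codes.reshape(3, 10)
        assert all(len(set(row)) == 1 for row in codes)

    def test_seeded_determinism(self, rng):
        X = rng.standard_normal((60, 4))
        a = kmeans_elbow(X, seed=5)
        b = kmeans_elbow(X, seed=5)
        np.testing.assert_array_equal(a.codes, b.codes)
        assert a.k == b.k

    def test_wss_non_increasing(self, rng):
        X = rng.standard_normal((50, 3))
        res = kmeans_elbow(X, k_candidates=range(1, 7), seed=1)
        assert np.all(np.diff(res.wss_curve.to_numpy()) <= 1e-9)

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_elbow(rng.standard_normal((4, 2)), k_candidates=range(1, 7))


class TestAnovaTukey:
    def test_null_contrast(self):
        values = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        groups = np.array([1, 2, 1, 2, 1, 2])
        res = anova_tukey(values, groups)
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)

    def test_printed_eta_squared_identity(self):
        # eta^2 from F = 5.83 with df = (2, 104) is 0.1 at one decimal
        assert round(anova_eta_squared(5.83, 2, 104), 1) == 0.1

    def test_matches_scipy_tukey_oracle(self, rng):
        """F, eta^2 and all pairwise Tukey-Kramer p-values on a small
        unbalanced fixture match scipy's independent implementations."""
        groups = [rng.normal(0, 1, 5), rng.normal(0.8, 1, 7), rng.normal(-0.3, 1, 4)]
        values = np.concatenate(groups)
        labels = np.repeat([0, 1, 2], [5, 7, 4])
        res = anova_tukey(values, labels)
        F, p = sps.f_oneway(*groups)
        assert res.f_stat == pytest.approx(F, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        grand = values.mean()
        ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_t = np.sum((values - grand) ** 2)
        assert res.eta_sq == pytest.approx(ss_b / ss_t, abs=1e-10)
        hsd = sps.tukey_hsd(*groups)
        for _, row in res.pairwise.iterrows():
            i, j = int(row["group_i"]), int(row["group_j"])
            assert row["p_adj"] == pytest.approx(hsd.pvalue[i, j], abs=1e-8)

    def test_group_size_guard(self):
        with pytest.raises(ValueError, match="n >= 2"):
            anova_tukey(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 2]))


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.037]), [0.037])

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_ties_collapse(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(
        ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12)
    )
    def test_monotone_never_below_raw(self, ps):
        """Adjusted values respect the raw ordering, never drop below the
        raw p, stay within [0, 1], and match a hand-rolled step-up."""
        adj = bh_adjust(ps)
        p = np.asarray(ps)
        assert np.all(adj >= p - 1e-12)
        assert np.all((adj >= 0) & (adj <= 1))
        order = np.argsort(p, kind="mergesort")
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(stepped[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.clip(stepped, 0, 1)
        np.testing.assert_allclose(adj, oracle, atol=1e-12)
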