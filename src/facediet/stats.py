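"""The inferential chain linking nutrition and facial shape.

Forward stepwise regression of each nutritional/behavioral/body variable
on shape principal-component scores, MANCOVA (Wilks' lambda with Rao's F
approximation and partial eta-squared), canonical variate analysis with
sequential Wilks tests, k-means clustering with elbow model selection,
one-way ANOVA with Tukey-Kramer post-hoc comparisons for unequal group
sizes, and Benjamini-Hochberg false-discovery-rate control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClusterMixin, RegressorMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "StepwiseFit",
    "ForwardStepwiseRegressor",
    "stepwise_select",
    "MancovaResult",
    "mancova",
    "partial_eta_squared",
    "CanonicalResult",
    "canonical_analysis",
    "ClusterResult",
    "KMeansElbow",
    "kmeans_elbow",
    "AnovaResult",
    "anova_tukey",
    "anova_eta_squared",
    "bh_adjust",
]


# ---------------------------------------------------------------------------
# forward stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseFit:
    """Forward-selection result for one response variable."""

    response_name: str
    selected: list[str]
    coefficients: pd.Series      # includes "intercept"
    entry_pvalues: pd.Series     # partial-F p at the step each term entered
    alpha_in: float
    r_squared: float


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


class ForwardStepwiseRegressor(RegressorMixin, BaseEstimator):
    """Forward-only stepwise OLS with a partial-F entry test.

    At each step the candidate with the smallest partial-F p-value enters
    if that p-value is below ``alpha_in``; selection stops when no
    candidate qualifies.  No removal step is performed.  Candidates that
    are numerically collinear with the current model are dropped with a
    log message.
    """

    def __init__(self, alpha_in: float = 0.05):
        self.alpha_in = alpha_in

    def fit(self, X, y, response_name: str = "response"):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(Xa.shape[1])]
        y = np.asarray(y, dtype=float).ravel()
        n = y.shape[0]
        if Xa.shape[0] != n:
            raise ValueError("X and y length mismatch")
        if np.var(y) <= 0:
            raise ValueError("zero-variance response")

        selected: list[int] = []
        entry_p: dict[str, float] = {}
        ones = np.ones((n, 1))
        design = ones
        _, rss0 = _ols_rss(design, y)
        remaining = list(range(Xa.shape[1]))
        while remaining:
            df_new = n - (len(selected) + 2)
            if df_new < 1:
                break
            best_j, best_p = None, np.inf
            for j in remaining:
                cand = np.column_stack([design, Xa[:, j]])
                if np.linalg.matrix_rank(cand) < cand.shape[1]:
                    logger.info(
                        "dropping collinear candidate %s for %s", names[j], response_name
                    )
                    continue
                _, rss1 = _ols_rss(cand, y)
                if rss1 >= rss0:
                    p = 1.0
                else:
                    F = (rss0 - rss1) / (rss1 / df_new) if rss1 > 0 else np.inf
                    p = float(sps.f.sf(F, 1, df_new))
                if p < best_p:
                    best_p, best_j = p, j
            if best_j is None or best_p >= self.alpha_in:
                break
            selected.append(best_j)
            remaining.remove(best_j)
            entry_p[names[best_j]] = best_p
            design = np.column_stack([design, Xa[:, best_j]])
            _, rss0 = _ols_rss(design, y)

        beta, rss = _ols_rss(design, y)
        tss = float(np.sum((y - y.mean()) ** 2))
        self.selected_ = [names[j] for j in selected]
        self.selected_idx_ = list(selected)
        self.intercept_ = float(beta[0])
        self.coef_ = np.asarray(beta[1:], dtype=float)
        self.entry_pvalues_ = pd.Series(entry_p, dtype=float)
        self.r_squared_ = 1.0 - rss / tss if tss > 0 else 0.0
        self.response_name_ = response_name
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return self.intercept_ + Xa[:, self.selected_idx_] @ self.coef_

    def to_result(self) -> StepwiseFit:
        check_is_fitted(self, "coef_")
        coefs = pd.Series(
            {"intercept": self.intercept_, **dict(zip(self.selected_, self.coef_))}
        )
        return StepwiseFit(
            self.response_name_, list(self.selected_), coefs,
            self.entry_pvalues_, self.alpha_in, self.r_squared_,
        )


def stepwise_select(
    response, candidates, alpha_in: float = 0.05, response_name: str = "response"
) -> StepwiseFit:
    """Forward stepwise selection; returns the fitted summary."""
    model = ForwardStepwiseRegressor(alpha_in=alpha_in)
    model.fit(candidates, response, response_name=response_name)
    return model.to_result()


# ---------------------------------------------------------------------------
# MANCOVA
# ---------------------------------------------------------------------------

def partial_eta_squared(wilks_lambda: float, n_roots: int = 1) -> float:
    """Multivariate effect size 1 - lambda^(1/s) for an s-root effect."""
    if not (0 < wilks_lambda <= 1):
        raise ValueError("Wilks' lambda must be in (0, 1]")
    if n_roots < 1:
        raise ValueError("number of roots must be >= 1")
    return 1.0 - wilks_lambda ** (1.0 / n_roots)


def _rao_f(lam: float, p: int, q: int, n: int) -> tuple[float, float, float, float]:
    """Rao's F approximation for Wilks' lambda with p responses and q
    hypothesis df at sample size n (intercept included in the model)."""
    num = p * p * q * q - 4
    den = p * p + q * q - 5
    t = np.sqrt(num / den) if den > 0 else 1.0
    w = n - 1 - (p + q + 1) / 2.0
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    F = np.inf if lam_t == 0 else (1 - lam_t) / lam_t * df2 / df1
    pval = float(sps.f.sf(F, df1, df2))
    return float(F), float(df1), float(df2), pval


@dataclass
class MancovaResult:
    """Overall multivariate test with per-predictor breakdown."""

    wilks_lambda: float
    f_stat: float
    df1: float
    df2: float
    p_value: float
    partial_eta_sq: float
    coefficients: pd.DataFrame          # responses x predictors
    per_predictor: pd.DataFrame = field(default_factory=pd.DataFrame)


def mancova(responses, predictors) -> MancovaResult:
    """Multivariate regression of several responses on shared predictors.

    Wilks' lambda is the determinant ratio of the residual to the total
    (intercept-adjusted) cross-product matrix; partial eta-squared is
    ``1 - lambda^(1/s)`` with s = min(p, q) roots.  Per-predictor tests
    drop one predictor at a time (single-root Wilks tests).
    """
    Y = responses.to_numpy(float) if isinstance(responses, pd.DataFrame) else np.asarray(responses, float)
    X = predictors.to_numpy(float) if isinstance(predictors, pd.DataFrame) else np.asarray(predictors, float)
    resp_names = (
        [str(c) for c in responses.columns]
        if isinstance(responses, pd.DataFrame)
        else [f"y{i}" for i in range(Y.shape[1])]
    )
    pred_names = (
        [str(c) for c in predictors.columns]
        if isinstance(predictors, pd.DataFrame)
        else [f"x{i}" for i in range(X.shape[1])]
    )
    n, p = Y.shape
    q = X.shape[1]
    if n <= p + q + 1:
        raise ValueError("too few observations for the MANCOVA design")

    def _sscp_resid(design: np.ndarray) -> np.ndarray:
        beta, _, _, _ = np.linalg.lstsq(design, Y, rcond=None)
        R = Y - design @ beta
        return R.T @ R

    ones = np.ones((n, 1))
    full = np.column_stack([ones, X])
    E = _sscp_resid(full)
    T = _sscp_resid(ones)
    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_t <= 0:
        raise ValueError("singular total cross-product matrix")
    if sign_e <= 0 or not np.isfinite(logdet_e):
        # zero-residual (perfect-fit) limit
        lam, logdet_e = 0.0, -np.inf
    else:
        lam = min(float(np.exp(logdet_e - logdet_t)), 1.0)
    F, df1, df2, pval = _rao_f(lam, p, q, n)
    s = min(p, q)
    beta, _, _, _ = np.linalg.lstsq(full, Y, rcond=None)
    coefs = pd.DataFrame(beta[1:].T, index=resp_names, columns=pred_names)

    rows = []
    for j in range(q):
        reduced = np.delete(full, j + 1, axis=1)
        Ej = _sscp_resid(reduced)
        lam_j = float(np.exp(logdet_e - np.linalg.slogdet(Ej)[1]))
        lam_j = min(lam_j, 1.0)
        Fj, d1j, d2j, pj = _rao_f(lam_j, p, 1, n - (q - 1))
        rows.append(
            {
                "predictor": pred_names[j], "wilks_lambda": lam_j, "f_stat": Fj,
                "df1": d1j, "df2": d2j, "p_value": pj,
                "partial_eta_sq": 1.0 if lam_j == 0 else partial_eta_squared(lam_j, 1),
            }
        )
    return MancovaResult(
        lam, F, df1, df2, pval,
        1.0 if lam == 0 else partial_eta_squared(lam, s), coefs,
        pd.DataFrame(rows).set_index("predictor") if rows else pd.DataFrame(),
    )


# ---------------------------------------------------------------------------
# canonical variate analysis
# ---------------------------------------------------------------------------

@dataclass
class CanonicalResult:
    """Canonical correlations with sequential Wilks significance tests."""

    correlations: np.ndarray     # r_1 >= r_2 >= ... in [0, 1]
    x_weights: np.ndarray        # (p, s) left (e.g. nutrition, U) coefficients
    y_weights: np.ndarray        # (q, s) right (e.g. face, V) coefficients
    wilks: np.ndarray            # sequential lambda for roots k..s
    f_stats: np.ndarray
    df1: np.ndarray
    df2: np.ndarray
    p_values: np.ndarray
    x_names: list[str] = field(default_factory=list)
    y_names: list[str] = field(default_factory=list)


def _principal_subspace(Z: np.ndarray, names: list[str], side: str):
    """Drop near-null directions of a centered matrix; returns the basis."""
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    tol = s.max() * max(Z.shape) * np.finfo(float).eps if s.size else 0.0
    r = int(np.sum(s > tol))
    if r < Z.shape[1]:
        logger.info("%s side rank-deficient: reduced from %d to %d", side, Z.shape[1], r)
    return Vt[:r].T  # (d, r)


def canonical_analysis(left, right) -> CanonicalResult:
    """Canonical correlation analysis via whitened cross-covariance SVD.

    Rank-deficient sides are reduced to their principal subspace (with a
    log message); weights are reported in the original coordinates.
    Significance of each root is tested sequentially with Wilks' lambda
    over the remaining roots and Rao's F approximation.
    """
    X = left.to_numpy(float) if isinstance(left, pd.DataFrame) else np.asarray(left, float)
    Y = right.to_numpy(float) if isinstance(right, pd.DataFrame) else np.asarray(right, float)
    x_names = [str(c) for c in left.columns] if isinstance(left, pd.DataFrame) else [f"x{i}" for i in range(X.shape[1])]
    y_names = [str(c) for c in right.columns] if isinstance(right, pd.DataFrame) else [f"y{i}" for i in range(Y.shape[1])]
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("left and right must have the same number of rows")
    if n <= max(X.shape[1], Y.shape[1]) + 1:
        raise ValueError("too few observations for canonical analysis")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Bx = _principal_subspace(Xc, x_names, "left")
    By = _principal_subspace(Yc, y_names, "right")
    Xr, Yr = Xc @ Bx, Yc @ By
    p, q = Xr.shape[1], Yr.shape[1]

    Sxx = Xr.T @ Xr / (n - 1)
    Syy = Yr.T @ Yr / (n - 1)
    Sxy = Xr.T @ Yr / (n - 1)

    def _inv_sqrt(S: np.ndarray) -> np.ndarray:
        w, V = np.linalg.eigh(S)
        w = np.clip(w, np.finfo(float).tiny, None)
        return V @ np.diag(1.0 / np.sqrt(w)) @ V.T

    Wx, Wy = _inv_sqrt(Sxx), _inv_sqrt(Syy)
    U, svals, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    s = min(p, q)
    r = np.clip(svals[:s], 0.0, 1.0)
    A = Bx @ (Wx @ U[:, :s])
    B = By @ (Wy @ Vt[:s].T)

    wilks = np.array([np.prod(1.0 - r[k:] ** 2) for k in range(s)])
    f_stats = np.empty(s)
    df1 = np.empty(s)
    df2 = np.empty(s)
    pvals = np.empty(s)
    for k in range(s):
        pk, qk = p - k, q - k
        f_stats[k], df1[k], df2[k], pvals[k] = _rao_f(float(wilks[k]), pk, qk, n - k)
    return CanonicalResult(r, A, B, wilks, f_stats, df1, df2, pvals, x_names, y_names)


# ---------------------------------------------------------------------------
# k-means with elbow selection
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Chosen k, 1-based codes, centroids, and the WSS curve."""

    k: int
    codes: np.ndarray            # 1..k per subject
    centroids: np.ndarray
    wss_curve: pd.Series         # indexed by candidate k


class KMeansElbow(ClusterMixin, BaseEstimator):
    """Seeded Lloyd k-means over candidate k with elbow selection.

    For every candidate k, the best of ``n_restarts`` seeded restarts is
    kept; the chosen k maximizes the second difference of the
    within-cluster sum-of-squares curve (the sharpest bend), evaluated at
    the interior candidates.
    """

    def __init__(self, k_candidates=range(1, 7), n_restarts: int = 25, seed: int = 0):
        self.k_candidates = k_candidates
        self.n_restarts = n_restarts
        self.seed = seed

    def fit(self, X, y=None):
        X = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        ks = sorted(set(int(k) for k in self.k_candidates))
        if len(ks) < 3:
            raise ValueError("need at least 3 candidate k values for the elbow")
        if min(ks) < 1:
            raise ValueError("candidate k must be >= 1")
        if max(ks) > X.shape[0]:
            raise ValueError("candidate k exceeds the number of observations")
        wss = {}
        models = {}
        for k in ks:
            km = KMeans(
                n_clusters=k, n_init=self.n_restarts, algorithm="lloyd",
                random_state=(self.seed + k) % (2**31),
            ).fit(X)
            wss[k] = float(km.inertia_)
            models[k] = km
        curve = pd.Series(wss)
        second = {
            ks[i]: curve[ks[i - 1]] - 2 * curve[ks[i]] + curve[ks[i + 1]]
            for i in range(1, len(ks) - 1)
        }
        k_star = max(second, key=lambda k: (second[k], -k))
        best = models[k_star]
        self.k_ = int(k_star)
        self.labels_ = best.labels_ + 1
        self.cluster_centers_ = best.cluster_centers_
        self.wss_curve_ = curve
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        d = ((X[:, None, :] - self.cluster_centers_[None]) ** 2).sum(axis=2)
        return d.argmin(axis=1) + 1

    def to_result(self) -> ClusterResult:
        check_is_fitted(self, "cluster_centers_")
        return ClusterResult(self.k_, self.labels_, self.cluster_centers_, self.wss_curve_)


def kmeans_elbow(
    features, k_candidates=range(1, 7), seed: int = 0, n_restarts: int = 25
) -> ClusterResult:
    """Cluster with seeded k-means restarts and pick k by the elbow."""
    model = KMeansElbow(k_candidates=k_candidates, n_restarts=n_restarts, seed=seed)
    return model.fit(features).to_result()


# ---------------------------------------------------------------------------
# ANOVA + Tukey-Kramer
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """One-way ANOVA with eta-squared and all-pairs Tukey-Kramer tests."""

    f_stat: float
    p_value: float
    eta_sq: float
    df_between: int
    df_within: int
    pairwise: pd.DataFrame       # group_i, group_j, diff, q_stat, p_adj


def anova_tukey(values, groups) -> AnovaResult:
    """One-way ANOVA and Tukey-Kramer honest significant differences.

    The Tukey-Kramer standard error accommodates unequal group sizes;
    pairwise p-values come from the studentized range distribution.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = np.unique(g)
    if levels.size < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([np.sum(g == lv) for lv in levels])
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    means = np.array([y[g == lv].mean() for lv in levels])
    grand = y.mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_total = float(np.sum((y - grand) ** 2))
    ss_within = ss_total - ss_between
    df_b = levels.size - 1
    df_w = y.size - levels.size
    mse = ss_within / df_w
    F = (ss_between / df_b) / mse if mse > 0 else np.inf
    pval = float(sps.f.sf(F, df_b, df_w))
    eta = ss_between / ss_total if ss_total > 0 else 0.0

    rows = []
    for i in range(levels.size):
        for j in range(i + 1, levels.size):
            diff = means[i] - means[j]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            qstat = np.abs(diff) / se if se > 0 else np.inf
            p_adj = float(sps.studentized_range.sf(qstat, levels.size, df_w))
            rows.append(
                {
                    "group_i": levels[i], "group_j": levels[j],
                    "diff": diff, "q_stat": float(qstat), "p_adj": min(p_adj, 1.0),
                }
            )
    return AnovaResult(float(F), pval, float(eta), df_b, df_w, pd.DataFrame(rows))


def anova_eta_squared(f_stat: float, df1: int, df2: int) -> float:
    """Recover eta-squared from a one-way ANOVA F and its dfs."""
    return f_stat * df1 / (f_stat * df1 + df2)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1D sequence")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
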