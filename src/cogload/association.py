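"""Quadratic logistic regression of initiation on cognitive-load metrics.

The model: logit P(initiated) = b0 + b1*loops + b2*loops^2 + b3*distinct
+ b4*distinct^2 + b5*duration + b6*avg_time + patient covariates
+ provider fixed effects, with standard errors clustered by encounter
(multiple prescribing providers can share one encounter, so rows are
correlated within encounters).

Estimation is iteratively reweighted least squares (Newton scoring);
inference uses the CR1 cluster-robust sandwich. Downstream analyses derive
the quadratic vertex -b_lin/(2*b_quad), average marginal effects
mean[(b_lin + 2*b_quad*x_i) * p_i * (1 - p_i)], and predicted-probability
curves over a metric grid with everything else held at sample means /
reference levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

DEFAULT_QUADRATIC = ("n_loops", "n_distinct")
DEFAULT_LINEAR = ("duration_min", "avg_time_sec")

#: categorical covariates with their reference levels
DEFAULT_CATEGORICAL = {
    "race_ethnicity": "Non-Hispanic/Latinx White",
    "patient_sex": "Male",
    "insurance_class": "commercial",
}
DEFAULT_CONTINUOUS_COVARIATES = ("patient_age", "n_active_dx", "elixhauser")


class SeparationError(RuntimeError):
    """The likelihood has no finite maximizer (e.g., all-one outcome)."""


@dataclass
class CurveAnalysis:
    """Vertex/shape/marginal-effect summary for one quadratic metric."""

    metric: str
    vertex: float
    shape: str  # "U" or "inverted-U"
    ame_below: float
    ame_above: float
    peak_x: float
    peak_p: float
    curve: pd.DataFrame  # columns: x, probability


def vertex(beta_lin: float, beta_quad: float) -> float:
    """Extremum of b_lin*x + b_quad*x^2, in raw metric units."""
    if beta_quad == 0:
        raise ValueError("vertex undefined for beta_quad = 0")
    return -beta_lin / (2.0 * beta_quad)


def quadratic_shape(beta_quad: float) -> str:
    if beta_quad == 0:
        raise ValueError("shape undefined for beta_quad = 0")
    return "U" if beta_quad > 0 else "inverted-U"


def build_design(
    records: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    quadratic_terms: tuple[str, ...] = DEFAULT_QUADRATIC,
    linear_terms: tuple[str, ...] = DEFAULT_LINEAR,
    categorical: dict[str, str] | None = None,
    continuous_covariates: tuple[str, ...] = DEFAULT_CONTINUOUS_COVARIATES,
    fixed_effect_col: str | None = "provider_id",
    cluster_col: str = "encounter_id",
    outcome_col: str = "initiated",
    min_provider_rows: int = 2,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Join metric rows to encounter metadata and build the model matrix.

    Returns (X, y, clusters). Columns: ``const``, each metric, ``<m>_sq``
    for quadratic metrics, dummy-coded categoricals against their reference
    level, continuous covariates, and provider dummies against the most
    frequent provider. Providers with fewer than ``min_provider_rows`` rows
    are pooled into one ``provider[rare]`` dummy. All-constant columns are
    dropped with a warning.
    """
    df = records
    if meta is not None:
        unmatched = ~df["encounter_id"].isin(meta["encounter_id"])
        if unmatched.any():
            raise ValueError(
                f"{int(unmatched.sum())} records do not join to the encounter table"
            )
        df = df.merge(meta, on="encounter_id", how="left", validate="many_to_one")
    if categorical is None:
        categorical = {k: v for k, v in DEFAULT_CATEGORICAL.items() if k in df.columns}
    overlap = set(quadratic_terms) & set(linear_terms)
    if overlap:
        raise ValueError(f"terms both quadratic and linear: {sorted(overlap)}")

    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for m in (*quadratic_terms, *linear_terms):
        X[m] = df[m].astype(float)
    for m in quadratic_terms:
        X[f"{m}_sq"] = df[m].astype(float) ** 2
    for col, ref in categorical.items():
        levels = df[col].astype(str)
        if ref not in set(levels):
            raise ValueError(f"reference level {ref!r} absent from {col}")
        for lev in sorted(set(levels) - {ref}):
            X[f"{col}[{lev}]"] = (levels == lev).astype(float)
    for cov in continuous_covariates:
        if cov in df.columns:
            X[cov] = df[cov].astype(float)
    if fixed_effect_col is not None and fixed_effect_col in df.columns:
        prov = df[fixed_effect_col].astype(str)
        counts = prov.value_counts()
        rare = set(counts.index[counts < min_provider_rows])
        if rare:
            prov = prov.where(~prov.isin(rare), "rare")
        counts = prov.value_counts()
        ref_provider = counts.index[0]  # most frequent = reference
        for lev in sorted(set(prov) - {ref_provider}):
            X[f"provider[{lev}]"] = (prov == lev).astype(float)

    constant = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping all-constant design columns: {constant}", stacklevel=2)
        X = X.drop(columns=constant)

    y = df[outcome_col].to_numpy(dtype=float)
    clusters = df[cluster_col].to_numpy()
    return X, y, clusters


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    score_tol: float = 1e-8,
    ll_rtol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Newton/IRLS for the logit MLE.

    Returns (beta, eta, loglik, converged). Convergence: max |score| below
    ``score_tol`` or relative log-likelihood change below ``ll_rtol``.
    """
    n, k = X.shape
    beta = np.zeros(k)
    eta = X @ beta
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        score = X.T @ (y - p)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as err:
            raise SeparationError(f"singular information matrix: {err}") from err
        # step-halving on the log-likelihood
        ll_new = None
        for _halving in range(30):
            beta_try = beta + step
            eta_try = X @ beta_try
            ll_try = float(np.sum(y * eta_try - np.logaddexp(0.0, eta_try)))
            if np.isfinite(ll_try) and (ll_try >= ll_old or _halving == 29):
                beta, eta, ll_new = beta_try, eta_try, ll_try
                break
            step *= 0.5
        if ll_new is None:  # pragma: no cover
            break
        if np.max(np.abs(score)) < score_tol or (
            np.isfinite(ll_old) and abs(ll_new - ll_old) <= ll_rtol * abs(ll_old)
        ):
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    return beta, eta, ll_old, converged


def clustered_vcov(
    X: np.ndarray, y: np.ndarray, eta: np.ndarray, clusters: np.ndarray
) -> np.ndarray:
    """CR1 cluster-robust sandwich covariance for a fitted logit.

    bread = inverse observed information; meat = sum over clusters of outer
    products of within-cluster score sums; small-sample factor
    G/(G-1) * (n-1)/(n-k).
    """
    n, k = X.shape
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    bread = np.linalg.inv(info)
    resid = (y - p)[:, None] * X  # per-row scores
    codes, _ = pd.factorize(clusters)
    G = int(codes.max()) + 1
    if G < 2:
        raise ValueError("need at least 2 clusters")
    sums = np.zeros((G, k))
    np.add.at(sums, codes, resid)
    meat = sums.T @ sums
    c = (G / (G - 1.0)) * ((n - 1.0) / (n - k))
    return c * bread @ meat @ bread


class ClusteredQuadraticLogit(BaseEstimator):
    """Logit with quadratic load terms, provider FEs, clustered SEs.

    scikit-learn-style estimator: ``fit(X, y)`` where ``X`` is a DataFrame
    of metric rows already joined to covariates (or pass ``meta`` to
    ``fit``); fitted attributes carry trailing underscores.

    Parameters
    ----------
    quadratic_terms, linear_terms : tuple of str
        Metric columns entering with/without a squared term.
    categorical : dict or None
        Categorical covariates mapped to reference levels (None = defaults
        for any present columns).
    continuous_covariates : tuple of str
        Continuous covariates (only those present are used).
    fixed_effect_col : str or None
        Provider-id column for fixed-effect dummies; None disables FEs.
    cluster_col : str
        Cluster key for robust SEs (the encounter id).
    min_provider_rows : int
        Providers with fewer rows are pooled into a "rare" dummy.
    separation : {"drop_dummy", "error"}
        Handling of provider dummies with a constant outcome.
    """

    def __init__(
        self,
        quadratic_terms: tuple[str, ...] = DEFAULT_QUADRATIC,
        linear_terms: tuple[str, ...] = DEFAULT_LINEAR,
        categorical: dict[str, str] | None = None,
        continuous_covariates: tuple[str, ...] = DEFAULT_CONTINUOUS_COVARIATES,
        fixed_effect_col: str | None = "provider_id",
        cluster_col: str = "encounter_id",
        outcome_col: str = "initiated",
        min_provider_rows: int = 2,
        separation: str = "drop_dummy",
        score_tol: float = 1e-8,
        ll_rtol: float = 1e-10,
        max_iter: int = 100,
    ):
        self.quadratic_terms = quadratic_terms
        self.linear_terms = linear_terms
        self.categorical = categorical
        self.continuous_covariates = continuous_covariates
        self.fixed_effect_col = fixed_effect_col
        self.cluster_col = cluster_col
        self.outcome_col = outcome_col
        self.min_provider_rows = min_provider_rows
        self.separation = separation
        self.score_tol = score_tol
        self.ll_rtol = ll_rtol
        self.max_iter = max_iter

    # ------------------------------------------------------------------ fit
    def fit(
        self, X: pd.DataFrame, y: np.ndarray | None = None, meta: pd.DataFrame | None = None
    ) -> "ClusteredQuadraticLogit":
        df = X.copy()
        if y is not None:
            df[self.outcome_col] = np.asarray(y)
        if meta is not None:
            df = df.merge(meta, on="encounter_id", how="left", validate="many_to_one")
        self._fit_frame_ = df
        design, yv, clusters = build_design(
            df,
            meta=None,
            quadratic_terms=self.quadratic_terms,
            linear_terms=self.linear_terms,
            categorical=self.categorical,
            continuous_covariates=self.continuous_covariates,
            fixed_effect_col=self.fixed_effect_col,
            cluster_col=self.cluster_col,
            outcome_col=self.outcome_col,
            min_provider_rows=self.min_provider_rows,
        )
        if yv.min() == yv.max():
            raise SeparationError("outcome is constant: no maximum-likelihood estimate")
        design = self._handle_provider_separation(design, yv)
        Xm = design.to_numpy(dtype=float)
        beta, eta, llf, converged = _irls(
            Xm, yv, self.score_tol, self.ll_rtol, self.max_iter
        )
        if not converged:
            warnings.warn("IRLS did not converge; results flagged", stacklevel=2)
        vcov = clustered_vcov(Xm, yv, eta, clusters)

        self.design_columns_ = list(design.columns)
        self.coef_ = pd.Series(beta, index=self.design_columns_)
        self.vcov_ = pd.DataFrame(vcov, index=self.design_columns_, columns=self.design_columns_)
        self.bse_ = pd.Series(np.sqrt(np.diag(vcov)), index=self.design_columns_)
        self.converged_ = bool(converged)
        self.nobs_ = len(yv)
        self.llf_ = llf
        p0 = yv.mean()
        self.llnull_ = float(len(yv) * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0)))
        k = Xm.shape[1]
        self.pseudo_r2_ = 1.0 - llf / self.llnull_
        self.adj_pseudo_r2_ = 1.0 - (llf - k) / self.llnull_
        p_hat = 1.0 / (1.0 + np.exp(-eta))
        self.rmse_ = float(np.sqrt(np.mean((yv - p_hat) ** 2)))
        self.fitted_probabilities_ = p_hat
        self.outcome_ = yv
        self.clusters_ = clusters
        self.design_ = design
        return self

    def _handle_provider_separation(
        self, design: pd.DataFrame, y: np.ndarray
    ) -> pd.DataFrame:
        dummy_cols = [c for c in design.columns if c.startswith("provider[")]
        drop = []
        for c in dummy_cols:
            mask = design[c].to_numpy() == 1.0
            if mask.any() and (y[mask].min() == y[mask].max()):
                drop.append(c)
        if drop:
            if self.separation == "error":
                raise SeparationError(f"complete separation in provider dummies: {drop}")
            warnings.warn(
                f"provider dummies with constant outcome merged into reference: {drop}",
                stacklevel=2,
            )
            design = design.drop(columns=drop)
        return design

    # ------------------------------------------------------------ inference
    def predict_proba_from_design(self, design: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "coef_")
        eta = design[self.design_columns_].to_numpy(dtype=float) @ self.coef_.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def summary_frame(self) -> pd.DataFrame:
        """Coefficients, clustered SEs, z statistics and p-values."""
        check_is_fitted(self, "coef_")
        z = self.coef_ / self.bse_
        return pd.DataFrame(
            {
                "coef": self.coef_,
                "se_clustered": self.bse_,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )

    def wald_quadratic(self, terms: tuple[str, ...] | None = None) -> dict:
        """Joint Wald test of the squared terms under the clustered vcov."""
        check_is_fitted(self, "coef_")
        if terms is None:
            terms = tuple(f"{m}_sq" for m in self.quadratic_terms)
        missing = [t for t in terms if t not in self.design_columns_]
        if missing:
            raise ValueError(f"terms absent from fit: {missing}")
        b = self.coef_[list(terms)].to_numpy()
        V = self.vcov_.loc[list(terms), list(terms)].to_numpy()
        stat = float(b @ np.linalg.solve(V, b))
        df = len(terms)
        return {"wald_stat": stat, "df": df, "p": float(stats.chi2.sf(stat, df))}

    def compare_with_linear(self) -> dict:
        """Wald test of curvature plus the adjusted-pseudo-R^2 gain vs the
        refitted all-linear model."""
        check_is_fitted(self, "coef_")
        wald = self.wald_quadratic()
        linear = ClusteredQuadraticLogit(
            quadratic_terms=(),
            linear_terms=(*self.quadratic_terms, *self.linear_terms),
            categorical=self.categorical,
            continuous_covariates=self.continuous_covariates,
            fixed_effect_col=self.fixed_effect_col,
            cluster_col=self.cluster_col,
            outcome_col=self.outcome_col,
            min_provider_rows=self.min_provider_rows,
            separation=self.separation,
        )
        linear.fit(self._refit_frame())
        delta = self.adj_pseudo_r2_ - linear.adj_pseudo_r2_
        return {**wald, "delta_adj_r2": float(delta), "linear_fit": linear}

    def _refit_frame(self) -> pd.DataFrame:
        if not hasattr(self, "_fit_frame_"):
            raise RuntimeError("original fit frame unavailable")
        return self._fit_frame_

    # -------------------------------------------------------- curve analysis
    def _term_betas(self, metric: str) -> tuple[float, float]:
        check_is_fitted(self, "coef_")
        if metric not in self.coef_.index:
            raise ValueError(f"metric {metric!r} not in fit")
        b_lin = float(self.coef_[metric])
        sq = f"{metric}_sq"
        b_quad = float(self.coef_[sq]) if sq in self.coef_.index else 0.0
        return b_lin, b_quad

    def vertex(self, metric: str) -> float:
        b_lin, b_quad = self._term_betas(metric)
        return vertex(b_lin, b_quad)

    def average_marginal_effect(self, metric: str, subset: str = "all") -> float:
        """Mean of (b_lin + 2 b_quad x_i) p_i (1-p_i) over the chosen rows.

        ``subset`` is "all", "below_vertex" or "above_vertex" (vertex of the
        metric's own quadratic).
        """
        b_lin, b_quad = self._term_betas(metric)
        x = self.design_[metric].to_numpy(dtype=float)
        p = self.fitted_probabilities_
        if subset == "all":
            mask = np.ones(len(x), dtype=bool)
        elif subset in ("below_vertex", "above_vertex"):
            v = vertex(b_lin, b_quad)
            mask = x < v if subset == "below_vertex" else x > v
        else:
            raise ValueError(f"unknown subset {subset!r}")
        if not mask.any():
            raise ValueError(f"empty subset {subset!r} for metric {metric!r}")
        deriv = (b_lin + 2.0 * b_quad * x[mask]) * p[mask] * (1.0 - p[mask])
        return float(deriv.mean())

    def predicted_curve(self, metric: str, grid: np.ndarray) -> CurveAnalysis:
        """Probability curve over ``grid`` with the other continuous terms at
        sample means, categoricals at reference (dummies = 0), and the
        provider effect at its sample mean."""
        check_is_fitted(self, "coef_")
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("empty grid")
        b = self.coef_
        base = 0.0
        for col in self.design_columns_:
            if col == "const":
                base += b[col]
            elif col == metric or col == f"{metric}_sq":
                continue
            elif col.startswith("provider["):
                base += b[col] * float(self.design_[col].mean())
            elif "[" in col:  # categorical dummy at reference
                continue
            else:
                base += b[col] * float(self.design_[col].mean())
        b_lin, b_quad = self._term_betas(metric)
        eta = base + b_lin * grid + b_quad * grid**2
        prob = 1.0 / (1.0 + np.exp(-eta))
        peak_i = int(np.argmax(prob))
        v = vertex(b_lin, b_quad) if b_quad != 0 else float("nan")
        shape = quadratic_shape(b_quad) if b_quad != 0 else "linear"
        ame_below = ame_above = float("nan")
        x_obs = self.design_[metric].to_numpy(dtype=float)
        if b_quad != 0:
            if (x_obs < v).any():
                ame_below = self.average_marginal_effect(metric, "below_vertex")
            if (x_obs > v).any():
                ame_above = self.average_marginal_effect(metric, "above_vertex")
        return CurveAnalysis(
            metric=metric,
            vertex=v,
            shape=shape,
            ame_below=ame_below,
            ame_above=ame_above,
            peak_x=float(grid[peak_i]),
            peak_p=float(prob[peak_i]),
            curve=pd.DataFrame({"x": grid, "probability": prob}),
        )
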