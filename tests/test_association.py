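"""Quadratic logit: design building, IRLS, clustered SEs, vertex, AME."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from cogload.association import (
    ClusteredQuadraticLogit,
    SeparationError,
    build_design,
    clustered_vcov,
    quadratic_shape,
    vertex,
)


def _simple_frame(n, rng, n_clusters=None, beta=(0.5, -1.0), intercept=0.0):
    """Two standard-normal regressors, logistic outcome, optional clusters."""
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    p = expit(intercept + beta[0] * x1 + beta[1] * x2)
    y = rng.binomial(1, p)
    cl = rng.integers(0, n_clusters, n) if n_clusters else np.arange(n)
    return pd.DataFrame(
        {"n_loops": x1, "duration_min": x2, "initiated": y, "encounter_id": cl}
    )


def _plain_model(**kw):
    return ClusteredQuadraticLogit(
        quadratic_terms=(),
        linear_terms=("n_loops", "duration_min"),
        categorical={},
        continuous_covariates=(),
        fixed_effect_col=None,
        **kw,
    )


# ------------------------------------------------------------------- design
def test_two_providers_give_one_dummy():
    df = pd.DataFrame(
        {
            "encounter_id": ["E1", "E2", "E3", "E4"],
            "provider_id": ["P1", "P1", "P2", "P2"],
            "n_loops": [1.0, 2, 3, 4],
            "n_distinct": [1.0, 2, 3, 4],
            "duration_min": [1.0, 2, 3, 4],
            "avg_time_sec": [1.0, 2, 3, 4],
            "initiated": [0, 1, 0, 1],
        }
    )
    X, y, cl = build_design(df, categorical={}, continuous_covariates=())
    provider_cols = [c for c in X.columns if c.startswith("provider[")]
    assert len(provider_cols) == 1


def test_quadratic_column_is_the_square():
    df = pd.DataFrame(
        {
            "encounter_id": ["E1", "E2", "E3", "E4"],
            "n_loops": [10.0, 2, 3, 4],
            "n_distinct": [1.0, 2, 3, 4],
            "duration_min": [1.0, 2, 3, 4],
            "avg_time_sec": [1.0, 2, 3, 4],
            "initiated": [0, 1, 0, 1],
        }
    )
    X, _, _ = build_design(df, categorical={}, continuous_covariates=(), fixed_effect_col=None)
    assert X.loc[0, "n_loops"] == 10.0
    assert X.loc[0, "n_loops_sq"] == 100.0


def test_dummy_sums_equal_category_counts():
    rng = np.random.default_rng(0)
    n = 200
    races = rng.choice(["Non-Hispanic/Latinx White", "Asian", "Other"], n)
    df = pd.DataFrame(
        {
            "encounter_id": [f"E{i}" for i in range(n)],
            "n_loops": rng.normal(size=n),
            "n_distinct": rng.normal(size=n),
            "duration_min": rng.normal(size=n),
            "avg_time_sec": rng.normal(size=n),
            "race_ethnicity": races,
            "initiated": rng.integers(0, 2, n),
        }
    )
    X, _, _ = build_design(
        df,
        categorical={"race_ethnicity": "Non-Hispanic/Latinx White"},
        continuous_covariates=(),
        fixed_effect_col=None,
    )
    for lev in ("Asian", "Other"):
        assert X[f"race_ethnicity[{lev}]"].sum() == (races == lev).sum()


def test_unjoinable_record_raises():
    rec = pd.DataFrame({"encounter_id": ["EX"], "n_loops": [1.0], "n_distinct": [1.0],
                        "duration_min": [1.0], "avg_time_sec": [1.0]})
    meta = pd.DataFrame({"encounter_id": ["EY"], "initiated": [1]})
    with pytest.raises(ValueError, match="join"):
        build_design(rec, meta)


# --------------------------------------------------------------------- IRLS
def test_parameter_recovery_on_synthetic_logit():
    rng = np.random.default_rng(1)
    df = _simple_frame(50_000, rng)
    m = _plain_model().fit(df)
    for name, truth in (("n_loops", 0.5), ("duration_min", -1.0)):
        assert abs(m.coef_[name] - truth) < 3 * m.bse_[name]


def test_matches_statsmodels_glm_with_cluster_vcov():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(2)
    df = _simple_frame(3000, rng, n_clusters=300)
    m = _plain_model().fit(df)
    res = sm.GLM(
        m.outcome_, m.design_.to_numpy(), family=sm.families.Binomial()
    ).fit(cov_type="cluster", cov_kwds={"groups": pd.factorize(m.clusters_)[0]})
    np.testing.assert_allclose(m.coef_.to_numpy(), res.params, atol=1e-8)
    np.testing.assert_allclose(m.bse_.to_numpy(), res.bse, rtol=1e-8)


def test_all_one_outcome_raises():
    df = pd.DataFrame(
        {"encounter_id": range(20), "n_loops": np.arange(20.0), "duration_min": 1.0 * np.arange(20),
         "initiated": 1}
    )
    with pytest.raises(SeparationError):
        _plain_model().fit(df)


def test_intercept_only_model_closed_form():
    y = np.array([1] * 60 + [0] * 40)
    df = pd.DataFrame(
        {"encounter_id": range(100), "n_loops": 0.0, "duration_min": 0.0, "initiated": y}
    )
    with pytest.warns(UserWarning, match="constant"):
        m = _plain_model().fit(df)
    assert m.coef_["const"] == pytest.approx(np.log(0.6 / 0.4), abs=1e-8)


def test_separated_provider_dummy_is_dropped_with_warning():
    rng = np.random.default_rng(3)
    n = 120
    df = pd.DataFrame(
        {
            "encounter_id": [f"E{i}" for i in range(n)],
            "provider_id": np.where(np.arange(n) < 20, "P_sep", "P_main"),
            "n_loops": rng.normal(size=n),
            "n_distinct": rng.normal(size=n),
            "duration_min": rng.normal(size=n),
            "avg_time_sec": rng.normal(size=n),
            "initiated": rng.integers(0, 2, n),
        }
    )
    df.loc[df.provider_id == "P_sep", "initiated"] = 1  # perfect separation
    m = ClusteredQuadraticLogit(categorical={}, continuous_covariates=())
    with pytest.warns(UserWarning, match="merged into reference"):
        m.fit(df)
    assert not any(c.startswith("provider[P_sep") for c in m.design_columns_)


# ------------------------------------------------------------ clustered SEs
def test_singleton_clusters_equal_hc_up_to_factor():
    rng = np.random.default_rng(4)
    df = _simple_frame(500, rng)
    m = _plain_model().fit(df)
    X, y = m.design_.to_numpy(), m.outcome_
    eta = X @ m.coef_.to_numpy()
    p = expit(eta)
    w = p * (1 - p)
    bread = np.linalg.inv((X * w[:, None]).T @ X)
    hc0 = bread @ ((X * ((y - p) ** 2)[:, None]).T @ X) @ bread
    n, k = X.shape
    factor = (n / (n - 1)) * ((n - 1) / (n - k))
    np.testing.assert_allclose(m.vcov_.to_numpy(), factor * hc0, rtol=1e-8)


def test_duplicating_rows_leaves_clustered_ses_stable():
    rng = np.random.default_rng(5)
    df = _simple_frame(1000, rng, n_clusters=200)
    m1 = _plain_model().fit(df)
    doubled = pd.concat([df, df], ignore_index=True)
    m2 = _plain_model().fit(doubled)
    np.testing.assert_allclose(m1.coef_.to_numpy(), m2.coef_.to_numpy(), atol=1e-7)
    # clustered SEs barely move (only the small-sample factor changes) ...
    np.testing.assert_allclose(m2.bse_.to_numpy(), m1.bse_.to_numpy(), rtol=0.01)
    # ... whereas naive iid SEs would shrink by ~1/sqrt(2)
    eta = m1.design_.to_numpy() @ m1.coef_.to_numpy()
    p = expit(eta)
    w = p * (1 - p)
    naive = np.sqrt(np.diag(np.linalg.inv((m1.design_.to_numpy() * w[:, None]).T
                                          @ m1.design_.to_numpy())))
    assert (m1.bse_.to_numpy() > 0.8 * naive).all()


def test_clustered_ses_exceed_naive_under_cluster_correlation():
    rng = np.random.default_rng(6)
    ratios = []
    for _ in range(20):
        G, mrows = 100, 8
        u = np.repeat(rng.normal(0, 1, G), mrows)  # cluster-shared regressor
        x = u + rng.normal(0, 0.5, G * mrows)
        cl = np.repeat(np.arange(G), mrows)
        re = np.repeat(rng.normal(0, 1, G), mrows)  # cluster random effect
        y = rng.binomial(1, expit(0.5 * x + re))
        df = pd.DataFrame({"encounter_id": cl, "n_loops": x, "duration_min": 0.0, "initiated": y})
        df = df.drop(columns="duration_min")
        m = ClusteredQuadraticLogit(
            quadratic_terms=(), linear_terms=("n_loops",), categorical={},
            continuous_covariates=(), fixed_effect_col=None,
        ).fit(df)
        X = m.design_.to_numpy()
        p = expit(X @ m.coef_.to_numpy())
        w = p * (1 - p)
        naive = np.sqrt(np.diag(np.linalg.inv((X * w[:, None]).T @ X)))
        ratios.append(m.bse_["n_loops"] / naive[list(m.coef_.index).index("n_loops")])
    assert np.mean(ratios) > 1.1


def test_clustered_vcov_requires_two_clusters():
    X = np.ones((5, 1))
    with pytest.raises(ValueError, match="clusters"):
        clustered_vcov(X, np.array([0, 1, 0, 1, 0.0]), np.zeros(5), np.zeros(5))


# ----------------------------------------------------------- vertex and AME
def test_vertex_from_published_loop_coefficients():
    assert vertex(-1.239e-02, 6.597e-05) == pytest.approx(93.9, abs=0.05)
    assert quadratic_shape(6.597e-05) == "U"


def test_vertex_from_published_distinct_coefficients():
    v = vertex(6.412e-02, -1.787e-03)
    assert round(v) == 18
    assert quadratic_shape(-1.787e-03) == "inverted-U"


def test_vertex_degenerate_cases():
    assert vertex(0.0, 2.0) == 0.0
    with pytest.raises(ValueError):
        vertex(1.0, 0.0)


def _quadratic_fit(n=1500, seed=7):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 20, n)
    p = expit(-1.2 + 0.4 * x - 0.012 * x**2)
    y = rng.binomial(1, p)
    df = pd.DataFrame({"encounter_id": range(n), "n_loops": x, "initiated": y})
    return ClusteredQuadraticLogit(
        quadratic_terms=("n_loops",), linear_terms=(), categorical={},
        continuous_covariates=(), fixed_effect_col=None,
    ).fit(df)


def test_ame_matches_central_finite_difference():
    m = _quadratic_fit()
    x = m.design_["n_loops"].to_numpy()
    b = m.coef_
    h = 1e-4

    def mean_p(shift):
        xs = x + shift
        eta = (b["const"] + b["n_loops"] * xs + b["n_loops_sq"] * xs**2)
        return expit(eta).mean()

    fd = (mean_p(h) - mean_p(-h)) / (2 * h)
    assert m.average_marginal_effect("n_loops", "all") == pytest.approx(fd, abs=1e-6)


def test_ame_zero_when_all_slopes_zero():
    rng = np.random.default_rng(8)
    df = pd.DataFrame(
        {"encounter_id": range(400), "n_loops": rng.normal(size=400),
         "initiated": rng.integers(0, 2, 400)}
    )
    m = ClusteredQuadraticLogit(
        quadratic_terms=("n_loops",), linear_terms=(), categorical={},
        continuous_covariates=(), fixed_effect_col=None,
    ).fit(df)
    m.coef_[:] = 0.0
    m.coef_["const"] = 0.3
    m.fitted_probabilities_ = np.full(400, expit(0.3))
    assert m.average_marginal_effect("n_loops", "all") == 0.0


def test_empty_subset_raises():
    m = _quadratic_fit()
    # inverted-U vertex ~16.7 lies inside the range; force an empty subset
    with pytest.raises(ValueError, match="empty subset"):
        x = m.design_["n_loops"]
        m.design_["n_loops"] = x + 100  # everything above the vertex now
        m.average_marginal_effect("n_loops", "below_vertex")


# ----------------------------------------------------------------- the Wald
def test_single_term_wald_equals_squared_z():
    m = _quadratic_fit()
    res = m.wald_quadratic(("n_loops_sq",))
    z = m.coef_["n_loops_sq"] / m.bse_["n_loops_sq"]
    assert res["wald_stat"] == pytest.approx(z**2)


def test_wald_type_one_error_near_nominal():
    # no true curvature: reject-at-5% rate should be near 5%
    rng = np.random.default_rng(9)
    rejections = 0
    n_sims = 100
    for _ in range(n_sims):
        n = 2000
        x = rng.uniform(0, 20, n)
        y = rng.binomial(1, expit(-0.5 + 0.08 * x))
        df = pd.DataFrame({"encounter_id": range(n), "n_loops": x, "initiated": y})
        m = ClusteredQuadraticLogit(
            quadratic_terms=("n_loops",), linear_terms=(), categorical={},
            continuous_covariates=(), fixed_effect_col=None,
        ).fit(df)
        rejections += m.wald_quadratic()["p"] < 0.05
    assert 1 <= rejections <= 12  # binomial(100, 0.05) central range


def test_wald_power_under_strong_curvature():
    rng = np.random.default_rng(10)
    hits = 0
    for _ in range(20):
        m = _quadratic_fit(n=2000, seed=int(rng.integers(1 << 30)))
        hits += m.wald_quadratic()["p"] < 0.001
    assert hits >= 19


def test_compare_with_linear_reports_fit_gain():
    m = _quadratic_fit(n=3000)
    res = m.compare_with_linear()
    assert res["p"] < 0.001
    assert res["delta_adj_r2"] > 0


# ------------------------------------------------------------------- curves
def test_curve_values_equal_pointwise_logistic():
    m = _quadratic_fit()
    grid = np.linspace(0, 20, 41)
    curve = m.predicted_curve("n_loops", grid)
    b = m.coef_
    expected = expit(b["const"] + b["n_loops"] * grid + b["n_loops_sq"] * grid**2)
    np.testing.assert_allclose(curve.curve["probability"].to_numpy(), expected, atol=1e-12)


def test_negative_quadratic_peaks_at_vertex():
    m = _quadratic_fit()
    assert m.coef_["n_loops_sq"] < 0
    grid = np.linspace(0, 20, 2001)
    curve = m.predicted_curve("n_loops", grid)
    assert curve.shape == "inverted-U"
    assert curve.peak_x == pytest.approx(curve.vertex, abs=0.02)


def test_monotone_linear_model_gives_monotone_curve():
    rng = np.random.default_rng(11)
    n = 2000
    x = rng.uniform(0, 10, n)
    y = rng.binomial(1, expit(-1 + 0.3 * x))
    df = pd.DataFrame({"encounter_id": range(n), "n_loops": x, "initiated": y})
    m = ClusteredQuadraticLogit(
        quadratic_terms=(), linear_terms=("n_loops",), categorical={},
        continuous_covariates=(), fixed_effect_col=None,
    ).fit(df)
    curve = m.predicted_curve("n_loops", np.linspace(0, 10, 50))
    probs = curve.curve["probability"].to_numpy()
    assert (np.diff(probs) > 0).all()
    with pytest.raises(ValueError):
        m.predicted_curve("n_loops", np.array([]))
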