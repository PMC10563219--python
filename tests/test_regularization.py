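"""Elastic-net fits cross-checked against independent solvers (scikit-learn
coordinate descent, LARS) and closed-form penalty-path properties."""

import numpy as np
import pytest
from sklearn.linear_model import ElasticNet, LogisticRegression, lars_path

from uniss.regularization import (
    DegenerateResponseError,
    ElasticNetSpec,
    fit_support,
    lambda_max,
    lambda_path,
    standardize_columns,
)


@pytest.fixture(scope="module")
def gaussian_toy():
    rng = np.random.default_rng(11)
    n, p = 150, 40
    X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
    beta = np.zeros(p)
    beta[3] = 3.0
    y = X @ beta + rng.standard_normal(n)
    return X, y


def test_lambda_max_closed_form(gaussian_toy):
    """lambda_max = max_j |<x_j, y_centered>| / (n * alpha) on standardized
    columns, and the first variant to enter the path is the arg max."""
    X, y = gaussian_toy
    spec = ElasticNetSpec(alpha=0.1)
    Xs, _, _ = standardize_columns(X)
    yc = y - y.mean()
    grads = np.abs(Xs.T @ yc) / len(y)
    assert lambda_max(X, y, "gaussian", spec) == pytest.approx(grads.max() / 0.1, rel=1e-9)

    path = lambda_path(X, y, "gaussian", spec)
    at_max = fit_support(X, y, family="gaussian", lam=path[0], spec=spec)
    assert at_max.n_nonzero == 0
    just_below = fit_support(X, y, family="gaussian", lam=path[0] * 0.995, spec=spec)
    assert just_below.support[np.argmax(grads)]


def test_lambda_path_shape_and_ratio(gaussian_toy):
    X, y = gaussian_toy
    path = lambda_path(X, y, "gaussian", ElasticNetSpec())
    assert len(path) == 100
    assert np.all(np.diff(path) < 0)
    assert path[-1] / path[0] == pytest.approx(0.01, rel=1e-9)


@pytest.mark.parametrize("position", [20, 49, 80])
def test_gaussian_support_matches_sklearn(gaussian_toy, position):
    X, y = gaussian_toy
    spec = ElasticNetSpec(alpha=0.1, tol=1e-9)
    lam = lambda_path(X, y, "gaussian", spec)[position]
    mine = fit_support(X, y, family="gaussian", lam=lam, spec=spec)
    Xs, _, _ = standardize_columns(X)
    yc = y - y.mean()
    sdy = yc.std()  # the response is standardized internally; match it
    ref = ElasticNet(alpha=lam / sdy, l1_ratio=0.1, fit_intercept=False, tol=1e-12,
                     max_iter=200_000).fit(Xs, yc / sdy)
    assert np.array_equal(mine.support, ref.coef_ != 0)
    assert mine.support[3]  # the causal variant is recovered
    assert mine.n_nonzero == mine.support.sum()


def test_lasso_alpha1_matches_lars_active_set():
    """At alpha=1 the support between two LARS knots equals the LARS active set."""
    rng = np.random.default_rng(13)
    n, p = 80, 5
    X = rng.standard_normal((n, p))
    y = X[:, 0] * 2 + X[:, 2] - X[:, 4] * 0.5 + 0.3 * rng.standard_normal(n)
    Xs, _, _ = standardize_columns(X)
    yc = y - y.mean()
    alphas, _, coefs = lars_path(Xs, yc, method="lasso")
    spec = ElasticNetSpec(alpha=1.0, tol=1e-12)
    for i in range(len(alphas) - 1):
        lam = np.sqrt(alphas[i] * alphas[i + 1])  # strictly between two knots
        if lam <= 0:
            continue
        mine = fit_support(X, y, family="gaussian", lam=lam, spec=spec)
        lars_active = coefs[:, i + 1] != 0
        assert np.array_equal(mine.support, lars_active)


def test_binomial_support_matches_sklearn_saga(causal_toy):
    X, Y = causal_toy
    y = Y.values[:, 1]
    spec = ElasticNetSpec(alpha=0.1, tol=1e-9)
    lam = lambda_path(X, y, "binomial", spec)[49]
    mine = fit_support(X, y, family="binomial", lam=lam, spec=spec)
    Xs, _, _ = standardize_columns(X.values)
    n = len(y)
    ref = LogisticRegression(solver="saga", l1_ratio=0.1, C=1.0 / (n * lam),
                             tol=1e-9, max_iter=100_000).fit(Xs, y)
    assert np.array_equal(mine.support, ref.coef_[0] != 0)
    assert mine.support[0]


def test_binomial_lambda_max_empties_support(causal_toy):
    X, Y = causal_toy
    y = Y.values[:, 1]
    spec = ElasticNetSpec()
    lmax = lambda_max(X, y, "binomial", spec)
    assert fit_support(X, y, family="binomial", lam=lmax * 1.001, spec=spec).n_nonzero == 0


def test_scaling_equivariance(gaussian_toy):
    """y -> c*y scales lambda_max by c and preserves supports at matched
    path positions (Gaussian loss, standardized X)."""
    X, y = gaussian_toy
    spec = ElasticNetSpec(alpha=0.1)
    c = 3.7
    assert lambda_max(X, c * y, "gaussian", spec) == pytest.approx(
        c * lambda_max(X, y, "gaussian", spec), rel=1e-9
    )
    path = lambda_path(X, y, "gaussian", spec)
    for pos in (30, 60):
        s1 = fit_support(X, y, family="gaussian", lam=path[pos], spec=spec)
        s2 = fit_support(X, c * y, family="gaussian", lam=c * path[pos], spec=spec)
        assert np.array_equal(s1.support, s2.support)


def test_unpenalized_covariate_equals_residualized_fit(gaussian_toy):
    """Frisch-Waugh: fitting with an unpenalized covariate is the same as
    fitting on covariate-residualized X and y (Gaussian loss)."""
    X, y = gaussian_toy
    rng = np.random.default_rng(17)
    cov = rng.standard_normal((len(y), 2))
    y = y + cov @ [2.0, -1.0]
    # pure lasso: profiling out the unpenalized block is exactly the
    # residualized problem (the ridge term would couple to the response scale)
    spec = ElasticNetSpec(alpha=1.0, tol=1e-10, standardize=False)

    Xs, _, _ = standardize_columns(X)
    C = np.column_stack([np.ones(len(y)), standardize_columns(cov)[0]])
    proj = C @ np.linalg.lstsq(C, np.column_stack([Xs, y]), rcond=None)[0]
    X_res = Xs - proj[:, :-1]
    y_res = y - proj[:, -1]

    lam = 0.05 * lambda_max(X_res, y_res, "gaussian", spec)
    with_cov = fit_support(Xs, y, covariates=cov, family="gaussian", lam=lam, spec=spec)
    residualized = fit_support(X_res, y_res, family="gaussian", lam=lam, spec=spec)
    assert np.array_equal(with_cov.support, residualized.support)
    assert with_cov.support.shape[0] == X.shape[1]  # covariates never counted


def test_support_grows_from_lambda_max_to_lambda_min(gaussian_toy):
    X, y = gaussian_toy
    spec = ElasticNetSpec()
    path = lambda_path(X, y, "gaussian", spec)
    at_max = fit_support(X, y, family="gaussian", lam=path[0], spec=spec)
    at_min = fit_support(X, y, family="gaussian", lam=path[-1], spec=spec)
    assert at_max.n_nonzero == 0
    assert at_min.n_nonzero >= at_max.n_nonzero


def test_error_conditions(gaussian_toy):
    X, y = gaussian_toy
    with pytest.raises(DegenerateResponseError):
        lambda_path(X, np.ones(len(y)), "gaussian", ElasticNetSpec())
    with pytest.raises(ValueError, match="alpha = 0"):
        lambda_max(X, y, "gaussian", ElasticNetSpec(alpha=0.0))
    with pytest.raises(ValueError, match="non-finite"):
        bad = X.copy()
        bad[0, 0] = np.nan
        fit_support(bad, y, family="gaussian", lam=1.0)
    with pytest.raises(ValueError, match="0/1"):
        fit_support(X, y, family="binomial", lam=1.0)
    with pytest.raises(ValueError, match="positive"):
        fit_support(X, y, family="gaussian", lam=0.0)


def test_null_binomial_false_positives_spread_uniformly():
    """On balanced, unassociated binary data, which variants enter the
    support is chance: selection counts over repeats are uniform across
    variants (chi-square goodness of fit)."""
    from scipy import stats

    rng = np.random.default_rng(23)
    n, p = 80, 30
    counts = np.zeros(p)
    total = 0
    for rep in range(40):
        X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        rng.shuffle(y)
        spec = ElasticNetSpec()
        lam = lambda_path(X, y, "binomial", spec)[49]
        res = fit_support(X, y, family="binomial", lam=lam, spec=spec)
        counts += res.support
        total += res.n_nonzero
    expected = total / p
    chi2 = ((counts - expected) ** 2 / expected).sum()
    assert stats.chi2.sf(chi2, df=p - 1) > 0.01
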