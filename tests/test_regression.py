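import numpy as np
import pytest

from circoutlier.angles import TWO_PI, circ_distance, mean_direction, wrap
from circoutlier.regression import (
    RegressionData,
    circular_residuals,
    cv_bandwidth,
    cv_score,
    fit_regression,
    ll_fit,
    mce,
    nw_fit,
    signed_residuals,
    _loo_fitted,
)


@pytest.fixture
def random_data():
    rng = np.random.default_rng(21)
    x = rng.normal(3.0, 0.5, 20)
    y = wrap(np.sin(x) + 0.4 * rng.standard_normal(20))
    return RegressionData(x, y)


def test_data_validation():
    with pytest.raises(ValueError):
        RegressionData([1, 2], [0.1, 0.2, 0.3])
    with pytest.raises(ValueError):
        RegressionData([1, np.inf], [0.1, 0.2])
    d = RegressionData([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
    with pytest.raises(ValueError):
        nw_fit(d, 1.0)  # no x spread


@pytest.mark.parametrize("fit", [nw_fit, ll_fit])
def test_huge_bandwidth_collapses_nw_to_mean_direction(fit, random_data):
    fitted = fit(random_data, 1e6, x_eval=[2.0, 3.0, 4.0])
    if fit is nw_fit:
        expected = mean_direction(random_data.y)
        assert np.all(circ_distance(fitted, expected) < 1e-6)
    else:
        assert np.all(np.isfinite(fitted))  # LL limit is the global linear fit


@pytest.mark.parametrize("fit", [nw_fit, ll_fit])
def test_constant_response_is_reproduced(fit):
    d = RegressionData(np.linspace(0, 1, 10), np.full(10, 2.5))
    for h in (0.05, 0.5, 5.0):
        assert np.all(circ_distance(fit(d, h), 2.5) < 1e-9)


def test_nw_near_interpolation_with_tiny_bandwidth():
    d = RegressionData([0.0, 1.0, 2.0], [0.1, 0.2, 0.3])
    assert circ_distance(nw_fit(d, 0.05, x_eval=[0.0])[0], 0.1) < 1e-6


def test_ll_flat_limit_equals_global_linear_component_fit():
    # as h grows, LL collapses to the atan2 of ordinary least-squares lines
    # fitted to the sine and cosine components
    rng = np.random.default_rng(61)
    x = rng.normal(0, 1, 30)
    y = wrap(rng.uniform(0, TWO_PI, 30))
    d = RegressionData(x, y)
    X = np.column_stack([np.ones(30), x])
    xe = np.array([-0.7, 0.0, 1.3])
    parts = []
    for comp in (np.sin(y), np.cos(y)):
        beta = np.linalg.lstsq(X, comp, rcond=None)[0]
        parts.append(beta[0] + beta[1] * xe)
    oracle = wrap(np.arctan2(parts[0], parts[1]))
    assert np.all(circ_distance(ll_fit(d, 1e6, xe), oracle) < 1e-6)


def test_ll_matches_weighted_least_squares_oracle(random_data):
    # independent oracle: explicit WLS solve per evaluation point
    d, h = random_data, 0.35
    for xe in np.linspace(2.2, 3.8, 7):
        w = np.exp(-0.5 * ((xe - d.x) / h) ** 2)
        X = np.column_stack([np.ones(d.n), d.x - xe])
        comps = []
        for comp in (np.sin(d.y), np.cos(d.y)):
            beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * comp))
            comps.append(beta[0])
        oracle = wrap(np.arctan2(comps[0], comps[1]))
        assert circ_distance(ll_fit(d, h, x_eval=[xe])[0], oracle) < 1e-10


@pytest.mark.parametrize("method", ["NW", "LL"])
def test_rotation_equivariance(method, random_data):
    rng = np.random.default_rng(5)
    fit = nw_fit if method == "NW" else ll_fit
    base = fit(random_data, 0.4)
    for c in rng.uniform(0, TWO_PI, 10):
        rotated = RegressionData(random_data.x, wrap(random_data.y + c))
        assert np.all(circ_distance(fit(rotated, 0.4), wrap(base + c)) < 1e-8)


@pytest.mark.parametrize("method", ["NW", "LL"])
def test_permutation_invariance(method, random_data):
    fit = nw_fit if method == "NW" else ll_fit
    perm = np.random.default_rng(9).permutation(random_data.n)
    shuffled = RegressionData(random_data.x[perm], random_data.y[perm])
    xe = [2.5, 3.0, 3.5]
    np.testing.assert_allclose(fit(random_data, 0.4, xe), fit(shuffled, 0.4, xe),
                               atol=1e-12)


def test_cv_single_element_grid_returned(random_data):
    h, scores = cv_bandwidth(random_data, "NW", [0.7])
    assert h == 0.7 and scores.shape == (1,)


def test_cv_score_bounds(random_data):
    for h in (0.1, 1.0, 10.0):
        assert -random_data.n <= cv_score(random_data, h) <= random_data.n


def test_cv_selected_bandwidth_is_interior_minimum():
    rng = np.random.default_rng(33)
    x = rng.normal(3.0, 0.5, 50)
    from circoutlier.wrapped_cauchy import WCParams, sample_wc
    y = wrap(np.sin(1.5 * x - np.pi / 2) + (4 / 3) * np.cos(x / 3)
             + sample_wc(50, WCParams(0, 0.9), rng))
    d = RegressionData(x, y)
    h, _ = cv_bandwidth(d, "NW")
    assert cv_score(d, h) <= cv_score(d, 10 * h)
    assert cv_score(d, h) <= cv_score(d, 0.1 * h)


def test_loo_fit_is_independent_of_held_out_pair(random_data):
    # replacing (x_i, y_i) must not change fhat_{-i}(x_i)
    d, h, i = random_data, 0.5, 4
    base = _loo_fitted(d, h, "NW")[i]
    y2 = d.y.copy()
    y2[i] = wrap(y2[i] + 2.0)
    assert circ_distance(_loo_fitted(RegressionData(d.x, y2), h, "NW")[i], base) < 1e-12


def test_circular_residuals_examples():
    y = np.array([0.5, 1.0, 2.0])
    assert np.all(circular_residuals(y, y) == 0)
    np.testing.assert_allclose(circular_residuals(y, wrap(y + np.pi)),
                               np.pi, atol=1e-12)
    with pytest.raises(ValueError):
        circular_residuals(y, y[:2])


def test_residuals_match_distance_elementwise():
    rng = np.random.default_rng(17)
    y, yhat = rng.uniform(0, TWO_PI, (2, 40))
    np.testing.assert_allclose(circular_residuals(y, yhat),
                               circ_distance(y, yhat))


def test_mce_range_and_direct_formula():
    y = np.array([0.3, 1.2, 4.0])
    assert mce(y, y) == 0.0
    assert mce(y, wrap(y + np.pi)) == pytest.approx(2.0)
    rng = np.random.default_rng(2)
    a, b = rng.uniform(0, TWO_PI, (2, 25))
    assert mce(a, b) == pytest.approx(np.mean(1 - np.cos(a - b)))
    with pytest.raises(ValueError):
        mce([], [])


def test_fit_regression_reports_cv_metadata(random_data):
    res = fit_regression(random_data, "LL")
    assert res.bandwidth > 0
    assert np.all((res.residuals >= 0) & (res.residuals <= np.pi))
    assert res.cv_score == pytest.approx(np.min(res.cv_scores))


def test_signed_residuals_wraps():
    assert signed_residuals([0.1], [0.3])[0] == pytest.approx(TWO_PI - 0.2)
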