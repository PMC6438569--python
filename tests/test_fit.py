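"""MAP estimation: posterior/gradient, coordinate ascent, CV, bootstraps, beta."""

import copy

import numpy as np
import pytest

from frfnet.fit import (
    FitConfig, Priors, bootstrap_fits, crossval_hyperparams, encode_responses,
    fit_filters, fit_internal_noise, laplacian_operator, log_posterior,
    weight_map_stats, _mirror,
)
from frfnet.model import FRFModel, simulate_responses


def random_problem(n=80, d=16, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.gamma(2.0, 1.0, (n, d))
    w_true = np.r_[np.ones(d // 2), -np.ones(d // 2)] * 0.4
    p = 1 / (1 + np.exp(-(X @ w_true)))
    b = (rng.random(n) < p).astype(float)
    return X, b


def test_encode_responses_variants():
    np.testing.assert_array_equal(encode_responses(["L", "R", "R"]), [0, 1, 1])
    np.testing.assert_array_equal(encode_responses([-1, 1, 1]), [0, 1, 1])
    np.testing.assert_array_equal(encode_responses([0, 1, 0]), [0, 1, 0])


def test_laplacian_operator_structure():
    s2 = laplacian_operator(3)
    assert s2.shape == (9, 9)
    center = s2[4]  # middle cell of the 3x3 grid
    assert center[4] == 4.0
    assert sorted(center[[1, 3, 5, 7]]) == [-1, -1, -1, -1]
    assert s2[0, 0] == 4.0 and s2[0, 1] == -1.0  # Dirichlet edges keep the stencil


def test_mirror_flips_grid_columns():
    w = np.arange(8, dtype=float)  # two channels on a 2x2 grid
    out = _mirror(w, 2)
    np.testing.assert_array_equal(out, [1, 0, 3, 2, 5, 4, 7, 6])


def test_log_posterior_zero_filters_is_chance():
    X, b = random_problem()
    m = FRFModel.zeros(16, grid=4)
    val = log_posterior(m, X, b, Priors(lam=1.0))
    assert val == pytest.approx(len(b) * np.log(0.5), rel=1e-9)


def test_prior_term_linear_in_inverse_lambda():
    X, b = random_problem()
    m = FRFModel.zeros(16, grid=4)
    rng = np.random.default_rng(1)
    m.filters = [rng.normal(size=16), rng.normal(size=16)]
    ll = log_posterior(m, X, b, Priors(lam=1e12))  # prior negligible
    p1 = log_posterior(m, X, b, Priors(lam=1.0)) - ll
    p2 = log_posterior(m, X, b, Priors(lam=0.5)) - ll
    assert p2 == pytest.approx(2 * p1, rel=1e-6)


@pytest.mark.parametrize("omega", [None, 0.9])
@pytest.mark.parametrize("active", [0, 1])
def test_gradient_matches_finite_differences(omega, active):
    X, b = random_problem(n=50, d=16, seed=3)
    m = FRFModel.zeros(16, grid=4, alpha=1.7)
    rng = np.random.default_rng(4)
    m.filters = [rng.normal(0, 0.5, 16), rng.normal(0, 0.5, 16)]
    m.bias = 0.3
    priors = Priors(lam=0.7, omega=omega, grid=4)
    _, grad = log_posterior(m, X, b, priors, active=active)
    eps = 1e-6
    num = np.zeros_like(grad)
    for j in range(17):
        for sign in (+1, -1):
            m2 = copy.deepcopy(m)
            if j < 16:
                m2.filters[active] = m2.filters[active].copy()
                m2.filters[active][j] += sign * eps
            else:
                m2.bias += sign * eps
            num[j] += sign * log_posterior(m2, X, b, priors)
    num /= 2 * eps
    rel = np.abs(grad - num) / np.maximum(np.abs(num), 1e-8)
    assert rel.max() < 1e-5


def fit_small(X, b, lam=1.0, omega=None, seed=0, **kw):
    return fit_filters(X, b, Priors(lam=lam, omega=omega, grid=4),
                       FitConfig(n_rounds=4, n_restarts=1, **kw), grid=4, seed=seed)


def test_coordinate_ascent_objective_monotone():
    X, b = random_problem(n=120, d=16, seed=5)
    fit = fit_small(X, b)
    steps = fit.trace[fit.trace["stage"] != "mirror_reinit"]["objective"].to_numpy()
    assert np.all(np.diff(steps) >= -1e-8)


def test_fit_deterministic_under_seed():
    X, b = random_problem(n=120, d=16, seed=6)
    a = fit_small(X, b, seed=9)
    c = fit_small(X, b, seed=9)
    assert a.log_posterior == c.log_posterior
    for wa, wc in zip(a.model.filters, c.model.filters):
        np.testing.assert_array_equal(wa, wc)


def test_strong_ridge_shrinks_uninformative_filters():
    rng = np.random.default_rng(7)
    X = rng.gamma(2.0, 1.0, (150, 16))
    b = rng.integers(0, 2, 150)  # responses independent of features
    strong = fit_small(X, b, lam=1e-4)
    assert sum(strong.filter_norms) < 0.05


def test_filter_norms_monotone_in_lambda():
    X, b = random_problem(n=200, d=16, seed=8)
    norms = [sum(fit_small(X, b, lam=lam, seed=2).filter_norms)
             for lam in (0.01, 0.1, 1.0, 10.0)]
    assert all(n2 >= n1 - 1e-6 for n1, n2 in zip(norms, norms[1:]))


def test_fit_requires_both_response_classes():
    X, _ = random_problem()
    with pytest.raises(ValueError):
        fit_small(X, np.ones(len(X)))


def test_crossval_single_lambda_grid_returns_it():
    X, b = random_problem(n=120, d=16, seed=9)
    lam, omega, curves = crossval_hyperparams(
        X, b, [0.7], k=3, config=FitConfig(n_rounds=2, n_restarts=1), grid=4, seed=1)
    assert lam == 0.7 and omega is None
    assert len(curves) == 1 and np.isfinite(curves["val_ll"]).all()


def test_crossval_folds_and_smoothness_tradeoff():
    """Contiguous folds partition the trials; the smoothness prior lowers the
    training likelihood of the best-fit solution on data from a smooth filter."""
    rng = np.random.default_rng(10)
    n, g = 300, 4
    X = rng.gamma(2.0, 1.0, (n, g * g))
    w_smooth = np.outer(np.linspace(-1, 1, g), np.ones(g)).reshape(-1)
    p = 1 / (1 + np.exp(-(X @ w_smooth)))
    b = (rng.random(n) < p).astype(float)
    from frfnet.fit import _fold_indices
    folds = _fold_indices(n, 4, True, rng)
    flat = np.concatenate(folds)
    assert len(flat) == n and len(np.unique(flat)) == n
    ridge = fit_filters(X, b, Priors(lam=1.0), FitConfig(n_rounds=3, n_restarts=1),
                        grid=g, seed=0)
    smooth = fit_filters(X, b, Priors(lam=1.0, omega=0.05, grid=g),
                         FitConfig(n_rounds=3, n_restarts=1), grid=g, seed=0)
    assert smooth.log_likelihood <= ridge.log_likelihood + 1e-6


def test_bootstrap_identity_equals_single_fit():
    X, b = random_problem(n=120, d=16, seed=11)
    single = fit_small(X, b, seed=4)
    ens = bootstrap_fits(X, b, 1, Priors(lam=1.0, grid=4),
                         FitConfig(n_rounds=4, n_restarts=1), grid=4, seed=4,
                         resample=False)
    assert ens[0].log_posterior == single.log_posterior
    means, sems = weight_map_stats(ens)
    np.testing.assert_array_equal(means[0], single.model.filters[0])
    assert np.all(sems[0] == 0)


def test_bootstrap_reproducible_and_sems_positive():
    X, b = random_problem(n=150, d=16, seed=12)
    kw = dict(priors=Priors(lam=1.0, grid=4), config=FitConfig(n_rounds=3, n_restarts=1),
              grid=4, seed=7)
    e1 = bootstrap_fits(X, b, 4, **kw)
    e2 = bootstrap_fits(X, b, 4, **kw)
    assert [f.log_posterior for f in e1] == [f.log_posterior for f in e2]
    _, sems = weight_map_stats(e1)
    assert np.all(sems[0] >= 0) and sems[0].mean() > 0


def test_internal_noise_self_consistency():
    """Trials generated by the model itself (STO) recover beta ~ 1."""
    rng = np.random.default_rng(13)
    X = rng.gamma(2.0, 1.0, (4000, 8))
    m = FRFModel.zeros(8, alpha=1.0)
    m.filters = [np.zeros(8), rng.normal(0, 0.4, 8)]
    m.bias = -float(np.median(np.abs(X @ m.filters[1])))
    trials = simulate_responses(X, m, "STO", seed=3)
    beta = fit_internal_noise(m, X, trials["response"])
    assert 0.8 < beta < 1.25


def test_internal_noise_bounds():
    rng = np.random.default_rng(14)
    X = rng.gamma(2.0, 1.0, (500, 8))
    m = FRFModel.zeros(8, alpha=1.0)
    m.filters = [np.zeros(8), rng.normal(0, 0.4, 8)]
    m.bias = -float(np.median(np.abs(X @ m.filters[1])))
    coin = np.where(rng.random(500) < 0.5, "R", "L")
    # random responses: likelihood is maximized by flattening p toward 0.5,
    # so beta shrinks toward the lower bound (an exact boundary solution is
    # prevented only by finite-sample correlation between u and the coin)
    assert fit_internal_noise(m, X, coin) < 0.1
    agree = np.where(m.decision_variable(X) > 0, "R", "L")
    assert fit_internal_noise(m, X, agree) == pytest.approx(1e3, rel=0.01)
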