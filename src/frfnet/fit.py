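"""MAP estimation of FRF models from binary trial data.

The posterior combines a Bernoulli log-likelihood over trials with a
Gaussian ridge prior on every second-stage filter, ln p0(w) =
-(1/2 lambda) sum_j w_j^2, optionally augmented by a smoothness prior
-(1/2 omega) w^T (S2^T S2) w built from the 2-D discrete Laplacian applied
at every grid location (smaller lambda / omega = stronger penalty).

Optimization is alternating coordinate ascent: each filter in turn is
optimized by L-BFGS (jointly with the bias, which is low-dimensional),
then the power-law exponent alpha by a grid + golden-section line search
over [0.1, 4.0].  Because the landscape is not log-concave the search can
stall in a one-nonzero-filter local maximum; after a configured round the
smaller-norm filter of each L/R pair is therefore re-initialized to the
mirror image (left-right flip on the grid) of the larger one and the
ascent continues.  Several random restarts are run and the best posterior
wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .model import FRFModel, POWER_EPS, rectified_power

__all__ = [
    "Priors", "FitConfig", "FitResult", "laplacian_operator", "log_posterior",
    "fit_filters", "crossval_hyperparams", "bootstrap_fits", "fit_internal_noise",
    "encode_responses", "weight_map_stats",
]


def encode_responses(responses) -> np.ndarray:
    """Map responses to the modeled event b in {0, 1}, with b = 1 for 'R'."""
    arr = np.asarray(responses)
    if arr.dtype.kind in "UOS":
        return (arr == "R").astype(float)
    vals = np.unique(arr)
    if np.all(np.isin(vals, (-1, 1))):
        return (arr > 0).astype(float)
    return arr.astype(float)


def laplacian_operator(grid: int) -> np.ndarray:
    """S2: the 2-D discrete Laplace stencil centered at every grid location.

    Zero-padded (Dirichlet) handling at the grid edges; shape (grid^2, grid^2).
    """
    d = grid * grid
    s2 = np.zeros((d, d))
    for i in range(grid):
        for j in range(grid):
            r = i * grid + j
            s2[r, r] = 4.0
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < grid and 0 <= jj < grid:
                    s2[r, ii * grid + jj] = -1.0
    return s2


@dataclass(frozen=True)
class Priors:
    """Ridge (lam) and optional Laplacian-smoothness (omega) hyperparameters."""

    lam: float = 1.0
    omega: float | None = None
    grid: int | None = None  # needed to build S2 when omega is set

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.omega is not None and self.omega <= 0:
            raise ValueError("omega must be positive when present")

    def smoothness_matrix(self) -> np.ndarray | None:
        if self.omega is None:
            return None
        if self.grid is None:
            raise ValueError("smoothness prior requires the grid size")
        s2 = laplacian_operator(self.grid)
        return s2.T @ s2


def _prior_terms(w: np.ndarray, priors: Priors, K: np.ndarray | None):
    """(log-prior value, gradient) for one filter; K = S2^T S2 per channel block."""
    value = -0.5 / priors.lam * float(w @ w)
    grad = -w / priors.lam
    if K is not None:
        d = K.shape[0]
        for start in range(0, w.size, d):
            blk = w[start : start + d]
            kb = K @ blk
            value += -0.5 / priors.omega * float(blk @ kb)
            grad[start : start + d] += -kb / priors.omega
    return value, grad


def _bernoulli_ll(u: np.ndarray, b: np.ndarray) -> float:
    # log sigma(u) = -log(1 + e^-u); numerically exact, equivalent to clipping p
    return float(b @ (-np.logaddexp(0.0, -u)) + (1 - b) @ (-np.logaddexp(0.0, u)))


def log_posterior(model: FRFModel, X: np.ndarray, b, priors: Priors,
                  active: int | None = None):
    """ln p(eta | D) up to a constant; optionally with its gradient.

    When ``active`` names a filter index, also returns the analytic gradient
    with respect to [that filter's weights, the bias], which matches central
    finite differences.
    """
    b = encode_responses(b)
    z = model.projections(X)
    v = np.asarray(model.output_weights, dtype=float)
    s = rectified_power(z, model.alpha)
    u = s @ v + model.bias
    value = _bernoulli_ll(u, b)
    K = priors.smoothness_matrix()
    for w in model.filters:
        value += _prior_terms(w, priors, K)[0]
    if active is None:
        return value
    from scipy.special import expit
    p = expit(u)
    resid = b - p
    zk = z[:, active]
    dsdz = model.alpha * (np.abs(zk) + POWER_EPS) ** (model.alpha - 1.0) * np.sign(zk)
    if model.architecture == "late_sum":
        d = model.filters[0].size
        Xk = X[:, (active // 2) * d : (active // 2 + 1) * d]
    else:
        Xk = X
    grad_w = Xk.T @ (resid * v[active] * dsdz)
    grad_w += _prior_terms(model.filters[active], priors, K)[1]
    grad_b = float(resid.sum())
    return value, np.concatenate([grad_w, [grad_b]])


@dataclass(frozen=True)
class FitConfig:
    """Coordinate-ascent schedule and optimizer settings."""

    n_rounds: int = 6
    mirror_round: int = 1  # mirror re-init happens after this round (0 disables)
    alpha_range: tuple[float, float] = (0.1, 4.0)
    alpha_step: float = 0.05
    n_restarts: int = 3
    init_sd: float = 0.01
    lbfgs_maxiter: int = 300
    tol: float = 1e-6  # relative posterior improvement for early stopping
    k_folds: int = 4


@dataclass
class FitResult:
    model: FRFModel
    priors: Priors
    config: FitConfig
    log_posterior: float
    log_likelihood: float
    trace: pd.DataFrame
    converged: bool
    seed: int
    restart: int
    bootstrap: list | None = None

    @property
    def filter_norms(self) -> list[float]:
        return self.model.filter_norms


def _mirror(w: np.ndarray, grid: int) -> np.ndarray:
    """Left-right flip of a (possibly multi-channel) grid-shaped filter."""
    d = grid * grid
    out = np.empty_like(w)
    for start in range(0, w.size, d):
        out[start : start + d] = np.fliplr(
            w[start : start + d].reshape(grid, grid)
        ).reshape(-1)
    return out


def _optimize_filter(model: FRFModel, k: int, X: np.ndarray, b: np.ndarray,
                     priors: Priors, config: FitConfig) -> float:
    """L-BFGS ascent on (w_k, v0) with all other filters and alpha fixed."""
    w0 = np.concatenate([model.filters[k], [model.bias]])

    def neg(theta):
        model.filters[k] = theta[:-1]
        model.bias = float(theta[-1])
        value, grad = log_posterior(model, X, b, priors, active=k)
        return -value, -grad

    res = minimize(neg, w0, jac=True, method="L-BFGS-B",
                   options={"maxiter": config.lbfgs_maxiter})
    best = res.x if -res.fun >= -neg(w0)[0] else w0  # never accept a decrease
    model.filters[k] = best[:-1]
    model.bias = float(best[-1])
    return log_posterior(model, X, b, priors)


def _optimize_alpha(model: FRFModel, X: np.ndarray, b: np.ndarray,
                    priors: Priors, config: FitConfig) -> float:
    """Grid + golden-section line search for alpha with filters fixed."""
    z = model.projections(X)
    v = np.asarray(model.output_weights, dtype=float)
    K = priors.smoothness_matrix()
    prior_const = sum(_prior_terms(w, priors, K)[0] for w in model.filters)

    def value(alpha: float) -> float:
        u = rectified_power(z, alpha) @ v + model.bias
        return _bernoulli_ll(u, b) + prior_const

    lo, hi = config.alpha_range
    grid = np.clip(np.arange(lo, hi + 1e-9, config.alpha_step), lo, hi)
    vals = np.array([value(a) for a in grid])
    i = int(np.argmax(vals))
    a_lo = grid[max(i - 1, 0)]
    a_hi = grid[min(i + 1, len(grid) - 1)]
    if a_hi > a_lo:
        res = minimize_scalar(lambda a: -value(a), bounds=(a_lo, a_hi),
                              method="bounded", options={"xatol": 1e-4})
        if -res.fun >= vals[i]:
            model.alpha = float(res.x)
        else:
            model.alpha = float(grid[i])
    else:
        model.alpha = float(grid[i])
    return value(model.alpha)


def _pairs(model: FRFModel):
    return [(0, 1)] if model.architecture != "late_sum" else [(0, 1), (2, 3)]


def fit_filters(X: np.ndarray, responses, priors: Priors,
                config: FitConfig = FitConfig(), architecture: str = "single",
                n_channels: int = 1, grid: int | None = None,
                seed: int = 0) -> FitResult:
    """MAP fit of an FRF model by alternating coordinate ascent.

    ``X`` is the (n_trials, n_features) feature matrix and ``responses`` the
    binary responses ('L'/'R', 0/1 or -1/+1; b=1 means R).  Returns the best
    solution over ``config.n_restarts`` random initializations.
    """
    X = np.asarray(X, dtype=float)
    b = encode_responses(responses)
    if b.sum() < 2 or (1 - b).sum() < 2:
        raise ValueError("need at least 2 trials of each response class")
    if grid is None:
        grid = priors.grid
    best: FitResult | None = None
    root = np.random.SeedSequence(entropy=seed, spawn_key=(0xF1,))
    for restart, ss in enumerate(root.spawn(config.n_restarts)):
        rng = np.random.default_rng(ss)
        model = FRFModel.zeros(X.shape[1], architecture=architecture,
                               n_channels=n_channels, grid=grid, alpha=2.0)
        for i in range(len(model.filters)):
            model.filters[i] = rng.normal(0.0, config.init_sd, model.filters[i].size)
        rows = []
        current = log_posterior(model, X, b, priors)
        rows.append({"round": 0, "stage": "init", "objective": current,
                     "alpha": model.alpha})
        converged = False
        for rnd in range(1, config.n_rounds + 1):
            start_obj = current
            for k in range(len(model.filters)):
                current = _optimize_filter(model, k, X, b, priors, config)
                rows.append({"round": rnd, "stage": f"filter_{k}",
                             "objective": current, "alpha": model.alpha})
            current = _optimize_alpha(model, X, b, priors, config)
            rows.append({"round": rnd, "stage": "alpha", "objective": current,
                         "alpha": model.alpha})
            if rnd == config.mirror_round and config.mirror_round > 0 and grid:
                for (i, j) in _pairs(model):
                    ni, nj = np.linalg.norm(model.filters[i]), np.linalg.norm(model.filters[j])
                    small, large = (i, j) if ni < nj else (j, i)
                    model.filters[small] = _mirror(model.filters[large], grid)
                current = log_posterior(model, X, b, priors)
                rows.append({"round": rnd, "stage": "mirror_reinit",
                             "objective": current, "alpha": model.alpha})
            elif rnd > config.mirror_round:
                rel = abs(current - start_obj) / max(abs(start_obj), 1.0)
                if rel < config.tol:
                    converged = True
                    break
        if not converged and config.n_rounds > 1:
            # ran out of rounds without the objective settling
            pass
        z = model.projections(X)
        u = rectified_power(z, model.alpha) @ np.asarray(model.output_weights, float) \
            + model.bias
        ll = _bernoulli_ll(u, b)
        result = FitResult(model=model, priors=priors, config=config,
                           log_posterior=current, log_likelihood=ll,
                           trace=pd.DataFrame(rows), converged=converged,
                           seed=seed, restart=restart)
        if best is None or result.log_posterior > best.log_posterior:
            best = result
    if not best.converged:
        warnings.warn("coordinate ascent used all rounds without converging; "
                      "returning the best solution found", RuntimeWarning)
    return best


def _fold_indices(n: int, k: int, contiguous: bool, rng: np.random.Generator):
    idx = np.arange(n)
    if not contiguous:
        idx = rng.permutation(n)
    return np.array_split(idx, k)


def crossval_hyperparams(X: np.ndarray, responses, lam_grid, omega_grid=None,
                         k: int = 4, config: FitConfig = FitConfig(),
                         architecture: str = "single", n_channels: int = 1,
                         grid: int | None = None, seed: int = 0,
                         contiguous: bool = True):
    """k-fold cross-validation over ridge / smoothness hyperparameter grids.

    Returns (best_lambda, best_omega, curves) where curves is a tidy frame of
    per-value mean train and validation log-likelihoods.  Folds are contiguous
    blocks in trial order by default (session blocks); a degenerate fold with
    a single response class is replaced by a random re-split.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    lam_grid = list(lam_grid)
    omega_grid = [None] if omega_grid is None else list(omega_grid)
    if not lam_grid or not omega_grid:
        raise ValueError("hyperparameter grids must be nonempty")
    b = encode_responses(responses)
    n = len(b)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xCF,)))
    folds = _fold_indices(n, k, contiguous, rng)
    for attempt in range(20):
        degenerate = any(b[f].min() == b[f].max() for f in folds)
        if not degenerate:
            break
        warnings.warn("degenerate fold (single response class); re-splitting randomly",
                      RuntimeWarning)
        folds = _fold_indices(n, k, False, rng)
    rows = []
    for lam in lam_grid:
        for omega in omega_grid:
            priors = Priors(lam=lam, omega=omega, grid=grid)
            train_ll, val_ll = [], []
            for f, val_idx in enumerate(folds):
                train_idx = np.setdiff1d(np.arange(n), val_idx)
                fit = fit_filters(X[train_idx], b[train_idx], priors, config,
                                  architecture=architecture, n_channels=n_channels,
                                  grid=grid, seed=seed + f)
                train_ll.append(fit.log_likelihood / len(train_idx))
                u = fit.model.decision_variable(X[val_idx])
                val_ll.append(_bernoulli_ll(u, b[val_idx]) / len(val_idx))
            rows.append({"lambda": lam, "omega": omega,
                         "train_ll": float(np.mean(train_ll)),
                         "val_ll": float(np.mean(val_ll))})
    curves = pd.DataFrame(rows)
    best = curves.loc[curves["val_ll"].idxmax()]
    return float(best["lambda"]), best["omega"], curves


def bootstrap_fits(X: np.ndarray, responses, B: int, priors: Priors,
                   config: FitConfig = FitConfig(), architecture: str = "single",
                   n_channels: int = 1, grid: int | None = None, seed: int = 0,
                   resample: bool = True) -> list[FitResult]:
    """B refits on with-replacement resamples of the trials.

    ``resample=False`` fits every replicate on the original data (so B=1
    reproduces a single fit exactly); the ensemble feeds weight-map means
    and SEMs.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    b = encode_responses(responses)
    n = len(b)
    root = np.random.SeedSequence(entropy=seed, spawn_key=(0xB0,))
    out = []
    for rep, ss in enumerate(root.spawn(B)):
        rng = np.random.default_rng(ss)
        idx = rng.integers(0, n, size=n) if resample else np.arange(n)
        out.append(fit_filters(X[idx], b[idx], priors, config,
                               architecture=architecture, n_channels=n_channels,
                               grid=grid, seed=seed))
    return out


def weight_map_stats(ensemble: list[FitResult]):
    """Per-filter mean and SEM weight maps over a bootstrap ensemble.

    The model is invariant under negating any filter (the rectifier is
    even), so refits return weights with arbitrary sign; each replicate is
    sign-aligned to the first ensemble member before averaging.
    """
    n_filters = len(ensemble[0].model.filters)
    means, sems = [], []
    for i in range(n_filters):
        ref = ensemble[0].model.filters[i]
        stack = np.stack([
            fr.model.filters[i] * (1.0 if fr.model.filters[i] @ ref >= 0 else -1.0)
            for fr in ensemble
        ])
        means.append(stack.mean(axis=0))
        sems.append(stack.std(axis=0, ddof=1) / np.sqrt(len(ensemble))
                    if len(ensemble) > 1 else np.zeros(stack.shape[1]))
    return means, sems


def fit_internal_noise(model: FRFModel, X: np.ndarray, responses,
                       bounds: tuple[float, float] = (1e-3, 1e3)) -> float:
    """1-D search for the inverse-internal-noise scale beta > 0.

    Maximizes the Bernoulli likelihood of the training responses with the
    decision variable scaled by beta; the default pipeline leaves beta = 1
    (absorbed into the filter norms).
    """
    b = encode_responses(responses)
    u = model.decision_variable(X)

    def neg(log_beta: float) -> float:
        return -_bernoulli_ll(np.exp(log_beta) * u, b)

    res = minimize_scalar(neg, bounds=(np.log(bounds[0]), np.log(bounds[1])),
                          method="bounded", options={"xatol": 1e-6})
    return float(np.exp(res.x))
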