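"""Model-accuracy diagnostics.

Psychometric functions and binomial-proportion comparisons use Wald
(normal-approximation) 95% intervals, p_hat +/- 1.96*sqrt(p_hat(1-p_hat)/n),
throughout.  Double-pass analysis compares observer self-consistency across
two presentations of the same stimuli with model-observer agreement, which
bounds the explainable response variance.  Decision-variable correlation
(DVC) estimates the trial-wise correlation between the latent decision
variables of model and observer per stimulus category, assuming a bivariate
Gaussian with criteria fixed from the marginal response rates and the
correlation estimated by maximum likelihood over the 2x2 agreement counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm, pearsonr, spearmanr

Z95 = 1.96


def _wald_ci(p: float, n: int) -> tuple[float, float]:
    half = Z95 * np.sqrt(p * (1 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def correctness(trials: pd.DataFrame) -> np.ndarray:
    """Per-trial correctness: response equals the (possibly random) category label."""
    return (np.asarray(trials["response"]) == np.asarray(trials["category"])).astype(float)


def psychometric(trials: pd.DataFrame, levels=None) -> pd.DataFrame:
    """Proportion correct per modulation level, with 95% Wald intervals."""
    df = trials.copy()
    df["correct"] = correctness(df)
    use_levels = sorted(df["level"].unique()) if levels is None else list(levels)
    rows = []
    for level in use_levels:
        sel = df[np.isclose(df["level"], level)]
        n = len(sel)
        if n == 0:
            warnings.warn(f"no trials at level {level}; skipped", RuntimeWarning)
            continue
        p = float(sel["correct"].mean())
        lo, hi = _wald_ci(p, n)
        rows.append({"level": level, "n": n, "p_correct": p, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


@dataclass
class ProportionDifference:
    difference: float
    ci_low: float
    ci_high: float
    brackets_zero: bool


def performance_difference(correct_obs, correct_model) -> ProportionDifference:
    """Observer-minus-model proportion correct with a binomial-difference 95% CI."""
    a = np.asarray(correct_obs, dtype=float)
    m = np.asarray(correct_model, dtype=float)
    p1, p2 = a.mean(), m.mean()
    d = p1 - p2
    half = Z95 * np.sqrt(p1 * (1 - p1) / len(a) + p2 * (1 - p2) / len(m))
    return ProportionDifference(d, d - half, d + half, bool(d - half <= 0 <= d + half))


@dataclass
class DoublePassResult:
    obs_obs_agreement: float
    model_obs_agreement: float
    difference: ProportionDifference


def double_pass(obs_pass1, obs_pass2, model_pass1, model_pass2=None) -> DoublePassResult:
    """Double-pass consistency analysis on a registered stimulus set.

    ``obs_pass1``/``obs_pass2`` are the observer's responses to the identical
    stimuli in registered order.  Model responses may be given once (DET: the
    prediction is the same on both passes) or per pass (STO).  Model-observer
    agreement is averaged over the two passes.
    """
    o1 = np.asarray(obs_pass1)
    o2 = np.asarray(obs_pass2)
    if o1.shape != o2.shape:
        raise ValueError("the two passes must cover the same stimuli in order")
    m1 = np.asarray(model_pass1)
    m2 = m1 if model_pass2 is None else np.asarray(model_pass2)
    obs_obs = float(np.mean(o1 == o2))
    per_pass = [float(np.mean(m1 == o1)), float(np.mean(m2 == o2))]
    model_obs = float(np.mean(per_pass))
    n = o1.size
    d = obs_obs - model_obs
    half = Z95 * np.sqrt(obs_obs * (1 - obs_obs) / n + model_obs * (1 - model_obs) / n)
    diff = ProportionDifference(d, d - half, d + half, bool(d - half <= 0 <= d + half))
    return DoublePassResult(obs_obs, model_obs, diff)


# ---------------------------------------------------------------------------
# decision variable correlation
# ---------------------------------------------------------------------------


def _rho_mle(counts: np.ndarray) -> float:
    """ML estimate of the latent correlation from 2x2 (obs x model) counts.

    ``counts[i, j]``: i = observer chose R, j = model chose R.  Criteria are
    fixed from the marginals (probit of the marginal response rates).
    """
    n = counts.sum()
    p_obs = counts[1].sum() / n
    p_mod = counts[:, 1].sum() / n
    if p_obs in (0.0, 1.0) or p_mod in (0.0, 1.0):
        return np.nan
    a = norm.ppf(1 - p_obs)
    bb = norm.ppf(1 - p_mod)

    def nll(rho: float) -> float:
        cdf = multivariate_normal.cdf([a, bb], mean=[0.0, 0.0],
                                      cov=[[1.0, rho], [rho, 1.0]])
        p_ll = cdf
        p_rl = norm.cdf(bb) - cdf
        p_lr = norm.cdf(a) - cdf
        p_rr = 1.0 - norm.cdf(a) - norm.cdf(bb) + cdf
        probs = np.clip([[p_ll, p_lr], [p_rl, p_rr]], 1e-12, 1.0)
        return -float((counts * np.log(probs)).sum())

    res = minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-5})
    return float(res.x)


def _agreement_counts(obs, mod) -> np.ndarray:
    obs_r = np.asarray(obs) == "R"
    mod_r = np.asarray(mod) == "R"
    return np.array([
        [np.sum(~obs_r & ~mod_r), np.sum(~obs_r & mod_r)],
        [np.sum(obs_r & ~mod_r), np.sum(obs_r & mod_r)],
    ], dtype=float)


@dataclass
class DVCResult:
    """Per-category decision-variable correlations with bootstrap SEMs."""

    rho: dict  # category -> rho_hat (nan if degenerate)
    sem: dict  # category -> bootstrap SEM
    counts: dict  # category -> 2x2 agreement counts (obs x model)
    degenerate: dict  # category -> bool


def decision_variable_correlation(categories, obs_responses, model_responses,
                                  n_boot: int = 200, seed: int = 0) -> DVCResult:
    """Estimate rho_A, rho_B from trial-wise model/observer agreement.

    One correlation per stimulus category; SEMs from ``n_boot`` bootstrap
    resamples of the trials within each category.  The estimator is symmetric
    in its observer/model arguments.
    """
    cats = np.asarray(categories)
    obs = np.asarray(obs_responses)
    mod = np.asarray(model_responses)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xDC,)))
    rho, sem, counts, degenerate = {}, {}, {}, {}
    for cat in np.unique(cats):
        sel = cats == cat
        c = _agreement_counts(obs[sel], mod[sel])
        counts[cat] = c
        r = _rho_mle(c)
        rho[cat] = r
        degenerate[cat] = bool(np.isnan(r))
        if np.isnan(r):
            warnings.warn(f"degenerate marginals for category {cat}; rho undefined",
                          RuntimeWarning)
            sem[cat] = np.nan
            continue
        o, m = obs[sel], mod[sel]
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(o), size=len(o))
            rb = _rho_mle(_agreement_counts(o[idx], m[idx]))
            if not np.isnan(rb):
                boots.append(rb)
        sem[cat] = float(np.std(boots, ddof=1)) if len(boots) > 1 else np.nan
    return DVCResult(rho=rho, sem=sem, counts=counts, degenerate=degenerate)


# ---------------------------------------------------------------------------
# 1-D profile collapse and ensemble summaries
# ---------------------------------------------------------------------------


def collapse_1d(weight_map: np.ndarray, orientation: str,
                unit_norm: bool = False) -> np.ndarray:
    """Collapse a square 2-D weight map into a 1-D profile.

    ``left_oblique`` averages along the matrix main diagonals (the direction
    of a left-oblique boundary on screen), ``right_oblique`` along the
    anti-diagonals, ``vertical`` along columns.  Diagonal profiles have
    length 2*grid - 1, the vertical profile has length grid.  The unit-norm
    variant divides the profile by its Euclidean norm.
    """
    w = np.asarray(weight_map, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight map must be square")
    g = w.shape[0]
    if orientation == "left_oblique":
        profile = np.array([np.diag(w, k).mean() for k in range(-(g - 1), g)])
    elif orientation == "right_oblique":
        flipped = np.fliplr(w)
        profile = np.array([np.diag(flipped, k).mean() for k in range(g - 1, -g, -1)])
    elif orientation == "vertical":
        profile = w.mean(axis=0)
    else:
        raise ValueError("orientation must be left_oblique, right_oblique or vertical")
    if unit_norm:
        nrm = np.linalg.norm(profile)
        if nrm > 0:
            profile = profile / nrm
    return profile


@dataclass
class SummaryStatistics:
    norm_sums: np.ndarray
    alphas: np.ndarray
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    degenerate: bool


def summary_statistics(fit_results, performance=None) -> SummaryStatistics:
    """Filter-norm sums and alphas per fitted observer, optionally correlated
    with supplied performance values (Pearson and Spearman)."""
    norm_sums = np.array([sum(fr.filter_norms) for fr in fit_results])
    alphas = np.array([fr.model.alpha for fr in fit_results])
    r = p = rho = sp = np.nan
    degenerate = True
    if performance is not None:
        perf = np.asarray(performance, dtype=float)
        if len(perf) >= 3 and np.std(norm_sums) > 0 and np.std(perf) > 0:
            r, p = pearsonr(norm_sums, perf)
            rho, sp = spearmanr(norm_sums, perf)
            degenerate = False
        else:
            warnings.warn("zero-variance or too-few observers; correlations undefined",
                          RuntimeWarning)
    return SummaryStatistics(norm_sums, alphas, float(r), float(p),
                             float(rho), float(sp), degenerate)
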