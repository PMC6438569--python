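"""Bayesian model comparison for binary-response models.

For two binomial models predicting positive-response probabilities p1, p2
against an observed proportion p* over n trials, the natural-log Bayes
factor has the closed form

    ln B21 = n * (D_KL(p*||p1) - D_KL(p*||p2)),

which is an exact algebraic rearrangement of the Bernoulli likelihood
ratio.  For two fitted models with equal parameter counts the BIC
complexity terms cancel and Delta_BIC = ln p2(D) - ln p1(D) evaluated at
the MAP parameters; 2 ln B21 > 10 is the conventional "very strong"
criterion.  Natural logarithms are used everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit import FitConfig, Priors, encode_responses, fit_filters, _bernoulli_ll

VERY_STRONG = 10.0  # conventional 2 ln B threshold


def kl_bernoulli(p: float, q: float) -> float:
    """D_KL(p||q) between Bernoulli distributions, natural log, 0*ln0 = 0."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if q in (0.0, 1.0):
        if p == q:
            return 0.0
        warnings.warn("infinite divergence: q is degenerate and p != q", RuntimeWarning)
        return np.inf
    out = 0.0
    if p > 0.0:
        out += p * np.log(p / q)
    if p < 1.0:
        out += (1.0 - p) * np.log((1.0 - p) / (1.0 - q))
    return float(out)


@dataclass
class BinomialComparison:
    p_star: float
    p1: float
    p2: float
    n: int
    ln_B21: float
    two_ln_B21: float
    fold_preference: float

    @property
    def very_strong(self) -> bool:
        return self.two_ln_B21 > VERY_STRONG


def bayes_factor_binomial(p_star: float, p1: float, p2: float, n: int) -> BinomialComparison:
    """Closed-form Bayes factor between two binomial response models."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ln_b = n * (kl_bernoulli(p_star, p1) - kl_bernoulli(p_star, p2))
    return BinomialComparison(
        p_star=p_star, p1=p1, p2=p2, n=n,
        ln_B21=float(ln_b), two_ln_B21=float(2 * ln_b),
        fold_preference=float(np.exp(ln_b)),
    )


@dataclass
class BICComparison:
    ln_l1: float
    ln_l2: float
    delta_bic: float  # ln p2(D) - ln p1(D) at the MAP
    two_ln_B21: float

    @property
    def very_strong(self) -> bool:
        return self.two_ln_B21 > VERY_STRONG


def model_log_likelihood(model, X: np.ndarray, responses) -> float:
    """Bernoulli log-likelihood of trials under a fitted model (gamma = 0)."""
    b = encode_responses(responses)
    u = model.beta * model.decision_variable(X)
    return _bernoulli_ll(u, b)


def delta_bic(model1, model2, X: np.ndarray, responses) -> BICComparison:
    """Delta BIC for two equal-dimension models on identical trials.

    Refuses models with different parameter counts: the cancellation of the
    BIC complexity terms (and hence the shortcut) is only valid when the
    dimensionalities match.
    """
    if model1.n_parameters != model2.n_parameters:
        raise ValueError(
            "delta_bic requires equal parameter counts "
            f"({model1.n_parameters} vs {model2.n_parameters})"
        )
    l1 = model_log_likelihood(model1, X, responses)
    l2 = model_log_likelihood(model2, X, responses)
    return BICComparison(ln_l1=l1, ln_l2=l2, delta_bic=l2 - l1,
                         two_ln_B21=2.0 * (l2 - l1))


def bootstrap_generalization(X: np.ndarray, responses, spec1: dict, spec2: dict,
                             B: int = 50, train_n: int = 4000, test_n: int = 1000,
                             config: FitConfig = FitConfig(), seed: int = 0) -> pd.DataFrame:
    """Held-out likelihood comparison of two model specifications.

    Each bootstrap draws a random train/test split (``train_n`` training
    trials, ``test_n`` held out), fits both specifications — each a dict with
    keys ``architecture``, ``n_channels``, ``grid`` and ``priors`` (its own
    cross-validated hyperparameters) — and records the test-set
    log-likelihood of each.  Returns one row per bootstrap with columns
    ``ll_test_1``, ``ll_test_2``; summarize with mean +/- SEM per model.
    """
    b = encode_responses(responses)
    n = len(b)
    if train_n + test_n > n:
        raise ValueError("train_n + test_n exceeds the number of trials")
    root = np.random.SeedSequence(entropy=seed, spawn_key=(0xB6,))
    rows = []
    for rep, ss in enumerate(root.spawn(B)):
        rng = np.random.default_rng(ss)
        perm = rng.permutation(n)
        train_idx = perm[:train_n]
        test_idx = perm[train_n : train_n + test_n]
        lls = {}
        for tag, spec in (("1", spec1), ("2", spec2)):
            fit = fit_filters(X[train_idx], b[train_idx], spec["priors"], config,
                              architecture=spec["architecture"],
                              n_channels=spec.get("n_channels", 1),
                              grid=spec.get("grid"), seed=seed + rep)
            lls[tag] = model_log_likelihood(fit.model, X[test_idx], b[test_idx])
        rows.append({"bootstrap": rep, "ll_test_1": lls["1"], "ll_test_2": lls["2"]})
    return pd.DataFrame(rows)


def summarize_generalization(results: pd.DataFrame) -> dict:
    out = {}
    for tag in ("1", "2"):
        col = results[f"ll_test_{tag}"]
        out[f"model{tag}_mean"] = float(col.mean())
        out[f"model{tag}_sem"] = float(col.std(ddof=1) / np.sqrt(len(col)))
    out["preference_rate_2"] = float((results["ll_test_2"] >= results["ll_test_1"]).mean())
    return out
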