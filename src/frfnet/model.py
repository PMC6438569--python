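"""The FRF psychophysical network: second-stage filters and decision rule.

Each hidden unit projects the feature vector x onto a second-stage filter
w_i and passes the result through the even rectified power law
h(z) = |z|^alpha.  Output weights are fixed at +1 for R-units and -1 for
L-units (the scale of a filter and its output weight are degenerate under
the power law, v*||w||^alpha = const, so v can be fixed).  The decision
variable u = sum_i v_i s_i + v0 feeds a logistic sigmoid to give
P(R) = gamma/2 + (1 - gamma) * sigma(beta * u); the lapse rate gamma is 0
throughout and the explicit inverse-internal-noise scale beta defaults to 1
(it is normally absorbed into the filter norms).

Three architectures are supported: ``single``/``early_sum`` (one L/R filter
pair over the full, possibly multi-channel, feature vector) and
``late_sum`` (one L/R pair per channel, summed at the output).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

ARCHITECTURES = ("single", "early_sum", "late_sum")
POWER_EPS = 1e-12  # |z| guard keeping gradients finite near 0 for alpha < 1


def rectified_power(z: np.ndarray, alpha: float) -> np.ndarray:
    """h(z) = |z|^alpha, evaluated as (|z| + eps)^alpha for gradient stability."""
    return np.exp(alpha * np.log(np.abs(z) + POWER_EPS))


@dataclass
class FRFModel:
    """Second-stage filters plus decision parameters.

    ``filters`` is a list of weight vectors aligned with ``output_weights``
    (each +1 or -1).  For ``single``/``early_sum`` the order is (L, R) with
    output weights (-1, +1); for ``late_sum`` it is (L1, R1, L2, R2), one
    L/R pair per first-stage channel, each filter of per-channel length.
    """

    filters: list[np.ndarray]
    output_weights: tuple[int, ...]
    bias: float = 0.0
    alpha: float = 2.0
    architecture: str = "single"
    decision_mode: str = "DET"
    gamma: float = 0.0
    beta: float = 1.0
    grid: int | None = None
    n_channels: int = 1

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.decision_mode not in ("DET", "STO"):
            raise ValueError("decision_mode must be DET or STO")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        expected = 4 if self.architecture == "late_sum" else 2
        if len(self.filters) != expected or len(self.output_weights) != expected:
            raise ValueError(
                f"{self.architecture} architecture requires {expected} filters"
            )
        self.filters = [np.asarray(w, dtype=float) for w in self.filters]

    # ---- construction -------------------------------------------------

    @classmethod
    def zeros(cls, n_features: int, architecture: str = "single",
              n_channels: int = 1, **kw) -> "FRFModel":
        if architecture == "late_sum":
            if n_channels != 2:
                raise ValueError("late_sum is defined for two first-stage channels")
            d = n_features // n_channels
            filters = [np.zeros(d) for _ in range(4)]
            output_weights = (-1, +1, -1, +1)
        else:
            filters = [np.zeros(n_features), np.zeros(n_features)]
            output_weights = (-1, +1)
        return cls(filters=filters, output_weights=output_weights,
                   architecture=architecture, n_channels=n_channels, **kw)

    # ---- forward pass --------------------------------------------------

    def projections(self, X: np.ndarray) -> np.ndarray:
        """(n, K) matrix of filter projections z_i = w_i^T x."""
        X = np.atleast_2d(X)
        if self.architecture == "late_sum":
            d = self.filters[0].size
            chunks = [X[:, (i // 2) * d : (i // 2 + 1) * d] for i in range(4)]
            return np.column_stack([c @ w for c, w in zip(chunks, self.filters)])
        return np.column_stack([X @ w for w in self.filters])

    def hidden_activities(self, X: np.ndarray) -> np.ndarray:
        """s_i = |w_i^T x|^alpha >= 0, one column per hidden unit."""
        return rectified_power(self.projections(X), self.alpha)

    def decision_variable(self, X: np.ndarray) -> np.ndarray:
        s = self.hidden_activities(X)
        return s @ np.asarray(self.output_weights, dtype=float) + self.bias

    def decision_prob(self, X: np.ndarray) -> np.ndarray:
        """P(response = R) for each row of X."""
        u = self.decision_variable(X)
        return self.gamma / 2.0 + (1.0 - self.gamma) * expit(self.beta * u)

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "decision_mode": self.decision_mode,
            "alpha": self.alpha,
            "bias": self.bias,
            "gamma": self.gamma,
            "beta": self.beta,
            "grid": self.grid,
            "n_channels": self.n_channels,
            "output_weights": list(self.output_weights),
            "filters": [w.tolist() for w in self.filters],
        }

    def to_json(self, path=None) -> str:
        doc = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_dict(cls, d: dict) -> "FRFModel":
        return cls(
            filters=[np.array(w, dtype=float) for w in d["filters"]],
            output_weights=tuple(int(v) for v in d["output_weights"]),
            bias=float(d["bias"]),
            alpha=float(d["alpha"]),
            architecture=d["architecture"],
            decision_mode=d["decision_mode"],
            gamma=float(d["gamma"]),
            beta=float(d["beta"]),
            grid=d.get("grid"),
            n_channels=int(d.get("n_channels", 1)),
        )

    @classmethod
    def from_json(cls, source) -> "FRFModel":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        with open(text) as fh:
            return cls.from_dict(json.load(fh))

    @property
    def filter_norms(self) -> list[float]:
        return [float(np.linalg.norm(w)) for w in self.filters]

    @property
    def n_parameters(self) -> int:
        """Free parameters at the MAP: all filter weights, the bias and alpha."""
        return sum(w.size for w in self.filters) + 2


def second_stage_response(x: np.ndarray, w: np.ndarray, alpha: float) -> float:
    """s = |w^T x|^alpha for one feature vector and one filter."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != w.shape:
        raise ValueError("filter and feature vector lengths differ")
    return float(rectified_power(np.array(w @ x), alpha))


def classify(p_r, mode: str, rng: np.random.Generator | None = None):
    """Map P(R) to a response; DET thresholds at 0.5 (tie -> L), STO samples."""
    p = np.asarray(p_r, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_R must lie in [0, 1]")
    if mode == "DET":
        resp = np.where(p > 0.5, "R", "L")
    elif mode == "STO":
        if rng is None:
            raise ValueError("STO classification requires an rng")
        resp = np.where(rng.random(p.shape) < p, "R", "L")
    else:
        raise ValueError("mode must be DET or STO")
    return resp if resp.ndim else str(resp)


def simulate_responses(X: np.ndarray, model: FRFModel, mode: str | None = None,
                       seed: int = 0, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Run the model over a feature matrix and build a trial table.

    Records the decision variable u and P(R) for every trial so downstream
    double-pass and decision-variable-correlation analyses can reuse them.
    ``meta`` (optional) supplies stimulus_id / category / level / phase
    columns aligned with the rows of X.
    """
    mode = mode or model.decision_mode
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    u = model.decision_variable(X)
    p = model.gamma / 2.0 + (1.0 - model.gamma) * expit(model.beta * u)
    responses = classify(p, mode, rng)
    out = pd.DataFrame({
        "trial_id": np.arange(len(u)),
        "response": responses,
        "p_R": p,
        "u": u,
    })
    if meta is not None:
        for col in ("stimulus_id", "category", "level", "phase"):
            if col in meta.columns:
                out[col] = np.asarray(meta[col])
    return out
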