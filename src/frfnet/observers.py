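"""Ideal and ground-truth simulated observers.

The *ideal observer* dataset is simply the true stimulus category labels:
fitting the FRF architecture to labels instead of behavioral responses
yields the ideal observer model for a task.

The *ground-truth observers* implement alternative spatial-summation
strategies (pizza-slice monitoring, single-boundary monitoring,
off-orientation filters, ...) directly on the feature grid.  Because
envelope phase is randomized, every strategy works from the magnitudes of
linear template projections (|T x|), which is exactly the statistic an FRF
hidden unit computes.  Simulated responses add logistic decision noise
whose gain is calibrated to a target accuracy; fitting the standard FRF
model to these trials should recover the generating structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

OBSERVER_KINDS = (
    "ideal_labels", "two_slice", "three_slice", "one_filter",
    "two_slice_random", "two_filter", "off_orientation",
)

# adjacent compass-quadrant pairs; each is informative for exactly one category
_RANDOM_PAIRS = (("N", "E", "R"), ("S", "W", "R"), ("E", "S", "L"), ("W", "N", "L"))


def ideal_trials(meta: pd.DataFrame) -> pd.DataFrame:
    """Trials whose response equals the true category label on every trial.

    Zero-modulation stimuli carry their randomly assigned label.  Fitting the
    FRF model to these trials defines the ideal observer for the design.
    """
    if "category" not in meta.columns:
        raise ValueError("stimulus metadata must include a 'category' column")
    out = meta.copy()
    out["response"] = out["category"].to_numpy()
    if "trial_id" not in out.columns:
        out.insert(0, "trial_id", np.arange(len(out)))
    return out


def _grid_coords(grid: int):
    c = (grid - 1) / 2.0
    jj, ii = np.meshgrid(np.arange(grid, dtype=float), np.arange(grid, dtype=float))
    return jj - c, ii - c  # dx rightward, dy downward


def quadrant_masks(grid: int) -> dict[str, np.ndarray]:
    """Compass-quadrant ("pizza slice") masks of the inscribed circular window."""
    dx, dy = _grid_coords(grid)
    r = np.hypot(dx, dy)
    window = r <= grid / 2.0
    return {
        "N": window & (dy < -np.abs(dx)),
        "E": window & (dx > np.abs(dy)),
        "S": window & (dy > np.abs(dx)),
        "W": window & (dx < -np.abs(dy)),
    }


def _norm_mask(mask: np.ndarray) -> np.ndarray:
    out = mask.astype(float)
    return out / out.sum()


def step_template(grid: int, orientation: float) -> np.ndarray:
    """Signed step on the feature grid: +1/-1 on the two sides of a boundary
    through the center at ``orientation`` degrees clockwise from vertical,
    zero outside the circular window and zero-mean inside it.

    Sign convention matches the stimulus envelope: the positive side is the
    one toward the bottom of the grid (the +x side for a vertical boundary),
    so the +theta and -theta templates are exact mirror images about the
    vertical midline.
    """
    dx, dy = _grid_coords(grid)
    th = np.deg2rad(orientation)
    s = dx * np.cos(th) + dy * np.sin(th)
    side = np.sign(np.sin(th)) if orientation != 0.0 else 1.0
    if side == 0.0:
        side = 1.0
    window = np.hypot(dx, dy) <= grid / 2.0
    t = side * np.sign(s) * window
    inside = window.sum()
    if inside:
        t = (t - window * (t.sum() / inside)) * window
    return t


@dataclass
class GroundTruthObserver:
    """A simulated observer defined by linear templates on the feature grid.

    ``templates`` maps template names to flattened grid weight vectors;
    ``thresholds`` (set by :meth:`calibrate`) centers each magnitude
    statistic, and ``gain`` scales the logistic decision noise.
    """

    kind: str
    grid: int
    templates: dict[str, np.ndarray]
    sectors: dict[str, np.ndarray] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    gain: float = 1.0

    def raw_statistics(self, X: np.ndarray, rng: np.random.Generator | None = None):
        """Per-trial decision statistic r (positive favors R) before noise.

        For ``two_slice_random`` the monitored slice pair is drawn per trial,
        which requires ``rng``; other kinds are deterministic.
        """
        X = np.atleast_2d(X)
        n = X.shape[0]
        if self.kind == "two_filter":
            return (np.abs(X @ self.templates["R"]) - np.abs(X @ self.templates["L"])
                    - self.thresholds.get("pair", 0.0))
        if self.kind == "off_orientation":
            return (np.abs(X @ self.templates["plus"]) - np.abs(X @ self.templates["minus"])
                    - self.thresholds.get("pair", 0.0))
        if self.kind in ("two_slice", "three_slice"):
            r = np.abs(X @ self.templates["T"]) - self.thresholds.get("T", 0.0)
            # two_slice: large magnitude signals R; three_slice: signals L
            return r if self.kind == "two_slice" else -r
        if self.kind == "one_filter":
            return np.abs(X @ self.templates["T"]) - self.thresholds.get("T", 0.0)
        if self.kind == "two_slice_random":
            if rng is None:
                raise ValueError("two_slice_random requires an rng")
            choice = rng.integers(0, len(_RANDOM_PAIRS), size=n)
            r = np.empty(n)
            for p, (a, bq, cat) in enumerate(_RANDOM_PAIRS):
                sel = choice == p
                name = a + bq
                stat = np.abs(X[sel] @ self.templates[name]) - self.thresholds.get(name, 0.0)
                r[sel] = stat if cat == "R" else -stat
            return r
        raise ValueError(f"unknown observer kind {self.kind!r}")

    def calibrate(self, X: np.ndarray) -> None:
        """Center each magnitude statistic at its median over a stimulus set."""
        X = np.atleast_2d(X)
        if self.kind in ("two_slice", "three_slice", "one_filter"):
            self.thresholds["T"] = float(np.median(np.abs(X @ self.templates["T"])))
        elif self.kind == "two_filter":
            self.thresholds["pair"] = float(np.median(
                np.abs(X @ self.templates["R"]) - np.abs(X @ self.templates["L"])))
        elif self.kind == "off_orientation":
            self.thresholds["pair"] = float(np.median(
                np.abs(X @ self.templates["plus"]) - np.abs(X @ self.templates["minus"])))
        elif self.kind == "two_slice_random":
            for a, bq, _ in _RANDOM_PAIRS:
                name = a + bq
                self.thresholds[name] = float(np.median(np.abs(X @ self.templates[name])))


def build_ground_truth(kind: str, grid: int, boundary_orientation: float = 45.0,
                       off_angle: float = 20.0) -> GroundTruthObserver:
    """Construct the filter set realizing one of the ground-truth observers."""
    if kind not in OBSERVER_KINDS or kind == "ideal_labels":
        raise ValueError(f"unknown ground-truth kind {kind!r}")
    q = quadrant_masks(grid)
    sectors: dict[str, np.ndarray] = {}
    templates: dict[str, np.ndarray] = {}
    if kind == "two_slice":
        t = _norm_mask(q["N"]) - _norm_mask(q["E"])
        templates["T"] = t.reshape(-1)
        sectors = {"N": q["N"], "E": q["E"]}
    elif kind == "three_slice":
        # monitors W, N, E: contrast in W against the N+E flank; the combined
        # magnitude is larger for a left-oblique boundary than a right-oblique
        t = 2.0 * _norm_mask(q["W"]) - _norm_mask(q["N"]) - _norm_mask(q["E"])
        templates["T"] = t.reshape(-1)
        sectors = {"W": q["W"], "N": q["N"], "E": q["E"]}
    elif kind == "one_filter":
        templates["T"] = step_template(grid, +boundary_orientation).reshape(-1)
    elif kind == "two_filter":
        templates["L"] = step_template(grid, -boundary_orientation).reshape(-1)
        templates["R"] = step_template(grid, +boundary_orientation).reshape(-1)
    elif kind == "two_slice_random":
        for a, bq, _ in _RANDOM_PAIRS:
            templates[a + bq] = (_norm_mask(q[a]) - _norm_mask(q[bq])).reshape(-1)
        sectors = dict(q)
    elif kind == "off_orientation":
        templates["plus"] = step_template(grid, +off_angle).reshape(-1)
        templates["minus"] = step_template(grid, -off_angle).reshape(-1)
    return GroundTruthObserver(kind=kind, grid=grid, templates=templates, sectors=sectors)


def calibrate_gain(u: np.ndarray, categories: np.ndarray, target_accuracy: float,
                   bounds: tuple[float, float] = (1e-4, 1e6)) -> float:
    """Logistic noise gain g such that E[accuracy] of STO responses hits target.

    For response R with probability sigma(g*u), the expected accuracy is
    mean(sigma(g * u * c)) with c = +1 for true category R and -1 for L.
    """
    c = np.where(np.asarray(categories) == "R", 1.0, -1.0)
    uc = u * c

    def acc(log_g: float) -> float:
        return float(np.mean(expit(np.exp(log_g) * uc)))

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    if acc(hi) < target_accuracy:
        warnings.warn("target accuracy unreachable; using maximum gain", RuntimeWarning)
        return float(bounds[1])
    if acc(lo) > target_accuracy:
        return float(bounds[0])
    return float(np.exp(brentq(lambda g: acc(g) - target_accuracy, lo, hi, xtol=1e-8)))


def simulate_ground_truth(X: np.ndarray, meta: pd.DataFrame,
                          observer: GroundTruthObserver, seed: int = 0,
                          target_accuracy: float = 0.8) -> pd.DataFrame:
    """Simulate stochastic trials from a ground-truth observer.

    Thresholds are calibrated at the median statistic over the presented set
    (balancing the response rates) and the logistic gain is calibrated so the
    expected accuracy matches ``target_accuracy``.  Returns a trial table with
    the per-trial decision variable and P(R) recorded.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0x6E,)))
    observer.calibrate(X)
    u_raw = observer.raw_statistics(X, rng=rng)
    categories = np.asarray(meta["category"])
    observer.gain = calibrate_gain(u_raw, categories, target_accuracy)
    p = expit(observer.gain * u_raw)
    responses = np.where(rng.random(len(p)) < p, "R", "L")
    out = meta.copy()
    out["response"] = responses
    out["p_R"] = p
    out["u"] = observer.gain * u_raw
    if "trial_id" not in out.columns:
        out.insert(0, "trial_id", np.arange(len(out)))
    return out
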