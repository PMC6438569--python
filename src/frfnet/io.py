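"""File formats, configuration and the end-to-end pipeline.

Trial tables are comma-separated text with a header; categories and
responses are the literal tokens "L"/"R" (internally the modeled event is
b = 1 for an R classification).  Stimuli are written as 8-bit grayscale
PNGs (128 = zero contrast) with a sidecar CSV manifest.  Models are JSON
documents.  All randomness flows from a single integer seed through
stage-scoped substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import evaluation, frontend, observers, stimuli
from .fit import FitConfig, Priors, fit_filters
from .model import FRFModel, simulate_responses
from .stimuli import to_uint8

log = logging.getLogger("frfnet")

REQUIRED_TRIAL_COLUMNS = ("trial_id", "level", "category", "response")
VALID_TOKENS = {"L", "R"}


def write_trials(trials: pd.DataFrame, path) -> None:
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    for col in ("category", "response"):
        bad = ~df[col].isin(VALID_TOKENS)
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(
                f"{path}: unknown {col} token {df[col].iloc[row]!r} at row {row}"
            )
    if (df["level"] < 0).any():
        raise ValueError(f"{path}: negative modulation level")
    return df


def group_passes(trials: pd.DataFrame) -> dict:
    """Split a mixed trial table into per-pass tables keyed by pass_id,
    each ordered by stimulus_id for registered double-pass comparison."""
    if "pass_id" not in trials.columns:
        return {0: trials}
    return {
        int(pid): grp.sort_values("stimulus_id").reset_index(drop=True)
        for pid, grp in trials.groupby("pass_id")
    }


def write_stimuli(stims, out_dir, design_name: str = "") -> pd.DataFrame:
    """Write PNGs plus a manifest CSV; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in stims:
        fname = f"{s.stimulus_id}.png"
        Image.fromarray(to_uint8(s.pixels), mode="L").save(out / fname)
        rows.append({
            "stimulus_id": s.stimulus_id, "file": fname, "category": s.category,
            "level": s.level, "phase": s.phase, "orientation_deg": s.orientation_deg,
            "seed": s.seed,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def stimulus_metadata(stims) -> pd.DataFrame:
    return pd.DataFrame([
        {"stimulus_id": s.stimulus_id, "category": s.category, "level": s.level,
         "phase": s.phase, "orientation_deg": s.orientation_deg, "seed": s.seed}
        for s in stims
    ])


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def featurize_design(design, n_trials: int, seed: int,
                     config: frontend.FrontendConfig):
    """Stream-generate a stimulus set and featurize it without holding the
    images in memory; returns (X, metadata)."""
    feats, meta = [], []
    for s in stimuli.iter_stimulus_set(design, n_trials, seed):
        feats.append(frontend.featurize(s, config))
        meta.append({"stimulus_id": s.stimulus_id, "category": s.category,
                     "level": s.level, "phase": s.phase,
                     "orientation_deg": s.orientation_deg, "seed": s.seed})
    return np.array(feats), pd.DataFrame(meta)


def run_pipeline(config: dict, out_dir) -> dict:
    """End-to-end run: generate -> featurize -> simulate -> fit -> evaluate.

    ``config`` has sections ``design`` (name, n_trials, optional image_size/
    grid), ``frontend`` (pooling, grid), ``observer`` (kind,
    target_accuracy), ``fit`` (lambda, omega, rounds, restarts) and ``seed``.
    Every artifact records the config hash; the same config and seed give
    byte-identical model output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    chash = config_hash(config)
    dcfg = config.get("design", {})
    name = dcfg.get("name", "exp1_var")
    if "image_size" in dcfg:
        design = stimuli.scaled_design(name, int(dcfg["image_size"]),
                                       int(dcfg.get("grid", 8)))
    else:
        design = stimuli.get_design(name)
    fcfg = config.get("frontend", {})
    fe = frontend.FrontendConfig.for_design(
        design, grid=fcfg.get("grid"), pooling=fcfg.get("pooling", "AVG"))

    t0 = time.time()
    X, meta = featurize_design(design, int(dcfg.get("n_trials", 1000)), seed, fe)
    log.info("featurized %d trials in %.1fs", len(meta), time.time() - t0)

    ocfg = config.get("observer", {"kind": "ideal_labels"})
    if ocfg.get("kind", "ideal_labels") == "ideal_labels":
        trials = observers.ideal_trials(meta)
    else:
        gt = observers.build_ground_truth(ocfg["kind"], fe.grid,
                                          boundary_orientation=design.boundary_orientation)
        trials = observers.simulate_ground_truth(
            X, meta, gt, seed=seed + 1,
            target_accuracy=float(ocfg.get("target_accuracy", 0.8)))
    write_trials(trials, out / "trials.csv")
    frontend.save_features(out / "features.txt", X, fe)

    fit_cfg = config.get("fit", {})
    priors = Priors(lam=float(fit_cfg.get("lambda", 1.0)),
                    omega=fit_cfg.get("omega"), grid=fe.grid)
    cfg = FitConfig(n_rounds=int(fit_cfg.get("rounds", 6)),
                    n_restarts=int(fit_cfg.get("restarts", 2)))
    t0 = time.time()
    fit = fit_filters(X, trials["response"], priors, cfg,
                      architecture=fit_cfg.get("architecture", "single"),
                      n_channels=fe.n_channels, grid=fe.grid, seed=seed + 2)
    log.info("fit complete in %.1fs (log posterior %.2f)", time.time() - t0,
             fit.log_posterior)

    model_doc = fit.model.to_dict()
    model_doc["config_hash"] = chash
    model_doc["seed"] = seed
    (out / "model.json").write_text(json.dumps(model_doc, sort_keys=True))
    fit.trace.to_csv(out / "fit_trace.csv", index=False)

    pred = simulate_responses(X, fit.model, mode="DET", seed=seed + 3, meta=meta)
    curve = evaluation.psychometric(
        pred.assign(category=np.asarray(meta["category"])))
    curve.to_csv(out / "psychometric_model.csv", index=False)
    report = {
        "config_hash": chash,
        "seed": seed,
        "design": design.name,
        "pooling": fe.pooling,
        "grid": fe.grid,
        "n_trials": int(len(meta)),
        "alpha": fit.model.alpha,
        "filter_norms": fit.filter_norms,
        "log_posterior": fit.log_posterior,
        "model_accuracy": float(np.mean(
            np.asarray(pred["response"]) == np.asarray(meta["category"]))),
    }
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return report
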