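"""End-to-end experiment: generate -> preprocess -> extract -> select -> train.

One :class:`ExperimentConfig` drives the full matrix of growth stages x input
variants x model families, mirroring how the field study compares feature
sets (CF / TF / integrated), selection routes (SCT / PCA) and regressors
(MLR, PLS, SVR, BPNN, RF, SFM).  Every cell's cross-validated metrics land in
a flat leaderboard; correlation reports and PCA bookkeeping tables are written
per stage; all randomness flows from the explicit seeds in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import extract_table
from .models import evaluate_variant
from .preprocess import MsrcrParams, msrcr, segment_leaf
from .select import VARIANT_NAMES, fit_pca, pearson_screen
from .synthgen import STAGES, GeneratorConfig, generate_dataset, write_dataset

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "report", "preprocess_samples"]

log = logging.getLogger("leafn")

MODEL_NAMES = ("MLR", "PLS", "SVR", "BPNN", "RF", "SFM")


@dataclass(frozen=True)
class ExperimentConfig:
    stages: tuple[str, ...] = STAGES
    n_samples: int = 60
    image_size: tuple[int, int] = (256, 256)
    variants: tuple[str, ...] = VARIANT_NAMES
    models: tuple[str, ...] = MODEL_NAMES
    threshold: float = 0.7
    levels: int = 64
    k: int = 5
    seed: int = 0
    use_true_masks: bool = False
    write_images: bool = False
    generator_overrides: dict[str, Any] = field(default_factory=dict)
    out_dir: str = "results/experiment"

    def __post_init__(self) -> None:
        unknown_v = set(self.variants) - set(VARIANT_NAMES)
        unknown_m = set(self.models) - set(MODEL_NAMES)
        unknown_s = set(self.stages) - set(STAGES)
        if unknown_v or unknown_m or unknown_s:
            raise ValueError(f"unknown config entries: {unknown_v | unknown_m | unknown_s}")
        if not self.models:
            raise ValueError("config lists no models")
        if not self.variants:
            raise ValueError("config lists no variants")
        if not self.stages:
            raise ValueError("config lists no stages")

    def generator_config(self, stage: str) -> GeneratorConfig:
        # stable per-stage seed derived from the master seed
        stage_seed = (self.seed * 1000 + 17 * STAGES.index(stage) + 1) % (2**31)
        return GeneratorConfig(
            n_samples=self.n_samples,
            image_size=self.image_size,
            stage=stage,
            seed=stage_seed,
            **self.generator_overrides,
        )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def hash(self) -> str:
        blob = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("stages", "variants", "models", "image_size"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class ExperimentReport:
    leaderboard: pd.DataFrame
    pca_tables: dict[str, pd.DataFrame]
    correlation_reports: dict[str, pd.DataFrame]
    provenance: dict[str, Any]
    failures: list[dict[str, str]]


def preprocess_samples(samples, params: MsrcrParams = MsrcrParams(), use_true_masks: bool = False):
    """MSRCR-correct every sample and segment the leaf; returns (images, masks)."""
    corrected, masks = [], []
    for s in samples:
        img = msrcr(s.image, params)
        corrected.append(img)
        masks.append(s.true_mask if use_true_masks else segment_leaf(img).mask)
    return corrected, masks


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the stage x variant x model matrix and write all artifacts.

    Cell failures are recorded and the run continues; the report carries the
    failure list so callers can exit nonzero.  Idempotent given the seeds.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, failures = [], []
    pca_tables: dict[str, pd.DataFrame] = {}
    corr_reports: dict[str, pd.DataFrame] = {}

    for stage in config.stages:
        gen_cfg = config.generator_config(stage)
        samples = generate_dataset(gen_cfg)
        log.info("stage %s: generated %d samples (seed %d)", stage, len(samples), gen_cfg.seed)
        if config.write_images:
            write_dataset(samples, out / "data" / stage)
        images, masks = preprocess_samples(samples, use_true_masks=config.use_true_masks)
        table = extract_table(images, masks, [s.sample_id for s in samples], levels=config.levels)
        y = np.array([s.n_value for s in samples])
        table.to_csv(out / f"features_{stage}.csv")

        # stage-level descriptive artifacts (full-data view, reporting only;
        # modelling below refits selectors inside each training fold)
        corr = pearson_screen(table, y, config.threshold).to_frame()
        corr.to_csv(out / f"correlation_{stage}.csv")
        corr_reports[stage] = corr
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pca_frame = pd.concat(
                [fit_pca(table.loc[:, list(cols)], block=blk).to_frame()
                 for blk, cols in (("CF", table.columns[:24]), ("TF", table.columns[24:]))],
                ignore_index=True,
            )
        pca_frame.to_csv(out / f"pca_{stage}.csv", index=False)
        pca_tables[stage] = pca_frame

        for variant in config.variants:
            for model in config.models:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = evaluate_variant(
                            table, y, variant, model,
                            k=config.k, seed=config.seed, threshold=config.threshold,
                        )
                    row = {"stage": stage, **res.summary()}
                    row["params"] = json.dumps(_jsonable(row["params"]))
                    rows.append(row)
                    log.info("cell %s/%s/%s: R2=%.4f", stage, variant, model, res.mean_r2)
                except Exception as exc:
                    failures.append({"stage": stage, "variant": variant, "model": model,
                                     "error": repr(exc)})
                    log.warning("cell %s/%s/%s failed: %r", stage, variant, model, exc)

    leaderboard = pd.DataFrame(
        rows, columns=["stage", "variant", "family", "R2", "RMSE", "MAPE", "params"]
    )
    provenance = {
        "config": _jsonable(config.to_dict()),
        "config_hash": config.hash(),
        "seed": config.seed,
        "leafn_version": __version__,
        "expected_cells": len(config.stages) * len(config.variants) * len(config.models),
    }
    leaderboard.to_csv(out / "leaderboard.csv", index=False)
    with open(out / "run_config.json", "w") as fh:
        json.dump({**provenance, "failures": failures}, fh, indent=2)
    return ExperimentReport(leaderboard, pca_tables, corr_reports, provenance, failures)


def report(results_dir: str | Path) -> str:
    """Human-readable summary of a completed run: best variant per model and
    best model per variant, per stage; missing cells are flagged."""
    results_dir = Path(results_dir)
    lb_path = results_dir / "leaderboard.csv"
    cfg_path = results_dir / "run_config.json"
    if not lb_path.exists():
        raise FileNotFoundError(f"missing artifact: {lb_path}")
    if not cfg_path.exists():
        raise FileNotFoundError(f"missing artifact: {cfg_path}")
    lb = pd.read_csv(lb_path)
    with open(cfg_path) as fh:
        meta = json.load(fh)

    lines = [f"leafn experiment report  (config {meta.get('config_hash', '?')})", ""]
    expected = meta.get("expected_cells")
    if expected is not None and len(lb) < expected:
        lines.append(f"WARNING: {expected - len(lb)} of {expected} cells missing "
                     f"(failures: {len(meta.get('failures', []))})")
        lines.append("")
    for stage, sub in lb.groupby("stage"):
        lines.append(f"== stage: {stage} ==")
        lines.append("-- best input variant per model family (by mean CV R2) --")
        for fam, fsub in sub.groupby("family"):
            best = fsub.loc[fsub["R2"].idxmax()]
            lines.append(f"  {fam:5s}: {best['variant']:9s} R2={best['R2']:.4f} "
                         f"RMSE={best['RMSE']:.4f} MAPE={best['MAPE']:.4f}")
        lines.append("-- best model family per input variant --")
        for var, vsub in sub.groupby("variant"):
            best = vsub.loc[vsub["R2"].idxmax()]
            lines.append(f"  {var:9s}: {best['family']:5s} R2={best['R2']:.4f}")
        top = sub.loc[sub["R2"].idxmax()]
        lines.append(f"-- overall best cell: {top['variant']} + {top['family']} "
                     f"(R2={top['R2']:.4f}) --")
        lines.append("")
    text = "\n".join(lines)
    with open(results_dir / "summary.txt", "w") as fh:
        fh.write(text)
    return text
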