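"""End-to-end orchestration: simulate -> grid -> screen -> ANOVA -> ranges.

Each stage is an ordinary library call (so it is unit-testable on its own);
the pipeline wires them together, writes every table as CSV, and records an
artifact manifest with content hashes.  All randomness flows from one master
seed, so re-running a configuration reproduces every non-wall-clock output
bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anova import fit_main_effects, logit_transform, residual_diagnostics, type3_anova
from .experiment import FactorLevels, run_factorial
from .model import ModelConfig
from .outliers import screen_results
from .ranges import contrasts_table, homogeneous_groups, ls_means, lsd_contrasts, means_table
from .synthetic import BagSpec, generate_bag_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

FACTORS = ["Wd", "Ly", "Dp", "Nt", "Nb"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, resolvable from a YAML file."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    alpha: float = 0.05
    # synthetic bags
    bag_spec: BagSpec = field(
        default_factory=lambda: BagSpec(n_patches=60, feature_dim=64)
    )
    n_train_bags_per_class: int = 10
    n_eval_bags_per_class: int = 8
    # grid + model
    grid: FactorLevels = field(default_factory=FactorLevels)
    model: ModelConfig = field(default_factory=ModelConfig)
    # screening
    auc_min: float = 0.65
    f1_min: float = 0.45
    screen_combine: str = "or"
    # per-response transform: None (raw) or "logit"
    transforms: dict = field(
        default_factory=lambda: {"F1": None, "AUC": "logit", "T": None}
    )
    #: clip applied before the logit so that boundary metric values (an AUC of
    #: exactly 1.0 on separable data) stay analyzable
    logit_eps: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key, typ in (("bag_spec", BagSpec), ("grid", FactorLevels), ("model", ModelConfig)):
            if key in raw and isinstance(raw[key], dict):
                sub = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw[key].items()
                }
                raw[key] = typ(**sub)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _transformed_response(table: pd.DataFrame, response: str, cfg: PipelineConfig):
    """(column name, table with the analysis column added)."""
    how = cfg.transforms.get(response)
    if how is None:
        return response, table
    if how != "logit":
        raise ValueError(f"unknown transform {how!r} for {response}")
    col = f"LOGIT_{response}"
    vals = table[response].clip(cfg.logit_eps, 1 - cfg.logit_eps)
    table = table.copy()
    table[col] = logit_transform(vals.to_numpy())
    return col, table


def run_pipeline(config: PipelineConfig) -> tuple[int, dict]:
    """Run every stage and return (exit status, artifact manifest)."""
    t_start = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> Path:
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)
        return path

    stage = "simulate"
    try:
        master = np.random.SeedSequence(config.seed)
        sim_seed, grid_seed = (int(s % 2**31) for s in master.generate_state(2))
        train_bags = generate_bag_dataset(
            config.bag_spec, config.n_train_bags_per_class, seed=sim_seed
        )
        eval_bags = generate_bag_dataset(
            config.bag_spec, config.n_eval_bags_per_class, seed=sim_seed + 1
        )
        logger.info("simulated %d train / %d eval bags", len(train_bags), len(eval_bags))

        stage = "grid"
        base = ModelConfig(
            **{
                **vars(config.model),
                "feature_dim": config.bag_spec.feature_dim,
                "n_classes": config.bag_spec.n_classes,
            }
        )
        results = run_factorial(config.grid, train_bags, eval_bags, base, grid_seed)
        emit(results, "results.csv")

        stage = "screen"
        screened, report = screen_results(
            results, config.auc_min, config.f1_min, config.screen_combine
        )
        emit(screened, "results_screened.csv")
        rep_path = out / "outlier_report.csv"
        report.to_csv(rep_path)
        written.append(rep_path)
        logger.info("screening: n_before=%d n_after=%d", report.n_before, report.n_after)

        stage = "analyze"
        factors = [f for f in FACTORS if screened[f].nunique() >= 2]
        analysis: dict[str, dict] = {}
        for response in ("F1", "AUC", "T"):
            col, table = _transformed_response(screened, response, config)
            fit = fit_main_effects(table, col, factors)
            anova = type3_anova(fit)
            emit(anova, f"anova_{response}.csv")
            diag = residual_diagnostics(fit)
            emit(
                pd.DataFrame(
                    {"predicted": diag["predicted"], "residual": diag["residuals"]}
                ),
                f"residuals_{response}.csv",
            )
            analysis[response] = {"fit": fit, "anova": anova}

        stage = "report"
        for response, parts in analysis.items():
            fit = parts["fit"]
            for f in factors:
                means = ls_means(fit, f, config.alpha)
                contrasts = lsd_contrasts(fit, f, config.alpha)
                letters = homogeneous_groups(means, contrasts)
                emit(means_table(means, letters), f"means_{response}_{f}.csv")
                emit(contrasts_table(contrasts), f"contrasts_{response}_{f}.csv")
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "n_before_screen": report.n_before,
        "n_after_screen": report.n_after,
        "elapsed_s": time.perf_counter() - t_start,
        "files": {p.name: _sha256(p) for p in written},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %d artifacts in %s", len(written), out)
    return 0, manifest
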