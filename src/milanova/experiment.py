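"""Model evaluation and the full factorial hyperparameter experiment.

Each run trains the MinMax classifier at one combination of the five studied
factors — weight decay (Wd), MLP depth (Ly), dropout (Dp), top instances (Nt),
bottom instances (Nb) — and records macro F1, one-vs-rest AUC, and wall-clock
training time into a tabular results set, one row per run, factor columns
before response columns.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score

from .model import ModelConfig, TrainedModel, mlp_widths_for_level, predict, train_model
from .synthetic import RESULTS_COLUMNS, FeatureBag

__all__ = ["FactorLevels", "macro_f1", "ovr_auc", "evaluate_model", "run_factorial"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FactorLevels:
    """Factor levels of the factorial design (defaults: the studied grid)."""

    Wd: tuple[float, ...] = (0.0, 0.1)
    Ly: tuple[int, ...] = (1, 2, 3)
    Dp: tuple[float, ...] = (0.2, 0.5, 0.8)
    Nt: tuple[int, ...] = (5, 10, 20, 40)
    Nb: tuple[int, ...] = (0, 5, 10, 20)
    replicates: int = 1

    def __post_init__(self) -> None:
        for name in ("Wd", "Ly", "Dp", "Nt", "Nb"):
            levels = getattr(self, name)
            if len(levels) == 0:
                raise ValueError(f"factor {name} has no levels")
            if len(set(levels)) != len(levels):
                raise ValueError(f"factor {name} has duplicate levels")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_cells(self) -> int:
        return (
            len(self.Wd) * len(self.Ly) * len(self.Dp) * len(self.Nt) * len(self.Nb)
        )

    def cells(self) -> Iterator[dict]:
        """Iterate factor cells in a fixed lexicographic order."""
        for wd, ly, dp, nt, nb in itertools.product(
            self.Wd, self.Ly, self.Dp, self.Nt, self.Nb
        ):
            yield {"Wd": wd, "Ly": ly, "Dp": dp, "Nt": nt, "Nb": nb}


def macro_f1(true_labels, predicted_labels, n_classes: int = 3) -> float:
    """Unweighted (macro) mean of per-class F1 = 2PR/(P+R).

    A class absent from both truth and prediction contributes 0.
    """
    y, yhat = np.asarray(true_labels), np.asarray(predicted_labels)
    if y.size == 0:
        raise ValueError("empty label vectors")
    if y.shape != yhat.shape:
        raise ValueError("label vectors must have the same length")
    return float(
        f1_score(y, yhat, labels=list(range(n_classes)), average="macro", zero_division=0)
    )


def ovr_auc(true_labels, score_matrix) -> float:
    """One-vs-rest ROC AUC per class, averaged unweighted across classes.

    Each class is treated as positive against the rest using that class's
    score column; ties are handled by midranks.  Every class must appear in
    the truth, otherwise its one-vs-rest AUC is undefined.
    """
    y = np.asarray(true_labels)
    scores = np.asarray(score_matrix, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != y.size:
        raise ValueError("score_matrix must be (n_samples, n_classes)")
    n_classes = scores.shape[1]
    present = set(np.unique(y).tolist())
    missing = sorted(set(range(n_classes)) - present)
    if missing:
        raise ValueError(
            f"classes {missing} absent from truth: their one-vs-rest AUC is "
            "undefined, so the macro average cannot be formed"
        )
    aucs = [roc_auc_score(y == c, scores[:, c]) for c in range(n_classes)]
    return float(np.mean(aucs))


def evaluate_model(
    model: TrainedModel, bags: Sequence[FeatureBag]
) -> tuple[float, float]:
    """(macro F1, one-vs-rest AUC) of a trained model on held-out bags."""
    y = np.array([b.label for b in bags])
    probs = np.vstack([predict(b, model) for b in bags])
    return macro_f1(y, probs.argmax(axis=1), model.config.n_classes), ovr_auc(y, probs)


def _cell_seed(master_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-(cell, replicate) training seed below 2**31."""
    ss = np.random.SeedSequence((master_seed, cell_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def run_factorial(
    grid: FactorLevels,
    train_bags: Sequence[FeatureBag],
    eval_bags: Sequence[FeatureBag],
    base_config: ModelConfig,
    seed: int,
) -> pd.DataFrame:
    """Train and evaluate one model per factor cell and replicate.

    Returns the results table (columns Wd, Ly, Dp, Nt, Nb, replicate, F1, AUC,
    T).  T is the wall-clock training time in seconds and is excluded from
    reproducibility guarantees.  Cells whose Nt+Nb exceeds the smallest bag
    are recorded as failed (logged, skipped) and the run continues.
    """
    min_patches = min(b.n_patches for b in (*train_bags, *eval_bags))
    rows = []
    for ci, cell in enumerate(grid.cells()):
        if cell["Nt"] + cell["Nb"] > min_patches:
            logger.warning(
                "skipping cell %s: Nt+Nb exceeds smallest bag (%d patches)",
                cell,
                min_patches,
            )
            continue
        for r in range(grid.replicates):
            config = replace(
                base_config,
                weight_decay=cell["Wd"],
                mlp_widths=mlp_widths_for_level(cell["Ly"]),
                dropout=cell["Dp"],
                Nt=cell["Nt"],
                Nb=cell["Nb"],
                seed=_cell_seed(seed, ci, r),
            )
            t0 = time.perf_counter()
            model = train_model(train_bags, config)
            elapsed = time.perf_counter() - t0
            f1, auc = evaluate_model(model, eval_bags)
            rows.append({**cell, "replicate": r, "F1": f1, "AUC": auc, "T": elapsed})
            logger.info("cell %s rep %d: F1=%.3f AUC=%.3f T=%.2fs", cell, r, f1, auc, elapsed)
    return pd.DataFrame(rows, columns=RESULTS_COLUMNS)
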