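"""Multiclass MinMax multiple-instance classifier for patch-feature bags.

The architecture follows the WELDON/CHOWDER family, extended to three classes:

1. Five stacked one-dimensional convolutions with kernel width 1 along the
   patch axis — i.e. the same small fully connected map applied to every
   patch — turn each patch embedding into one attention score per class.
2. A MinMax layer sorts each class's per-patch scores and keeps only the
   ``Nt`` highest (most salient instances) and the ``Nb`` lowest (negative
   evidence: the regions that best support a class's absence).
3. An MLP head consumes the concatenated selected scores (length
   ``n_classes * (Nt + Nb)``) and produces class probabilities.

Training minimizes cross-entropy with an L2 weight penalty (weight decay) via
Adam.  Because the MinMax layer is a hard selection, backpropagation reaches
only the selected patches: the loss gradient with respect to any unselected
patch's score is exactly zero.  The network is small enough that forward and
backward passes are written directly in NumPy, which keeps that selection
property explicit and makes seeded training bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .synthetic import FeatureBag

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "mlp_widths_for_level",
    "minmax_select",
    "minmax_indices",
    "score_patches",
    "predict",
    "train_model",
    "attention_map",
    "export_cam",
    "save_checkpoint",
    "load_checkpoint",
]

#: MLP hidden-layer widths for each "number of hidden layers" (Ly) level.
_LY_WIDTHS = {1: (64,), 2: (128, 64), 3: (256, 128, 64)}


def mlp_widths_for_level(ly: int) -> tuple[int, ...]:
    """Map the Ly factor level (1-3 hidden layers) to MLP hidden widths."""
    try:
        return _LY_WIDTHS[int(ly)]
    except KeyError:
        raise ValueError(f"Ly level must be one of {sorted(_LY_WIDTHS)}, got {ly!r}")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training factors of the MinMax classifier.

    ``Nt``/``Nb`` are the numbers of top / bottom (negative-evidence) patches
    kept by the MinMax layer; ``weight_decay`` (Wd) is the L2 penalty
    coefficient; ``dropout`` (Dp) applies to every MLP hidden layer;
    ``mlp_widths`` encodes the Ly factor via :func:`mlp_widths_for_level`.
    """

    feature_dim: int = 768
    n_classes: int = 3
    conv_widths: tuple[int, ...] | None = None  # per-layer widths, last == n_classes
    Nt: int = 10
    Nb: int = 5
    mlp_widths: tuple[int, ...] = (128, 64)
    dropout: float = 0.2
    weight_decay: float = 0.0
    learning_rate: float = 3e-3
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Nt < 1:
            raise ValueError("Nt must be >= 1")
        if self.Nb < 0:
            raise ValueError("Nb must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")
        widths = self.resolved_conv_widths()
        if widths[-1] != self.n_classes:
            raise ValueError("last conv width must equal n_classes")

    def resolved_conv_widths(self) -> tuple[int, ...]:
        if self.conv_widths is not None:
            return tuple(int(w) for w in self.conv_widths)
        # five 1x1 conv layers tapering to one score per class
        return (256, 128, 64, 32, self.n_classes)


# ---------------------------------------------------------------------------
# parameters


def _init_params(config: ModelConfig, rng: np.random.Generator) -> dict:
    """He-initialized weights; zero biases."""
    conv_w, conv_b = [], []
    fan = config.feature_dim
    for width in config.resolved_conv_widths():
        conv_w.append(rng.standard_normal((fan, width)) * np.sqrt(2.0 / fan))
        conv_b.append(np.zeros(width))
        fan = width
    mlp_w, mlp_b = [], []
    fan = config.n_classes * (config.Nt + config.Nb)
    for width in (*config.mlp_widths, config.n_classes):
        mlp_w.append(rng.standard_normal((fan, width)) * np.sqrt(2.0 / fan))
        mlp_b.append(np.zeros(width))
        fan = width
    return {"conv_w": conv_w, "conv_b": conv_b, "mlp_w": mlp_w, "mlp_b": mlp_b}


@dataclass
class TrainedModel:
    """Parameters + config + per-epoch mean training loss."""

    params: dict
    config: ModelConfig
    history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        widths = self.config.resolved_conv_widths()
        fan = self.config.feature_dim
        for w, width in zip(self.params["conv_w"], widths):
            if w.shape != (fan, width):
                raise ValueError("conv parameter shapes inconsistent with config")
            fan = width


# ---------------------------------------------------------------------------
# MinMax selection


def minmax_indices(scores: np.ndarray, Nt: int, Nb: int) -> np.ndarray:
    """Indices of the Nt highest (descending) then Nb lowest (ascending) scores.

    Ties are broken by lower patch index, matching a stable full sort, so the
    selection is deterministic.
    """
    s = np.asarray(scores, dtype=float).ravel()
    n = s.size
    if n < Nt + Nb:
        raise ValueError(f"bag too small: {n} patches < Nt+Nb = {Nt + Nb}")
    idx = np.arange(n)
    desc = np.lexsort((idx, -s))  # by score desc, then index asc
    asc = np.lexsort((idx, s))  # by score asc, then index asc
    return np.concatenate([desc[:Nt], asc[:Nb] if Nb else idx[:0]])


def minmax_select(scores: np.ndarray, Nt: int, Nb: int) -> np.ndarray:
    """MinMax layer for one class: the Nt largest scores in descending order
    followed by the Nb smallest in ascending order."""
    s = np.asarray(scores, dtype=float).ravel()
    return s[minmax_indices(s, Nt, Nb)]


# ---------------------------------------------------------------------------
# forward / backward


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def _conv_forward(params: dict, X: np.ndarray) -> tuple[np.ndarray, list]:
    """Shared-weight per-patch map: (P, d) -> (P, n_classes) attention scores.

    Rectifier between layers, none after the final score layer (scores must be
    orderable over the whole real line for MinMax).
    """
    cache = []
    h = X
    last = len(params["conv_w"]) - 1
    for i, (w, b) in enumerate(zip(params["conv_w"], params["conv_b"])):
        z = h @ w + b
        cache.append((h, z))
        h = z if i == last else _relu(z)
    return h, cache


def _head_forward(
    params: dict,
    scores: np.ndarray,
    Nt: int,
    Nb: int,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """MinMax selection + MLP head on a bag's score matrix -> class probs."""
    P, C = scores.shape
    sel_idx = [minmax_indices(scores[:, c], Nt, Nb) for c in range(C)]
    v = np.concatenate([scores[sel_idx[c], c] for c in range(C)])
    cache: dict = {"sel_idx": sel_idx, "v": v, "mlp": [], "masks": []}
    a = v
    last = len(params["mlp_w"]) - 1
    for j, (w, b) in enumerate(zip(params["mlp_w"], params["mlp_b"])):
        z = a @ w + b
        cache["mlp"].append((a, z))
        if j == last:
            a = z
        else:
            a = _relu(z)
            if dropout > 0.0 and rng is not None:
                mask = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
                a = a * mask
                cache["masks"].append(mask)
            else:
                cache["masks"].append(None)
    probs = _softmax(a)
    cache["probs"] = probs
    return probs, cache


def _head_backward(params: dict, cache: dict, label: int, P: int) -> tuple[dict, np.ndarray]:
    """Backprop cross-entropy through the MLP and MinMax selection.

    Returns MLP parameter grads and dL/dscores, a (P, C) matrix that is
    nonzero only at selected (patch, class) entries.
    """
    probs = cache["probs"]
    C = probs.size
    grad = {"mlp_w": [], "mlp_b": []}
    delta = probs.copy()
    delta[label] -= 1.0  # dL/dlogits for cross-entropy + softmax
    last = len(params["mlp_w"]) - 1
    for j in range(last, -1, -1):
        a_in, z = cache["mlp"][j]
        grad["mlp_w"].insert(0, np.outer(a_in, delta))
        grad["mlp_b"].insert(0, delta.copy())
        if j > 0:
            delta = params["mlp_w"][j] @ delta
            mask = cache["masks"][j - 1]
            if mask is not None:
                delta = delta * mask
            delta = delta * (cache["mlp"][j - 1][1] > 0)
    # dL/dv: the selected-score vector feeds layer 0 directly (no activation)
    delta_v = params["mlp_w"][0] @ grad["mlp_b"][0]
    d_scores = np.zeros((P, C))
    k = len(cache["sel_idx"][0])
    for c in range(C):
        np.add.at(d_scores[:, c], cache["sel_idx"][c], delta_v[c * k : (c + 1) * k])
    return grad, d_scores


def _conv_backward(params: dict, cache: list, d_scores: np.ndarray) -> dict:
    grad = {"conv_w": [], "conv_b": []}
    delta = d_scores
    last = len(params["conv_w"]) - 1
    for i in range(last, -1, -1):
        h_in, z = cache[i]
        if i != last:
            delta = delta * (z > 0)
        grad["conv_w"].insert(0, h_in.T @ delta)
        grad["conv_b"].insert(0, delta.sum(axis=0))
        if i > 0:
            delta = delta @ params["conv_w"][i].T
    return grad


def bag_loss_from_scores(
    model: "TrainedModel", scores: np.ndarray, label: int
) -> float:
    """Cross-entropy loss of one bag given its attention-score matrix.

    Exposes the MinMax + MLP head as a function of the scores alone (no
    dropout, no weight penalty), so that the hard-selection property — zero
    sensitivity to unselected patch scores — can be probed directly, e.g. by
    finite differences.
    """
    probs, _ = _head_forward(
        model.params, np.asarray(scores, float), model.config.Nt, model.config.Nb
    )
    return float(-np.log(max(probs[label], 1e-300)))


# ---------------------------------------------------------------------------
# public inference ops


def _check_bag(bag: FeatureBag, config: ModelConfig) -> None:
    if bag.feature_dim != config.feature_dim:
        raise ValueError(
            f"bag feature_dim {bag.feature_dim} != model feature_dim {config.feature_dim}"
        )


def score_patches(bag: FeatureBag, model: TrainedModel) -> np.ndarray:
    """Per-patch, per-class attention scores, shape (n_patches, n_classes).

    Every patch is mapped independently by the same shared weights (kernel
    width 1), so the map is permutation-equivariant along the patch axis.
    """
    _check_bag(bag, model.config)
    scores, _ = _conv_forward(model.params, bag.features)
    return scores


def predict(bag: FeatureBag, model: TrainedModel) -> np.ndarray:
    """Class-probability vector for one bag (nonnegative, sums to 1)."""
    scores = score_patches(bag, model)
    probs, _ = _head_forward(model.params, scores, model.config.Nt, model.config.Nb)
    return probs


def attention_map(bag: FeatureBag, model: TrainedModel, class_idx: int) -> np.ndarray:
    """Per-patch attention scores for one class (CAM values, length n_patches).

    Index i is patch i's score; the argmax patch is the one the MinMax layer
    ranks first for this class.
    """
    if not 0 <= class_idx < model.config.n_classes:
        raise IndexError(f"class index {class_idx} out of range")
    return score_patches(bag, model)[:, class_idx]


def export_cam(
    bags: Sequence[FeatureBag], model: TrainedModel, path: str | Path
) -> Path:
    """Write per-patch class scores as CSV (bag_id, patch_index, class, score)."""
    import pandas as pd

    rows = []
    for bag in bags:
        scores = score_patches(bag, model)
        for c in range(model.config.n_classes):
            for p in range(bag.n_patches):
                rows.append((bag.bag_id, p, c, scores[p, c]))
    path = Path(path)
    pd.DataFrame(rows, columns=["bag_id", "patch_index", "class", "score"]).to_csv(
        path, index=False
    )
    return path


# ---------------------------------------------------------------------------
# training


def _penalty_and_grads(params: dict, wd: float, grads: dict) -> float:
    """Add the L2 weight-decay gradient in place; return the penalty value.

    The penalty is 0.5 * wd * sum of squared weights (biases excluded), so wd
    has the same meaning regardless of optimizer.
    """
    if wd == 0.0:
        return 0.0
    pen = 0.0
    for key in ("conv_w", "mlp_w"):
        for w, g in zip(params[key], grads[key]):
            pen += 0.5 * wd * float(np.sum(w * w))
            g += wd * w
    return pen


def train_model(bags: Sequence[FeatureBag], config: ModelConfig) -> TrainedModel:
    """Train the MinMax classifier with Adam on cross-entropy + L2 penalty.

    Gradients flow only through the patches selected by the MinMax layer.
    Seeded: identical (bags, config) reproduce parameters bit for bit.
    """
    bags = list(bags)
    if not bags:
        raise ValueError("empty dataset")
    labels = {b.label for b in bags}
    if len(labels) < 2:
        raise ValueError("training requires at least two classes present")
    for b in bags:
        _check_bag(b, config)
        if b.n_patches < config.Nt + config.Nb:
            raise ValueError(
                f"bag {b.bag_id!r} has {b.n_patches} patches < Nt+Nb = "
                f"{config.Nt + config.Nb}"
            )

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x7EA1)))
    params = _init_params(config, rng)

    # Adam state
    m = {k: [np.zeros_like(a) for a in v] for k, v in params.items()}
    v2 = {k: [np.zeros_like(a) for a in v] for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history: list[float] = []
    n = len(bags)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            grads = {k: [np.zeros_like(a) for a in v] for k, v in params.items()}
            batch_loss = 0.0
            for bi in batch:
                bag = bags[bi]
                scores, conv_cache = _conv_forward(params, bag.features)
                probs, head_cache = _head_forward(
                    params, scores, config.Nt, config.Nb, config.dropout, rng
                )
                batch_loss += -np.log(max(probs[bag.label], 1e-300))
                g_head, d_scores = _head_backward(
                    params, head_cache, bag.label, bag.n_patches
                )
                g_conv = _conv_backward(params, conv_cache, d_scores)
                for key, gs in (*g_head.items(), *g_conv.items()):
                    for acc, g in zip(grads[key], gs):
                        acc += g / len(batch)
            pen = _penalty_and_grads(params, config.weight_decay, grads)
            epoch_loss += batch_loss + pen * len(batch)
            step += 1
            corr1 = 1.0 - beta1**step
            corr2 = 1.0 - beta2**step
            for key in params:
                for p, g, mk, vk in zip(params[key], grads[key], m[key], v2[key]):
                    mk *= beta1
                    mk += (1 - beta1) * g
                    vk *= beta2
                    vk += (1 - beta2) * g * g
                    p -= config.learning_rate * (mk / corr1) / (
                        np.sqrt(vk / corr2) + eps
                    )
        history.append(float(epoch_loss / n))
    return TrainedModel(params=params, config=config, history=history)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: TrainedModel, path: str | Path) -> Path:
    """Serialize parameters + config + history to a single .npz file."""
    path = Path(path)
    arrays = {}
    for key in ("conv_w", "conv_b", "mlp_w", "mlp_b"):
        for i, a in enumerate(model.params[key]):
            arrays[f"{key}_{i}"] = a
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(model.config).items()
    }
    arrays["config_json"] = np.array(json.dumps(cfg))
    arrays["history"] = np.asarray(model.history)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path: str | Path) -> TrainedModel:
    data = np.load(path, allow_pickle=False)
    cfg = json.loads(str(data["config_json"]))
    for key in ("conv_widths", "mlp_widths"):
        if cfg.get(key) is not None:
            cfg[key] = tuple(cfg[key])
    config = ModelConfig(**cfg)
    params = {}
    for key in ("conv_w", "conv_b", "mlp_w", "mlp_b"):
        arrs = []
        i = 0
        while f"{key}_{i}" in data:
            arrs.append(data[f"{key}_{i}"])
            i += 1
        params[key] = arrs
    return TrainedModel(params=params, config=config, history=list(data["history"]))
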