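"""Synthetic slide-level feature bags and factorial results tables.

Real studies of weakly supervised slide classifiers start from whole-slide
images tiled into patches, each patch embedded by a pretrained encoder into a
768-dimensional feature vector.  Only the slide carries a label (benign /
atypical / malignant), and only a minority of patches carry the diagnostic
signal.  This module emulates exactly that structure — class-conditional bags
in which a known fraction of patches is shifted along a class prototype
direction and the rest are background noise — plus tabular factorial "results
tables" with known injected factor effects and outliers, so every downstream
stage (training, screening, ANOVA, range tests) is testable end to end with
known ground truth and no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BagSpec",
    "EffectSpec",
    "FeatureBag",
    "class_prototypes",
    "generate_bag_dataset",
    "generate_results_table",
    "save_bags",
    "load_bags",
]

#: Column order of a results table: factors first, then responses.
RESULTS_COLUMNS = ["Wd", "Ly", "Dp", "Nt", "Nb", "replicate", "F1", "AUC", "T"]


@dataclass(frozen=True)
class FeatureBag:
    """One slide: a matrix of per-patch feature vectors plus a slide label.

    Attributes
    ----------
    features : ndarray of shape (n_patches, feature_dim)
        One embedding vector per patch.
    label : int
        Slide-level class index in {0, 1, 2} (benign / atypical / malignant).
    bag_id : str
        Stable identifier used in manifests and CAM exports.
    """

    features: np.ndarray
    label: int
    bag_id: str

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        if feats.ndim != 2 or feats.shape[0] < 1:
            raise ValueError("features must be a (n_patches >= 1, feature_dim) matrix")
        if not np.all(np.isfinite(feats)):
            raise ValueError(f"bag {self.bag_id!r} contains non-finite features")
        object.__setattr__(self, "features", feats)

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class BagSpec:
    """Parameters of the class-conditional bag generator.

    A bag of ``n_patches`` patches gets ``round(signal_fraction * n_patches)``
    "diagnostic" patches drawn from the labeled class's prototype-shifted
    Gaussian; the remainder are i.i.d. background Gaussian(0, noise_sd^2 I).
    Class prototypes are mutually orthogonal unit vectors derived
    deterministically from ``seed`` and scaled by ``signal_strength``.
    """

    n_patches: int
    feature_dim: int = 768
    n_classes: int = 3
    signal_fraction: float = 0.2
    signal_strength: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in [0, 1]")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_classes > self.feature_dim:
            raise ValueError("need feature_dim >= n_classes for orthogonal prototypes")


def class_prototypes(spec: BagSpec) -> np.ndarray:
    """Mutually orthogonal unit prototype directions, one row per class.

    Derived deterministically from ``spec.seed`` via QR decomposition of a
    seeded Gaussian matrix, so identical specs always yield identical
    prototypes (and hence identical class geometry).
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xC1A55)))
    raw = rng.standard_normal((spec.feature_dim, spec.n_classes))
    q, r = np.linalg.qr(raw)
    # fix the sign convention so the decomposition is unique
    q = q * np.sign(np.diag(r))
    return q.T  # (n_classes, feature_dim)


def generate_bag_dataset(
    spec: BagSpec, n_bags_per_class: int, seed: int
) -> list[FeatureBag]:
    """Generate a balanced labeled dataset of feature bags.

    Returns ``spec.n_classes * n_bags_per_class`` bags.  Within each bag,
    exactly ``round(signal_fraction * n_patches)`` patches are drawn from the
    labeled class's shifted distribution; patch order is shuffled so signal
    patches occupy random positions.  Identical (spec, n_bags_per_class, seed)
    always reproduces the dataset bit for bit.
    """
    if n_bags_per_class < 1:
        raise ValueError("n_bags_per_class must be >= 1")
    protos = class_prototypes(spec)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, seed, 0xBA65)))
    n_signal = int(round(spec.signal_fraction * spec.n_patches))
    bags: list[FeatureBag] = []
    for label in range(spec.n_classes):
        for b in range(n_bags_per_class):
            feats = rng.normal(
                0.0, spec.noise_sd, size=(spec.n_patches, spec.feature_dim)
            )
            feats[:n_signal] += spec.signal_strength * protos[label]
            feats = feats[rng.permutation(spec.n_patches)]
            bags.append(
                FeatureBag(features=feats, label=label, bag_id=f"c{label}_b{b:04d}")
            )
    return bags


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth additive structure of a synthetic results-table response.

    ``factor_effects`` maps a factor name to per-level offsets; offsets are
    centered to sum to zero across each factor's levels (so "effect" is
    identifiable), which makes them directly comparable to sum-to-zero ANOVA
    effect estimates.  ``outlier_rows`` are (row_index, value) pairs that
    overwrite the response after generation — gross failures, not noise-tail
    events.
    """

    factor_effects: Mapping[str, Mapping[object, float]] = field(default_factory=dict)
    baseline: float = 0.6
    noise_sd: float = 0.01
    replicates: int | None = None
    outlier_rows: Sequence[tuple[int, float]] = ()

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.replicates is not None and self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def centered_effects(
        self, grid_levels: Mapping[str, Sequence] | None = None
    ) -> dict[str, dict[object, float]]:
        """Per-factor offsets recentered to sum to zero across levels.

        When ``grid_levels`` supplies a factor's full level set, unlisted
        levels enter the centering with offset 0, so "+0.05 on one level"
        means that level sits 0.05 above the others before centering.
        """
        out: dict[str, dict[object, float]] = {}
        for factor, offsets in self.factor_effects.items():
            vals = dict(offsets)
            if grid_levels is not None and factor in grid_levels:
                for lvl in grid_levels[factor]:
                    vals.setdefault(lvl, 0.0)
                missing = set(vals) - set(grid_levels[factor])
                if missing:
                    raise ValueError(
                        f"effects for factor {factor!r} name levels not in the "
                        f"grid: {sorted(missing, key=repr)}"
                    )
            mean = float(np.mean(list(vals.values())))
            out[factor] = {lvl: v - mean for lvl, v in vals.items()}
        return out


def _default_effects() -> dict[str, "EffectSpec"]:
    # Plausible fills for responses without an explicit spec: mid-range F1,
    # adequate AUC, and a training time near 490 s.
    return {
        "F1": EffectSpec(baseline=0.63, noise_sd=0.0),
        "AUC": EffectSpec(baseline=0.85, noise_sd=0.0),
        "T": EffectSpec(baseline=490.0, noise_sd=0.0),
    }


def generate_results_table(
    grid,
    effects: "EffectSpec | Mapping[str, EffectSpec]",
    seed: int,
) -> pd.DataFrame:
    """One row per (factor cell x replicate), responses = additive model + noise.

    ``grid`` is a :class:`milanova.experiment.FactorLevels`.  ``effects`` may be
    a single :class:`EffectSpec` (applied to the F1 response) or a mapping from
    response name ('F1', 'AUC', 'T') to EffectSpec.  Factor columns precede
    response columns.  Listed outlier rows overwrite the response after
    generation.
    """
    if not isinstance(effects, Mapping):
        effects = {"F1": effects}
    unknown = set(effects) - {"F1", "AUC", "T"}
    if unknown:
        raise ValueError(f"unknown response names: {sorted(unknown)}")
    full = _default_effects()
    full.update(effects)

    cells = list(grid.cells())
    if not cells:
        raise ValueError("factor grid is empty")
    reps = {s.replicates for s in effects.values() if s.replicates is not None}
    if len(reps) > 1:
        raise ValueError("conflicting replicate counts across EffectSpecs")
    replicates = reps.pop() if reps else grid.replicates

    rows = []
    for cell in cells:
        for r in range(replicates):
            rows.append({**cell, "replicate": r})
    table = pd.DataFrame(rows)

    grid_levels = {f: getattr(grid, f) for f in ("Wd", "Ly", "Dp", "Nt", "Nb")}
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x7AB1E)))
    for resp in ("F1", "AUC", "T"):
        espec = full[resp]
        eff = espec.centered_effects(grid_levels)
        unknown_factors = set(eff) - set(table.columns)
        if unknown_factors:
            raise ValueError(f"effects refer to unknown factors: {sorted(unknown_factors)}")
        y = np.full(len(table), espec.baseline, dtype=float)
        for factor, offsets in eff.items():
            y += table[factor].map(offsets).fillna(0.0).to_numpy()
        if espec.noise_sd > 0:
            y += rng.normal(0.0, espec.noise_sd, size=len(table))
        for idx, value in espec.outlier_rows:
            if not 0 <= idx < len(table):
                raise IndexError(f"outlier row {idx} out of range for {len(table)} rows")
            y[idx] = value
        table[resp] = y
    return table[RESULTS_COLUMNS]


def save_bags(bags: Sequence[FeatureBag], directory: str | Path) -> Path:
    """Write one feature matrix per bag plus a manifest table.

    Matrices are CSV (patches x features, no header); the manifest lists
    bag_id, label, n_patches, and the matrix file name.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for bag in bags:
        fname = f"bag_{bag.bag_id}.csv"
        np.savetxt(directory / fname, bag.features, delimiter=",", fmt="%.8g")
        records.append(
            {
                "bag_id": bag.bag_id,
                "label": bag.label,
                "n_patches": bag.n_patches,
                "file": fname,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest


def load_bags(directory: str | Path) -> list[FeatureBag]:
    """Inverse of :func:`save_bags`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    bags = []
    for rec in manifest.itertuples():
        feats = np.loadtxt(directory / rec.file, delimiter=",", ndmin=2)
        bags.append(FeatureBag(features=feats, label=int(rec.label), bag_id=str(rec.bag_id)))
    return bags
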