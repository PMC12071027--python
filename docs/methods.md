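# Methods

This note records the models, procedures, defaults, and numerical choices
behind `milanova`, and what the synthetic experiments do and do not show.

## The classifier

The network maps a bag of patch embeddings `X ∈ R^{P×d}` to class
probabilities in three stages.

**Shared-weight score stack.** Five consecutive one-dimensional convolutions
with kernel width 1 along the patch axis. A width-1 kernel is exactly a
fully connected layer whose weights are shared across patches, so the stack
is a per-patch map `R^d → R^C` applied independently to every patch —
permutation-equivariant by construction. Rectifier nonlinearities sit
between layers; none after the final layer, because the outputs are
attention scores that must be orderable over the whole real line. Default
widths taper `d → 256 → 128 → 64 → 32 → C`; the depth (five) and the output
width (one score per class) are the fixed design elements, the intermediate
widths are free and configurable (tests and examples use a narrower
`64 → 32 → 16 → 8 → 3` stack sized for 64-dimensional synthetic features).

**MinMax selection.** Per class, the `Nt` largest scores (descending) and
`Nb` smallest (ascending) are kept; `Nb = 0` disables negative evidence and
is a studied factor level. Ties are broken by lower patch index, matching a
stable full sort, so selection is deterministic. Because selection is hard,
the training loss is locally constant in every unselected score: the
gradient reaching unselected patches is *exactly* zero, not merely small.
This is verified both analytically (the backward pass scatters gradient only
to selected indices) and by finite differences. Bags smaller than `Nt + Nb`
are an error, not padded — synthetic bag sizes must respect the largest
selection (the full grid needs `n_patches ≥ 60`).

**Head and training.** The concatenated selected scores (`C·(Nt+Nb)`
values; concatenation across classes, CHOWDER-style) feed an MLP with hidden
widths `(64,)`, `(128, 64)`, or `(256, 128, 64)` for depth levels 1–3,
rectifier activations, and inverted dropout at one shared rate on every
hidden layer (the factorial design treats the per-layer rates as one
factor). Softmax cross-entropy is minimized by Adam
(`β₁ = 0.9, β₂ = 0.999`). Weight decay is an explicit L2 penalty
`(Wd/2)·Σ‖W‖²` on weight matrices (biases excluded) added to the loss, so
`Wd` has the same meaning regardless of optimizer. Defaults: learning rate
`3e-3`, 30 epochs, batch size 8, He initialization; the learning rate was
set so the reference synthetic task converges comfortably within a 20–30
epoch budget. The implementation is plain NumPy with hand-written gradients;
with a fixed seed, training is bit-reproducible on one machine.

## Synthetic data generator

`generate_bag_dataset` emulates the statistical skeleton of embedded
whole-slide images: per class, a unit prototype direction (rows of a seeded
random orthogonal matrix, so prototypes are exactly orthonormal and
reproducible); each bag holds `round(signal_fraction · n_patches)`
"diagnostic" patches drawn as background noise plus
`signal_strength × prototype`, the rest i.i.d. Gaussian background, with
patch order shuffled. Reference conditions used throughout the tests:
100-patch bags, 20% signal fraction, signal strength 5 at noise sd 1 —
strongly separable, as confirmed by a closed-form nearest-prototype oracle
before any training. Feature dimension is 768 in the emulated setting; most
tests use 64 to keep runtimes small, which changes no property being tested.

What this generator does **not** emulate: spatial correlation between
neighboring patches, staining/batch variation, class-dependent bag sizes,
ambiguous borderline lesions, or encoder-specific embedding geometry.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted signal, not clinical performance.

`generate_results_table` builds factorial response tables as
`baseline + Σ factor offsets + N(0, noise_sd)`. Offsets are recentered to
sum to zero across each factor's grid levels (unlisted levels enter at 0),
making the injected values directly comparable to sum-to-zero effect
estimates; with `noise_sd = 0` recovery is exact to numerical precision.
Outliers are injected by overwriting rows after generation — gross failures,
not noise-tail events. Replicates per cell are a free parameter.

## Factorial experiment

`run_factorial` trains one model per cell × replicate, deriving each run's
seed deterministically from (master seed, cell index, replicate), and
records macro F1 (unweighted mean of per-class `2PR/(P+R)`; a class absent
from truth and prediction contributes 0), one-vs-rest AUC (per-class ROC AUC
with midrank tie handling, unweighted mean; a class absent from the truth is
an error rather than a silent average over fewer classes), and wall-clock
training time. Time is excluded from reproducibility contracts. Cells
exceeding the smallest bag's patch count are logged and skipped, not fatal.

## Outlier screening

Hard adequacy thresholds: a run is excluded when `AUC < 0.65` **or**
`F1 < 0.45` (defaults). The two criteria are phrased jointly in the source
analysis but applied per metric; OR is the conservative reading, is the
default, and an AND switch is provided. Each removed row is documented with
studentized z-scores (with and without deleting the observation from the
mean/sd), modified Z-scores `0.6745(x_i − x̃)/MAD`, and Grubbs' test.

Grubbs' statistic uses the standard Grubbs↔t correspondence
`t² = n(n−2)·t²max / ((n−1)² − n·t²max)` with `t_max` the largest absolute
studentized value, and the two-sided p-value approximation
`min(1, 2n · P(T_{n−2} > t))`. This reproduces published critical values
(e.g. 1.715 at `n = 5, α = 0.05`) and calibrates correctly under the null
(empirical size ≈ 0.05 at `n = 20` over 10,000 Monte-Carlo replicates).
Sample sd uses the `n − 1` denominator throughout.

## ANOVA engine

Responses bounded in (0, 1) that crowd the boundary (AUC here) are analyzed
on the logit scale; F1 and time are analyzed raw. The transform is a config
field per response, not hard-coded. The strict `logit_transform` rejects
p ≤ 0 and p ≥ 1; the pipeline clips at `logit_eps = 1e-6` first, because
small separable demonstrations can produce runs with AUC exactly 1.

The linear model is additive main effects only (no interactions), with
factors always categorical — numeric level labels are never treated as
continuous covariates — under sum-to-zero coding, which is what makes
Type III sums of squares well-defined. `SS_factor` is computed literally as
the model-comparison difference `SSE(reduced) − SSE(full)` via least
squares; an independent sum-coded GLS implementation (statsmodels) serves as
the cross-check oracle in the tests, agreeing within 1e-8 on random
unbalanced tables. For the studied design (levels 2, 3, 3, 4, 4) at
`n = 861`, residual df = `861 − 1 − 11 = 849`. Degenerate inputs: a perfect
fit (`MS_res = 0`) reports `F = ∞, p = 0` for factors with positive SS and
`F = 0, p = 1` otherwise; empty factor levels and confounded (rank-
deficient) designs are errors naming the offending factor.

Diagnostics: residual-vs-predicted pairs, normal Q-Q pairs with Blom
plotting positions, Shapiro-Wilk on residuals, and the median-centered
Levene (Brown-Forsythe) test across replicated design cells. Both formal
tests are reported even where a graphical check would suffice; each is
omitted with a warning when the sample structure cannot support it.

## Range tests

LS means average model predictions over the other factors' levels with
equal weight (the standard least-squares-means definition, not
observed-frequency weighting); under sum-to-zero coding this reduces to
intercept + factor effect. Standard errors come from `MS_res · cᵀ(XᵀX)⁻¹c`;
intervals use the t quantile at the residual df (at df = 849 the normal
quantile differs only in the fourth decimal, below printed precision).
Fisher LSD compares every unordered pair at per-pair level α with no
multiplicity correction — the 5%-per-pair risk is the procedure's defining
property, so Tukey/Bonferroni corrections are deliberately out of scope.
Homogeneous-group letters use the standard sweep over levels sorted by mean:
each maximal run of consecutive levels containing no significant pair shares
a letter; with equal-SE (balanced) contrasts this makes "shares a letter"
exactly equivalent to "pair not significant".

## Pipeline and problem sizes

The orchestrator runs simulate → grid → screen → per-response ANOVA → range
tests, writes every table as CSV, and records a SHA-256 manifest; identical
seeds reproduce all non-time outputs bit for bit. The demonstration
configuration used in tests and `examples/06_full_pipeline.py` — a 2×2×2
grid (`Wd × Nt × Nb`, with depth and dropout pinned) × 2 replicates on
60-patch × 64-feature bags, 12 training bags per class, 25 epochs — was
sized so that a complete run takes on the order of ten seconds on one CPU
while most runs clear the adequacy screen, mirroring the regime of the full
study where 861 of 864 runs survive. The Monte-Carlo suites use 10,000
replicates (Grubbs calibration), 1,000 vectors (selection oracle), and 100
seeded repetitions (effect recovery).

## Known limitations

- Single-factor recovery claims are about the *injected* factor: with five
  factors tested at α = 0.05, null factors are flagged at ≈ the nominal rate
  (~5% each), so "no other factor flagged" cannot hold in ~19% of
  repetitions by design; the false-positive rate is reported alongside the
  detection rate.
- The published study's raw 861 runs are unavailable, so its ANOVA tables
  are validated through derivable-cell arithmetic (MS, F, p, df, LS-mean
  differences) from printed inputs, not recomputed from data.
- Duplicating every patch in a bag generally changes the prediction (the
  selected multiset gains repeated extremes); invariance holds under
  permutation always, and under duplication only in fully tied bags.
- No interaction terms, no alternatives to the logit transform, no
  multivariate outlier detection, and no real-image processing (tiling,
  stain handling, feature extraction) — inputs are always embedded bags.
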