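"""Generate synthetic patch-feature bags and verify their class signal.

Builds a small labeled dataset of slide-level "bags" — each bag a matrix of
per-patch embeddings in which 20% of patches are shifted along a hidden
class-prototype direction — then classifies every bag with a closed-form
nearest-prototype rule (mean of the 20 most prototype-aligned patches).
A macro F1 near 1.0 confirms the generator builds in exactly the weak,
patch-sparse class signal the MinMax classifier is designed to find.
"""

import numpy as np

from milanova import BagSpec, generate_bag_dataset, macro_f1
from milanova.synthetic import class_prototypes

spec = BagSpec(
    n_patches=100,
    feature_dim=768,
    signal_fraction=0.2,
    signal_strength=5.0,
    noise_sd=1.0,
    seed=2,
)
bags = generate_bag_dataset(spec, n_bags_per_class=100, seed=11)
print(f"{len(bags)} bags of {spec.n_patches} patches x {spec.feature_dim} features")

protos = class_prototypes(spec)
truth, predicted = [], []
for bag in bags:
    alignment = bag.features @ protos.T  # (patches, classes)
    evidence = [np.sort(alignment[:, c])[-20:].mean() for c in range(3)]
    truth.append(bag.label)
    predicted.append(int(np.argmax(evidence)))

f1 = macro_f1(truth, predicted)
print(f"nearest-prototype rule macro F1: {f1:.3f}")
print("(~1.0 means the diagnostic patches carry a recoverable class signal)")
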