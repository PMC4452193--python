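"""Segment a synthetic macular volume and compare against ground truth.

Builds a phantom with known layer surfaces, trains the boundary classifier
on three sibling phantoms, runs the full preprocess -> random forest ->
graph-extraction chain, and prints per-surface accuracy plus the
fovea-centred per-layer thickness means.
"""

import numpy as np

from octlayers import (
    COMPACT_TEST_PROFILE,
    PhantomSpec,
    measure_eye,
    segment_volume,
    simulate_volume,
    train_from_phantoms,
)

spec = PhantomSpec()
profile = COMPACT_TEST_PROFILE

print("training boundary classifier on 3 phantoms ...")
clf = train_from_phantoms(spec, profile, n_phantoms=3, seed=100)

vol, truth = simulate_volume(spec, profile, seed=200)  # held out
result = segment_volume(vol, clf)

err = result.surfaces.mean_abs_error(truth)
print(f"mean absolute surface error: {err.mean():.2f} px "
      f"(worst surface {err.max():.2f} px)")
print("   -> errors well under one axial sample mean the solver is "
      "recovering the rendered geometry, not just the forest's argmax")

true_m = measure_eye(truth, profile)
print(f"\n{'layer':8s} {'estimated':>10s} {'truth':>8s}   (um, 5x5 mm mean)")
for layer in ("mRNFL", "GCIP", "INL+OPL", "ONL+PR", "RPE", "total"):
    print(f"{layer:8s} {result.measurements[layer]:10.2f} "
          f"{true_m[layer]:8.2f}")
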