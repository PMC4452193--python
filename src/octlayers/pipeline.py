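"""End-to-end segmentation chains built from the stage modules.

``segment_volume`` runs preprocess -> boundary classification -> coupled
surface extraction and returns surfaces in the native (unflattened) space
of the input volume. ``train_from_phantoms`` builds a boundary classifier
entirely from synthetic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .classifier import (
    TrainedBoundaryClassifier,
    predict_probabilities,
    train_boundary_classifier,
)
from .graph import SurfaceConstraints, extract_surfaces
from .phantom import PhantomSpec, simulate_volume
from .preprocess import preprocess_volume
from .profiles import DeviceProfile
from .surfaces import SurfaceSet
from .thickness import measure_eye
from .volume import OCTVolume

__all__ = ["SegmentationResult", "segment_volume", "train_from_phantoms",
           "surface_error_px"]


@dataclass
class SegmentationResult:
    surfaces: SurfaceSet          # native space
    surfaces_flat: SurfaceSet     # flattened space (solver output)
    shifts: np.ndarray
    measurements: dict[str, float]  # reported per-layer means, um


def segment_volume(
    volume: OCTVolume,
    classifier: TrainedBoundaryClassifier,
    constraints: Optional[SurfaceConstraints] = None,
    *,
    coupling: str = "bscan",
) -> SegmentationResult:
    """Segment one volume and compute its fovea-centred measurements."""
    flat = preprocess_volume(volume)
    probs = predict_probabilities(classifier, flat)
    surf_flat = extract_surfaces(probs, constraints, volume.profile,
                                 coupling=coupling)
    native = np.clip(surf_flat.depths - flat.shifts[None, :, :],
                     0, volume.profile.n_depth - 1 - 1e-9)
    native = np.maximum.accumulate(native, axis=0)  # clipping cannot break order
    surfaces = SurfaceSet(native, volume.profile)
    return SegmentationResult(
        surfaces=surfaces,
        surfaces_flat=surf_flat,
        shifts=flat.shifts,
        measurements=measure_eye(surfaces, volume.profile),
    )


def train_from_phantoms(
    spec: PhantomSpec,
    profile: DeviceProfile,
    n_phantoms: int = 3,
    *,
    seed: int = 0,
    n_trees: int = 50,
    max_depth: int = 12,
    label_tolerance_px: float = 1.0,
    per_class_cap: int = 20000,
) -> TrainedBoundaryClassifier:
    """Train the boundary classifier on freshly simulated phantoms.

    Each phantom is preprocessed exactly as real data would be, and its
    ground-truth surfaces are carried into the flattened space via the
    recorded shifts before labelling.
    """
    ss = np.random.SeedSequence(seed)
    vol_seeds = ss.spawn(n_phantoms + 1)
    flats, truths = [], []
    for i in range(n_phantoms):
        vol, truth = simulate_volume(spec, profile,
                                     seed=int(vol_seeds[i].generate_state(1)[0] % 2**31))
        flat = preprocess_volume(vol)
        flats.append(flat)
        truths.append(truth.shifted(flat.shifts))
    return train_boundary_classifier(
        flats, truths,
        n_trees=n_trees, max_depth=max_depth,
        label_tolerance_px=label_tolerance_px, per_class_cap=per_class_cap,
        seed=int(vol_seeds[-1].generate_state(1)[0] % 2**31),
    )


def surface_error_px(segmented: SurfaceSet, truth: SurfaceSet) -> np.ndarray:
    """Per-surface mean absolute depth error in pixels."""
    return segmented.mean_abs_error(truth)
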