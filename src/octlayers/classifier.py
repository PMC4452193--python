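"""Stage 2: random-forest classification of pixels into boundary classes.

Each ROI pixel is assigned a probability vector over 10 classes: background
(class 0) and the 9 layer boundaries (classes 1..9). Training labels come
from ground-truth (or manually corrected) surfaces: pixels within a small
depth tolerance of surface k get class k, everything else in the ROI is
background. Classes are balanced by per-class subsampling before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .exceptions import FeatureRecipeMismatchError, TrainingError, ValidationError
from .features import FEATURE_RECIPE, extract_features
from .layers import N_SURFACES
from .preprocess import FlattenedVolume
from .surfaces import SurfaceSet

__all__ = [
    "BoundaryProbabilityMap",
    "TrainedBoundaryClassifier",
    "train_boundary_classifier",
    "predict_probabilities",
    "save_classifier",
    "load_classifier",
]

N_CLASSES = N_SURFACES + 1  # 9 boundaries + background


@dataclass
class BoundaryProbabilityMap:
    """Class probabilities per pixel, shape (n_bscans, n_ascans, depth, 10).

    Index 0 of the last axis is background; index k is boundary k-1 of the
    surface set. ``roi`` is the depth band the probabilities cover within
    the flattened volume (outside it, background probability is 1).
    """

    probs: np.ndarray
    roi: tuple[int, int]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 4 or self.probs.shape[-1] != N_CLASSES:
            raise ValidationError(
                f"probability array must be (..., {N_CLASSES}), got {self.probs.shape}"
            )
        if self.probs.min() < -1e-9 or self.probs.max() > 1 + 1e-9:
            raise ValidationError("probabilities outside [0, 1]")
        sums = self.probs.sum(axis=-1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValidationError("probability vectors do not sum to 1")

    @property
    def boundary_probs(self) -> np.ndarray:
        """Probabilities of the 9 boundary classes, shape (9, nb, nx, nz)."""
        return np.moveaxis(self.probs[..., 1:], -1, 0)


@dataclass
class TrainedBoundaryClassifier:
    """A fitted forest plus the provenance needed to reproduce inference."""

    forest: RandomForestClassifier
    feature_recipe: str = FEATURE_RECIPE
    manifest: dict = field(default_factory=dict)


def _label_volume(flat: FlattenedVolume, truth_flat: SurfaceSet, tolerance_px: float) -> np.ndarray:
    """Integer labels over the ROI: 0 background, k = boundary k-1."""
    z0, z1 = flat.roi
    n_b, n_x, _ = flat.volume.shape
    z = np.arange(z0, z1, dtype=np.float64)
    labels = np.zeros((n_b, n_x, z1 - z0), dtype=np.int8)
    dist_best = np.full(labels.shape, np.inf)
    for k in range(N_SURFACES):
        d = np.abs(z[None, None, :] - truth_flat.depths[k][:, :, None])
        take = (d <= tolerance_px) & (d < dist_best)
        labels[take] = k + 1
        dist_best = np.minimum(dist_best, np.where(d <= tolerance_px, d, np.inf))
    return labels


def train_boundary_classifier(
    volumes: Sequence[FlattenedVolume],
    truths: Sequence[SurfaceSet],
    *,
    n_trees: int = 50,
    max_depth: int = 12,
    label_tolerance_px: float = 1.0,
    per_class_cap: int = 20000,
    seed: int = 0,
) -> TrainedBoundaryClassifier:
    """Train the boundary forest from flattened volumes + ground truth.

    ``truths`` must be in the same (flattened) space as the volumes — shift
    native-space surfaces by the flattening shifts first. Raises
    :class:`TrainingError` if any boundary class ends up with no labelled
    pixels.
    """
    if len(volumes) == 0 or len(volumes) != len(truths):
        raise ValidationError("need matching, non-empty volume and truth lists")
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for flat, truth in zip(volumes, truths):
        feats = extract_features(flat)
        labels = _label_volume(flat, truth, label_tolerance_px)
        X_parts.append(feats.reshape(-1, feats.shape[-1]))
        y_parts.append(labels.ravel())
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    keep = []
    for c in range(N_CLASSES):
        idx = np.flatnonzero(y == c)
        if idx.size == 0 and c > 0:
            raise TrainingError(f"no labelled pixels for boundary class {c}")
        if idx.size > per_class_cap:
            idx = rng.choice(idx, size=per_class_cap, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(X[keep], y[keep])
    manifest = {
        "n_training_volumes": len(volumes),
        "label_tolerance_px": label_tolerance_px,
        "per_class_cap": per_class_cap,
        "n_trees": n_trees,
        "max_depth": max_depth,
        "seed": seed,
        "training_source": "synthetic phantom ground truth"
        if not any(getattr(v.volume.meta, "subject_id", "") for v in volumes)
        else "provided segmentations",
        "n_samples_fit": int(keep.size),
    }
    return TrainedBoundaryClassifier(forest, FEATURE_RECIPE, manifest)


def predict_probabilities(
    classifier: TrainedBoundaryClassifier, flat: FlattenedVolume
) -> BoundaryProbabilityMap:
    """Full-ROI class probability map for one flattened volume.

    Classes the forest never saw (impossible here by construction, but kept
    robust) get probability zero; vectors are re-ordered to the canonical
    class order and are guaranteed to sum to 1.
    """
    if classifier.feature_recipe != FEATURE_RECIPE:
        raise FeatureRecipeMismatchError(
            f"model built with recipe {classifier.feature_recipe!r}, "
            f"this build uses {FEATURE_RECIPE!r}"
        )
    feats = extract_features(flat)
    n_b, n_x, nz, n_f = feats.shape
    raw = classifier.forest.predict_proba(feats.reshape(-1, n_f))
    probs = np.zeros((n_b * n_x * nz, N_CLASSES))
    for j, c in enumerate(classifier.forest.classes_):
        probs[:, int(c)] = raw[:, j]
    probs /= probs.sum(axis=1, keepdims=True)
    return BoundaryProbabilityMap(probs.reshape(n_b, n_x, nz, N_CLASSES), flat.roi)


def save_classifier(clf: TrainedBoundaryClassifier, path: str | Path) -> Path:
    path = Path(path)
    joblib.dump(
        {"format": "octlayers-boundary-model", "version": 1,
         "feature_recipe": clf.feature_recipe, "manifest": clf.manifest,
         "forest": clf.forest},
        path,
    )
    return path


def load_classifier(path: str | Path) -> TrainedBoundaryClassifier:
    blob = joblib.load(path)
    if not isinstance(blob, dict) or blob.get("format") != "octlayers-boundary-model":
        raise ValidationError(f"{path}: not an octlayers boundary model file")
    return TrainedBoundaryClassifier(
        blob["forest"], blob.get("feature_recipe", ""), blob.get("manifest", {})
    )
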