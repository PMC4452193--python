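"""Stage 1: intensity normalization, coarse ILM/BM estimation, flattening.

Each B-scan is normalized by a robust linear rescale (1st percentile -> 0,
99th -> 1, clipped), then coarse estimates of the inner limiting membrane
(first supra-threshold depth descending from the vitreous) and Bruch's
membrane (bottom edge of the brightest deep band) are computed per A-scan.
Columns are circularly shifted by integers so BM aligns to a common row;
the shifts are recorded, making flattening exactly invertible, and a depth
region of interest bracketing the retina is derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter

from .exceptions import LowSignalError, ValidationError
from .volume import OCTVolume

__all__ = [
    "FlattenedVolume",
    "normalize_bscan",
    "normalize_volume",
    "estimate_ilm_bm",
    "flatten_to_bm",
    "unflatten",
    "preprocess_volume",
]


@dataclass
class FlattenedVolume:
    """A BM-flattened volume plus everything needed to undo the flattening."""

    volume: OCTVolume
    shifts: np.ndarray       # (n_bscans, n_ascans) int: applied column roll
    ilm: np.ndarray          # coarse ILM depth per A-scan, flattened space
    bm: np.ndarray           # coarse BM depth per A-scan, flattened space
    roi: tuple[int, int]     # [z_top, z_bottom) depth band of interest

    @property
    def roi_depth(self) -> int:
        return self.roi[1] - self.roi[0]


def normalize_bscan(image: np.ndarray) -> np.ndarray:
    """Robust linear rescale of one B-scan: p1 -> 0, p99 -> 1, clipped.

    A constant image maps to all zeros. Idempotent up to the percentile
    discretization and clipping.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValidationError("empty B-scan")
    if not np.all(np.isfinite(image)):
        raise ValidationError("B-scan contains non-finite values")
    p1, p99 = np.percentile(image, [1.0, 99.0])
    if p99 <= p1:
        return np.zeros_like(image)
    return np.clip((image - p1) / (p99 - p1), 0.0, 1.0)


def normalize_volume(volume: OCTVolume) -> OCTVolume:
    """Apply :func:`normalize_bscan` to every B-scan of a volume."""
    cube = np.stack([normalize_bscan(volume.intensities[b])
                     for b in range(volume.shape[0])])
    return OCTVolume(cube, volume.profile, volume.meta)


def estimate_ilm_bm(
    volume: OCTVolume,
    *,
    axial_sigma_px: float = 3.0,
    threshold_fraction: float = 0.3,
    strong_fraction: float = 0.7,
    lateral_median_px: int = 7,
    min_signal: float = 0.1,
    max_dark_fraction: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Coarse per-A-scan ILM and BM depth estimates (pixels).

    ILM: first depth at which the axially smoothed A-scan exceeds an
    adaptive threshold ``vitreous level + threshold_fraction * (column max -
    vitreous level)``. BM: the steepest intensity fall-off just below the
    deepest strong reflector (the RPE complex — taken as the deepest sample
    above ``strong_fraction`` of the column maximum, so bright inner layers
    cannot capture it). Both maps are laterally median-filtered. Raises
    :class:`LowSignalError` when more than ``max_dark_fraction`` of A-scans
    carry no supra-threshold signal.
    """
    cube = volume.intensities
    n_b, n_x, n_z = cube.shape
    sm = gaussian_filter1d(cube, sigma=axial_sigma_px, axis=2, mode="nearest")
    vitreous = np.median(sm[:, :, : max(3, n_z // 50)], axis=2)
    colmax = sm.max(axis=2)
    dark = (colmax - vitreous) < min_signal
    if dark.mean() > max_dark_fraction:
        raise LowSignalError(
            f"{dark.mean():.0%} of A-scans have no detectable retinal signal"
        )
    thresh = vitreous + threshold_fraction * (colmax - vitreous)
    above = sm > thresh[:, :, None]
    ilm = np.argmax(above, axis=2).astype(np.float64)

    # deepest strong reflector = RPE complex; BM is its bottom edge
    z = np.arange(n_z)
    strong = sm >= (strong_fraction * colmax)[:, :, None]
    rpe_peak = n_z - 1 - np.argmax(strong[:, :, ::-1], axis=2)
    grad = np.gradient(sm, axis=2)
    window = max(3, int(round(30.0 / volume.profile.axial_um_per_px)))
    below_peak = (z[None, None, :] >= rpe_peak[:, :, None]) & (
        z[None, None, :] <= rpe_peak[:, :, None] + window
    )
    bm = np.argmin(np.where(below_peak, grad, np.inf), axis=2).astype(np.float64)

    if dark.any():  # fill dark columns from neighbours via the median filter
        ilm[dark] = np.nan
        bm[dark] = np.nan
        for arr in (ilm, bm):
            med = np.nanmedian(arr)
            arr[np.isnan(arr)] = med
    k = (min(3, n_b), lateral_median_px)  # across B-scans too: kills outliers
    ilm = median_filter(ilm, size=k, mode="nearest")
    bm = median_filter(bm, size=k, mode="nearest")
    bm = np.maximum(bm, ilm + 1)
    return ilm, bm


def flatten_to_bm(
    volume: OCTVolume,
    bm: np.ndarray,
    ilm: np.ndarray | None = None,
    *,
    margin_above_px: int = 15,
    margin_below_px: int = 10,
) -> FlattenedVolume:
    """Circularly shift each A-scan so the BM estimate aligns to one row.

    Integer shifts are recorded, so :func:`unflatten` restores the input
    exactly; the ROI band spans [min flattened ILM - margin_above, target BM
    + margin_below], clipped to the depth range.
    """
    cube = volume.intensities
    n_b, n_x, n_z = cube.shape
    if bm.shape != (n_b, n_x):
        raise ValidationError("BM estimate grid does not match volume")
    if bm.min() < 0 or bm.max() >= n_z:
        raise ValidationError("BM estimate outside volume depth")
    target = int(round(float(np.median(bm))))
    shifts = (target - np.rint(bm)).astype(int)
    if np.abs(shifts).max() >= n_z:
        raise ValidationError("required flattening shift exceeds volume depth")
    flat = np.empty_like(cube)
    for b in range(n_b):
        for x in range(n_x):
            s = shifts[b, x]
            flat[b, x] = cube[b, x] if s == 0 else np.roll(cube[b, x], s)
    bm_flat = bm + shifts
    if ilm is None:
        ilm_flat = np.zeros_like(bm_flat)
        z_top = 0
    else:
        ilm_flat = ilm + shifts
        z_top = max(0, int(np.floor(ilm_flat.min())) - margin_above_px)
    z_bottom = min(n_z, target + margin_below_px + 1)
    if z_bottom <= z_top:
        raise ValidationError("degenerate ROI band after flattening")
    out = OCTVolume(flat, volume.profile, volume.meta)
    return FlattenedVolume(out, shifts, ilm_flat, bm_flat, (z_top, z_bottom))


def unflatten(flat: FlattenedVolume) -> OCTVolume:
    """Exactly invert :func:`flatten_to_bm` (shifts are integer rolls)."""
    cube = flat.volume.intensities
    n_b, n_x, _ = cube.shape
    out = np.empty_like(cube)
    for b in range(n_b):
        for x in range(n_x):
            s = flat.shifts[b, x]
            out[b, x] = cube[b, x] if s == 0 else np.roll(cube[b, x], -s)
    return OCTVolume(out, flat.volume.profile, flat.volume.meta)


def preprocess_volume(volume: OCTVolume, **kwargs) -> FlattenedVolume:
    """normalize -> estimate ILM/BM -> flatten, the full stage-1 chain."""
    norm = normalize_volume(volume)
    ilm, bm = estimate_ilm_bm(norm)
    return flatten_to_bm(norm, bm, ilm, **kwargs)
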