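"""Per-pixel features for boundary classification.

Feature recipe (version 1), computed on the flattened, normalized volume,
for every pixel in the depth ROI, in this fixed order:

0.  raw intensity
1.  intensity smoothed axially, sigma 1 px
2.  intensity smoothed axially, sigma 2 px
3.  intensity smoothed axially, sigma 4 px
4.  first axial derivative, sigma 1 px
5.  first axial derivative, sigma 2 px
6.  second axial derivative, sigma 1 px
7.  second axial derivative, sigma 2 px
8.  signed depth distance to the coarse ILM estimate (px)
9.  signed depth distance to the flattened BM row (px)
10. normalized lateral position |x - centre| / width
11. depth below the top of the ROI (px)

Pixels outside the ROI are never featurized. The recipe identifier is
stored with trained models so incompatible feature sets are rejected at
prediction time rather than silently misclassified.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .preprocess import FlattenedVolume

__all__ = ["FEATURE_RECIPE", "FEATURE_NAMES", "extract_features"]

FEATURE_RECIPE = "octlayers-boundary-features-v1"

FEATURE_NAMES: tuple[str, ...] = (
    "intensity",
    "smooth_s1", "smooth_s2", "smooth_s4",
    "d1_s1", "d1_s2",
    "d2_s1", "d2_s2",
    "dist_ilm_px", "dist_bm_px",
    "lateral_pos", "depth_in_roi_px",
)


def extract_features(flat: FlattenedVolume) -> np.ndarray:
    """Feature array of shape (n_bscans, n_ascans, roi_depth, n_features)."""
    cube = flat.volume.intensities
    n_b, n_x, _ = cube.shape
    z0, z1 = flat.roi
    nz = z1 - z0

    def smooth(sigma, order=0):
        return gaussian_filter1d(cube, sigma=sigma, axis=2, order=order,
                                 mode="nearest")[:, :, z0:z1]

    z = np.arange(z0, z1, dtype=np.float64)
    feats = np.empty((n_b, n_x, nz, len(FEATURE_NAMES)))
    feats[..., 0] = cube[:, :, z0:z1]
    feats[..., 1] = smooth(1.0)
    feats[..., 2] = smooth(2.0)
    feats[..., 3] = smooth(4.0)
    feats[..., 4] = smooth(1.0, order=1)
    feats[..., 5] = smooth(2.0, order=1)
    feats[..., 6] = smooth(1.0, order=2)
    feats[..., 7] = smooth(2.0, order=2)
    feats[..., 8] = z[None, None, :] - flat.ilm[:, :, None]
    feats[..., 9] = z[None, None, :] - flat.bm[:, :, None]
    cx = (n_x - 1) / 2.0
    lateral = np.abs(np.arange(n_x) - cx) / n_x
    feats[..., 10] = lateral[None, :, None]
    feats[..., 11] = z[None, None, :] - z0
    return feats
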