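"""Surfaces -> thickness maps -> fovea-centred averaged measures.

Layer thickness at each A-scan is the depth separation of its bounding
surfaces times the axial sampling. The fovea is located as the A-scan of
minimal total retinal thickness within the central 2 x 2 mm; per-layer
means are then taken over the closed 5 x 5 mm square centred on it (the
fovea may sit up to 1 mm off-centre so the window still fits a 6 x 6 mm
scan — farther off, the scan is flagged rather than clamped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import FoveaOutOfToleranceError, ValidationError
from .layers import BASE_LAYERS, composite_layers
from .profiles import DeviceProfile
from .surfaces import SurfaceSet

__all__ = [
    "ThicknessMaps",
    "surfaces_to_thickness",
    "find_fovea",
    "average_window",
    "measure_eye",
    "composite_layers",
]

FOVEA_SEARCH_HALF_MM = 1.0   # central 2 x 2 mm search box
WINDOW_HALF_MM = 2.5         # 5 x 5 mm averaging square
FOVEA_TOLERANCE_MM = 1.0


@dataclass
class ThicknessMaps:
    """Per-layer thickness (um) on the A-scan grid, plus the total map."""

    layers: dict[str, np.ndarray]   # 8 base layers, each (n_bscans, n_ascans)
    total: np.ndarray
    profile: DeviceProfile

    def __post_init__(self) -> None:
        for name in BASE_LAYERS:
            if name not in self.layers:
                raise ValidationError(f"missing thickness map for layer {name}")
            if self.layers[name].min() < -1e-9:
                raise ValidationError(f"negative thickness in layer {name}")
        total = sum(self.layers[name] for name in BASE_LAYERS)
        if np.abs(total - self.total).max() > 1e-6:
            raise ValidationError("total map is not the sum of the base layers")


def surfaces_to_thickness(surfaces: SurfaceSet, profile: DeviceProfile) -> ThicknessMaps:
    """Convert 9 surfaces to 8 per-layer maps: (s_{k+1} - s_k) * um/px."""
    dz = profile.axial_um_per_px
    d = surfaces.depths
    layers = {name: (d[k + 1] - d[k]) * dz for k, name in enumerate(BASE_LAYERS)}
    total = (d[-1] - d[0]) * dz
    return ThicknessMaps(layers, total, profile)


def find_fovea(total: np.ndarray, profile: DeviceProfile) -> tuple[float, float]:
    """Locate the fovea: the thinnest A-scan within the central 2 x 2 mm.

    Returns (x_mm, y_mm) relative to the scan centre. Ties break toward the
    scan centre, then lexicographically in (y, x).
    """
    if not np.all(np.isfinite(total)):
        raise ValidationError("total thickness map contains non-finite values")
    x = np.linspace(-profile.fov_x_mm / 2, profile.fov_x_mm / 2,
                    profile.n_ascans_per_bscan)
    y = np.linspace(-profile.fov_y_mm / 2, profile.fov_y_mm / 2, profile.n_bscans)
    xx, yy = np.meshgrid(x, y)
    central = (np.abs(xx) <= FOVEA_SEARCH_HALF_MM) & (np.abs(yy) <= FOVEA_SEARCH_HALF_MM)
    if not central.any():
        raise ValidationError("grid does not cover the central 2 x 2 mm")
    masked = np.where(central, total, np.inf)
    tmin = masked.min()
    cand = np.argwhere(masked <= tmin + 1e-12)
    d2 = xx[cand[:, 0], cand[:, 1]] ** 2 + yy[cand[:, 0], cand[:, 1]] ** 2
    best = cand[np.lexsort((cand[:, 1], cand[:, 0], np.round(d2, 12)))][0]
    return float(xx[best[0], best[1]]), float(yy[best[0], best[1]])


def average_window(
    maps: ThicknessMaps, fovea_mm: tuple[float, float]
) -> dict[str, float]:
    """Mean thickness per base layer over the 5 x 5 mm fovea-centred square.

    Membership is by A-scan centre in the closed square. A fovea more than
    1 mm off-centre (window would leave the scan) raises
    :class:`FoveaOutOfToleranceError`.
    """
    fx, fy = fovea_mm
    if abs(fx) > FOVEA_TOLERANCE_MM + 1e-9 or abs(fy) > FOVEA_TOLERANCE_MM + 1e-9:
        raise FoveaOutOfToleranceError(
            f"fovea at ({fx:.2f}, {fy:.2f}) mm exceeds the +-1 mm tolerance"
        )
    p = maps.profile
    x = np.linspace(-p.fov_x_mm / 2, p.fov_x_mm / 2, p.n_ascans_per_bscan)
    y = np.linspace(-p.fov_y_mm / 2, p.fov_y_mm / 2, p.n_bscans)
    xx, yy = np.meshgrid(x, y)
    inside = (np.abs(xx - fx) <= WINDOW_HALF_MM + 1e-9) & (
        np.abs(yy - fy) <= WINDOW_HALF_MM + 1e-9
    )
    if not inside.any():
        raise ValidationError("empty averaging window")
    return {name: float(maps.layers[name][inside].mean()) for name in BASE_LAYERS}


def measure_eye(surfaces: SurfaceSet, profile: DeviceProfile) -> dict[str, float]:
    """Full measurement chain: thickness maps -> fovea -> 5 x 5 mm means ->
    reported composite set (mRNFL ... RPE, total), in um."""
    maps = surfaces_to_thickness(surfaces, profile)
    fovea = find_fovea(maps.total, profile)
    base_means = average_window(maps, fovea)
    return composite_layers(base_means)
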