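"""Synthetic macular phantoms with known layer geometry.

The phantom stands in for real retinas so the whole segmentation pipeline
can be exercised against exact ground truth. The generative model is
deliberately simple but captures the features the algorithm keys on:

* Bruch's membrane is a smooth, gently undulating reference surface;
  the 8 layers stack on top of it with prescribed thicknesses.
* A radially symmetric Gaussian foveal pit thins the inner layers (RNFL,
  GCIP, and to a lesser degree INL/OPL) to near zero at the pit centre, so
  total thickness is minimal at the fovea — the property the fovea finder
  exploits.
* Rendering paints piecewise-constant per-layer reflectivity, applies an
  axial Gaussian blur (point-spread surrogate) and multiplicative
  gamma-distributed speckle, the standard first-order OCT noise model.

It does NOT model vascular shadowing, motion artifacts, or curvature, so
accuracy measured on phantoms is an algorithmic sanity bound, not a
clinical error estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .exceptions import ValidationError
from .layers import BASE_LAYERS, N_SURFACES
from .profiles import DeviceProfile
from .surfaces import SurfaceSet
from .volume import OCTVolume, ScanMeta

__all__ = ["PhantomSpec", "simulate_surfaces", "render_volume", "simulate_volume"]

# Layer thicknesses (um) chosen to reproduce typical macular averages:
# composites come out near mRNFL 32, GCIP 66, INL+OPL 60, ONL+PR 108, RPE 33.
DEFAULT_THICKNESS_UM: dict[str, float] = {
    "RNFL": 32.0, "GCIP": 66.0, "INL": 35.0, "OPL": 25.0,
    "ONL": 63.0, "IS": 22.0, "OS": 23.0, "RPE": 33.0,
}

# Mean reflectivities in [0,1]; alternating bright/dark bands as in real
# B-scans (bright RNFL and photoreceptor/RPE complex, dark nuclear layers).
DEFAULT_REFLECTIVITY: dict[str, float] = {
    "vitreous": 0.04,
    "RNFL": 0.75, "GCIP": 0.40, "INL": 0.22, "OPL": 0.48,
    "ONL": 0.16, "IS": 0.55, "OS": 0.35, "RPE": 0.88,
    "choroid": 0.18,
}

# Share of the pit depression each inner layer absorbs (weights; outer
# layers are unaffected, as in real foveal anatomy).
_PIT_WEIGHTS: dict[str, float] = {"RNFL": 1.0, "GCIP": 1.0, "INL": 0.8, "OPL": 0.5}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic retina.

    ``pit_depth_um`` is the total reduction of retinal thickness at the pit
    centre; ``undulation_um`` the amplitude (SD) of the smooth random
    surface relief shared by all boundaries; ``speckle_shape`` the gamma
    shape parameter of multiplicative speckle (mean 1, variance 1/shape;
    ``None`` disables); ``axial_blur_fwhm_um`` the axial PSF width
    (0 disables).
    """

    thickness_um: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THICKNESS_UM))
    reflectivity: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFLECTIVITY))
    pit_depth_um: float = 120.0
    pit_radius_mm: float = 0.75
    undulation_um: float = 10.0
    speckle_shape: Optional[float] = 4.0
    axial_blur_fwhm_um: float = 8.0

    def __post_init__(self) -> None:
        for l in BASE_LAYERS:
            if l not in self.thickness_um:
                raise ValidationError(f"thickness_um missing layer {l!r}")
            if self.thickness_um[l] <= 0:
                raise ValidationError(f"thickness of {l} must be > 0")
        for name, r in self.reflectivity.items():
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"reflectivity[{name!r}]={r} outside [0,1]")
        if self.pit_depth_um < 0 or self.pit_radius_mm <= 0:
            raise ValidationError("pit depth must be >= 0 and radius > 0")
        inner_sum = sum(self.thickness_um[l] for l in _PIT_WEIGHTS)
        if self.pit_depth_um >= inner_sum:
            raise ValidationError(
                f"pit depth {self.pit_depth_um} um >= inner-layer thickness "
                f"sum {inner_sum} um (surfaces would cross)"
            )
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise ValidationError("speckle shape must be positive (or None)")

    def with_overrides(self, **kwargs) -> "PhantomSpec":
        return replace(self, **kwargs)

    @property
    def total_thickness_um(self) -> float:
        return sum(self.thickness_um[l] for l in BASE_LAYERS)


def simulate_surfaces(
    spec: PhantomSpec, profile: DeviceProfile, seed: int | np.random.Generator = 0
) -> SurfaceSet:
    """Generate the 9 ground-truth boundary surfaces on the profile's grid.

    Bruch's membrane sits so the retina is vertically centred, plus a
    seeded smooth random undulation; layers stack upward by their thickness
    fields, with the Gaussian pit thinning the inner layers. Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    p = profile
    dz = p.axial_um_per_px
    x = np.linspace(-p.fov_x_mm / 2, p.fov_x_mm / 2, p.n_ascans_per_bscan)
    y = np.linspace(-p.fov_y_mm / 2, p.fov_y_mm / 2, p.n_bscans)
    xx, yy = np.meshgrid(x, y)  # (ny, nx)
    r2 = xx**2 + yy**2
    pit = np.exp(-r2 / (2.0 * spec.pit_radius_mm**2))

    # pit reduction split among inner layers proportionally to weight*thickness
    w_total = sum(spec.thickness_um[l] * w for l, w in _PIT_WEIGHTS.items())
    thickness_px: dict[str, np.ndarray] = {}
    for l in BASE_LAYERS:
        t = np.full_like(xx, spec.thickness_um[l])
        if l in _PIT_WEIGHTS and spec.pit_depth_um > 0:
            share = spec.pit_depth_um * spec.thickness_um[l] * _PIT_WEIGHTS[l] / w_total
            t = t - share * pit
            if t.min() <= 0.5:
                raise ValidationError(
                    f"pit parameters drive layer {l} thickness to {t.min():.2f} um"
                )
        thickness_px[l] = t / dz

    if spec.undulation_um > 0:
        relief = rng.standard_normal(xx.shape)
        relief = gaussian_filter(relief, sigma=max(2.0, p.n_ascans_per_bscan / 12),
                                 mode="reflect")
        sd = relief.std()
        relief = relief / sd * (spec.undulation_um / dz) if sd > 0 else relief * 0
    else:
        relief = np.zeros_like(xx)

    total_px = sum(thickness_px[l] for l in BASE_LAYERS)
    bm = (p.n_depth + spec.total_thickness_um / dz) / 2.0 + relief
    depths = np.empty((N_SURFACES,) + xx.shape)
    depths[-1] = bm
    for k in range(len(BASE_LAYERS) - 1, -1, -1):
        depths[k] = depths[k + 1] - thickness_px[BASE_LAYERS[k]]
    if depths[0].min() < 0 or depths[-1].max() >= p.n_depth:
        raise ValidationError(
            "retina does not fit the axial range; reduce thicknesses or "
            "undulation, or increase n_depth"
        )
    _ = total_px
    return SurfaceSet(depths, profile)


def render_volume(
    truth: SurfaceSet,
    spec: PhantomSpec,
    profile: DeviceProfile,
    seed: int | np.random.Generator = 0,
    meta: Optional[ScanMeta] = None,
) -> OCTVolume:
    """Render an intensity volume from ground-truth surfaces.

    Voxel centre z belongs to the layer whose bounding surfaces satisfy
    ``s_k <= z < s_{k+1}`` (vitreous above the ILM, choroid below BM); the
    layer's mean reflectivity is painted, then axial blur and multiplicative
    gamma speckle are applied and the result clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    p = profile
    if truth.depths.shape[1:] != (p.n_bscans, p.n_ascans_per_bscan):
        raise ValidationError("truth surface grid does not match profile")
    z = np.arange(p.n_depth)
    # region index 0=vitreous, 1..8 layers, 9 choroid
    region = np.zeros((p.n_bscans, p.n_ascans_per_bscan, p.n_depth), dtype=np.int8)
    for k in range(N_SURFACES):
        region += (z[None, None, :] >= truth.depths[k][:, :, None])
    palette = np.array(
        [spec.reflectivity["vitreous"]]
        + [spec.reflectivity[l] for l in BASE_LAYERS]
        + [spec.reflectivity["choroid"]]
    )
    cube = palette[region]
    if spec.axial_blur_fwhm_um > 0:
        sigma_px = spec.axial_blur_fwhm_um / p.axial_um_per_px / 2.3548
        cube = gaussian_filter1d(cube, sigma=sigma_px, axis=2, mode="nearest")
    if spec.speckle_shape is not None:
        k = spec.speckle_shape
        cube = cube * rng.gamma(shape=k, scale=1.0 / k, size=cube.shape)
    cube = np.clip(cube, 0.0, 1.0)
    m = meta or ScanMeta(quality=30.0, art=p.art_required)
    return OCTVolume(cube, profile, m)


def simulate_volume(
    spec: PhantomSpec, profile: DeviceProfile, seed: int = 0,
    meta: Optional[ScanMeta] = None,
) -> tuple[OCTVolume, SurfaceSet]:
    """Convenience: surfaces + rendered volume from one seed.

    The surface and speckle random streams are derived from ``seed`` so the
    pair is reproducible as a unit.
    """
    ss = np.random.SeedSequence(seed)
    s_surf, s_render = ss.spawn(2)
    truth = simulate_surfaces(spec, profile, np.random.default_rng(s_surf))
    vol = render_volume(truth, spec, profile, np.random.default_rng(s_render), meta)
    return vol, truth
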