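"""Device acquisition profiles and scan quality gating.

A :class:`DeviceProfile` captures everything the toolkit needs to know about
how a scanner samples the macula: grid geometry, lateral field of view, axial
sampling, and the per-device quality metric with its gating threshold.

Two built-in profiles approximate the common macular protocols:

* ``cirrus-like`` — 512 A-scans x 128 B-scans x 1024 depth pixels over
  6 x 6 mm, ~1.95 um/px axial (2 mm scan depth), gated on device signal
  strength >= 7.
* ``spectralis-like`` — 512 A-scans x 49 B-scans x 496 depth pixels over
  6 x 6 mm, 3.87 um/px axial, gated on SNR >= 20 dB with a required
  frame-averaging (ART) count of 16.

These numbers are configuration defaults describing typical exports, not
measurements; override any field for a specific instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from typing import Mapping, Optional

from .exceptions import MissingMetadataError, ValidationError

__all__ = [
    "DeviceProfile",
    "QCResult",
    "qc_gate",
    "builtin_profile",
    "BUILTIN_PROFILES",
    "COMPACT_TEST_PROFILE",
]


@dataclass(frozen=True)
class DeviceProfile:
    """Acquisition geometry and quality gating for one OCT device."""

    name: str
    n_ascans_per_bscan: int
    n_bscans: int
    n_depth: int
    fov_x_mm: float
    fov_y_mm: float
    axial_um_per_px: float
    quality_metric: str = "signal_strength"  # or "snr_db"
    quality_threshold: float = 7.0
    art_required: Optional[int] = None

    def __post_init__(self) -> None:
        for field in ("n_ascans_per_bscan", "n_bscans", "n_depth"):
            if getattr(self, field) < 1:
                raise ValidationError(f"{field} must be >= 1, got {getattr(self, field)}")
        if self.fov_x_mm <= 0 or self.fov_y_mm <= 0:
            raise ValidationError("field of view must be positive")
        if self.axial_um_per_px <= 0:
            raise ValidationError("axial sampling must be positive")
        if self.quality_metric not in ("signal_strength", "snr_db"):
            raise ValidationError(f"unknown quality metric {self.quality_metric!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Volume array shape as (n_bscans, n_ascans, n_depth)."""
        return (self.n_bscans, self.n_ascans_per_bscan, self.n_depth)

    @property
    def n_voxels(self) -> int:
        return self.n_bscans * self.n_ascans_per_bscan * self.n_depth

    @property
    def spacing(self) -> tuple[float, float, float]:
        """(dx mm, dy mm, dz um): lateral A-scan pitch, B-scan pitch, axial."""
        dx = self.fov_x_mm / self.n_ascans_per_bscan
        dy = self.fov_y_mm / self.n_bscans
        return (dx, dy, self.axial_um_per_px)

    def with_overrides(self, **kwargs) -> "DeviceProfile":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "DeviceProfile":
        return cls(**dict(d))


BUILTIN_PROFILES: dict[str, DeviceProfile] = {
    "cirrus-like": DeviceProfile(
        name="cirrus-like",
        n_ascans_per_bscan=512,
        n_bscans=128,
        n_depth=1024,
        fov_x_mm=6.0,
        fov_y_mm=6.0,
        axial_um_per_px=2000.0 / 1024.0,
        quality_metric="signal_strength",
        quality_threshold=7.0,
        art_required=None,
    ),
    "spectralis-like": DeviceProfile(
        name="spectralis-like",
        n_ascans_per_bscan=512,
        n_bscans=49,
        n_depth=496,
        fov_x_mm=6.0,
        fov_y_mm=6.0,
        axial_um_per_px=3.87,
        quality_metric="snr_db",
        quality_threshold=20.0,
        art_required=16,
    ),
}

# Down-sampled grid used by the phantom-based test battery: same 6x6 mm field
# and axial sampling class as the full profiles, small enough to segment in
# seconds.
COMPACT_TEST_PROFILE = DeviceProfile(
    name="compact-test",
    n_ascans_per_bscan=96,
    n_bscans=12,
    n_depth=192,
    fov_x_mm=6.0,
    fov_y_mm=6.0,
    axial_um_per_px=3.87,
    quality_metric="signal_strength",
    quality_threshold=7.0,
)


def builtin_profile(name: str) -> DeviceProfile:
    try:
        return BUILTIN_PROFILES[name]
    except KeyError:
        if name == COMPACT_TEST_PROFILE.name:
            return COMPACT_TEST_PROFILE
        raise ValidationError(
            f"unknown profile {name!r}; available: {sorted(BUILTIN_PROFILES)}"
        ) from None


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: Optional[str] = None  # machine-readable, None when passed

    def __bool__(self) -> bool:
        return self.passed


def qc_gate(meta: Mapping, profile: DeviceProfile) -> QCResult:
    """Gate one scan on the profile's quality threshold (and ART, if required).

    ``meta`` must contain ``quality`` (the device's signal strength or SNR in
    dB); when the profile requires a frame-averaging count, ``art`` must be
    present and equal to it. A missing quality value is an error, never a
    silent pass.
    """
    quality = meta.get("quality")
    if quality is None:
        raise MissingMetadataError("scan metadata has no 'quality' value")
    if quality < profile.quality_threshold:
        return QCResult(False, f"{profile.quality_metric}<{profile.quality_threshold:g}")
    if profile.art_required is not None:
        art = meta.get("art")
        if art is None:
            raise MissingMetadataError("profile requires ART but metadata has no 'art'")
        if art != profile.art_required:
            return QCResult(False, f"art!={profile.art_required}")
    return QCResult(True)
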