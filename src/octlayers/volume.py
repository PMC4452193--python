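"""The in-memory OCT volume container.

An :class:`OCTVolume` is a 3-D reflectivity cube indexed ``(b-scan y,
lateral x, depth z)`` with values in [0, 1], carrying its device profile and
per-scan metadata. All image-stage operations consume and produce this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .exceptions import ValidationError
from .profiles import DeviceProfile

__all__ = ["ScanMeta", "OCTVolume"]


@dataclass
class ScanMeta:
    """Provenance of one scan: who, which eye, when, how good."""

    subject_id: str = ""
    eye: str = ""  # "OD" | "OS" | ""
    scan_date: str = ""  # ISO date string
    quality: Optional[float] = None
    art: Optional[int] = None
    extra: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "eye": self.eye,
            "scan_date": self.scan_date,
            "quality": self.quality,
            "art": self.art,
            "extra": dict(self.extra),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanMeta":
        return cls(
            subject_id=d.get("subject_id", ""),
            eye=d.get("eye", ""),
            scan_date=d.get("scan_date", ""),
            quality=d.get("quality"),
            art=d.get("art"),
            extra=dict(d.get("extra", {})),
        )


@dataclass
class OCTVolume:
    """3-D intensity cube with physical spacings and device provenance.

    ``intensities`` has shape ``profile.shape`` = (n_bscans, n_ascans,
    n_depth) and values in [0, 1]; validation runs at construction so no
    partially-formed volume escapes a reader.
    """

    intensities: np.ndarray
    profile: DeviceProfile
    meta: ScanMeta = field(default_factory=ScanMeta)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.intensities.ndim != 3:
            raise ValidationError(
                f"intensity cube must be 3-D, got ndim={self.intensities.ndim}"
            )
        if self.intensities.shape != self.profile.shape:
            raise ValidationError(
                f"cube shape {self.intensities.shape} does not match profile "
                f"{self.profile.name!r} shape {self.profile.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensity cube contains non-finite values")
        lo, hi = float(self.intensities.min()), float(self.intensities.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValidationError(f"intensities outside [0, 1]: range [{lo}, {hi}]")

    @property
    def spacing(self) -> tuple[float, float, float]:
        """(dx mm, dy mm, dz um), derived from the profile."""
        return self.profile.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def bscan(self, y: int) -> np.ndarray:
        """One B-scan as a (depth, lateral) image for display conventions."""
        return self.intensities[y].T

    def copy(self) -> "OCTVolume":
        return OCTVolume(self.intensities.copy(), self.profile, ScanMeta.from_dict(self.meta.to_dict()))

    def ascan_positions_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Lateral A-scan centre coordinates (x_mm, y_mm) about scan centre.

        Positions span [-fov/2, fov/2] inclusive along each lateral axis.
        """
        p = self.profile
        x = np.linspace(-p.fov_x_mm / 2, p.fov_x_mm / 2, p.n_ascans_per_bscan)
        y = np.linspace(-p.fov_y_mm / 2, p.fov_y_mm / 2, p.n_bscans)
        return x, y
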