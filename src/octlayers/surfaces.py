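"""The 9-surface container shared by ground truth and segmentation output.

A :class:`SurfaceSet` stores, for each of the 9 layer boundaries, a
continuous depth (in pixels) at every A-scan of a volume's lateral grid.
Surface 0 is the inner limiting membrane, surface 8 Bruch's membrane;
ordering ``s0 <= s1 <= ... <= s8`` holds at every A-scan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .layers import N_SURFACES, SURFACE_NAMES
from .profiles import DeviceProfile

__all__ = ["SurfaceSet"]


@dataclass
class SurfaceSet:
    """Ordered boundary depths, shape (9, n_bscans, n_ascans), in pixels."""

    depths: np.ndarray
    profile: DeviceProfile

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        p = self.profile
        expected = (N_SURFACES, p.n_bscans, p.n_ascans_per_bscan)
        if self.depths.shape != expected:
            raise ValidationError(
                f"surface array shape {self.depths.shape}, expected {expected}"
            )
        if not np.all(np.isfinite(self.depths)):
            raise ValidationError("surface depths contain non-finite values")
        if self.depths.min() < 0 or self.depths.max() >= p.n_depth:
            raise ValidationError(
                f"surface depths outside [0, {p.n_depth}): "
                f"range [{self.depths.min()}, {self.depths.max()}]"
            )
        diffs = np.diff(self.depths, axis=0)
        if diffs.min() < -1e-9:
            k = int(np.argwhere(diffs < -1e-9)[0][0])
            raise ValidationError(
                f"surface ordering violated between {SURFACE_NAMES[k]} and "
                f"{SURFACE_NAMES[k + 1]}"
            )

    def copy(self) -> "SurfaceSet":
        return SurfaceSet(self.depths.copy(), self.profile)

    def shifted(self, shift: np.ndarray) -> "SurfaceSet":
        """Return surfaces with a per-A-scan depth offset added (px)."""
        return SurfaceSet(self.depths + shift[None, :, :], self.profile)

    def mean_abs_error(self, other: "SurfaceSet") -> np.ndarray:
        """Per-surface mean absolute depth difference (px) against ``other``."""
        return np.abs(self.depths - other.depths).mean(axis=(1, 2))

    # -- long-format CSV (surface, y, x, depth_px) + JSON metadata ----------

    def to_frame(self) -> pd.DataFrame:
        k, y, x = np.meshgrid(
            np.arange(N_SURFACES),
            np.arange(self.profile.n_bscans),
            np.arange(self.profile.n_ascans_per_bscan),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "surface": k.ravel(),
                "y": y.ravel(),
                "x": x.ravel(),
                "depth_px": self.depths.ravel(),
            }
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        path.with_suffix(".json").write_text(
            json.dumps({"format": "octlayers-surfaces", "version": 1,
                        "surface_names": list(SURFACE_NAMES),
                        "profile": self.profile.to_dict()}, indent=2)
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SurfaceSet":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        profile = DeviceProfile.from_dict(sidecar["profile"])
        df = pd.read_csv(path)
        depths = np.full(
            (N_SURFACES, profile.n_bscans, profile.n_ascans_per_bscan), np.nan
        )
        depths[df["surface"], df["y"], df["x"]] = df["depth_px"]
        return cls(depths, profile)
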