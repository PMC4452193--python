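"""Pipeline configuration: one YAML file, every stage's knobs visible.

The default config written by ``octlayers init-config`` spells out all
parameters that are implementation choices (normalization percentiles,
flattening margins, forest size, surface constraints, statistics
conventions), so they can be inspected and overridden per study. Configs
round-trip losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import ValidationError
from .graph import SurfaceConstraints
from .layers import N_SURFACES
from .profiles import BUILTIN_PROFILES, DeviceProfile

__all__ = ["PipelineConfig", "default_config"]


@dataclass
class PipelineConfig:
    profiles: dict = field(default_factory=dict)      # name -> DeviceProfile dict
    phantom: dict = field(default_factory=dict)       # PhantomSpec overrides
    preprocess: dict = field(default_factory=lambda: {
        "margin_above_px": 15,
        "margin_below_px": 10,
    })
    classifier: dict = field(default_factory=lambda: {
        "n_trees": 50,
        "max_depth": 12,
        "label_tolerance_px": 1.0,
        "per_class_cap": 20000,
        "n_training_phantoms": 3,
    })
    constraints: dict = field(default_factory=dict)   # min_sep/max_sep/smoothness
    statistics: dict = field(default_factory=lambda: {
        "difference_convention": "spectralis_minus_cirrus",
        "loa_multiplier": 1.96,
        "variance_components": "anova",
        "mixed_model": "reml_wald",
    })
    seed: int = 0

    def device_profile(self, name: str) -> DeviceProfile:
        if name in self.profiles:
            return DeviceProfile.from_dict(self.profiles[name])
        if name in BUILTIN_PROFILES:
            return BUILTIN_PROFILES[name]
        raise ValidationError(f"profile {name!r} not in config or builtins")

    def surface_constraints(self, axial_um_per_px: float) -> SurfaceConstraints:
        if self.constraints:
            return SurfaceConstraints(
                tuple(self.constraints["min_sep"]),
                tuple(self.constraints["max_sep"]),
                tuple(self.constraints["smoothness"]),
            )
        return SurfaceConstraints.default(N_SURFACES, axial_um_per_px)

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config() -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.profiles = {name: prof.to_dict() for name, prof in BUILTIN_PROFILES.items()}
    return cfg
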