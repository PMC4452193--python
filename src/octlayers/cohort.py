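"""Simulated paired-device and longitudinal thickness cohorts.

These generators stand in for a clinical cohort scanned on two OCT devices,
so the agreement statistics can be validated against known parameters. The
defaults encode a typical two-scanner macular study: per-layer population
means/SDs, a fixed inter-device bias with its own SD (device B reads
``bias`` um higher than device A on average), and slow per-layer atrophy
with subject-level random intercepts shared by both eyes (which is what
induces intereye correlation).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ValidationError

__all__ = [
    "COHORT_LAYERS",
    "DEFAULT_BASE_MEAN_UM",
    "DEFAULT_BASE_SD_UM",
    "DEFAULT_DEVICE_BIAS_UM",
    "DEFAULT_DEVICE_DIFF_SD_UM",
    "DEFAULT_ANNUAL_SLOPE_UM",
    "DEFAULT_MS_DEFICIT_UM",
    "simulate_paired_eyes",
    "simulate_longitudinal_cohort",
]

# Layers as reported by two-scanner agreement tables.
COHORT_LAYERS: tuple[str, ...] = (
    "mRNFL", "GCIP", "INL", "INL+OPL", "ONL", "ONL+PR", "RPE",
)

# Population mean (SD) thickness per layer, um.
DEFAULT_BASE_MEAN_UM: dict[str, float] = {
    "mRNFL": 32.35, "GCIP": 65.59, "INL": 35.59, "INL+OPL": 60.59,
    "ONL": 63.10, "ONL+PR": 108.56, "RPE": 33.32,
}
DEFAULT_BASE_SD_UM: dict[str, float] = {
    "mRNFL": 4.38, "GCIP": 8.13, "INL": 1.81, "INL+OPL": 3.31,
    "ONL": 5.80, "ONL+PR": 7.14, "RPE": 1.92,
}

# Inter-device difference (device B minus device A): mean bias and SD, um.
DEFAULT_DEVICE_BIAS_UM: dict[str, float] = {
    "mRNFL": 4.71, "GCIP": 0.26, "INL": -1.31, "INL+OPL": -1.09,
    "ONL": -2.16, "ONL+PR": 0.20, "RPE": 0.14,
}
DEFAULT_DEVICE_DIFF_SD_UM: dict[str, float] = {
    "mRNFL": 1.79, "GCIP": 1.48, "INL": 0.77, "INL+OPL": 1.59,
    "ONL": 1.30, "ONL+PR": 1.74, "RPE": 1.42,
}

# Annual atrophy slope per layer, um/year (negative = thinning).
DEFAULT_ANNUAL_SLOPE_UM: dict[str, float] = {
    "mRNFL": -0.28, "GCIP": -0.59, "INL": -0.07, "INL+OPL": -0.08,
    "ONL": -0.06, "ONL+PR": 0.05, "RPE": 0.004,
}

# Cross-sectional MS-minus-HC thickness deficit per layer, um.
DEFAULT_MS_DEFICIT_UM: dict[str, float] = {
    "mRNFL": -3.54, "GCIP": -9.47, "INL": -0.57, "INL+OPL": -0.87,
    "ONL": -2.58, "ONL+PR": -2.71, "RPE": -1.39,
}

_MIN_THICKNESS_UM = 1.0


def _resolve(per_layer, layers, default, name) -> dict[str, float]:
    if per_layer is None:
        return {l: default[l] for l in layers}
    if np.isscalar(per_layer):
        return {l: float(per_layer) for l in layers}
    missing = [l for l in layers if l not in per_layer]
    if missing:
        raise ValidationError(f"{name} missing layers {missing}")
    return {l: float(per_layer[l]) for l in layers}


def simulate_paired_eyes(
    n_eyes: int,
    bias_um: Optional[Mapping[str, float] | float] = None,
    diff_sd_um: Optional[Mapping[str, float] | float] = None,
    base_mean_um: Optional[Mapping[str, float] | float] = None,
    base_sd_um: Optional[Mapping[str, float] | float] = None,
    layers: Sequence[str] = COHORT_LAYERS,
    device_a: str = "cirrus",
    device_b: str = "spectralis",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate same-day paired measurements of ``n_eyes`` eyes on two devices.

    Device A thickness is drawn from N(base_mean, base_sd^2) per layer;
    device B adds the inter-device bias plus N(0, diff_sd^2). Thicknesses
    are truncated at 1 um (a warning is issued if the parameters put more
    than 1% of the mass at or below zero). Returns a long table with columns
    ``subject, eye, layer, x_a, x_b`` (device names in ``DataFrame.attrs``).
    """
    if n_eyes < 2:
        raise ValidationError("n_eyes must be >= 2")
    rng = np.random.default_rng(seed)
    bias = _resolve(bias_um, layers, DEFAULT_DEVICE_BIAS_UM, "bias_um")
    dsd = _resolve(diff_sd_um, layers, DEFAULT_DEVICE_DIFF_SD_UM, "diff_sd_um")
    bmean = _resolve(base_mean_um, layers, DEFAULT_BASE_MEAN_UM, "base_mean_um")
    bsd = _resolve(base_sd_um, layers, DEFAULT_BASE_SD_UM, "base_sd_um")
    if any(v < 0 for v in dsd.values()):
        raise ValidationError("diff_sd_um must be >= 0")
    for l in layers:
        sd_b = float(np.hypot(bsd[l], dsd[l]))
        if sd_b > 0 and norm.cdf(0.0, loc=bmean[l] + bias[l], scale=sd_b) > 0.01:
            warnings.warn(
                f"layer {l}: >1% of simulated thickness mass is non-positive; "
                "truncation will bias the distribution", stacklevel=2)
    rows = []
    for i in range(n_eyes):
        subject, eye = f"S{i // 2:04d}", ("OD", "OS")[i % 2]
        for l in layers:
            xa = bmean[l] + bsd[l] * rng.standard_normal()
            xb = xa + bias[l] + dsd[l] * rng.standard_normal()
            rows.append((subject, eye, l,
                         max(xa, _MIN_THICKNESS_UM), max(xb, _MIN_THICKNESS_UM)))
    df = pd.DataFrame(rows, columns=["subject", "eye", "layer", "x_a", "x_b"])
    df.attrs["device_a"] = device_a
    df.attrs["device_b"] = device_b
    return df


def simulate_longitudinal_cohort(
    n_subjects: int,
    visit_years: Sequence[float] = (0.0, 1.4),
    slope_um_per_year: Optional[Mapping[str, float] | float] = None,
    intercept_sd_um: Optional[Mapping[str, float] | float] = None,
    eye_sd_um: float = 0.0,
    residual_sd_um: float = 1.5,
    age_effect_um_per_year: float = -0.05,
    sex_effect_um: float = 1.0,
    ms_fraction: float = 0.75,
    ms_deficit_um: Optional[Mapping[str, float] | float] = None,
    device_bias_um: Optional[Mapping[str, float] | float] = None,
    devices: Sequence[str] = ("spectralis",),
    layers: Sequence[str] = COHORT_LAYERS,
    eyes_per_subject: int = 2,
    age_mean: float = 43.0,
    age_sd: float = 11.0,
    female_fraction: float = 0.62,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a longitudinal two-eye cohort measured on one or two devices.

    Per eye and layer: thickness = subject intercept (shared by both eyes,
    N(0, intercept_sd^2)) + slope x years + age and sex fixed effects +
    group deficit (MS subjects) + device bias (devices after the first) +
    visit residual. The shared subject intercept induces an intereye
    correlation of intercept_sd^2 / (intercept_sd^2 + residual_sd^2 +
    eye_sd^2) in the fixed-effect-free thickness; ``eye_sd_um`` adds an
    optional eye-level deviation (0 by default, matching the analysis
    model's single random intercept).

    Returns a wide table: one row per subject x eye x device x visit with
    columns ``subject, eye, device, group, sex, age, years`` plus one
    thickness column per layer.
    """
    if n_subjects < 5:
        raise ValidationError("n_subjects must be >= 5")
    if len(visit_years) < 2:
        raise ValidationError("need at least 2 visits")
    rng = np.random.default_rng(seed)
    slope = _resolve(slope_um_per_year, layers, DEFAULT_ANNUAL_SLOPE_UM,
                     "slope_um_per_year")
    isd = _resolve(intercept_sd_um, layers, DEFAULT_BASE_SD_UM, "intercept_sd_um")
    deficit = _resolve(ms_deficit_um, layers, DEFAULT_MS_DEFICIT_UM, "ms_deficit_um")
    dbias = _resolve(device_bias_um, layers, DEFAULT_DEVICE_BIAS_UM, "device_bias_um")
    rows = []
    for s in range(n_subjects):
        subject = f"S{s:04d}"
        group = "RRMS" if rng.random() < ms_fraction else "HC"
        sex = "F" if rng.random() < female_fraction else "M"
        age0 = float(np.clip(age_mean + age_sd * rng.standard_normal(), 18.0, 80.0))
        subj_int = {l: isd[l] * rng.standard_normal() for l in layers}
        for e in range(eyes_per_subject):
            eye = ("OD", "OS")[e % 2]
            eye_dev = {l: eye_sd_um * rng.standard_normal() for l in layers}
            for t in visit_years:
                for d_idx, device in enumerate(devices):
                    row = {
                        "subject": subject, "eye": eye, "device": device,
                        "group": group, "sex": sex, "age": age0,
                        "years": float(t),
                    }
                    for l in layers:
                        mu = (
                            DEFAULT_BASE_MEAN_UM.get(l, 50.0)
                            + subj_int[l] + eye_dev[l]
                            + slope[l] * t
                            + age_effect_um_per_year * (age0 - age_mean)
                            + (sex_effect_um if sex == "M" else 0.0)
                            + (deficit[l] if group != "HC" else 0.0)
                            + (dbias[l] if d_idx > 0 else 0.0)
                        )
                        row[l] = max(mu + residual_sd_um * rng.standard_normal(),
                                     _MIN_THICKNESS_UM)
                    rows.append(row)
    return pd.DataFrame(rows)
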