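"""Retinal layer and surface naming conventions.

The segmentation finds 9 surfaces bounding 8 macular layers, listed inner
(vitreous side) to outer (choroid side). The composite measures reported by
the statistics stage combine base layers the way clinical tables do:
``INL+OPL``, ``ONL+PR`` (= ONL + photoreceptor inner and outer segments) and
``total`` (all 8 base layers).
"""

from __future__ import annotations

# 8 base anatomical layers, inner to outer. GCIP is the ganglion cell +
# inner plexiform composite, segmented as a single band.
BASE_LAYERS: tuple[str, ...] = (
    "RNFL", "GCIP", "INL", "OPL", "ONL", "IS", "OS", "RPE",
)

N_SURFACES = len(BASE_LAYERS) + 1  # 9

# Surface k (0-based) is the inner boundary of BASE_LAYERS[k]; surface 8 is
# Bruch's membrane. Names for file output / display.
SURFACE_NAMES: tuple[str, ...] = (
    "ILM",          # inner limiting membrane = top of RNFL
    "RNFL-GCIP",
    "GCIP-INL",     # = IPL-INL
    "INL-OPL",
    "OPL-ONL",
    "ONL-IS",       # external limiting membrane region
    "IS-OS",
    "OS-RPE",
    "BM",           # Bruch's membrane
)

# Measures reported by the statistics stage (column order of result tables).
REPORTED_LAYERS: tuple[str, ...] = (
    "mRNFL", "GCIP", "INL", "OPL", "INL+OPL", "ONL", "ONL+PR", "RPE", "total",
)

# CSV-safe aliases for reported layer labels.
CSV_ALIASES: dict[str, str] = {"INL+OPL": "INL_OPL", "ONL+PR": "ONL_PR"}
CSV_ALIASES_INV: dict[str, str] = {v: k for k, v in CSV_ALIASES.items()}


def to_csv_label(layer: str) -> str:
    return CSV_ALIASES.get(layer, layer)


def from_csv_label(column: str) -> str:
    return CSV_ALIASES_INV.get(column, column)


def composite_layers(base_means: dict[str, float]) -> dict[str, float]:
    """Combine 8 base-layer means (um) into the reported measurement set.

    ``mRNFL`` is the macular RNFL, ``INL+OPL`` and ``ONL+PR`` are the
    composites clinical tables print, and ``total`` is the full retinal
    thickness (sum of all base layers).
    """
    missing = [l for l in BASE_LAYERS if l not in base_means]
    if missing:
        raise KeyError(f"missing base layer means: {missing}")
    out = {
        "mRNFL": base_means["RNFL"],
        "GCIP": base_means["GCIP"],
        "INL": base_means["INL"],
        "OPL": base_means["OPL"],
        "INL+OPL": base_means["INL"] + base_means["OPL"],
        "ONL": base_means["ONL"],
        "ONL+PR": base_means["ONL"] + base_means["IS"] + base_means["OS"],
        "RPE": base_means["RPE"],
        "total": sum(base_means[l] for l in BASE_LAYERS),
    }
    return out
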