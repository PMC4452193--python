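"""Device export formats: write and re-read .img and .vol volumes.

Renders a phantom, exports it in both device-style formats, reads each
back and verifies geometry and intensities survive, then applies the
per-device scan quality gates.
"""

import tempfile
from pathlib import Path

import numpy as np

from octlayers import (
    COMPACT_TEST_PROFILE,
    PhantomSpec,
    qc_gate,
    read_cirrus_img,
    read_spectralis_vol,
    simulate_volume,
    write_cirrus_img,
    write_spectralis_vol,
)
from octlayers.profiles import BUILTIN_PROFILES

vol, _ = simulate_volume(PhantomSpec(), COMPACT_TEST_PROFILE, seed=3)
tmp = Path(tempfile.mkdtemp())

img = write_cirrus_img(vol, tmp / "scan.img")
back = read_cirrus_img(img, COMPACT_TEST_PROFILE)
print(f".img: {img.stat().st_size} bytes (= product of grid dims), "
      f"max abs round-trip error {np.abs(back.intensities - vol.intensities).max():.4f} "
      "(8-bit quantization)")

volf = write_spectralis_vol(vol, tmp / "scan.vol")
back = read_spectralis_vol(volf)
print(f".vol: geometry {back.shape}, axial {back.profile.axial_um_per_px:.2f} um/px, "
      f"max abs round-trip error {np.abs(back.intensities - vol.intensities).max():.2e} "
      "(float32 + fourth-root display transform)")

cirrus = BUILTIN_PROFILES["cirrus-like"]
spectralis = BUILTIN_PROFILES["spectralis-like"]
print("\nquality gating:")
for meta, prof in [({"quality": 7}, cirrus), ({"quality": 6}, cirrus),
                   ({"quality": 21.0, "art": 16}, spectralis),
                   ({"quality": 21.0, "art": 9}, spectralis)]:
    res = qc_gate(meta, prof)
    verdict = "pass" if res else f"FAIL ({res.reason})"
    print(f"  {prof.name:16s} {meta} -> {verdict}")
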