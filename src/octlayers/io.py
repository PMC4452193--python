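"""Readers and writers for OCT volume exports and measurement tables.

Supported volume formats:

* **Raw ``.img``** — headerless byte cube as exported by Cirrus-style
  devices: one unsigned 8-bit value per voxel, geometry supplied by the
  :class:`~octlayers.profiles.DeviceProfile`. Default byte order is depth
  fastest, then lateral position, then B-scan (configurable, since the
  export does not self-describe).
* **``.vol`` (HSF layout)** — Spectralis-style export: a 2048-byte header
  (magic ``HSF-OCT-``), an en-face SLO image, then per-B-scan blocks of a
  small header followed by 32-bit float reflectivities. Raw reflectivity is
  mapped to display intensity by the conventional fourth-root transform.
* **Internal raw+sidecar** — a float32 cube (``.octraw``) plus a JSON
  sidecar carrying the device profile and scan metadata; lossless to ~1e-7.

Measurement tables (one row per eye x device x date, one column per layer)
are plain CSV via pandas; see :func:`write_measurements_csv`.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    CorruptFileError,
    GeometryMismatchError,
    UnsupportedFormatError,
    ValidationError,
)
from .layers import REPORTED_LAYERS, from_csv_label, to_csv_label
from .profiles import DeviceProfile
from .volume import OCTVolume, ScanMeta

__all__ = [
    "read_cirrus_img",
    "write_cirrus_img",
    "read_spectralis_vol",
    "write_spectralis_vol",
    "read_internal",
    "write_internal",
    "read_measurements_csv",
    "write_measurements_csv",
]

_VOL_MAGIC = b"HSF-OCT"
_VOL_HEADER_SIZE = 2048
_VOL_BSCAN_HDR_SIZE = 256
_VOL_SENTINEL = 1e6  # raw reflectivities above this are invalid markers

ID_COLUMNS = ["subject", "eye", "device", "scan_date", "group", "age", "sex"]


# ---------------------------------------------------------------------------
# raw .img
# ---------------------------------------------------------------------------

def read_cirrus_img(
    path: str | Path,
    profile: DeviceProfile,
    *,
    axis_order: Sequence[str] = ("y", "x", "z"),
    meta: Optional[ScanMeta] = None,
) -> OCTVolume:
    """Read a headerless raw byte cube.

    ``axis_order`` lists the file's dimension order slowest-to-fastest;
    the default ``("y", "x", "z")`` means depth varies fastest. Intensities
    are rescaled to [0, 1] by dividing by 255.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) != profile.n_voxels:
        raise GeometryMismatchError(
            f"{path.name}: expected {profile.n_voxels} bytes for profile "
            f"{profile.name!r} ({profile.shape}), found {len(data)}"
        )
    dims = {"y": profile.n_bscans, "x": profile.n_ascans_per_bscan, "z": profile.n_depth}
    if sorted(axis_order) != ["x", "y", "z"]:
        raise ValidationError(f"axis_order must be a permutation of x,y,z, got {axis_order}")
    cube = np.frombuffer(data, dtype=np.uint8).reshape([dims[a] for a in axis_order])
    cube = np.moveaxis(cube, [axis_order.index(a) for a in ("y", "x", "z")], [0, 1, 2])
    return OCTVolume(cube.astype(np.float64) / 255.0, profile, meta or ScanMeta())


def write_cirrus_img(
    volume: OCTVolume,
    path: str | Path,
    *,
    axis_order: Sequence[str] = ("y", "x", "z"),
) -> Path:
    """Write a volume as a raw uint8 cube (inverse of :func:`read_cirrus_img`)."""
    path = Path(path)
    cube = np.clip(np.rint(volume.intensities * 255.0), 0, 255).astype(np.uint8)
    cube = np.moveaxis(cube, [0, 1, 2], [axis_order.index(a) for a in ("y", "x", "z")])
    path.write_bytes(np.ascontiguousarray(cube).tobytes())
    return path


# ---------------------------------------------------------------------------
# .vol (HSF layout)
# ---------------------------------------------------------------------------

_HSF_FIXED = struct.Struct(
    "<12s"  # version magic
    "iii"   # sizeX, numBScans, sizeZ
    "ddd"   # scaleX (mm), distance (mm), scaleZ (mm)
    "ii"    # sizeXSlo, sizeYSlo
    "dd"    # scaleXSlo, scaleYSlo
    "i"     # fieldSizeSlo
    "d"     # scanFocus
    "4s"    # scanPosition (e.g. b"OD  ")
    "q"     # examTime
    "i"     # scanPattern
    "i"     # bScanHdrSize
)


def read_spectralis_vol(
    path: str | Path,
    *,
    quality_metric: str = "snr_db",
    quality_threshold: float = 20.0,
    art_required: Optional[int] = 16,
) -> OCTVolume:
    """Read an HSF-layout ``.vol`` volume.

    Geometry comes from the header; raw float reflectivity is mapped to
    display intensity by ``clip(r, 0, inf) ** 0.25`` clipped to [0, 1], with
    invalid sentinel values (> 1e6) set to 0. The en-face SLO image and the
    per-B-scan headers are skipped (quality/eye fields are read when
    present).
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) < _VOL_HEADER_SIZE or not data.startswith(_VOL_MAGIC):
        raise UnsupportedFormatError(f"{path.name}: not an HSF .vol file (bad magic)")
    fields = _HSF_FIXED.unpack_from(data, 0)
    (_, size_x, n_bscans, size_z, scale_x, distance, scale_z,
     slo_x, slo_y, _sx, _sy, _fs, _focus, scan_pos, _t, _pattern, hdr_size) = fields
    if min(size_x, n_bscans, size_z) < 1 or hdr_size < 0:
        raise CorruptFileError(f"{path.name}: nonsensical header geometry")
    expected = (
        _VOL_HEADER_SIZE + slo_x * slo_y + n_bscans * (hdr_size + size_x * size_z * 4)
    )
    if len(data) != expected:
        raise CorruptFileError(
            f"{path.name}: header implies {expected} bytes, file has {len(data)}"
        )
    profile = DeviceProfile(
        name="spectralis-vol",
        n_ascans_per_bscan=size_x,
        n_bscans=n_bscans,
        n_depth=size_z,
        fov_x_mm=scale_x * size_x,
        fov_y_mm=distance * n_bscans,
        axial_um_per_px=scale_z * 1000.0,
        quality_metric=quality_metric,
        quality_threshold=quality_threshold,
        art_required=art_required,
    )
    offset = _VOL_HEADER_SIZE + slo_x * slo_y
    cube = np.empty((n_bscans, size_x, size_z), dtype=np.float64)
    qualities = []
    for b in range(n_bscans):
        if hdr_size >= 40:
            # B-scan header: version[12], bScanHdrSize i, startX/startY/endX/endY d...
            q_off = offset + 12 + 4 + 4 * 8 + 4 + 4  # after numSeg, offSeg
            if hdr_size >= q_off - offset + 4:
                (q,) = struct.unpack_from("<f", data, q_off)
                qualities.append(q)
        offset += hdr_size
        raw = np.frombuffer(data, dtype=np.float32, count=size_x * size_z, offset=offset)
        offset += size_x * size_z * 4
        raw = raw.reshape(size_z, size_x).T.astype(np.float64)  # file stores z slowest per A-scan row
        raw[~np.isfinite(raw)] = 0.0
        raw[raw > _VOL_SENTINEL] = 0.0
        cube[b] = np.clip(np.clip(raw, 0.0, None) ** 0.25, 0.0, 1.0)
    eye = scan_pos.decode("ascii", "ignore").strip("\x00 ").upper()
    meta = ScanMeta(eye=eye if eye in ("OD", "OS") else "",
                    quality=float(np.mean(qualities)) if qualities else None)
    return OCTVolume(cube, profile, meta)


def write_spectralis_vol(volume: OCTVolume, path: str | Path, *, quality: float = 25.0) -> Path:
    """Write a minimal valid HSF-layout ``.vol`` (inverse display transform).

    Intended for fixtures and interchange tests: display intensity d is
    stored as raw reflectivity d**4, so a read round-trips within float32
    precision. No SLO image is embedded.
    """
    path = Path(path)
    p = volume.profile
    header = bytearray(_VOL_HEADER_SIZE)
    eye = (volume.meta.eye or "OD").ljust(4)[:4].encode("ascii")
    _HSF_FIXED.pack_into(
        header, 0,
        b"HSF-OCT-103\x00",
        p.n_ascans_per_bscan, p.n_bscans, p.n_depth,
        p.fov_x_mm / p.n_ascans_per_bscan, p.fov_y_mm / p.n_bscans,
        p.axial_um_per_px / 1000.0,
        0, 0, 0.0, 0.0, 0, 0.0, eye, 0, 0, _VOL_BSCAN_HDR_SIZE,
    )
    chunks = [bytes(header)]
    for b in range(p.n_bscans):
        bh = bytearray(_VOL_BSCAN_HDR_SIZE)
        struct.pack_into("<12s", bh, 0, b"HSF-BS-103\x00\x00")
        struct.pack_into("<i", bh, 12, _VOL_BSCAN_HDR_SIZE)
        struct.pack_into("<f", bh, 12 + 4 + 32 + 8, float(quality))
        chunks.append(bytes(bh))
        raw = (volume.intensities[b] ** 4).T.astype(np.float32)  # (z, x)
        chunks.append(np.ascontiguousarray(raw).tobytes())
    path.write_bytes(b"".join(chunks))
    return path


# ---------------------------------------------------------------------------
# internal raw + JSON sidecar
# ---------------------------------------------------------------------------

def _internal_paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in (".octraw", ".json"):
        base = base.with_suffix("")
    return base.with_suffix(".octraw"), base.with_suffix(".json")


def write_internal(volume: OCTVolume, path: str | Path) -> Path:
    """Write the internal format: float32 cube + JSON sidecar. Returns the cube path."""
    if not np.all(np.isfinite(volume.intensities)):
        raise ValidationError("refusing to write volume with non-finite intensities")
    cube_path, sidecar_path = _internal_paths(path)
    cube_path.write_bytes(volume.intensities.astype(np.float32).tobytes())
    sidecar = {
        "format": "octlayers-internal",
        "version": 1,
        "dtype": "float32",
        "shape": list(volume.shape),
        "profile": volume.profile.to_dict(),
        "meta": volume.meta.to_dict(),
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return cube_path


def read_internal(path: str | Path) -> OCTVolume:
    cube_path, sidecar_path = _internal_paths(path)
    if not sidecar_path.exists():
        raise CorruptFileError(f"missing sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("format") != "octlayers-internal":
        raise UnsupportedFormatError(f"{sidecar_path.name}: not an internal sidecar")
    profile = DeviceProfile.from_dict(sidecar["profile"])
    shape = tuple(sidecar["shape"])
    raw = np.frombuffer(cube_path.read_bytes(), dtype=np.float32)
    if shape != profile.shape or raw.size != int(np.prod(shape)):
        raise CorruptFileError(
            f"{cube_path.name}: sidecar shape {shape} inconsistent with "
            f"profile {profile.shape} / {raw.size} stored voxels"
        )
    meta = ScanMeta.from_dict(sidecar.get("meta", {}))
    return OCTVolume(raw.reshape(shape).astype(np.float64), profile, meta)


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

def write_measurements_csv(table: pd.DataFrame, path: str | Path) -> Path:
    """Write an eye-measurement table; composite labels use CSV-safe aliases."""
    path = Path(path)
    out = table.rename(columns={c: to_csv_label(c) for c in table.columns})
    out.to_csv(path, index=False)
    return path


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    """Read an eye-measurement table, restoring composite layer labels."""
    df = pd.read_csv(path)
    df = df.rename(columns={c: from_csv_label(c) for c in df.columns})
    known = [c for c in df.columns if c in ID_COLUMNS or c in REPORTED_LAYERS
             or c in ("years", "visit")]
    unknown = [c for c in df.columns if c not in known]
    if not any(c in df.columns for c in ("subject", "eye")):
        raise ValidationError(f"{path}: not a measurement table (no subject/eye columns)")
    _ = unknown  # extra covariate columns pass through untouched
    return df
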