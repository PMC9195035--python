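"""Image and manifest persistence.

Images are stored as single-image 32-bit-float TIFF (or ``.npy`` arrays)
with a JSON sidecar carrying the panel geometry and acquisition
metadata; a reader for DICOM RT Image files maps the plane/position tags
into the same container.  Acquisition sets are described by a JSON
manifest so any method can run from a directory without knowing how the
images were produced.

Coordinate conventions follow :mod:`epidpsm.geometry`: 0-based indices,
row 0 on the negative-y panel edge, all lengths in cm at the isocenter
plane.  The sidecar records these conventions in a ``conventions`` field.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Dict, Iterable, List, Tuple

import numpy as np
import tifffile

from .geometry import (
    ImageKind,
    PanelGeometry,
    PixelSensitivityMap,
    PsmNormalization,
    RawImage,
)

__all__ = [
    "MetadataError",
    "save_image",
    "load_image",
    "save_psm",
    "load_psm",
    "save_manifest",
    "load_manifest",
    "write_stats",
]

CONVENTIONS = "0-based indices; row 0 at longitudinal -; cm at isocenter plane"


class MetadataError(ValueError):
    """A required metadata field is missing or inconsistent."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_image(path: str | Path, img: RawImage) -> Path:
    """Write pixels (TIFF float32 or .npy by extension) plus JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels.astype(np.float32))
    elif path.suffix.lower() == ".npy":
        np.save(path, img.pixels)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    g = img.geometry
    meta = {
        "conventions": CONVENTIONS,
        "geometry": dataclasses.asdict(g),
        "mu": img.mu,
        "field_x": img.field_x,
        "field_y": img.field_y,
        "kind": img.kind.value,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _load_sidecar(path: Path) -> Dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing metadata sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    for fld in ("geometry", "mu", "field_x", "field_y", "kind"):
        if fld not in meta:
            raise MetadataError(f"sidecar {sidecar.name} lacks field '{fld}'")
    return meta


def _from_dicom(path: Path) -> RawImage:
    """Map a DICOM RT Image into :class:`RawImage`.

    Required tags: Rows/Columns, ImagePlanePixelSpacing, RTImageSID,
    RadiationMachineSAD, XRayImageReceptorTranslation.  Pixel spacing and
    translation are given at the detector plane in mm and are projected
    to the isocenter plane.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    required = {
        "Rows": "Rows",
        "Columns": "Columns",
        "ImagePlanePixelSpacing": "ImagePlanePixelSpacing",
        "RTImageSID": "RTImageSID",
        "RadiationMachineSAD": "RadiationMachineSAD",
        "XRayImageReceptorTranslation": "XRayImageReceptorTranslation",
    }
    for attr in required.values():
        if getattr(ds, attr, None) is None:
            raise MetadataError(f"DICOM file lacks required tag {attr}")
    sad = float(ds.RadiationMachineSAD)
    sid = float(ds.RTImageSID) / 10.0  # mm -> cm
    sad_cm = sad / 10.0
    mag = sad_cm / sid
    pitch_iso = float(ds.ImagePlanePixelSpacing[0]) / 10.0 * mag
    tx, ty = (float(v) / 10.0 * mag for v in ds.XRayImageReceptorTranslation[:2])
    pixels = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    pixels = pixels * slope + intercept
    geom = PanelGeometry(
        n_rows=int(ds.Rows),
        n_cols=int(ds.Columns),
        pitch_iso=pitch_iso,
        sid=sid,
        shift_x=tx,
        shift_y=ty,
        sid_ref=sad_cm,
    )
    mu = float(getattr(ds, "MetersetExposure", 0.0) or 0.0)
    return RawImage(pixels=pixels, geometry=geom, mu=mu, kind=ImageKind.beam)


def load_image(path: str | Path) -> RawImage:
    """Load an image and its metadata (TIFF/.npy + sidecar, or DICOM)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".dcm":
        return _from_dicom(path)
    if suffix in (".tif", ".tiff"):
        pixels = tifffile.imread(path).astype(float)
    elif suffix == ".npy":
        pixels = np.load(path).astype(float)
    else:
        raise ValueError(f"unsupported image format: {suffix}")
    meta = _load_sidecar(path)
    geom = PanelGeometry(**meta["geometry"])
    if pixels.shape != geom.shape:
        raise MetadataError(
            f"pixel array {pixels.shape} does not match sidecar geometry {geom.shape}"
        )
    return RawImage(
        pixels=pixels,
        geometry=geom,
        mu=meta["mu"],
        field_x=meta["field_x"],
        field_y=meta["field_y"],
        kind=ImageKind(meta["kind"]),
    )


def save_psm(path: str | Path, psm: PixelSensitivityMap, geom: PanelGeometry) -> Path:
    """Write a PSM as float32 TIFF plus its validity mask and metadata."""
    path = Path(path)
    tifffile.imwrite(path, psm.values.astype(np.float32))
    mask_path = path.with_name(path.stem + "_mask" + path.suffix)
    tifffile.imwrite(mask_path, psm.valid_mask.astype(np.uint8))
    meta = {
        "conventions": CONVENTIONS,
        "geometry": dataclasses.asdict(geom),
        "normalization": psm.normalization.value,
        "mask_path": mask_path.name,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_psm(path: str | Path) -> Tuple[PixelSensitivityMap, PanelGeometry]:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    values = tifffile.imread(path).astype(float)
    mask = tifffile.imread(path.parent / meta["mask_path"]).astype(bool)
    geom = PanelGeometry(**meta["geometry"])
    psm = PixelSensitivityMap(
        values=values,
        valid_mask=mask,
        normalization=PsmNormalization(meta["normalization"]),
    )
    return psm, geom


# ---------------------------------------------------------------------------
# manifests


def save_manifest(path: str | Path, entries: List[Dict], scenario_hash: str = "") -> Path:
    """Write an acquisition manifest.

    Each entry holds at least ``path`` and ``role`` (free-form, e.g.
    "reference", "offset", "wide", "abdf_beam"); additional keys (shift,
    sid, mu, field, seed) are preserved verbatim.
    """
    path = Path(path)
    path.write_text(json.dumps({"scenario_hash": scenario_hash, "entries": entries}, indent=1))
    return path


def load_manifest(path: str | Path) -> Tuple[List[Dict], str]:
    """Load a manifest, check entry paths exist and geometry is consistent."""
    path = Path(path)
    data = json.loads(path.read_text())
    entries = data["entries"]
    base = path.parent
    shapes = set()
    for e in entries:
        p = base / e["path"]
        if not p.exists():
            raise MetadataError(f"manifest entry missing on disk: {e['path']}")
        sidecar = _sidecar_path(p)
        if sidecar.exists():
            g = json.loads(sidecar.read_text())["geometry"]
            shapes.add((g["n_rows"], g["n_cols"], g["pitch_iso"]))
    if len(shapes) > 1:
        raise MetadataError(f"inconsistent geometries across manifest: {shapes}")
    return entries, data.get("scenario_hash", "")


# ---------------------------------------------------------------------------
# stats output


def write_stats(path: str | Path, rows: Iterable[Dict]) -> None:
    """Write comparison rows as CSV, and as JSON next to it."""
    path = Path(path)
    rows = list(rows)
    if not rows:
        raise ValueError("no stats rows to write")
    keys = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(rows)
    path.with_suffix(".json").write_text(json.dumps(rows, indent=1, default=float))
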