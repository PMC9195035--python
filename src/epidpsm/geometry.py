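"""Panel/beam coordinate model and the multiplicative raw-image decomposition.

A raw (non-flood-field-corrected) portal image is modelled pixelwise as

    raw = scale * PSM * BeamResponse (+ noise)

where the pixel-sensitivity-map (PSM) carries every non-uniformity the
imager itself introduces (gain structure, dead pixels) and the
Beam-Response carries the non-uniformity of the incident beam (profile
dome, horns, penumbra).  Everything in this module is expressed at the
isocenter-projected scale: pixel pitch and panel shifts are given in cm
in the isocenter plane, and the source-to-imager distance (SID) only
enters through explicit magnification / inverse-square factors applied
by the simulator and the two-SID method.

Conventions (used consistently across the package):

* arrays are indexed ``[row, col]``; row = longitudinal/inplane axis (y),
  col = lateral/crossplane axis (x); indices are 0-based and row 0 is the
  panel edge on the negative-y side;
* on the even-sized grids used here the beam axis falls between pixels:
  the "central-axis value" of a map is the mean of the central 2x2
  pixels, and the PSM normalization region is the 10x10 block symmetric
  about the array center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Tuple

import numpy as np

__all__ = [
    "PanelGeometry",
    "RawImage",
    "PixelSensitivityMap",
    "BeamResponse",
    "DeviationStats",
    "DegenerateNormalizationError",
    "pixel_to_offaxis",
    "offaxis_to_pixel",
    "pixel_coords",
    "normalize_psm",
    "normalize_beam_response",
    "extract_crossplane_profile",
    "decompose",
    "compose",
    "central_roi_slices",
]


class DegenerateNormalizationError(ValueError):
    """Raised when a normalization reference region is non-positive."""


@dataclass(frozen=True)
class PanelGeometry:
    """Panel grid, pitch and shift state, all at the isocenter plane.

    Parameters
    ----------
    n_rows, n_cols:
        Pixel grid size (>= 2 each).
    pitch_iso:
        Pixel pitch in cm per pixel, projected to the isocenter plane at
        the reference SID.
    sid:
        Source-to-imager distance in cm for the acquisition.
    shift_x, shift_y:
        Panel translation in cm (isocenter plane, beam frame); a positive
        ``shift_x`` moves the panel so that a pixel's beam-frame x grows
        by ``shift_x``.
    sid_ref:
        Reference SID for magnification / inverse-square scaling.
    """

    n_rows: int
    n_cols: int
    pitch_iso: float
    sid: float = 100.0
    shift_x: float = 0.0
    shift_y: float = 0.0
    sid_ref: float = 100.0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("panel grid must be at least 2x2")
        if self.pitch_iso <= 0:
            raise ValueError("pitch_iso must be positive")
        if self.sid <= 0 or self.sid_ref <= 0:
            raise ValueError("SID values must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def active_width_x(self) -> float:
        """Active lateral width in cm at isocenter."""
        return self.n_cols * self.pitch_iso

    @property
    def active_width_y(self) -> float:
        return self.n_rows * self.pitch_iso

    def with_shift(self, shift_x: float, shift_y: float) -> "PanelGeometry":
        return replace(self, shift_x=shift_x, shift_y=shift_y)

    def with_sid(self, sid: float) -> "PanelGeometry":
        return replace(self, sid=sid)


class ImageKind(str, Enum):
    beam = "beam"
    dark = "dark"
    net = "net"


@dataclass
class RawImage:
    """A 2D portal image plus the acquisition metadata the methods need."""

    pixels: np.ndarray
    geometry: PanelGeometry
    mu: float = 0.0
    field_x: float = 0.0
    field_y: float = 0.0
    kind: ImageKind = ImageKind.beam

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != self.geometry.shape:
            raise ValueError(
                f"pixel array shape {self.pixels.shape} does not match "
                f"geometry {self.geometry.shape}"
            )
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.kind == ImageKind.dark and self.mu != 0:
            raise ValueError("dark frames must have mu = 0")


class PsmNormalization(str, Enum):
    raw = "raw"
    central_roi = "central_roi"


@dataclass
class PixelSensitivityMap:
    """Per-pixel relative gain; 1.0 means nominal sensitivity.

    ``valid_mask`` is True where the producing method actually constrained
    the value; dead pixels may be 0 but never negative.
    """

    values: np.ndarray
    valid_mask: np.ndarray | None = None
    normalization: PsmNormalization = PsmNormalization.raw

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise ValueError("valid_mask shape mismatch")
        if np.any(self.values < 0):
            raise ValueError("PSM values must be non-negative")


class BrNormalization(str, Enum):
    raw = "raw"
    central_axis = "central_axis"


class BrProvenance(str, Enum):
    sampled_grid = "sampled_grid"
    spline_fit = "spline_fit"
    radial_fit = "radial_fit"
    simulator_truth = "simulator_truth"


@dataclass
class BeamResponse:
    """Smooth beam-introduced signal map on the panel grid (beam frame)."""

    values: np.ndarray
    normalization: BrNormalization = BrNormalization.raw
    provenance: BrProvenance = BrProvenance.sampled_grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class DeviationStats:
    """Summary of a per-pixel percentage-deviation map."""

    mean: float
    median: float
    sd: float
    p95_abs: float
    bin_edges: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    n_pixels: int = 0


# ---------------------------------------------------------------------------
# coordinates


def pixel_to_offaxis(geom: PanelGeometry, row, col):
    """Off-axis (x, y) in cm at isocenter for pixel indices (row, col).

    ``x = (col - (n_cols - 1)/2) * pitch_iso + shift_x`` and analogously
    for y; the beam axis is at x = y = 0 when the shifts are zero.  Row
    and column may be scalars or arrays; indices must be inside the grid.
    """
    row = np.asarray(row)
    col = np.asarray(col)
    if np.any(row < 0) or np.any(row >= geom.n_rows):
        raise IndexError("row index out of range")
    if np.any(col < 0) or np.any(col >= geom.n_cols):
        raise IndexError("col index out of range")
    x = (col - (geom.n_cols - 1) / 2.0) * geom.pitch_iso + geom.shift_x
    y = (row - (geom.n_rows - 1) / 2.0) * geom.pitch_iso + geom.shift_y
    return x, y


def offaxis_to_pixel(geom: PanelGeometry, x, y):
    """Fractional pixel indices (row, col) for beam-frame (x, y) in cm."""
    col = (np.asarray(x) - geom.shift_x) / geom.pitch_iso + (geom.n_cols - 1) / 2.0
    row = (np.asarray(y) - geom.shift_y) / geom.pitch_iso + (geom.n_rows - 1) / 2.0
    return row, col


def pixel_coords(geom: PanelGeometry):
    """(x, y) 1D coordinate vectors (cm) of the pixel columns and rows."""
    cols = np.arange(geom.n_cols)
    rows = np.arange(geom.n_rows)
    x = (cols - (geom.n_cols - 1) / 2.0) * geom.pitch_iso + geom.shift_x
    y = (rows - (geom.n_rows - 1) / 2.0) * geom.pitch_iso + geom.shift_y
    return x, y


def central_roi_slices(shape: Tuple[int, int], size: int = 10):
    """Slices of the size x size block symmetric about the array center."""
    r0 = (shape[0] - size) // 2
    c0 = (shape[1] - size) // 2
    return slice(r0, r0 + size), slice(c0, c0 + size)


# ---------------------------------------------------------------------------
# normalizations


def normalize_psm(psm: PixelSensitivityMap, roi_size: int = 10) -> PixelSensitivityMap:
    """Divide a PSM by the mean of its central ``roi_size**2`` pixels.

    Idempotent and scale invariant; raises
    :class:`DegenerateNormalizationError` if the central region mean is
    not positive (e.g. a dead panel center).
    """
    rs, cs = central_roi_slices(psm.values.shape, roi_size)
    ref = float(np.mean(psm.values[rs, cs]))
    if ref <= 0:
        raise DegenerateNormalizationError(
            f"central {roi_size}x{roi_size} mean is {ref}; cannot normalize"
        )
    return PixelSensitivityMap(
        values=psm.values / ref,
        valid_mask=psm.valid_mask.copy(),
        normalization=PsmNormalization.central_roi,
    )


def normalize_beam_response(br: BeamResponse) -> BeamResponse:
    """Divide a Beam-Response by its central-axis value.

    The central-axis value on an even grid is the mean of the central 2x2
    pixels.
    """
    rs, cs = central_roi_slices(br.values.shape, 2)
    ref = float(np.mean(br.values[rs, cs]))
    if ref <= 0:
        raise DegenerateNormalizationError(f"central-axis value is {ref}")
    return BeamResponse(
        values=br.values / ref,
        normalization=BrNormalization.central_axis,
        provenance=br.provenance,
    )


def extract_crossplane_profile(img: np.ndarray, geom: PanelGeometry):
    """Central crossplane profile: mean of the two central rows vs x (cm)."""
    img = np.asarray(img, dtype=float)
    if img.shape != geom.shape:
        raise ValueError("image shape does not match geometry")
    r = geom.n_rows // 2
    profile = img[r - 1 : r + 1].mean(axis=0)
    x, _ = pixel_coords(geom)
    return x, profile


# ---------------------------------------------------------------------------
# decomposition


def decompose(
    raw: RawImage | np.ndarray,
    br: BeamResponse | np.ndarray,
    *,
    normalize: bool = True,
) -> PixelSensitivityMap:
    """PSM = raw / Beam-Response, pixelwise, then central-ROI normalization.

    Pixels where the Beam-Response is not safely positive (``br <= eps``
    with ``eps = 1e-9 *`` central value) get PSM value 0 and
    ``valid_mask`` False: this makes dead-pixel and out-of-field handling
    explicit instead of emitting infs.
    """
    pix = raw.pixels if isinstance(raw, RawImage) else np.asarray(raw, dtype=float)
    brv = br.values if isinstance(br, BeamResponse) else np.asarray(br, dtype=float)
    if pix.shape != brv.shape:
        raise ValueError("raw and Beam-Response shapes differ")
    rs, cs = central_roi_slices(brv.shape, 2)
    eps = 1e-9 * abs(float(np.mean(brv[rs, cs])))
    good = brv > eps
    values = np.zeros_like(pix)
    np.divide(pix, brv, out=values, where=good)
    values[values < 0] = 0.0
    psm = PixelSensitivityMap(values=values, valid_mask=good)
    return normalize_psm(psm) if normalize else psm


def compose(psm: PixelSensitivityMap | np.ndarray, br: BeamResponse | np.ndarray):
    """Raw-image model: pixelwise product PSM * Beam-Response."""
    p = psm.values if isinstance(psm, PixelSensitivityMap) else np.asarray(psm)
    b = br.values if isinstance(br, BeamResponse) else np.asarray(br)
    if p.shape != b.shape:
        raise ValueError("shapes differ")
    return p * b
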