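"""Constant-beam offset-grid PSM method ("CMN").

A small field (default 5x5 cm) is delivered repeatedly while the panel
is translated to a grid of offsets, so different panel regions sample
the *same* part of the beam.  The ratio of an offset image to the
centered reference image — both read in a small ROI at the beam-center
projection — cancels the Beam-Response exactly and leaves the relative
pixel sensitivity at the sampled panel point.  Dividing a wide-field raw
image by those sensitivities gives Beam-Response samples on the offset
grid; a tensor-product not-a-knot cubic spline (linearly extrapolated
outside the sampled rectangle) turns them into a full-panel
Beam-Response, whose removal from the wide-field raw image yields the
PSM for every pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .geometry import (
    BeamResponse,
    BrProvenance,
    PanelGeometry,
    PixelSensitivityMap,
    RawImage,
    decompose,
)

__all__ = [
    "OffsetPlan",
    "SampledBeamResponse",
    "cmn_plan",
    "relative_sensitivity_at_points",
    "beam_response_samples",
    "fit_beam_response_2d",
    "cmn_psm",
    "run",
]


@dataclass(frozen=True)
class OffsetPlan:
    """Panel-offset acquisition plan for the constant-beam method.

    ``offsets`` are panel shifts (cm, isocenter plane); each offset
    places the beam center over the panel point ``(-sx, -sy)``.  The plan
    implies one extra centered reference acquisition at (0, 0).
    """

    lat_offsets: Tuple[float, ...]
    long_offsets: Tuple[float, ...]
    field_x: float = 5.0
    field_y: float = 5.0
    roi_halfwidth_cm: float = 0.5

    @property
    def offsets(self) -> List[Tuple[float, float]]:
        return [(sx, sy) for sy in self.long_offsets for sx in self.lat_offsets]

    def __len__(self) -> int:
        return len(self.lat_offsets) * len(self.long_offsets)


def cmn_plan(
    lat_range: Tuple[float, float] = (-15.0, 15.0),
    long_range: Tuple[float, float] = (-15.0, 10.0),
    step: float = 5.0,
    field_x: float = 5.0,
    field_y: float = 5.0,
    roi_halfwidth_cm: float = 0.5,
) -> OffsetPlan:
    """Offset grid plan; defaults give the 7 lateral x 6 longitudinal =
    42 offsets (5 cm spacing, lateral -15..+15, longitudinal -15..+10)
    plus the centered reference."""
    if step <= 0:
        raise ValueError("step must be positive")
    out = []
    for lo, hi in (lat_range, long_range):
        span = hi - lo
        n = span / step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"range {lo}..{hi} is not a multiple of step {step}")
        out.append(tuple(lo + step * k for k in range(int(round(n)) + 1)))
    return OffsetPlan(
        lat_offsets=out[0],
        long_offsets=out[1],
        field_x=field_x,
        field_y=field_y,
        roi_halfwidth_cm=roi_halfwidth_cm,
    )


@dataclass
class SampledBeamResponse:
    """Beam-Response values on the rectangular grid of sampled panel points."""

    x: np.ndarray  # (n_lat,) panel-local x of sample columns, cm
    y: np.ndarray  # (n_long,) panel-local y of sample rows, cm
    values: np.ndarray  # (n_long, n_lat), normalized to the (0, 0) point


def _roi_indices(geom: PanelGeometry, sx: float, sy: float, halfwidth_cm: float):
    """Pixel slices of the ROI at the beam-center projection for shift (sx, sy).

    The beam axis projects onto panel-local point (-sx, -sy); the ROI is
    the square of half-width ``halfwidth_cm`` centered on the nearest
    pixel.  Returns (row slice, col slice, actual panel-local x, y of the
    ROI center) — the actual coordinates are used as the sample location
    so that sub-pixel rounding never breaks the beam cancellation.
    """
    hw = max(1, int(round(halfwidth_cm / geom.pitch_iso)))
    col_f = -sx / geom.pitch_iso + (geom.n_cols - 1) / 2.0
    row_f = -sy / geom.pitch_iso + (geom.n_rows - 1) / 2.0
    col = int(round(col_f))
    row = int(round(row_f))
    if not (hw <= row < geom.n_rows - hw and hw <= col < geom.n_cols - hw):
        raise ValueError(f"ROI for offset ({sx}, {sy}) falls outside the panel")
    x_actual = (col - (geom.n_cols - 1) / 2.0) * geom.pitch_iso
    y_actual = (row - (geom.n_rows - 1) / 2.0) * geom.pitch_iso
    return (
        slice(row - hw, row + hw + 1),
        slice(col - hw, col + hw + 1),
        x_actual,
        y_actual,
    )


def _check_roi_inside_field(plan: OffsetPlan, penumbra_sigma: float = 0.4) -> None:
    limit = min(plan.field_x, plan.field_y) / 2.0 - 3.0 * penumbra_sigma
    if plan.roi_halfwidth_cm > limit:
        raise ValueError(
            f"ROI halfwidth {plan.roi_halfwidth_cm} cm touches the field "
            f"penumbra (limit {limit:.2f} cm for a "
            f"{plan.field_x}x{plan.field_y} cm field)"
        )


def relative_sensitivity_at_points(
    images: Dict[Tuple[float, float], RawImage],
    reference: RawImage,
    plan: OffsetPlan,
    penumbra_sigma: float = 0.4,
) -> np.ndarray:
    """Relative sensitivities s_rel on the offset grid.

    ``s_rel = ROI mean of the offset image at the beam-center projection
    / ROI mean of the centered image at its own beam-center projection``;
    the constant beam cancels, so noiseless ratios equal the PSM ROI mean
    at the sampled point divided by the central one.
    """
    _check_roi_inside_field(plan, penumbra_sigma)
    geom = reference.geometry
    rs, cs, _, _ = _roi_indices(geom, 0.0, 0.0, plan.roi_halfwidth_cm)
    ref_mean = float(reference.pixels[rs, cs].mean())
    if ref_mean <= 0:
        raise ValueError("reference ROI mean is not positive")
    s_rel = np.empty((len(plan.long_offsets), len(plan.lat_offsets)))
    for iy, sy in enumerate(plan.long_offsets):
        for ix, sx in enumerate(plan.lat_offsets):
            try:
                img = images[(sx, sy)]
            except KeyError as exc:
                raise ValueError(f"missing offset image for ({sx}, {sy})") from exc
            rs, cs, _, _ = _roi_indices(geom, sx, sy, plan.roi_halfwidth_cm)
            s_rel[iy, ix] = float(img.pixels[rs, cs].mean()) / ref_mean
    return s_rel


def beam_response_samples(
    wide_raw: RawImage, s_rel: np.ndarray, plan: OffsetPlan
) -> SampledBeamResponse:
    """Beam-Response samples: wide-field ROI means divided by s_rel.

    ``wide_raw`` must be a centered acquisition.  Each sample uses the
    identical pixel ROI that produced its sensitivity, so the PSM
    content of the wide image cancels exactly; the result is normalized
    to the (0, 0) sample.
    """
    if wide_raw.geometry.shift_x or wide_raw.geometry.shift_y:
        raise ValueError("wide-field image must be acquired with the panel centered")
    if s_rel.shape != (len(plan.long_offsets), len(plan.lat_offsets)):
        raise ValueError("s_rel shape does not match the plan")
    geom = wide_raw.geometry
    n_long, n_lat = s_rel.shape
    values = np.empty((n_long, n_lat))
    xs = np.empty(n_lat)
    ys = np.empty(n_long)
    for iy, sy in enumerate(plan.long_offsets):
        for ix, sx in enumerate(plan.lat_offsets):
            rs, cs, x_act, y_act = _roi_indices(geom, sx, sy, plan.roi_halfwidth_cm)
            roi_mean = float(wide_raw.pixels[rs, cs].mean())
            if roi_mean <= 0:
                raise ValueError(f"wide-field ROI at ({sx}, {sy}) has no signal")
            values[iy, ix] = roi_mean / s_rel[iy, ix]
            xs[ix] = x_act
            ys[iy] = y_act
    # normalize to the sample nearest the beam axis (the (0, 0) offset)
    i0 = int(np.argmin(np.abs(ys)))
    j0 = int(np.argmin(np.abs(xs)))
    values /= values[i0, j0]
    order_x = np.argsort(xs)
    order_y = np.argsort(ys)
    return SampledBeamResponse(
        x=xs[order_x], y=ys[order_y], values=values[np.ix_(order_y, order_x)]
    )


def _spline_with_linear_tails(knots: np.ndarray, values: np.ndarray, axis: int):
    """Not-a-knot cubic spline along ``axis`` whose extrapolation is the
    linear continuation of the boundary gradient."""
    cs = CubicSpline(knots, values, axis=axis, bc_type="not-a-knot")

    def evaluate(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tc = np.clip(t, knots[0], knots[-1])
        val = cs(tc)
        der = cs(tc, 1)
        excess = t - tc
        shape = [1] * val.ndim
        shape[axis if axis >= 0 else val.ndim + axis] = t.size
        return val + excess.reshape(shape) * der

    return evaluate


def fit_beam_response_2d(samples: SampledBeamResponse, geom: PanelGeometry) -> BeamResponse:
    """Full-panel Beam-Response from grid samples.

    Tensor-product cubic spline with not-a-knot end conditions on the
    sample grid, evaluated on the panel grid; outside the sampled
    rectangle the surface continues linearly along each axis with the
    boundary gradient of the spline (x-extension applied first, then y —
    the construction is order independent).
    """
    if samples.x.size < 4 or samples.y.size < 4:
        raise ValueError(
            "not-a-knot spline needs at least 4 sample points along each axis"
        )
    cols = np.arange(geom.n_cols)
    rows = np.arange(geom.n_rows)
    px = (cols - (geom.n_cols - 1) / 2.0) * geom.pitch_iso
    py = (rows - (geom.n_rows - 1) / 2.0) * geom.pitch_iso

    along_x = _spline_with_linear_tails(samples.x, samples.values, axis=1)
    on_cols = along_x(px)  # (n_long, n_cols)
    along_y = _spline_with_linear_tails(samples.y, on_cols, axis=0)
    full = along_y(py)  # (n_rows, n_cols)
    return BeamResponse(values=full, provenance=BrProvenance.spline_fit)


def cmn_psm(wide_raw: RawImage, br_fit: BeamResponse) -> PixelSensitivityMap:
    """PSM = wide-field raw image / fitted Beam-Response, normalized."""
    return decompose(wide_raw, br_fit)


def run(
    images: Dict[Tuple[float, float], RawImage],
    reference: RawImage,
    wide_raw: RawImage,
    plan: OffsetPlan,
    penumbra_sigma: float = 0.4,
):
    """Full pipeline: sensitivities -> Beam-Response samples -> spline fit
    -> PSM.  Returns (psm, beam_response, samples, s_rel)."""
    s_rel = relative_sensitivity_at_points(images, reference, plan, penumbra_sigma)
    samples = beam_response_samples(wide_raw, s_rel, plan)
    br = fit_beam_response_2d(samples, wide_raw.geometry)
    psm = cmn_psm(wide_raw, br)
    return psm, br, samples, s_rel
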