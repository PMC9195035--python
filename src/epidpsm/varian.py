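"""Three-stage PSM method ("Varian").

Stage 1 builds a coarse PSM from three large-field acquisitions shifted
by a fixed number of pixels (lateral and longitudinal), using the same
pixel-ratio propagation as the small-shift method but with a long chain
step.  Stage 2 corrects the low-spatial-frequency error of that estimate
from two images of the same field taken at different source-to-imager
distances: after inverse-square scaling and magnification resampling to
a common beam frame, any remaining smooth disagreement between the two
PSM-corrected images is a smooth PSM error, modelled as the exponential
of a low-order 2D polynomial.  Stage 3 tunes the result regionally with
four images of one small field placed over the four panel quadrants:
each image's smooth log-ratio to the four-image geometric mean is fitted
by a polynomial and fed back with cosine-feathered blending.

The method assumes the beam output is identical between deliveries;
output fluctuation propagates into the result as a systematic error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import (
    PanelGeometry,
    PixelSensitivityMap,
    RawImage,
    normalize_psm,
    offaxis_to_pixel,
    pixel_coords,
)
from .propagation import (
    PropagationResult,
    ShiftConstraint,
    recursive_sensitivity_propagation,
)
from .washu import AbdfAverage, field_footprint_mask

logger = logging.getLogger(__name__)

__all__ = [
    "VarianConfig",
    "varian_stage1",
    "varian_stage2",
    "varian_stage3",
    "varian_psm",
]


@dataclass(frozen=True)
class VarianConfig:
    stage1_shift_px: int = 50
    stage1_seed_size: int = 60
    stage1_field: Tuple[float, float] = (40.0, 40.0)
    stage2_sids: Tuple[float, float] = (115.0, 175.0)
    stage2_poly_degree: int = 4
    stage3_quadrant_centers: Tuple[Tuple[float, float], ...] = (
        (6.0, 6.0),
        (-6.0, 6.0),
        (-6.0, -6.0),
        (6.0, -6.0),
    )
    stage3_field: Tuple[float, float] = (24.0, 24.0)
    stage3_poly_degree: int = 3
    penumbra_margin_cm: float = 1.4
    feather_cm: float = 2.0

    def __post_init__(self) -> None:
        if self.stage2_sids[0] == self.stage2_sids[1]:
            raise ValueError("stage-2 SIDs must differ")


def _poly_design(tx: np.ndarray, ty: np.ndarray, degree: int) -> np.ndarray:
    """Bivariate monomials up to total ``degree``; column 0 is the constant."""
    cols = []
    for total in range(degree + 1):
        for ix in range(total + 1):
            cols.append((tx**ix) * (ty ** (total - ix)))
    return np.stack(cols, axis=-1)


# ---------------------------------------------------------------------------
# stage 1


def varian_stage1(
    nets: Sequence[Tuple[np.ndarray | AbdfAverage, Tuple[float, float]]],
    geom: PanelGeometry,
    cfg: VarianConfig = VarianConfig(),
) -> PropagationResult:
    """Coarse PSM from the 50-pixel-shifted large-field acquisitions.

    A chain step of k pixels splits the panel into k x k interleaved
    residue classes, so the seed region must be larger than the step for
    every class to be anchored.
    """
    step = cfg.stage1_shift_px
    if cfg.stage1_seed_size < step:
        raise ValueError(
            f"seed region ({cfg.stage1_seed_size} px) smaller than the chain "
            f"step ({step} px): some residue classes would be unconstrained"
        )
    pitch = geom.pitch_iso
    ref = None
    constraints: List[ShiftConstraint] = []
    for net, shift in nets:
        arr = net.net if isinstance(net, AbdfAverage) else np.asarray(net, dtype=float)
        dc = int(round(shift[0] / pitch))
        dr = int(round(shift[1] / pitch))
        if abs(shift[0] / pitch - dc) > 1e-6 or abs(shift[1] / pitch - dr) > 1e-6:
            raise ValueError(f"shift {shift} is not a whole number of pixels")
        fp = field_footprint_mask(geom, shift, *cfg.stage1_field, cfg.penumbra_margin_cm)
        if (dr, dc) == (0, 0):
            ref, ref_fp = arr, fp
        else:
            if {abs(dr), abs(dc)} != {0, step}:
                raise ValueError(
                    f"stage-1 shifts must be exactly {step} px along one axis, "
                    f"got ({dr}, {dc})"
                )
            constraints.append(ShiftConstraint(net=arr, shift_px=(dr, dc), footprint=fp))
    if ref is None or not constraints:
        raise ValueError("stage 1 needs a centered reference and shifted acquisitions")

    seed = np.zeros(geom.shape, dtype=bool)
    r0 = (geom.n_rows - cfg.stage1_seed_size) // 2
    c0 = (geom.n_cols - cfg.stage1_seed_size) // 2
    seed[r0 : r0 + cfg.stage1_seed_size, c0 : c0 + cfg.stage1_seed_size] = True
    return recursive_sensitivity_propagation(
        reference=ref, reference_footprint=ref_fp, constraints=constraints,
        seed_region=seed,
    )


# ---------------------------------------------------------------------------
# stage 2


def _fill_invalid_rows(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid pixels by linear interpolation along their row.

    PSM-corrected images are smooth, so bridging dead columns this way
    keeps the resampling splines free of artificial edges; the bridged
    pixels are excluded from fits through the validity mask anyway.
    """
    if valid.all():
        return values
    out = values.copy()
    cols = np.arange(values.shape[1])
    for r in np.flatnonzero(~valid.all(axis=1)):
        good = valid[r]
        if good.sum() >= 2:
            out[r, ~good] = np.interp(cols[~good], cols[good], values[r, good])
    return out


def _sample_in_beam_frame(
    corrected: np.ndarray, geom: PanelGeometry, bx: np.ndarray, by: np.ndarray,
    order: int = 1,
) -> np.ndarray:
    """Bilinear sample of a panel-grid image at beam-frame (bx, by) cm."""
    scale = geom.sid / geom.sid_ref
    row, col = offaxis_to_pixel(geom, bx * scale, by * scale)
    return map_coordinates(corrected, np.array([row, col]), order=order, mode="nearest")


def varian_stage2(
    psm_init: PixelSensitivityMap,
    img_a: RawImage,
    img_b: RawImage,
    cfg: VarianConfig = VarianConfig(),
) -> Tuple[PixelSensitivityMap, Dict[str, float]]:
    """Low-frequency correction from two images at different SIDs.

    Both PSM-corrected images, once scaled by (SID/SID_ref)^2 and
    resampled to the common beam frame, record the same Beam-Response;
    their log-difference therefore only contains the smooth PSM error
    evaluated at two different panel magnifications.  That error is
    modelled as exp(P) with P a 2D polynomial (zero constant term — a
    global scale is unobservable and irrelevant) and fitted by linear
    least squares; a free intercept absorbs the output ratio of the two
    deliveries.
    """
    if img_a.geometry.sid == img_b.geometry.sid:
        raise ValueError("stage-2 images must be at different SIDs (no leverage)")
    for img in (img_a, img_b):
        if img.geometry.shift_x or img.geometry.shift_y:
            raise ValueError("stage-2 images must be acquired with the panel centered")

    geom_a, geom_b = img_a.geometry, img_b.geometry
    sr = geom_a.sid_ref
    good = psm_init.valid_mask & (psm_init.values > 0)
    psm_vals = np.where(good, psm_init.values, np.nan)

    def corrected(img: RawImage) -> np.ndarray:
        c = np.nan_to_num(img.pixels / psm_vals * (img.geometry.sid / sr) ** 2, nan=0.0)
        return _fill_invalid_rows(c, good)

    ca, cb = corrected(img_a), corrected(img_b)

    def usable_half(img: RawImage, axis: str) -> float:
        g = img.geometry
        panel = (g.active_width_x if axis == "x" else g.active_width_y) / 2.0
        fld = (img.field_x if axis == "x" else img.field_y) / 2.0
        return min((panel - 2 * g.pitch_iso) * sr / g.sid, fld - cfg.penumbra_margin_cm)

    xmax = min(usable_half(img_a, "x"), usable_half(img_b, "x"))
    ymax = min(usable_half(img_a, "y"), usable_half(img_b, "y"))
    areas = [
        4 * usable_half(i, "x") * usable_half(i, "y") for i in (img_a, img_b)
    ]
    if 4 * xmax * ymax < 0.25 * max(areas):
        raise ValueError("stage-2 beam-frame footprints overlap by less than 25%")

    # common grid = image-A pixel centers inside the mutual footprint, so
    # only image B needs (bilinear) resampling
    pax, pay = pixel_coords(geom_a.with_shift(0.0, 0.0))
    gx = pax[np.abs(pax * sr / geom_a.sid) <= xmax] * sr / geom_a.sid
    gy = pay[np.abs(pay * sr / geom_a.sid) <= ymax] * sr / geom_a.sid
    bx, by = np.meshgrid(gx, gy)
    sa = _sample_in_beam_frame(ca, geom_a, bx, by)
    sb = _sample_in_beam_frame(cb, geom_b, bx, by)
    # exclude samples whose support touches invalid (bridged) PSM pixels
    vmask = good.astype(float)
    va = _sample_in_beam_frame(vmask, geom_a, bx, by, order=1)
    vb = _sample_in_beam_frame(vmask, geom_b, bx, by, order=1)
    ok = (sa > 0) & (sb > 0) & (va > 0.999) & (vb > 0.999)
    y = np.log(sa[ok]) - np.log(sb[ok])

    # basis in panel-local coordinates (cm / half panel width), evaluated
    # at each image's own magnification of the common beam coordinates
    half_panel = geom_a.active_width_x / 2.0
    ta = (bx[ok] * geom_a.sid / sr / half_panel, by[ok] * geom_a.sid / sr / half_panel)
    tb = (bx[ok] * geom_b.sid / sr / half_panel, by[ok] * geom_b.sid / sr / half_panel)
    phi_a = _poly_design(*ta, cfg.stage2_poly_degree)
    phi_b = _poly_design(*tb, cfg.stage2_poly_degree)
    dphi = phi_a - phi_b  # constant column cancels to 0
    design = np.concatenate([np.ones((y.size, 1)), dphi[:, 1:]], axis=1)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)

    rms_before = float(np.sqrt(np.mean((y - y.mean()) ** 2)))
    resid = y - design @ beta
    rms_after = float(np.sqrt(np.mean(resid**2)))

    px, py = pixel_coords(geom_a.with_shift(0.0, 0.0))
    txx, tyy = np.meshgrid(px / half_panel, py / half_panel)
    phi_panel = _poly_design(txx, tyy, cfg.stage2_poly_degree)
    log_e = phi_panel[..., 1:] @ beta[1:]
    psm = PixelSensitivityMap(
        values=psm_init.values * np.exp(log_e),
        valid_mask=psm_init.valid_mask.copy(),
    )
    diag = {
        "rms_log_diff_before": rms_before,
        "rms_log_diff_after": rms_after,
        "n_samples": int(y.size),
    }
    logger.debug("stage2: rms %.3e -> %.3e", rms_before, rms_after)
    return normalize_psm(psm), diag


# ---------------------------------------------------------------------------
# stage 3


def _cosine_ramp(dist: np.ndarray, feather: float) -> np.ndarray:
    """0 outside, 1 deep inside, half-cosine over ``feather`` at the edge.
    ``dist`` is the distance inside the footprint edge (negative = outside)."""
    t = np.clip(dist / feather, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * t))


def varian_stage3(
    psm_mid: PixelSensitivityMap,
    quadrant_images: Sequence[RawImage],
    cfg: VarianConfig = VarianConfig(),
) -> Tuple[PixelSensitivityMap, Dict[str, float]]:
    """Regional tuning from four small-field images over the quadrants.

    Each PSM-corrected image, expressed in the beam frame, is compared to
    the geometric mean of all four; the smooth log-ratio is fitted per
    image by a 2D polynomial and applied back on the panel with
    cosine-feathered blending between the quadrant footprints.  Keeping
    the fitted intercepts assumes constant beam output across the four
    deliveries (the method's stated assumption).
    """
    if len(quadrant_images) != 4:
        raise ValueError("stage 3 needs exactly four quadrant images")
    geom0 = quadrant_images[0].geometry
    sr = geom0.sid_ref
    fx, fy = cfg.stage3_field
    quadrants = []
    for img in quadrant_images:
        if (img.field_x, img.field_y) != (fx, fy):
            raise ValueError("stage-3 images must share the same field")
        quadrants.append((-img.geometry.shift_x, -img.geometry.shift_y))
    signs = {(np.sign(q[0]), np.sign(q[1])) for q in quadrants}
    if len(signs) != 4 or any(0 in s for s in signs):
        raise ValueError("quadrant images must cover four distinct quadrants")

    goodm = psm_mid.valid_mask & (psm_mid.values > 0)
    psm_vals = np.where(goodm, psm_mid.values, np.nan)
    hx = fx / 2.0 - cfg.penumbra_margin_cm
    hy = fy / 2.0 - cfg.penumbra_margin_cm
    h = geom0.pitch_iso
    gx = np.arange(-hx, hx + h / 2, h)
    gy = np.arange(-hy, hy + h / 2, h)
    bx, by = np.meshgrid(gx, gy)

    vmask = goodm.astype(float)
    sampled = []
    ok = np.ones(bx.shape, dtype=bool)
    for img in quadrant_images:
        c = np.nan_to_num(img.pixels / psm_vals * (img.geometry.sid / sr) ** 2, nan=0.0)
        c = _fill_invalid_rows(c, goodm)
        s = _sample_in_beam_frame(c, img.geometry, bx, by)
        v = _sample_in_beam_frame(vmask, img.geometry, bx, by, order=1)
        ok &= (s > 0) & (v > 0.999)
        sampled.append(s)
    if ok.mean() < 0.5:
        raise ValueError("stage-3 quadrant footprints barely overlap in the beam frame")
    logs = np.array([np.log(np.where(ok, s, 1.0)) for s in sampled])
    mean_log = logs.mean(axis=0)
    rms_before = float(np.sqrt(np.mean(((logs - mean_log)[:, ok]) ** 2)))

    tx, ty = bx / (fx / 2.0), by / (fy / 2.0)
    phi_ok = _poly_design(tx[ok], ty[ok], cfg.stage3_poly_degree)
    betas = []
    sq_after = 0.0
    for k in range(4):
        rho = (logs[k] - mean_log)[ok]
        beta, *_ = np.linalg.lstsq(phi_ok, rho, rcond=None)
        betas.append(beta)
        sq_after += float(np.mean((rho - phi_ok @ beta) ** 2))
    rms_after = float(np.sqrt(sq_after / 4.0))

    # apply on the panel: for pixel p, image k saw it at beam coord p + s_k
    px, py = pixel_coords(geom0.with_shift(0.0, 0.0))
    pxx, pyy = np.meshgrid(px, py)
    num = np.zeros(geom0.shape)
    den = np.zeros(geom0.shape)
    for k, img in enumerate(quadrant_images):
        sx, sy = img.geometry.shift_x, img.geometry.shift_y
        bxx, byy = pxx + sx, pyy + sy
        inside_x = hx - np.abs(bxx)
        inside_y = hy - np.abs(byy)
        w = _cosine_ramp(inside_x, cfg.feather_cm) * _cosine_ramp(inside_y, cfg.feather_cm)
        phi_p = _poly_design(bxx / (fx / 2.0), byy / (fy / 2.0), cfg.stage3_poly_degree)
        num += w * (phi_p @ betas[k])
        den += w
    log_corr = np.where(den > 1e-9, num / np.maximum(den, 1e-9), 0.0)
    psm = PixelSensitivityMap(
        values=psm_mid.values * np.exp(log_corr),
        valid_mask=psm_mid.valid_mask.copy(),
    )
    diag = {
        "rms_log_diff_before": rms_before,
        "rms_log_diff_after": rms_after,
        "corrected_area_fraction": float(np.mean(den > 1e-9)),
    }
    logger.debug("stage3: rms %.3e -> %.3e", rms_before, rms_after)
    return normalize_psm(psm), diag


# ---------------------------------------------------------------------------
# pipeline


def varian_psm(
    stage1_nets,
    geom: PanelGeometry,
    stage2_images: Tuple[RawImage, RawImage],
    stage3_images: Sequence[RawImage],
    cfg: VarianConfig = VarianConfig(),
):
    """Stage 1 -> 2 -> 3 -> normalization; per-stage results retained.

    Returns (psm, report) where report holds the intermediate PSMs and
    the stage diagnostics.
    """
    res1 = varian_stage1(stage1_nets, geom, cfg)
    psm2, diag2 = varian_stage2(res1.psm, *stage2_images, cfg)
    psm3, diag3 = varian_stage3(psm2, stage3_images, cfg)
    psm = normalize_psm(psm3)
    report = {
        "stage1": res1,
        "stage2_psm": psm2,
        "stage2_diag": diag2,
        "stage3_diag": diag3,
    }
    return psm, report
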