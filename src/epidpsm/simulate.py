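"""Synthetic EPID panel / beam simulator.

Generates ground-truth pixel-sensitivity maps, a parametric flattened-beam
fluence model, and raw-image acquisitions (panel shifts, SID changes,
alternating beam/dark frame sequences, noise) with the statistical
structure the PSM-determination methods assume:

* the panel's static sensitivity (smooth gain field, per-pixel gain
  spread, dead columns, blob defects) is frozen per seed — it is a
  property of the panel, not of an acquisition;
* each irradiation carries its own global output factor (linac output
  fluctuation), while readout noise is redrawn per frame;
* the recorded signal is ``mu * output * PSM * fluence(x, y) *
  (SID_ref/SID)^2`` with beam-frame coordinates that include the panel
  shift and the SID magnification.

The fluence model is a radially symmetric flattened profile (polynomial
dome plus a Gaussian horn ring, sigmoid field-edge penumbra, a sigmoid
corner shadow emulating the primary collimator) with optional small
linear asymmetry terms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .geometry import (
    BeamResponse,
    BrProvenance,
    ImageKind,
    PanelGeometry,
    PixelSensitivityMap,
    RawImage,
    normalize_psm,
    pixel_coords,
)

__all__ = [
    "BeamModel",
    "PanelDefectModel",
    "AcquisitionNoise",
    "COUNTS_PER_MU",
    "generate_ground_truth_psm",
    "beam_fluence",
    "beam_response_grid",
    "render_raw_image",
    "simulate_abdf_sequence",
    "subseed",
]

#: raw counts per monitor unit at the central axis (nominal SID, unit PSM)
COUNTS_PER_MU = 500.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def subseed(root_seed: int, index: int) -> int:
    """Counter-based per-acquisition seed derivation.

    Deterministic in ``(root_seed, index)`` so appending an acquisition to
    a scenario never perturbs the seeds of earlier ones.  The result is
    kept below 2**31.
    """
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass(frozen=True)
class BeamModel:
    """Parametric relative-fluence model of the beam at the imager.

    ``radial_coeffs`` are polynomial coefficients of relative fluence vs
    radius r (cm at isocenter), lowest order first; the constant term
    should be 1.  The horn term is a Gaussian ring of relative amplitude
    ``horn_amplitude`` centered at ``horn_radius`` with width
    ``horn_width`` — flattened photon beams recorded by an EPID show
    exaggerated off-axis horns near the field edge.  ``asym_x`` /
    ``asym_y`` are fractional linear tilts per 10 cm.  The field edge is
    a sigmoid with penumbra ``penumbra_sigma`` and the corner shadow is a
    radially symmetric sigmoid dip starting at ``shadow_onset``.
    """

    radial_coeffs: Tuple[float, ...] = (1.0, 0.0, 2.0e-4)
    horn_amplitude: float = 0.05
    horn_radius: float = 16.0
    horn_width: float = 3.0
    asym_x: float = 0.0
    asym_y: float = 0.0
    penumbra_sigma: float = 0.4
    shadow_onset: float = 26.0
    shadow_falloff: float = 1.5
    shadow_depth: float = 0.2

    def symmetric(self) -> "BeamModel":
        """The same beam with the asymmetry terms removed."""
        return replace(self, asym_x=0.0, asym_y=0.0)


@dataclass(frozen=True)
class PanelDefectModel:
    """Static panel non-uniformity: what the ground-truth PSM is made of."""

    smooth_gain_amplitude: float = 0.02
    smooth_gain_corr_cm: float = 10.0
    pixel_noise_sd: float = 0.02
    dead_columns: Tuple[int, ...] = ()
    #: blobs as (center_x_cm, center_y_cm, radius_cm, gain)
    blob_defects: Tuple[Tuple[float, float, float, float], ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class AcquisitionNoise:
    """Per-acquisition noise model.

    ``output_fluctuation_sd`` is the fractional sd of the per-irradiation
    global output factor; ``readout_noise_sd`` is the per-pixel per-frame
    additive noise expressed as a fraction of the frame's nominal
    central-axis signal; ``dark_offset`` is a constant background in
    counts; ``lag_fraction`` of each frame is carried into the next one
    (image lag / ghosting).
    """

    output_fluctuation_sd: float = 0.0005
    readout_noise_sd: float = 0.001
    dark_offset: float = 20.0
    lag_fraction: float = 0.02

    def __post_init__(self) -> None:
        for name in ("output_fluctuation_sd", "readout_noise_sd", "dark_offset", "lag_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


NO_NOISE = AcquisitionNoise(0.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# ground truth panel


def generate_ground_truth_psm(
    defects: PanelDefectModel, geom: PanelGeometry
) -> PixelSensitivityMap:
    """Ground-truth PSM: smooth gain x (1 + static pixel spread) + defects.

    Deterministic for a fixed ``defects.seed``; the result is normalized
    to the central 10x10 mean.  Dead columns are exactly zero and carry
    ``valid_mask`` False.
    """
    rng = np.random.default_rng(defects.seed)
    shape = geom.shape
    values = np.ones(shape)

    if defects.smooth_gain_amplitude > 0:
        sigma_px = defects.smooth_gain_corr_cm / geom.pitch_iso
        white = rng.standard_normal(shape)
        low = gaussian_filter(white, sigma=sigma_px, mode="reflect")
        low -= low.mean()
        sd = low.std()
        if sd > 0:
            low *= defects.smooth_gain_amplitude / sd
        values *= 1.0 + low
    else:
        # keep the stream position stable so pixel noise is comparable
        rng.standard_normal(shape)

    if defects.pixel_noise_sd > 0:
        values *= 1.0 + defects.pixel_noise_sd * rng.standard_normal(shape)

    x, y = pixel_coords(geom.with_shift(0.0, 0.0))
    xx, yy = np.meshgrid(x, y)
    for cx, cy, radius, gain in defects.blob_defects:
        # compactly supported smooth bump: a defect has finite extent
        t2 = ((xx - cx) ** 2 + (yy - cy) ** 2) / radius**2
        profile = np.where(t2 < 1.0, (1.0 - np.minimum(t2, 1.0)) ** 2, 0.0)
        values *= 1.0 + (gain - 1.0) * profile

    np.clip(values, 1e-6, None, out=values)
    mask = np.ones(shape, dtype=bool)
    for col in defects.dead_columns:
        values[:, col] = 0.0
        mask[:, col] = False

    return normalize_psm(PixelSensitivityMap(values=values, valid_mask=mask))


# ---------------------------------------------------------------------------
# beam fluence


def beam_fluence(model: BeamModel, x, y, field_x: float, field_y: float):
    """Relative fluence at beam-frame position (x, y) cm, isocenter plane.

    Normalized so the value at the origin is exactly 1 when the asymmetry
    terms are zero; symmetric models satisfy f(x, y) = f(-x, y) exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.hypot(x, y)

    def symmetric_part(radius):
        f = np.polynomial.polynomial.polyval(radius, model.radial_coeffs)
        if model.horn_amplitude != 0.0:
            f = f * (
                1.0
                + model.horn_amplitude
                * np.exp(-0.5 * ((radius - model.horn_radius) / model.horn_width) ** 2)
            )
        if model.shadow_depth != 0.0:
            f = f * (
                1.0
                - model.shadow_depth
                * expit((radius - model.shadow_onset) / model.shadow_falloff)
            )
        return f

    value = symmetric_part(r) / symmetric_part(np.asarray(0.0))
    if model.penumbra_sigma > 0:
        value = value * expit((field_x / 2.0 - np.abs(x)) / model.penumbra_sigma)
        value = value * expit((field_y / 2.0 - np.abs(y)) / model.penumbra_sigma)
        value = value / (
            expit(field_x / 2.0 / model.penumbra_sigma)
            * expit(field_y / 2.0 / model.penumbra_sigma)
        )
    else:
        value = value * (np.abs(x) <= field_x / 2.0) * (np.abs(y) <= field_y / 2.0)
    value = value * (1.0 + model.asym_x * x / 10.0) * (1.0 + model.asym_y * y / 10.0)
    return value


def beam_response_grid(
    model: BeamModel, geom: PanelGeometry, field_x: float, field_y: float
) -> BeamResponse:
    """Simulator-truth Beam-Response evaluated on the panel grid.

    Beam-frame coordinates include the panel shift and the SID
    magnification (a pixel at larger SID sits on a ray that crossed the
    isocenter plane closer to the axis).
    """
    x, y = pixel_coords(geom)
    scale = geom.sid_ref / geom.sid
    xx, yy = np.meshgrid(x * scale, y * scale)
    values = beam_fluence(model, xx, yy, field_x, field_y)
    return BeamResponse(values=values, provenance=BrProvenance.simulator_truth)


# ---------------------------------------------------------------------------
# acquisition rendering


def _noiseless_signal(
    psm_true: PixelSensitivityMap,
    beam: BeamModel,
    geom: PanelGeometry,
    mu: float,
    field_x: float,
    field_y: float,
) -> np.ndarray:
    br = beam_response_grid(beam, geom, field_x, field_y)
    inv_sq = (geom.sid_ref / geom.sid) ** 2
    return mu * COUNTS_PER_MU * inv_sq * psm_true.values * br.values


def render_raw_image(
    psm_true: PixelSensitivityMap,
    beam: BeamModel,
    geom: PanelGeometry,
    mu: float,
    noise: AcquisitionNoise = NO_NOISE,
    seed=0,
    field_x: float = 40.0,
    field_y: float = 40.0,
) -> RawImage:
    """Render one raw acquisition (single irradiation, single frame).

    Pixels are ``mu * o * PSM * BeamResponse(x, y) * (SID_ref/SID)^2``
    plus additive readout noise, where ``o`` is the per-irradiation
    output factor.  Deterministic per seed.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if psm_true.values.shape != geom.shape:
        raise ValueError("PSM shape does not match geometry")
    rng = _as_rng(seed)
    signal = _noiseless_signal(psm_true, beam, geom, mu, field_x, field_y)
    o = 1.0 + noise.output_fluctuation_sd * rng.standard_normal() if noise.output_fluctuation_sd else 1.0
    pixels = signal * o
    if noise.readout_noise_sd > 0:
        central = mu * COUNTS_PER_MU * (geom.sid_ref / geom.sid) ** 2
        pixels = pixels + noise.readout_noise_sd * central * rng.standard_normal(geom.shape)
    return RawImage(
        pixels=pixels, geometry=geom, mu=mu, field_x=field_x, field_y=field_y,
        kind=ImageKind.beam,
    )


def simulate_abdf_sequence(
    psm_true: PixelSensitivityMap,
    beam: BeamModel,
    geom: PanelGeometry,
    n_pairs: int,
    mu_per_frame: float,
    noise: AcquisitionNoise = NO_NOISE,
    seed=0,
    field_x: float = 37.0,
    field_y: float = 37.0,
) -> List[Tuple[RawImage, RawImage]]:
    """Alternating beam / dark field sequence of ``n_pairs`` frame pairs.

    Each beam frame carries the signal plus ``dark_offset`` plus a
    ``lag_fraction`` of the previous frame; each dark frame carries the
    offset plus the lag of the preceding beam frame.  The sequence starts
    as if a previous irradiation just ended (the lag chain is primed with
    a noiseless signal frame), which is what discarding the first pairs
    protects against.  Deterministic per seed.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = _as_rng(seed)
    signal = _noiseless_signal(psm_true, beam, geom, mu_per_frame, field_x, field_y)
    central = mu_per_frame * COUNTS_PER_MU * (geom.sid_ref / geom.sid) ** 2
    read_sd = noise.readout_noise_sd * central

    pairs: List[Tuple[RawImage, RawImage]] = []
    prev = signal.copy()  # residual of a fictitious previous irradiation
    for _ in range(n_pairs):
        o = 1.0 + noise.output_fluctuation_sd * rng.standard_normal() if noise.output_fluctuation_sd else 1.0
        beam_px = noise.dark_offset + noise.lag_fraction * prev + signal * o
        if read_sd > 0:
            beam_px = beam_px + read_sd * rng.standard_normal(geom.shape)
        prev = beam_px
        dark_px = noise.dark_offset + noise.lag_fraction * prev
        if read_sd > 0:
            dark_px = dark_px + read_sd * rng.standard_normal(geom.shape)
        prev = dark_px
        beam_img = RawImage(
            pixels=beam_px, geometry=geom, mu=mu_per_frame,
            field_x=field_x, field_y=field_y, kind=ImageKind.beam,
        )
        dark_img = RawImage(
            pixels=dark_px, geometry=geom, mu=0.0,
            field_x=field_x, field_y=field_y, kind=ImageKind.dark,
        )
        pairs.append((beam_img, dark_img))
    return pairs
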