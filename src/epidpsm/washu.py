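"""Small-shift overlapping-field PSM method ("WashU").

Large, almost panel-covering fields are delivered repeatedly with small
whole-pixel panel shifts between irradiations; frames are acquired as
alternating beam / dark fields (ABDF) so dark offset and image lag can
be subtracted.  Pixels of different acquisitions that saw the same part
of the beam constrain their sensitivity ratio; propagating those
constraints from a central seed region yields the full PSM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .geometry import PanelGeometry, RawImage
from .propagation import (
    PropagationResult,
    ShiftConstraint,
    recursive_sensitivity_propagation,
)

__all__ = [
    "AbdfAverage",
    "abdf_average",
    "washu_plan",
    "field_footprint_mask",
    "washu_psm",
]

DEFAULT_FIELD = 37.0  # cm; smaller than the panel to spare the electronics
DEFAULT_SHIFT_CM = 0.4  # nominal small-shift magnitude (snapped to pixels)
SEED_SIZE = 20  # central anchor block, pixels


@dataclass
class AbdfAverage:
    """Averaged net signal of an ABDF sequence."""

    net: np.ndarray
    n_used: int
    n_discarded: int


def abdf_average(pairs: Sequence[Tuple[RawImage, RawImage]], n_discard: int = 40) -> AbdfAverage:
    """Discard the first ``n_discard`` pairs (lag settling), then average:
    net = mean(kept beam frames) - mean(kept dark frames)."""
    if len(pairs) <= n_discard:
        raise ValueError(
            f"need more than n_discard={n_discard} pairs, got {len(pairs)}"
        )
    kept = pairs[n_discard:]
    beam = np.mean([p[0].pixels for p in kept], axis=0)
    dark = np.mean([p[1].pixels for p in kept], axis=0)
    return AbdfAverage(net=beam - dark, n_used=len(kept), n_discarded=n_discard)


def washu_plan(
    geom: PanelGeometry, shift_cm: float | None = None
) -> List[Tuple[float, float]]:
    """Acquisition shifts for the overlapping-field deliveries.

    Shifts must be whole pixels — the solver never resamples.  An
    explicit ``shift_cm`` gives the centered reference plus one lateral
    and one longitudinal shift of that size, and raises (suggesting the
    nearest valid value) if it is not an integer multiple of the pitch.

    The default plan snaps the nominal 4 mm shift to the nearest
    whole-pixel value k and delivers two coprime shift sizes per axis
    (k and k+1 pixels).  A single shift size k links only pixels k apart,
    leaving k x k interleaved lattices tied together only through the
    seed anchor, and lets one dead column sever every chain of the
    lattice it sits on; a second, coprime shift size makes the
    constraint graph a single component and lets chains step over dead
    columns.
    """
    pitch = geom.pitch_iso
    if shift_cm is None:
        k = max(1, int(round(DEFAULT_SHIFT_CM / pitch)))
        s2, s3 = k * pitch, (k + 1) * pitch
        return [(0.0, 0.0), (s2, 0.0), (s3, 0.0), (0.0, s2), (0.0, s3)]
    n_px = shift_cm / pitch
    if abs(n_px - round(n_px)) > 1e-6:
        nearest = max(1, int(round(n_px))) * pitch
        raise ValueError(
            f"shift {shift_cm} cm is {n_px:.2f} pixels — not a whole-pixel "
            f"shift (no resampling); nearest valid shift is {nearest:.4f} cm"
        )
    return [(0.0, 0.0), (shift_cm, 0.0), (0.0, shift_cm)]


def field_footprint_mask(
    geom: PanelGeometry,
    shift: Tuple[float, float],
    field_x: float,
    field_y: float,
    penumbra_margin_cm: float = 1.4,
) -> np.ndarray:
    """Pixels safely inside the field for an acquisition at ``shift``.

    The margin keeps the penumbra out of the usable footprint (default
    1.4 cm, about 3 penumbra sigma plus one pixel).
    """
    cols = np.arange(geom.n_cols)
    rows = np.arange(geom.n_rows)
    x = (cols - (geom.n_cols - 1) / 2.0) * geom.pitch_iso + shift[0]
    y = (rows - (geom.n_rows - 1) / 2.0) * geom.pitch_iso + shift[1]
    in_x = np.abs(x) <= field_x / 2.0 - penumbra_margin_cm
    in_y = np.abs(y) <= field_y / 2.0 - penumbra_margin_cm
    return np.outer(in_y, in_x)


def _seed_mask(geom: PanelGeometry, size: int = SEED_SIZE) -> np.ndarray:
    mask = np.zeros(geom.shape, dtype=bool)
    r0 = (geom.n_rows - size) // 2
    c0 = (geom.n_cols - size) // 2
    mask[r0 : r0 + size, c0 : c0 + size] = True
    return mask


def washu_psm(
    nets: Sequence[Tuple[np.ndarray | AbdfAverage, Tuple[float, float]]],
    geom: PanelGeometry,
    field_x: float = DEFAULT_FIELD,
    field_y: float = DEFAULT_FIELD,
    seed_size: int = SEED_SIZE,
    penumbra_margin_cm: float = 1.4,
    compute_chain_length: bool = False,
) -> PropagationResult:
    """Full PSM from averaged net images and their panel shifts.

    ``nets`` holds (net image or AbdfAverage, (shift_x, shift_y) cm); one
    entry must be the centered reference.  Shifts must be whole pixels.
    """
    pitch = geom.pitch_iso
    ref = None
    constraints: List[ShiftConstraint] = []
    for net, shift in nets:
        arr = net.net if isinstance(net, AbdfAverage) else np.asarray(net, dtype=float)
        dc_f, dr_f = shift[0] / pitch, shift[1] / pitch
        if abs(dc_f - round(dc_f)) > 1e-6 or abs(dr_f - round(dr_f)) > 1e-6:
            raise ValueError(f"shift {shift} is not a whole number of pixels")
        dr, dc = int(round(dr_f)), int(round(dc_f))
        fp = field_footprint_mask(geom, shift, field_x, field_y, penumbra_margin_cm)
        if (dr, dc) == (0, 0):
            if ref is not None:
                raise ValueError("more than one centered reference acquisition")
            ref, ref_fp = arr, fp
        else:
            constraints.append(ShiftConstraint(net=arr, shift_px=(dr, dc), footprint=fp))
    if ref is None:
        raise ValueError("no centered reference acquisition in the set")
    if not constraints:
        raise ValueError("no shifted acquisitions in the set")
    return recursive_sensitivity_propagation(
        reference=ref,
        reference_footprint=ref_fp,
        constraints=constraints,
        seed_region=_seed_mask(geom, seed_size),
        compute_chain_length=compute_chain_length,
    )
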