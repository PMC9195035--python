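"""Shifted-field pixel-ratio propagation.

When the panel is shifted by a whole number of pixels between two
irradiations of the same beam, pixel (r, c) of the shifted image and
pixel (r+dr, c+dc) of the reference image record the same beam-frame
location, so their ratio isolates the sensitivity ratio

    s(r, c) / s(r+dr, c+dc) = shifted(r, c) / reference(r+dr, c+dc).

Chaining such ratios outward from a seed region determines the
sensitivity of every reachable pixel.  This module solves the full
constraint set at once: in the log domain every ratio is a linear
equation ``u_i - u_j = d_ij`` and the least-squares solution is the
symmetric merge of every chain that connects a pixel to the seed (the
generalization of taking the geometric mean over individual chains).
With noiseless, consistent ratios the solution is exact.

A shift of k pixels only ever links pixels k apart, so the panel
decouples into k x k interleaved residue classes with no constraints
between them.  Each connected component is therefore anchored on its own
intersection with the seed region (geometric mean over the seed -> 1);
components that never touch the seed are masked as unreachable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .geometry import PixelSensitivityMap, normalize_psm

logger = logging.getLogger(__name__)

__all__ = ["ShiftConstraint", "PropagationResult", "recursive_sensitivity_propagation"]


@dataclass
class ShiftConstraint:
    """One shifted acquisition paired against the reference.

    ``net`` is the dark-subtracted image, ``shift_px = (dr, dc)`` the
    whole-pixel panel shift, and ``footprint`` a boolean mask of pixels
    inside this acquisition's usable field footprint.
    """

    net: np.ndarray
    shift_px: Tuple[int, int]
    footprint: np.ndarray


@dataclass
class PropagationResult:
    psm: PixelSensitivityMap
    n_unreachable: int
    chain_length: np.ndarray | None = None


def _constraints_for_shift(
    ref: np.ndarray,
    ref_fp: np.ndarray,
    con: ShiftConstraint,
    floor: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flat index pairs (i, j) and log-ratio data for one shifted image."""
    n_rows, n_cols = ref.shape
    dr, dc = con.shift_px
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    r2, c2 = rr + dr, cc + dc
    inside = (r2 >= 0) & (r2 < n_rows) & (c2 >= 0) & (c2 < n_cols)
    r2c = np.clip(r2, 0, n_rows - 1)
    c2c = np.clip(c2, 0, n_cols - 1)
    valid = (
        inside
        & con.footprint
        & ref_fp[r2c, c2c]
        & (con.net > floor)
        & (ref[r2c, c2c] > floor)
    )
    i = (rr * n_cols + cc)[valid]
    j = (r2c * n_cols + c2c)[valid]
    d = np.log(con.net[valid]) - np.log(ref[r2c, c2c][valid])
    return i, j, d


def recursive_sensitivity_propagation(
    reference: np.ndarray,
    reference_footprint: np.ndarray,
    constraints: Sequence[ShiftConstraint],
    seed_region: np.ndarray,
    signal_floor: float | None = None,
    compute_chain_length: bool = False,
    normalize: bool = True,
) -> PropagationResult:
    """Solve the shifted-field ratio constraints for the full PSM.

    Parameters
    ----------
    reference:
        Dark-subtracted net image of the unshifted acquisition.
    reference_footprint:
        Boolean usable-footprint mask for the reference image.
    constraints:
        Shifted acquisitions with whole-pixel shifts.
    seed_region:
        Boolean mask of the anchor region; every connected component of
        the constraint graph that intersects it is anchored there
        (geometric mean over its seed pixels = 1), all other components
        are masked as unreachable.
    signal_floor:
        Pixels at or below this net signal contribute no constraints
        (default: 5% of the reference central 2x2 mean); this is what
        breaks chains across dead pixels.
    compute_chain_length:
        Also return the per-pixel unweighted graph distance to the seed
        (diagnostic: error accumulates with chain length).
    """
    reference = np.asarray(reference, dtype=float)
    shape = reference.shape
    n_rows, n_cols = shape
    n = reference.size
    seed_region = np.asarray(seed_region, dtype=bool)
    if seed_region.shape != shape:
        raise ValueError("seed_region shape mismatch")
    if signal_floor is None:
        r0, c0 = n_rows // 2 - 1, n_cols // 2 - 1
        signal_floor = 0.05 * float(reference[r0 : r0 + 2, c0 : c0 + 2].mean())

    ii: List[np.ndarray] = []
    jj: List[np.ndarray] = []
    dd: List[np.ndarray] = []
    for con in constraints:
        if con.net.shape != shape:
            raise ValueError("constraint image shape mismatch")
        dr, dc = con.shift_px
        if (dr, dc) == (0, 0):
            continue
        i, j, d = _constraints_for_shift(reference, reference_footprint, con, signal_floor)
        ii.append(i)
        jj.append(j)
        dd.append(d)
    if not ii:
        raise ValueError("no usable shifted acquisitions")
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    d = np.concatenate(dd)
    m = i.size
    if m == 0:
        raise ValueError("no valid ratio constraints (footprints do not overlap?)")

    adj = sp.coo_matrix((np.ones(m), (i, j)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)

    seed_flat = seed_region.ravel()
    # components anchored by the seed; isolated pixels form their own
    # (unconstrained) components and are dropped unless seeded and linked
    degree = np.zeros(n, dtype=np.int64)
    np.add.at(degree, i, 1)
    np.add.at(degree, j, 1)
    constrained = degree > 0
    anchored_comps = np.unique(labels[seed_flat & constrained])
    keep = np.isin(labels, anchored_comps) & constrained
    n_unreachable = int(n - keep.sum())
    if n_unreachable:
        warnings.warn(
            f"{n_unreachable} pixels unreachable from the seed region; masked",
            stacklevel=2,
        )

    # reduced least-squares system over kept pixels
    new_index = -np.ones(n, dtype=np.int64)
    kept_idx = np.flatnonzero(keep)
    new_index[kept_idx] = np.arange(kept_idx.size)
    row_ok = keep[i] & keep[j]
    ir, jr, dr_ = new_index[i[row_ok]], new_index[j[row_ok]], d[row_ok]
    mr = ir.size
    rows = np.repeat(np.arange(mr), 2)
    cols = np.empty(2 * mr, dtype=np.int64)
    cols[0::2], cols[1::2] = ir, jr
    data = np.empty(2 * mr)
    data[0::2], data[1::2] = 1.0, -1.0
    D = sp.csr_matrix((data, (rows, cols)), shape=(mr, kept_idx.size))

    # pin one pixel per kept component to remove the per-component gauge
    comp_of_kept = labels[kept_idx]
    _, pin_pos = np.unique(comp_of_kept, return_index=True)
    P = sp.csr_matrix(
        (np.ones(pin_pos.size), (np.arange(pin_pos.size), pin_pos)),
        shape=(pin_pos.size, kept_idx.size),
    )
    A = (D.T @ D + P.T @ P).tocsc()
    b = D.T @ dr_
    u = spsolve(A, b)

    # re-anchor each component on its seed pixels (geometric mean -> 1)
    seed_kept = seed_flat[kept_idx]
    comp_sum = np.bincount(comp_of_kept[seed_kept], weights=u[seed_kept], minlength=n_comp)
    comp_cnt = np.bincount(comp_of_kept[seed_kept], minlength=n_comp)
    with np.errstate(invalid="ignore"):
        comp_mean = np.where(comp_cnt > 0, comp_sum / np.maximum(comp_cnt, 1), 0.0)
    u = u - comp_mean[comp_of_kept]

    values = np.zeros(n)
    values[kept_idx] = np.exp(u)
    psm = PixelSensitivityMap(values=values.reshape(shape), valid_mask=keep.reshape(shape))
    if normalize:
        psm = normalize_psm(psm)

    chain = None
    if compute_chain_length:
        from scipy.sparse.csgraph import dijkstra

        seeds = np.flatnonzero(seed_flat & keep)
        sym = adj + adj.T
        dist = dijkstra(sym, directed=False, unweighted=True, indices=seeds, min_only=True)
        chain = dist.reshape(shape)
        chain[~keep.reshape(shape)] = np.nan
    logger.debug("propagation: %d constraints, %d components, %d unreachable",
                 mr, n_comp, n_unreachable)
    return PropagationResult(psm=psm, n_unreachable=n_unreachable, chain_length=chain)
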