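"""Comparison surface: percentage-deviation maps, histograms, summary
statistics, short-term repeatability, and recovery reports against a
known ground truth.

Medians are reported alongside means throughout: deviation maps of PSM
methods have heavy tails at panel edges and corners, where the median is
the more faithful agreement metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

from .geometry import DeviationStats, PanelGeometry, PixelSensitivityMap, pixel_coords

__all__ = [
    "percent_deviation_map",
    "deviation_stats",
    "RepeatabilityMap",
    "repeatability_map",
    "recovery_report",
    "predicted_repeatability_p95",
    "DEFAULT_BANDS",
]

DEFAULT_BANDS: Tuple[Tuple[float, float], ...] = ((0.0, 10.0), (10.0, 15.0), (15.0, 20.0))


def percent_deviation_map(
    a: PixelSensitivityMap, b: PixelSensitivityMap
) -> Tuple[np.ndarray, np.ndarray]:
    """Pixel-by-pixel percentage deviation 100 * (a - b) / b.

    Returns (map, valid) where pixels are valid only if both inputs are
    valid and the reference is non-zero; invalid pixels hold NaN.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("shapes differ")
    valid = a.valid_mask & b.valid_mask & (b.values != 0)
    dev = np.full(a.values.shape, np.nan)
    np.divide(a.values - b.values, b.values, out=dev, where=valid)
    dev[valid] *= 100.0
    return dev, valid


def deviation_stats(
    dev_map: np.ndarray,
    valid: np.ndarray | None = None,
    bin_width: float = 0.05,
) -> DeviationStats:
    """Mean / median / SD / 95th percentile of |dev| plus a histogram.

    Histogram bin edges are aligned to multiples of ``bin_width`` and the
    counts conserve the number of valid pixels.
    """
    dev_map = np.asarray(dev_map, dtype=float)
    if valid is None:
        valid = np.isfinite(dev_map)
    vals = dev_map[valid & np.isfinite(dev_map)]
    if vals.size == 0:
        raise ValueError("deviation map has no valid pixels")
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    return DeviationStats(
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        p95_abs=float(np.percentile(np.abs(vals), 95)),
        bin_edges=edges,
        counts=counts,
        n_pixels=int(vals.size),
    )


@dataclass
class RepeatabilityMap:
    """Per-pixel 100 * SD / mean over repeated PSM determinations."""

    values: np.ndarray
    valid: np.ndarray
    n_repeats: int
    p95: float
    median: float


def repeatability_map(psm_list: Sequence[PixelSensitivityMap]) -> RepeatabilityMap:
    """Short-term repeatability: sample SD (n-1 divisor) over the repeats
    divided by their mean, in percent, per pixel."""
    if len(psm_list) < 2:
        raise ValueError("repeatability needs at least 2 repeats")
    stack = np.array([p.values for p in psm_list])
    valid = np.all([p.valid_mask for p in psm_list], axis=0)
    mean = stack.mean(axis=0)
    valid &= mean > 0
    sd = stack.std(axis=0, ddof=1)
    values = np.full(mean.shape, np.nan)
    np.divide(sd, mean, out=values, where=valid)
    values[valid] *= 100.0
    vals = values[valid]
    return RepeatabilityMap(
        values=values,
        valid=valid,
        n_repeats=len(psm_list),
        p95=float(np.percentile(vals, 95)),
        median=float(np.median(vals)),
    )


def _radius_map(geom: PanelGeometry) -> np.ndarray:
    x, y = pixel_coords(geom.with_shift(0.0, 0.0))
    xx, yy = np.meshgrid(x, y)
    return np.hypot(xx, yy)


def recovery_report(
    psm_est: PixelSensitivityMap,
    psm_true: PixelSensitivityMap,
    geom: PanelGeometry,
    bands: Sequence[Tuple[float, float]] = DEFAULT_BANDS,
    bin_width: float = 0.05,
) -> Dict:
    """Deviation of an estimated PSM from the ground truth, overall and in
    concentric radial bands (center vs edge behaviour)."""
    dev, valid = percent_deviation_map(psm_est, psm_true)
    overall = deviation_stats(dev, valid, bin_width)
    r = _radius_map(geom)
    band_stats = {}
    for r0, r1 in bands:
        sel = valid & (r >= r0) & (r < r1)
        key = f"{r0:g}-{r1:g}cm"
        if sel.sum() == 0:
            band_stats[key] = None
            continue
        vals = dev[sel]
        band_stats[key] = {
            "median": float(np.median(vals)),
            "median_abs": float(np.median(np.abs(vals))),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "n_pixels": int(vals.size),
        }
    return {
        "stats": overall,
        "median_abs": float(np.median(np.abs(dev[valid]))),
        "bands": band_stats,
        "n_invalid": int((~valid).sum()),
        "deviation_map": dev,
        "valid": valid,
    }


def predicted_repeatability_p95(
    noise_sd_map: np.ndarray,
    mean_map: np.ndarray,
    n_repeats: int,
    valid: np.ndarray | None = None,
) -> float:
    """Noise-propagation prediction of the repeatability 95th percentile.

    For Gaussian per-pixel noise, the sample SD over n repeats follows
    ``sigma * sqrt(chi2_{n-1} / (n-1))``; the predicted distribution of
    the per-pixel 100*SD/mean values is the mixture of those laws over
    the pixels, and its 95th percentile is solved numerically.  This is
    what the measured p95 should approach when the only repeat-to-repeat
    variation is the modelled noise.
    """
    if n_repeats < 2:
        raise ValueError("need n_repeats >= 2")
    sd = np.asarray(noise_sd_map, dtype=float).ravel()
    mu = np.asarray(mean_map, dtype=float).ravel()
    if valid is None:
        good = (mu > 0) & (sd >= 0)
    else:
        good = np.asarray(valid, dtype=bool).ravel() & (mu > 0)
    cv = 100.0 * sd[good] / mu[good]  # percent sd of a single determination
    k = n_repeats - 1

    def frac_below(t: float) -> float:
        with np.errstate(divide="ignore"):
            q = k * (t / np.where(cv > 0, cv, np.inf)) ** 2
        return float(np.mean(np.where(cv > 0, chi2.cdf(q, k), 1.0)))

    hi = float(np.percentile(cv, 99.9)) * 4 + 1e-9
    return brentq(lambda t: frac_below(t) - 0.95, 0.0, hi, xtol=1e-6)
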