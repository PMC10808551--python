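"""Per-cell speed-modulation and spatial-tuning metrics.

Speed modulation: mean dF/F as a function of running speed in 1 cm/s bins,
fitted with a line (with offset); the slope carries the sign and magnitude
of modulation, and significance is the sample-level Pearson correlation
between fluorescence and speed. Spatial tuning: Skaggs-style spatial
information

    SI = sum_i lambda_i * log2(lambda_i / lambda_bar) * p_i

over occupied track bins, optionally normalized by the cell's mean activity
(bits per unit dF/F); spatial coherence (each bin against the mean of its
two neighbors); circular vector tuning (resultant length and angle of the
activity-weighted bin angles); and split-half stability (zero-lag Pearson
correlation of first- and second-half maps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behavior_ops import SpatialMap

__all__ = [
    "SpeedTuning",
    "speed_tuning",
    "move_immobile_ratio",
    "spatial_information",
    "spatial_coherence",
    "vector_tuning",
    "within_session_stability",
]


@dataclass
class SpeedTuning:
    bin_centers: np.ndarray       # cm/s
    mean_dff_per_bin: np.ndarray
    slope: float                  # dF/F per cm/s
    intercept: float
    pearson_r: float
    p_value: float
    modulation_class: str         # {positive, negative, none}
    valid: bool = True


def speed_tuning(
    dff: np.ndarray,
    speed: np.ndarray,
    mask: np.ndarray,
    bin_w: float = 1.0,
    min_bin_time_s: float = 1.0,
    fs: float = 10.0,
    alpha: float = 0.05,
) -> SpeedTuning:
    """Speed-modulation metrics for one cell.

    The slope comes from a linear fit to the binned means (bins occupied
    for at least ``min_bin_time_s`` are kept); the significance comes from
    the sample-level Pearson correlation of (dF/F, speed) pairs under the
    movement mask. The modulation class is the sign of the slope when the
    correlation is significant at ``alpha`` (two-sided), else "none".
    """
    dff = np.asarray(dff, dtype=float)
    speed = np.asarray(speed, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    d, s = dff[mask], speed[mask]
    min_count = max(1, int(round(min_bin_time_s * fs)))
    idx = np.floor(s / bin_w).astype(np.int64)
    if idx.size == 0:
        return _undefined_speed_tuning()
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=d, minlength=n_bins)
    keep = counts >= min_count
    if keep.sum() < 2:
        return _undefined_speed_tuning()
    centers = (np.arange(n_bins)[keep] + 0.5) * bin_w
    means = sums[keep] / counts[keep]
    slope, intercept = np.polyfit(centers, means, 1)
    if np.std(d) == 0 or np.std(s) == 0:
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(d, s)
    if np.isfinite(p) and p < alpha:
        cls = "positive" if slope > 0 else "negative"
    else:
        cls = "none"
    return SpeedTuning(
        bin_centers=centers, mean_dff_per_bin=means, slope=float(slope),
        intercept=float(intercept), pearson_r=float(r), p_value=float(p),
        modulation_class=cls,
    )


def _undefined_speed_tuning() -> SpeedTuning:
    return SpeedTuning(
        bin_centers=np.empty(0), mean_dff_per_bin=np.empty(0),
        slope=np.nan, intercept=np.nan, pearson_r=np.nan, p_value=np.nan,
        modulation_class="none", valid=False,
    )


def move_immobile_ratio(
    activity: np.ndarray,
    moving: np.ndarray,
    immobile: np.ndarray,
) -> float:
    """Mean activity while moving divided by mean activity while immobile.

    Values below 1 indicate immobility-preferring cells. NaN (undefined) if
    either mask is empty or the immobile mean is not positive.
    """
    activity = np.asarray(activity, dtype=float)
    moving = np.asarray(moving, dtype=bool)
    immobile = np.asarray(immobile, dtype=bool)
    if not moving.any() or not immobile.any():
        return np.nan
    denom = float(np.mean(activity[immobile]))
    if denom <= 0:
        return np.nan
    return float(np.mean(activity[moving])) / denom


def spatial_information(spmap: SpatialMap, normalize: bool = False,
                        mean_activity: float | None = None) -> float:
    """Skaggs-style spatial information of one activity map, in bits.

    Sums ``lambda_i * log2(lambda_i / lambda_bar) * p_i`` over occupied
    bins with the convention 0*log(0) = 0. Negative bin means (possible
    for dF/F traces) are clamped to zero before the logarithm. Returns NaN
    for inactive cells (lambda_bar <= 0). With ``normalize=True`` the value
    is divided by the cell's mean activity (bits per unit dF/F); pass
    ``mean_activity`` to use the whole-trace mean (area under the curve per
    unit time) instead of the map mean.
    """
    occ = spmap.occupied
    lam = np.maximum(np.nan_to_num(spmap.lambda_i[occ]), 0.0)
    p = spmap.p_i[occ]
    lam_bar = float(np.sum(p * lam))
    if lam_bar <= 0:
        return np.nan
    active = lam > 0
    si = float(np.sum(lam[active] * np.log2(lam[active] / lam_bar) * p[active]))
    if normalize:
        denom = lam_bar if mean_activity is None else float(mean_activity)
        si = np.nan if denom <= 0 else si / denom
    return si


def _neighbor_means(lam: np.ndarray, circular: bool) -> np.ndarray:
    """Mean of the two nearest neighbors per bin (NaN-aware at edges/holes)."""
    n = len(lam)
    left = np.roll(lam, 1)
    right = np.roll(lam, -1)
    if not circular:
        left[0] = np.nan
        right[-1] = np.nan
    pair = np.vstack([left, right])
    with np.errstate(invalid="ignore"):
        return np.nanmean(pair, axis=0)


def spatial_coherence(spmap: SpatialMap) -> float:
    """Local smoothness: Pearson r between each bin and its neighbor mean.

    Wraparound neighbors are used on circular tracks. Returns NaN if fewer
    than 4 occupied bins or either vector is constant.
    """
    lam = spmap.lambda_i.copy()
    neigh = _neighbor_means(lam, spmap.circular)
    ok = np.isfinite(lam) & np.isfinite(neigh)
    if ok.sum() < 4:
        return np.nan
    a, b = lam[ok], neigh[ok]
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.pearsonr(a, b)[0])


def vector_tuning(spmap: SpatialMap) -> tuple[float, float]:
    """Circular-mean tuning vector (length in [0, 1], angle in radians).

    Each occupied bin contributes a unit vector at its track angle weighted
    by its mean activity; the resultant is normalized by the summed
    activity. Undefined (NaN, NaN) for all-zero maps.
    """
    occ = spmap.occupied
    lam = np.maximum(np.nan_to_num(spmap.lambda_i[occ]), 0.0)
    total = lam.sum()
    if total <= 0:
        return np.nan, np.nan
    L = spmap.bin_edges[-1]
    theta = 2 * np.pi * spmap.bin_centers[occ] / L
    z = np.sum(lam * np.exp(1j * theta)) / total
    return float(np.abs(z)), float(np.angle(z) % (2 * np.pi))


def within_session_stability(map_h1: SpatialMap, map_h2: SpatialMap) -> float:
    """Zero-lag Pearson correlation of two half-session maps.

    Computed over bins occupied in both halves; NaN if fewer than 4 such
    bins or either map is constant over them.
    """
    if map_h1.n_bins != map_h2.n_bins:
        raise ValueError("maps must share bin edges")
    ok = map_h1.occupied & map_h2.occupied
    if ok.sum() < 4:
        return np.nan
    a, b = map_h1.lambda_i[ok], map_h2.lambda_i[ok]
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.pearsonr(a, b)[0])
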