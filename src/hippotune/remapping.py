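"""Between-context and between-condition comparison of spatial maps.

Remapping of place cells between the familiar and novel context is
quantified two ways:

* per cell, the Pearson correlation of the two spatial activity profiles
  (5-cm bins) over jointly occupied bins — cells qualify when they are a
  place cell in at least one of the compared conditions;
* per session, the population-vector correlation: each place cell's map
  (10-cm bins) is z-scored over space (removing mean-rate differences
  between cells), the maps are stacked into per-bin population vectors,
  and the two contexts are correlated bin by bin. Sessions with fewer
  than 5 place cells in either condition are excluded.

Conditions (e.g. baseline vs chemogenetic suppression) are contrasted by
an unpaired two-sided Wilcoxon rank-sum test on the per-cell field
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .behavior_ops import SpatialMap

__all__ = [
    "RemapResult",
    "field_correlation",
    "population_vector_correlation",
    "condition_contrast",
]


@dataclass
class RemapResult:
    """Per-session remapping summary."""

    field_corr: np.ndarray          # per place cell, NaN where undefined
    pv_corr: np.ndarray | None      # per 10-cm bin; None if not eligible
    eligible: bool
    n_place_cells: tuple[int, int] = (0, 0)
    n_excluded_cells: int = 0


def field_correlation(map_a: SpatialMap, map_b: SpatialMap) -> float:
    """Pearson correlation of two spatial activity profiles of one cell.

    Computed over bins occupied in both conditions; NaN (undefined) with
    fewer than 4 such bins or a zero-variance map.
    """
    if map_a.n_bins != map_b.n_bins:
        raise ValueError("maps must share bin edges")
    ok = map_a.occupied & map_b.occupied
    if ok.sum() < 4:
        return np.nan
    a, b = map_a.lambda_i[ok], map_b.lambda_i[ok]
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.pearsonr(a, b)[0])


def _zscore_rows(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each cell's map over space; returns (z, keep) dropping flats."""
    mu = np.nanmean(maps, axis=1, keepdims=True)
    sd = np.nanstd(maps, axis=1, keepdims=True)
    keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (maps - mu) / sd
    return z[keep], keep


def population_vector_correlation(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    n_place_cells: tuple[int, int] | None = None,
    min_place_cells: int = 5,
) -> RemapResult:
    """Per-bin population-vector correlation between two contexts.

    ``maps_a``/``maps_b`` are (place cells x bins) mean-activity matrices
    on identical (10-cm) bin edges. Each cell's map is z-scored over space
    before stacking, so the measure reflects the spatial pattern and not
    mean-rate differences. Sessions with fewer than ``min_place_cells``
    place cells in either condition are ineligible and get ``pv_corr=None``.
    """
    maps_a = np.atleast_2d(np.asarray(maps_a, dtype=float))
    maps_b = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if maps_a.shape != maps_b.shape:
        raise ValueError("the two map stacks must have identical shape")
    counts = n_place_cells if n_place_cells is not None else (len(maps_a), len(maps_b))
    if min(counts) < min_place_cells:
        return RemapResult(field_corr=np.empty(0), pv_corr=None, eligible=False,
                           n_place_cells=tuple(counts))
    sd_a = np.nanstd(maps_a, axis=1)
    sd_b = np.nanstd(maps_b, axis=1)
    keep = (sd_a > 0) & (sd_b > 0) & np.isfinite(sd_a) & np.isfinite(sd_b)
    za = _zscore_rows(maps_a[keep])[0]
    zb = _zscore_rows(maps_b[keep])[0]
    n_bins = maps_a.shape[1]
    pv = np.full(n_bins, np.nan)
    for j in range(n_bins):
        x, y = za[:, j], zb[:, j]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
            pv[j] = stats.pearsonr(x[ok], y[ok])[0]
    return RemapResult(
        field_corr=np.empty(0), pv_corr=pv, eligible=True,
        n_place_cells=tuple(counts),
        n_excluded_cells=int((~keep).sum()),
    )


def condition_contrast(corr_a: np.ndarray, corr_b: np.ndarray) -> dict:
    """Unpaired two-sided rank-sum contrast of field-correlation sets.

    Undefined (NaN) correlations are excluded, with counts reported; the
    effect direction is the sign of median(b) - median(a).
    """
    a = np.asarray(corr_a, dtype=float)
    b = np.asarray(corr_b, dtype=float)
    a_ok, b_ok = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a_ok) < 2 or len(b_ok) < 2:
        raise ValueError("each condition needs >= 2 finite correlations")
    stat, p = stats.ranksums(a_ok, b_ok)
    direction = float(np.sign(np.median(b_ok) - np.median(a_ok)))
    return {
        "statistic": float(stat), "p_value": float(p),
        "n_a": len(a_ok), "n_b": len(b_ok),
        "n_excluded": int(len(a) - len(a_ok) + len(b) - len(b_ok)),
        "median_a": float(np.median(a_ok)), "median_b": float(np.median(b_ok)),
        "direction": direction,
    }
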