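"""Circular-shuffle nulls, per-cell significance, and place-cell calls.

The null model circularly shifts the behavior (position, movement mask,
half labels) against the calcium trace: the trace and the position are
concatenated across all runs of a condition, the position is shifted
forward by a random interval, and the values falling off the end re-enter
at the beginning. This preserves the autocorrelation of both signals while
destroying their alignment. For each of n (default 1000) random shifts the
spatial metrics (SI, coherence, tuning-vector length, split-half
stability) are recomputed; a cell's tuning is significant when its true
value exceeds the null distribution in strictly more than 95% of shuffles.

Shifts are drawn uniformly (with replacement) from
[min_shift, T - min_shift] frames, excluding near-zero/near-full shifts
that would replicate the true alignment. The same shift sequence is shared
across metrics of a cell so that metrics see one common null alignment.

A place cell is a cell with significant SI and a transient rate of at
least 1 per minute of movement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavior_ops import position_bins

__all__ = [
    "ShuffleNull",
    "circular_shuffle_null",
    "population_bootstrap_compare",
    "classify_place_cells",
]

METRICS = ("si", "coherence", "vector_length", "stability")


@dataclass
class ShuffleNull:
    metric_name: str
    n_shuffles: int
    null_values: np.ndarray
    true_value: float
    percentile_of_true: float   # % of null values strictly below the true value
    significant: bool


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``a`` against the matching row of ``b``.

    NaN columns are excluded pairwise per row; rows with < 4 finite pairs
    or zero variance yield NaN.
    """
    ok = np.isfinite(a) & np.isfinite(b)
    n = ok.sum(axis=1)
    a0 = np.where(ok, a, 0.0)
    b0 = np.where(ok, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = a0.sum(axis=1) / n
        mb = b0.sum(axis=1) / n
        da = np.where(ok, a0 - ma[:, None], 0.0)
        db = np.where(ok, b0 - mb[:, None], 0.0)
        num = (da * db).sum(axis=1)
        den = np.sqrt((da ** 2).sum(axis=1) * (db ** 2).sum(axis=1))
        r = num / den
    r[(n < 4) | ~np.isfinite(r)] = np.nan
    return r


def _binned_means(A: np.ndarray, bins: np.ndarray, mask: np.ndarray,
                  n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean of each row of ``A`` under ``mask``; (lam (C,B), counts)."""
    sel = bins[mask]
    counts = np.bincount(sel, minlength=n_bins).astype(float)
    if sel.size == 0:
        return np.full((A.shape[0], n_bins), np.nan), counts
    order = np.argsort(sel, kind="stable")
    sorted_bins = sel[order]
    starts = np.r_[0, 1 + np.flatnonzero(np.diff(sorted_bins))]
    present = sorted_bins[starts]
    sums_present = np.add.reduceat(A[:, mask][:, order], starts, axis=1)
    lam = np.full((A.shape[0], n_bins), np.nan)
    lam[:, present] = sums_present / counts[present]
    return lam, counts


def _alignment_metrics(
    A: np.ndarray,
    bins: np.ndarray,
    mask: np.ndarray,
    n_bins: int,
    circular: bool,
    metrics: tuple[str, ...],
    halves: tuple[np.ndarray, np.ndarray] | None,
    bin_centers: np.ndarray,
    track_length: float,
) -> dict[str, np.ndarray]:
    """All requested map metrics for one behavior/activity alignment.

    Vectorized over cells (rows of ``A``); used identically for the true
    alignment and for every shuffle, so true values and nulls go through
    one code path.
    """
    out: dict[str, np.ndarray] = {}
    lam, counts = _binned_means(A, bins, mask, n_bins)
    p = counts / counts.sum() if counts.sum() > 0 else counts
    lam_pos = np.maximum(np.nan_to_num(lam), 0.0)
    occ = counts > 0

    if "si" in metrics:
        lam_bar = lam_pos[:, occ] @ p[occ]
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = lam_pos[:, occ] / lam_bar[:, None]
            terms = np.where(lam_pos[:, occ] > 0,
                             lam_pos[:, occ] * np.log2(np.where(ratio > 0, ratio, 1.0)),
                             0.0)
            si = terms @ p[occ]
        si[lam_bar <= 0] = np.nan
        out["si"] = si
    if "coherence" in metrics:
        left = np.roll(lam, 1, axis=1)
        right = np.roll(lam, -1, axis=1)
        if not circular:
            left[:, 0] = np.nan
            right[:, -1] = np.nan
        with np.errstate(invalid="ignore"):
            neigh = np.nanmean(np.stack([left, right]), axis=0)
        out["coherence"] = _rowwise_pearson(lam, neigh)
    if "vector_length" in metrics:
        theta = 2 * np.pi * bin_centers / track_length
        w = lam_pos[:, occ]
        total = w.sum(axis=1)
        z = w @ np.exp(1j * theta[occ])
        with np.errstate(invalid="ignore", divide="ignore"):
            vl = np.abs(z) / total
        vl[total <= 0] = np.nan
        out["vector_length"] = vl
    if "stability" in metrics:
        if halves is None:
            raise ValueError("stability metric requires half-session masks")
        h1, h2 = halves
        lam1, _ = _binned_means(A, bins, mask & h1, n_bins)
        lam2, _ = _binned_means(A, bins, mask & h2, n_bins)
        out["stability"] = _rowwise_pearson(lam1, lam2)
    return out


def draw_shifts(n_frames: int, n: int, min_shift: int,
                rng: np.random.Generator) -> np.ndarray:
    """Uniform circular shifts in [min_shift, n_frames - min_shift]."""
    if n_frames <= 2 * min_shift:
        raise ValueError(
            f"trace of {n_frames} frames too short for min_shift={min_shift}"
        )
    return rng.integers(min_shift, n_frames - min_shift + 1, size=n)


def circular_shuffle_null(
    activity: np.ndarray,
    position: np.ndarray,
    mask: np.ndarray,
    track_length: float,
    fs: float,
    metrics: tuple[str, ...] = METRICS,
    bin_w: float = 5.0,
    circular: bool = True,
    n_shuffles: int = 1000,
    min_shift_s: float = 10.0,
    halves: tuple[np.ndarray, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
    percentile: float = 95.0,
) -> dict[str, list[ShuffleNull]]:
    """Circular-shuffle null distributions for one or many cells.

    ``activity`` is (cells x frames) or a single (frames,) trace, already
    concatenated across the runs of one condition; ``position``, ``mask``
    and the optional ``halves`` masks are frame-aligned to it. For every
    random shift, the behavior arrays are rotated together against the
    activity and the requested metrics recomputed. Returns one list of
    :class:`ShuffleNull` (one entry per cell) per metric; a single input
    trace yields bare :class:`ShuffleNull` objects.
    """
    rng = rng if rng is not None else np.random.default_rng()
    unknown = set(metrics) - set(METRICS)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}; valid: {METRICS}")
    if "stability" in metrics and halves is None:
        raise ValueError("stability metric requires halves=(first, second) masks")
    single = np.ndim(activity) == 1
    A = np.atleast_2d(np.asarray(activity, dtype=float))
    position = np.asarray(position, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    T = A.shape[1]
    if len(position) != T or len(mask) != T:
        raise ValueError("activity, position and mask must share frame count")
    import math
    n_bins = math.ceil(track_length / bin_w)
    bins = position_bins(position, track_length, bin_w)
    centers = (np.arange(n_bins) + 0.5) * bin_w
    min_shift = int(round(min_shift_s * fs))
    shifts = draw_shifts(T, n_shuffles, min_shift, rng)

    kwargs = dict(n_bins=n_bins, circular=circular, metrics=tuple(metrics),
                  bin_centers=centers, track_length=track_length)
    true_vals = _alignment_metrics(A, bins, mask, halves=halves, **kwargs)
    null_vals = {m: np.empty((n_shuffles, A.shape[0])) for m in metrics}
    for k, s in enumerate(shifts):
        rb = np.roll(bins, s)
        rm = np.roll(mask, s)
        rh = None
        if halves is not None:
            rh = (np.roll(halves[0], s), np.roll(halves[1], s))
        vals = _alignment_metrics(A, rb, rm, halves=rh, **kwargs)
        for m in metrics:
            null_vals[m][k] = vals[m]

    out: dict[str, list[ShuffleNull]] = {}
    for m in metrics:
        nulls_m = []
        for c in range(A.shape[0]):
            true = float(true_vals[m][c])
            null = null_vals[m][:, c]
            finite = null[np.isfinite(null)]
            if np.isfinite(true) and finite.size:
                pct = 100.0 * np.mean(finite < true)
            else:
                pct = np.nan
            nulls_m.append(ShuffleNull(
                metric_name=m, n_shuffles=n_shuffles, null_values=null,
                true_value=true, percentile_of_true=float(pct),
                significant=bool(np.isfinite(pct) and pct > percentile),
            ))
        out[m] = nulls_m
    if single:
        return {m: v[0] for m, v in out.items()}
    return out


def population_bootstrap_compare(
    true_values: np.ndarray,
    nulls: list[ShuffleNull],
    rng: np.random.Generator | None = None,
) -> dict:
    """Population-level tuning test against one resampled null per cell.

    For every cell one value is drawn at random from its shuffle null, and
    the distribution of drawn values is compared with the true values by a
    paired two-sided Wilcoxon signed-rank test. Returns statistic, p and n.
    """
    rng = rng if rng is not None else np.random.default_rng()
    true_values = np.asarray(true_values, dtype=float)
    if len(true_values) != len(nulls):
        raise ValueError("one null per cell required")
    picked = np.array([
        null.null_values[rng.integers(0, len(null.null_values))] for null in nulls
    ])
    ok = np.isfinite(true_values) & np.isfinite(picked)
    t, s = true_values[ok], picked[ok]
    if len(t) < 5:
        raise ValueError(f"need >= 5 cells with finite values, got {len(t)}")
    if np.allclose(t, s):
        return {"statistic": np.nan, "p_value": 1.0, "n": len(t)}
    stat, p = stats.wilcoxon(t, s, alternative="two-sided")
    return {"statistic": float(stat), "p_value": float(p), "n": len(t)}


def classify_place_cells(
    si_nulls: list[ShuffleNull],
    transient_rates: np.ndarray,
    min_rate_per_min: float = 1.0,
    cell_ids: list[str] | None = None,
    context: str = "familiar",
) -> pd.DataFrame:
    """Place-cell classification: significant SI and >= 1 transient/min.

    Cells with a missing (NaN) transient rate are excluded from the
    returned table. The frame carries per-session summary fractions in
    ``df.attrs`` (fraction of included cells that are place cells, and the
    number excluded).
    """
    rates = np.asarray(transient_rates, dtype=float)
    if len(rates) != len(si_nulls):
        raise ValueError("one rate per SI null required")
    ids = cell_ids if cell_ids is not None else [f"cell{i:04d}" for i in range(len(rates))]
    rows = []
    n_excluded = 0
    for cid, null, rate in zip(ids, si_nulls, rates):
        if not np.isfinite(rate):
            n_excluded += 1
            continue
        rows.append({
            "cell_id": cid,
            "context": context,
            "si_significant": bool(null.significant),
            "transient_rate": float(rate),
            "is_place_cell": bool(null.significant and rate >= min_rate_per_min),
        })
    df = pd.DataFrame(rows, columns=["cell_id", "context", "si_significant",
                                     "transient_rate", "is_place_cell"])
    df.attrs["n_excluded"] = n_excluded
    df.attrs["fraction_place_cells"] = float(df["is_place_cell"].mean()) if len(df) else np.nan
    df.attrs["fraction_si_significant"] = float(df["si_significant"].mean()) if len(df) else np.nan
    return df
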