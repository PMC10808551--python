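"""dF/F extraction and calibrated calcium-transient detection.

Two dF/F variants are provided, matching how principal cells and
interneurons are treated:

* :func:`dff_sliding_percentile` — principal cells: slow drift is removed
  by subtracting a sliding 8th-percentile baseline (~8-s window around each
  time point), and the corrected trace is divided by an initial baseline
  estimate (mean of all points not exceeding 3 SD of the total signal).
* :func:`dff_segment_percentile` — interneurons: each recording segment is
  divided by the 8th percentile of its own fluorescence-value distribution.
  The resulting trace has baseline near 1 and is analyzed as a continuous
  rate proxy; no transient detection is applied.

Transient detection on principal cells is threshold/duration based and the
parameters are calibrated per dataset so that the false-positive rate —
the ratio of negative-going to positive-going transients, with negative
transients found by running the same detector on the sign-inverted,
baseline-centered trace — stays below 5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig

__all__ = [
    "TransientParams",
    "TransientEvents",
    "dff_sliding_percentile",
    "dff_segment_percentile",
    "calibrate_transient_params",
    "detect_transients",
    "transient_rate",
]


class CalibrationError(RuntimeError):
    """No candidate parameter set achieved the false-positive target."""


@dataclass
class TransientParams:
    onset_threshold: float          # multiples of baseline SD
    min_duration: float             # s
    offset_fraction: float = 0.5    # event ends below this fraction of onset level
    achieved_fpr: float = np.nan    # negative/positive transient ratio

    def __post_init__(self) -> None:
        if self.onset_threshold <= 0 or self.min_duration <= 0:
            raise ValueError("onset_threshold and min_duration must be positive")
        if not 0 < self.offset_fraction <= 1:
            raise ValueError("offset_fraction must be in (0, 1]")


@dataclass
class TransientEvents:
    """Detected transients for one session (all cells)."""

    onsets: list[np.ndarray]        # frame index per cell
    offsets: list[np.ndarray]       # exclusive end frame per cell
    peaks: list[np.ndarray]         # peak dF/F per event
    baseline: np.ndarray            # definitive per-cell baseline (dF/F units)
    sd: np.ndarray                  # definitive per-cell SD
    mask: np.ndarray                # bool, cells x frames, True inside events

    @property
    def n_cells(self) -> int:
        return len(self.onsets)

    def counts(self) -> np.ndarray:
        return np.array([len(o) for o in self.onsets])

    def masked_dff(self, dff: np.ndarray) -> np.ndarray:
        """dF/F with all samples outside detected transients set to zero."""
        out = np.where(self.mask, np.atleast_2d(dff), 0.0)
        return out

    def to_frame(self, fs: float) -> pd.DataFrame:
        rows = []
        for c in range(self.n_cells):
            for on, off, pk in zip(self.onsets[c], self.offsets[c], self.peaks[c]):
                rows.append((c, on / fs, off / fs, pk))
        return pd.DataFrame(rows, columns=["cell", "onset_s", "offset_s", "peak_dff"])


def _initial_baseline(trace: np.ndarray, sd_cut: float = 3.0) -> tuple[float, float]:
    """Mean/SD of all points not exceeding ``sd_cut`` SD of the total signal."""
    mu, sd = float(np.mean(trace)), float(np.std(trace))
    keep = trace <= mu + sd_cut * sd
    if not keep.any():
        keep = np.ones_like(trace, dtype=bool)
    return float(np.mean(trace[keep])), float(np.std(trace[keep]))


def dff_sliding_percentile(
    raw_f: np.ndarray,
    fs: float,
    window_s: float = 8.0,
    pct: float = 8.0,
    recording_gap: np.ndarray | None = None,
    sd_cut: float = 3.0,
) -> np.ndarray:
    """Principal-cell dF/F: sliding-percentile drift correction + baseline division.

    The 8th-percentile of the fluorescence distribution in a ~``window_s``
    window around each time point (truncated at the trace edges, gap frames
    excluded from the window statistics) is subtracted from the raw trace;
    the corrected trace is divided by the initial baseline estimate — the
    mean of all points of the raw signal not exceeding ``sd_cut`` SD.

    Accepts a single trace or a (cells x frames) array.
    """
    raw = np.atleast_2d(np.asarray(raw_f, dtype=float))
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw_f contains non-finite values")
    win = int(round(window_s * fs))
    if win < 3:
        raise ValueError("window must cover at least 3 samples")
    if win > raw.shape[1]:
        raise ValueError("window longer than trace")
    out = np.empty_like(raw)
    for i, trace in enumerate(raw):
        series = pd.Series(trace.copy())  # copy: Series would alias the row
        if recording_gap is not None:
            series[np.asarray(recording_gap, dtype=bool)] = np.nan
        drift = series.rolling(win, center=True, min_periods=1).quantile(pct / 100.0)
        drift = drift.ffill().bfill().to_numpy()
        corrected = trace - drift
        f0, _ = _initial_baseline(trace, sd_cut)
        if f0 <= 0:
            raise ValueError("non-positive baseline estimate; check raw units")
        out[i] = corrected / f0
    return out if np.ndim(raw_f) == 2 else out[0]


def dff_segment_percentile(
    raw_f: np.ndarray,
    segment_bounds: list[tuple[int, int]],
    pct: float = 8.0,
) -> np.ndarray:
    """Interneuron dF/F: divide each recording segment by its 8th percentile.

    ``segment_bounds`` are half-open (start, stop) frame intervals that
    partition the frames to be normalized; frames outside every segment
    (e.g. teleport gaps) are set to NaN.
    """
    raw = np.atleast_2d(np.asarray(raw_f, dtype=float))
    out = np.full_like(raw, np.nan)
    for start, stop in segment_bounds:
        seg = raw[:, start:stop]
        if seg.size == 0:
            raise ValueError(f"empty segment ({start}, {stop})")
        p8 = np.percentile(seg, pct, axis=1, keepdims=True)
        if np.any(p8 <= 0):
            raise ValueError(
                "segment 8th percentile <= 0; raw fluorescence units invalid"
            )
        out[:, start:stop] = seg / p8
    return out if np.ndim(raw_f) == 2 else out[0]


def _find_events(
    trace: np.ndarray,
    baseline: float,
    sd: float,
    fs: float,
    params: TransientParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold-crossing events on one trace. Returns (onsets, offsets).

    An event starts where the trace exceeds ``baseline + onset_threshold*SD``
    for at least ``min_duration``, and ends when it decays below
    ``baseline + offset_fraction*onset_threshold*SD``.
    """
    hi = baseline + params.onset_threshold * sd
    lo = baseline + params.offset_fraction * params.onset_threshold * sd
    min_frames = max(1, int(round(params.min_duration * fs)))
    above = trace > hi
    if not above.any():
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(trace)]
    onsets, offsets = [], []
    last_end = -1
    for s, e in zip(starts, ends):
        if s < last_end:          # swallowed by a previous event's decay tail
            continue
        if e - s < min_frames:
            continue
        # extend to where the trace falls back below the offset level
        below = np.flatnonzero(trace[e:] < lo)
        off = e + (below[0] if below.size else len(trace) - e)
        onsets.append(s)
        offsets.append(off)
        last_end = off
    return np.asarray(onsets, dtype=int), np.asarray(offsets, dtype=int)


def detect_transients(
    dff: np.ndarray,
    fs: float,
    params: TransientParams,
    sd_cut: float = 3.0,
) -> TransientEvents:
    """Detect significant positive transients on each cell's dF/F trace.

    Runs a first pass with the initial 3-SD baseline estimate, recomputes
    the definitive baseline and SD from all transient-free samples, and
    re-detects once with the definitive values. The returned mask is True
    inside detected events; masking a trace with it and zeroing the rest
    yields the "significant transients only" trace used downstream.
    """
    dff2 = np.atleast_2d(np.asarray(dff, dtype=float))
    n_cells, n_frames = dff2.shape
    onsets, offsets, peaks = [], [], []
    baseline = np.empty(n_cells)
    sd = np.empty(n_cells)
    mask = np.zeros((n_cells, n_frames), dtype=bool)
    for c in range(n_cells):
        trace = dff2[c]
        b0, s0 = _initial_baseline(trace, sd_cut)
        on, off = _find_events(trace, b0, s0, fs, params)
        free = np.ones(n_frames, dtype=bool)
        for s, e in zip(on, off):
            free[s:e] = False
        if free.sum() >= 2:
            b1, s1 = float(np.mean(trace[free])), float(np.std(trace[free]))
        else:
            b1, s1 = b0, s0
        if s1 <= 0:
            s1 = s0 if s0 > 0 else 1.0
        on, off = _find_events(trace, b1, s1, fs, params)
        for s, e in zip(on, off):
            mask[c, s:e] = True
        onsets.append(on)
        offsets.append(off)
        peaks.append(np.array([trace[s:e].max() for s, e in zip(on, off)]))
        baseline[c] = b1
        sd[c] = s1
    return TransientEvents(onsets=onsets, offsets=offsets, peaks=peaks,
                           baseline=baseline, sd=sd, mask=mask)


def _count_events(dff2: np.ndarray, fs: float, params: TransientParams,
                  sd_cut: float) -> tuple[int, int]:
    """Positive and negative transient counts pooled over cells.

    Negative transients are detected by the identical detector applied to
    the sign-inverted, baseline-centered trace.
    """
    pos = detect_transients(dff2, fs, params, sd_cut=sd_cut)
    inverted = 2.0 * pos.baseline[:, None] - dff2
    neg = detect_transients(inverted, fs, params, sd_cut=sd_cut)
    return int(pos.counts().sum()), int(neg.counts().sum())


def calibrate_transient_params(
    dff: np.ndarray,
    fs: float,
    cfg: AnalysisConfig | None = None,
    onset_grid: tuple[float, ...] | None = None,
    duration_grid: tuple[float, ...] | None = None,
) -> TransientParams:
    """Choose detection parameters with a false-positive ratio below target.

    Walks the (onset_threshold, min_duration) grid from permissive to
    stringent and returns the least stringent point whose ratio of
    negative-going to positive-going transients is below the target (5% by
    default). Raises :class:`CalibrationError` reporting the best achieved
    ratio if no point qualifies.
    """
    cfg = cfg or AnalysisConfig()
    onset_grid = onset_grid if onset_grid is not None else cfg.onset_grid_sd
    duration_grid = duration_grid if duration_grid is not None else cfg.duration_grid_s
    if not onset_grid or not duration_grid:
        raise ValueError("calibration grid must be non-empty")
    dff2 = np.atleast_2d(np.asarray(dff, dtype=float))
    best_ratio = np.inf
    # permissive -> stringent: low threshold / short duration first
    for thr in sorted(onset_grid):
        for dur in sorted(duration_grid):
            params = TransientParams(thr, dur, offset_fraction=cfg.offset_fraction)
            n_pos, n_neg = _count_events(dff2, fs, params, cfg.baseline_sd_cut)
            if n_pos == 0:
                continue
            ratio = n_neg / n_pos
            best_ratio = min(best_ratio, ratio)
            if ratio < cfg.fpr_target:
                params.achieved_fpr = ratio
                return params
    raise CalibrationError(
        f"no grid point achieved FPR < {cfg.fpr_target}; best ratio {best_ratio:.3f}"
    )


def transient_rate(
    events: TransientEvents,
    movement_mask: np.ndarray,
    fs: float,
) -> np.ndarray:
    """Transients per minute of movement, per cell.

    Counts event onsets falling inside the movement mask and divides by the
    total moving time in minutes. NaN if there is no moving time.
    """
    movement_mask = np.asarray(movement_mask, dtype=bool)
    minutes = movement_mask.sum() / fs / 60.0
    if minutes == 0:
        return np.full(events.n_cells, np.nan)
    return np.array(
        [np.count_nonzero(movement_mask[on]) for on in events.onsets]
    ) / minutes
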