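"""Movement masking, context segmentation, occupancy, spatial activity maps.

Analyses are restricted to running periods (speed >= 2 cm/s by default;
slower frames count as immobility, since head-motion jitter of the position
signal makes a strictly-zero criterion unusable). The track is divided into
half-open bins [k*w, (k+1)*w) of width 5 cm (10 cm for population vectors);
a :class:`SpatialMap` holds the per-bin mean activity, the occupancy
fraction, and the overall mean, which satisfy the exact identity
``lambda_bar = sum_i p_i * lambda_i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .session import BehaviorTrace, Session

__all__ = [
    "SpatialMap",
    "movement_mask",
    "immobility_mask",
    "position_bins",
    "compute_occupancy",
    "spatial_map",
    "split_halves",
    "segment_contexts",
]


@dataclass
class SpatialMap:
    """Mean activity per track bin with occupancy.

    ``lambda_i`` is NaN in unoccupied bins; ``p_i`` sums to 1 over occupied
    bins; ``lambda_bar`` is the occupancy-weighted mean activity.
    """

    bin_edges: np.ndarray      # cm, length n_bins + 1
    lambda_i: np.ndarray       # mean activity per bin (NaN if unoccupied)
    p_i: np.ndarray            # occupancy fraction per bin (0 if unoccupied)
    lambda_bar: float
    circular: bool = True

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def occupied(self) -> np.ndarray:
        return self.p_i > 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def movement_mask(
    speed: np.ndarray,
    threshold: float = 2.0,
    recording_gap: np.ndarray | None = None,
) -> np.ndarray:
    """True where the animal runs at >= ``threshold`` cm/s, outside gaps."""
    mask = np.asarray(speed, dtype=float) >= threshold
    if recording_gap is not None:
        mask &= ~np.asarray(recording_gap, dtype=bool)
    return mask


def immobility_mask(
    speed: np.ndarray,
    threshold: float = 2.0,
    recording_gap: np.ndarray | None = None,
) -> np.ndarray:
    """Complement of the movement mask within non-gap frames."""
    mask = np.asarray(speed, dtype=float) < threshold
    if recording_gap is not None:
        mask &= ~np.asarray(recording_gap, dtype=bool)
    return mask


def position_bins(position: np.ndarray, track_length: float, bin_w: float) -> np.ndarray:
    """Half-open bin index per frame; the last bin closes at the track length."""
    n_bins = math.ceil(track_length / bin_w)
    idx = np.floor(np.asarray(position, dtype=float) / bin_w).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def compute_occupancy(
    behavior: BehaviorTrace,
    mask: np.ndarray,
    bin_w: float = 5.0,
) -> np.ndarray:
    """Fraction of (masked) time spent in each track bin; sums to 1."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no frames to compute occupancy from")
    n_bins = math.ceil(behavior.track_length_cm / bin_w)
    bins = position_bins(behavior.position, behavior.track_length_cm, bin_w)
    counts = np.bincount(bins[mask], minlength=n_bins).astype(float)
    return counts / counts.sum()


def spatial_map(
    activity: np.ndarray,
    behavior: BehaviorTrace,
    mask: np.ndarray,
    bin_w: float = 5.0,
    circular: bool = True,
) -> SpatialMap:
    """Mean activity per track bin under a movement mask.

    ``activity`` is a single cell's trace aligned to the behavior (dF/F for
    interneurons, masked-transient dF/F for principal cells). At the fixed
    sampling rate the per-bin frame mean equals the time mean.
    """
    activity = np.asarray(activity, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if activity.shape[0] != behavior.n_frames:
        raise ValueError("activity length must match behavior frames")
    if not mask.any():
        raise ValueError("empty mask")
    n_bins = math.ceil(behavior.track_length_cm / bin_w)
    bins = position_bins(behavior.position, behavior.track_length_cm, bin_w)
    sel = bins[mask]
    counts = np.bincount(sel, minlength=n_bins).astype(float)
    sums = np.bincount(sel, weights=activity[mask], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        lam = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    p = counts / counts.sum()
    lam_bar = float(np.nansum(p * np.nan_to_num(lam)))
    edges = bin_w * np.arange(n_bins + 1)
    edges[-1] = behavior.track_length_cm
    return SpatialMap(bin_edges=edges, lambda_i=lam, p_i=p,
                      lambda_bar=lam_bar, circular=circular)


def split_halves(behavior: BehaviorTrace) -> tuple[np.ndarray, np.ndarray]:
    """Frame masks for the first and second half of a session, per context.

    Trials (laps or blocks) of each context are split at the median trial
    boundary; with an odd trial count the first half gets the extra trial.
    Gap frames belong to neither half.
    """
    first = np.zeros(behavior.n_frames, dtype=bool)
    second = np.zeros(behavior.n_frames, dtype=bool)
    nongap = ~behavior.recording_gap
    for ctx in np.unique(behavior.context_id[nongap]):
        in_ctx = nongap & (behavior.context_id == ctx)
        trials = np.unique(behavior.trial_index[in_ctx])
        if len(trials) < 2:
            raise ValueError(
                f"context '{ctx}' has {len(trials)} trial(s); need >= 2 to split"
            )
        n_first = math.ceil(len(trials) / 2)
        first |= in_ctx & np.isin(behavior.trial_index, trials[:n_first])
        second |= in_ctx & np.isin(behavior.trial_index, trials[n_first:])
    return first, second


def segment_contexts(behavior: BehaviorTrace,
                     contexts: list[str] | None = None) -> dict[str, np.ndarray]:
    """Frame indices per context, order preserved, gap frames excluded."""
    nongap = ~behavior.recording_gap
    present = list(np.unique(behavior.context_id[nongap]))
    if contexts is not None:
        unknown = set(contexts) - set(present)
        if unknown:
            raise ValueError(f"unknown context label(s): {sorted(unknown)}")
    else:
        contexts = present
    return {
        ctx: np.flatnonzero(nongap & (behavior.context_id == ctx))
        for ctx in contexts
    }
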