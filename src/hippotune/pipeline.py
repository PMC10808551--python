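"""End-to-end per-session analysis producing a per-cell metric table.

``analyze_session`` runs the full chain for one session: dF/F extraction
(interneuron or principal-cell variant), transient detection for principal
cells, movement masking, per-context spatial maps, speed and spatial
tuning metrics, circular-shuffle significance, and — for principal cells —
place-cell classification. The result is one tidy DataFrame with one row
per cell per context; ``df.attrs`` carries the provenance seed and config
hash, so identical (session, config, seed) re-runs are bit-identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior_ops import (immobility_mask, movement_mask, segment_contexts,
                           spatial_map, split_halves)
from .config import AnalysisConfig, config_hash
from .session import Session
from .signals import (calibrate_transient_params, detect_transients,
                      dff_segment_percentile, dff_sliding_percentile,
                      transient_rate)
from .significance import circular_shuffle_null, classify_place_cells
from .tuning import move_immobile_ratio, speed_tuning

__all__ = ["preprocess_session", "analyze_session"]


def _nongap_segments(recording_gap: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) bounds of contiguous non-gap runs."""
    good = ~np.asarray(recording_gap, dtype=bool)
    d = np.diff(good.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if good[0]:
        starts.insert(0, 0)
    if good[-1]:
        stops.append(len(good))
    return list(zip(starts, stops))


def preprocess_session(session: Session, cfg: AnalysisConfig,
                       mode: str = "interneuron") -> Session:
    """Fill ``session.traces.dff`` (and the transient mask for principal cells).

    ``mode='interneuron'`` divides each contiguous recording segment by its
    8th-percentile fluorescence and analyzes the continuous trace;
    ``mode='principal'`` applies sliding-percentile drift correction and
    baseline division, calibrates transient detection to a false-positive
    ratio below the configured target, and masks everything outside
    significant transients to zero.
    """
    raw = session.traces.raw_f
    gap = session.behavior.recording_gap
    if mode == "interneuron":
        dff = dff_segment_percentile(raw, _nongap_segments(gap),
                                     pct=cfg.dff_percentile)
        dff = np.nan_to_num(dff, nan=1.0)   # gap frames; excluded downstream
        session.traces.dff = dff
        session.traces.transient_mask = np.zeros_like(dff, dtype=bool)
    elif mode == "principal":
        dff = dff_sliding_percentile(raw, session.traces.fs,
                                     window_s=cfg.dff_window_s,
                                     pct=cfg.dff_percentile,
                                     recording_gap=gap,
                                     sd_cut=cfg.baseline_sd_cut)
        params = calibrate_transient_params(dff, session.traces.fs, cfg)
        events = detect_transients(dff, session.traces.fs, params,
                                   sd_cut=cfg.baseline_sd_cut)
        session.traces.dff = dff
        session.traces.transient_mask = events.mask
        session.provenance["transient_params"] = (
            f"{params.onset_threshold}sd/{params.min_duration}s"
            f"/fpr={params.achieved_fpr:.4f}"
        )
    else:
        raise ValueError("mode must be 'interneuron' or 'principal'")
    return session


def analyze_session(
    session: Session,
    cfg: AnalysisConfig,
    seed: int,
    mode: str = "interneuron",
    metrics: tuple[str, ...] = ("si", "coherence", "vector_length", "stability"),
) -> pd.DataFrame:
    """Full per-cell analysis of one session; one row per cell per context."""
    rng = np.random.default_rng(seed)
    if session.traces.dff is None:
        preprocess_session(session, cfg, mode=mode)
    beh = session.behavior
    dff = session.traces.dff
    activity = np.where(session.traces.transient_mask, dff, 0.0) \
        if mode == "principal" else dff

    h1, h2 = split_halves(beh)
    contexts = segment_contexts(beh)
    cell_ids = [m.cell_id for m in session.meta] or [
        f"cell{i:04d}" for i in range(session.n_cells)
    ]
    rows = []
    for ctx, idx in contexts.items():
        pos = beh.position[idx]
        spd = beh.speed[idx]
        act = activity[:, idx]
        raw_dff = dff[:, idx]
        move = movement_mask(spd, cfg.speed_threshold_cm_s)
        still = immobility_mask(spd, cfg.speed_threshold_cm_s)
        halves = (h1[idx], h2[idx])
        nulls = circular_shuffle_null(
            act, pos, move, beh.track_length_cm, cfg.fs_hz,
            metrics=metrics, bin_w=cfg.spatial_bin_cm,
            circular=cfg.circular_track, n_shuffles=cfg.n_shuffles,
            min_shift_s=cfg.min_shift_s, halves=halves, rng=rng,
            percentile=cfg.significance_percentile,
        )
        if mode == "principal":
            ev = detect_transients(raw_dff, session.traces.fs,
                                   _calibrated(session, cfg, raw_dff),
                                   sd_cut=cfg.baseline_sd_cut)
            rates = transient_rate(ev, move, cfg.fs_hz)
        else:
            rates = np.full(session.n_cells, np.nan)
        for c in range(session.n_cells):
            st = speed_tuning(raw_dff[c], spd, move,
                              bin_w=cfg.speed_bin_cm_s,
                              min_bin_time_s=cfg.min_speed_bin_time_s,
                              fs=cfg.fs_hz, alpha=cfg.alpha)
            row = {
                "cell_id": cell_ids[c],
                "context": ctx,
                "speed_slope": st.slope,
                "speed_r": st.pearson_r,
                "speed_p": st.p_value,
                "speed_class": st.modulation_class,
                "move_immobile_ratio": move_immobile_ratio(raw_dff[c], move, still),
                "transient_rate": rates[c],
            }
            for m in metrics:
                null = nulls[m][c]
                row[m] = null.true_value
                row[f"{m}_pct"] = null.percentile_of_true
                row[f"{m}_significant"] = null.significant
            if mode == "principal" and "si" in metrics:
                row["is_place_cell"] = bool(
                    nulls["si"][c].significant
                    and np.isfinite(rates[c])
                    and rates[c] >= cfg.place_cell_min_rate_per_min
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["seed"] = int(seed)
    df.attrs["config_hash"] = config_hash(cfg)
    df.attrs["session_seed"] = session.provenance.get("seed")
    return df


def _calibrated(session: Session, cfg: AnalysisConfig, dff: np.ndarray):
    from .signals import TransientParams
    tag = session.provenance.get("transient_params")
    if tag:
        thr_s, dur_s = tag.split("/")[:2]
        return TransientParams(float(thr_s.rstrip("sd")), float(dur_s.rstrip("s")),
                               offset_fraction=cfg.offset_fraction)
    return calibrate_transient_params(dff, session.traces.fs, cfg)
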