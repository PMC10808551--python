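"""Session container: behavior, fluorescence traces, cell metadata, HDF5 I/O.

A :class:`Session` bundles everything recorded in one imaging run:

* :class:`BehaviorTrace` — time, track position, running speed, context
  label, trial index, and a flag for teleport/blank intervals during which
  the acquisition system logged no behavior,
* :class:`CellTraces` — raw fluorescence per cell per frame, later filled
  with dF/F and a transient mask by the signal-processing stage,
* a list of :class:`CellMeta` records, and
* provenance (random seed and config hash) that is propagated to every
  result table derived from the session.

The on-disk format is a plain HDF5 container with groups ``/behavior``,
``/traces`` and ``/meta``; ``read_session`` / ``write_session`` round-trip
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "BehaviorTrace",
    "CellTraces",
    "CellMeta",
    "Session",
    "read_session",
    "write_session",
]


class SessionFormatError(ValueError):
    """Raised when an on-disk container is missing datasets or malformed."""


@dataclass
class BehaviorTrace:
    """Time-aligned behavior for one session.

    All arrays share one length (the frame count). ``position`` is in cm in
    [0, L) and wraps modulo the track length on circular tracks; ``speed``
    is cm/s and never negative; ``recording_gap`` marks teleport/blank
    frames that are excluded from every analysis.
    """

    t: np.ndarray                 # s, monotonically increasing
    position: np.ndarray          # cm in [0, L)
    speed: np.ndarray             # cm/s, >= 0
    context_id: np.ndarray        # str labels, e.g. "familiar"/"novel"
    trial_index: np.ndarray       # int >= 0
    recording_gap: np.ndarray     # bool
    track_length_cm: float = 400.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.context_id = np.asarray(self.context_id, dtype="U32")
        self.trial_index = np.asarray(self.trial_index, dtype=np.int64)
        self.recording_gap = np.asarray(self.recording_gap, dtype=bool)
        n = len(self.t)
        for name in ("position", "speed", "context_id", "trial_index", "recording_gap"):
            if len(getattr(self, name)) != n:
                raise SessionFormatError(
                    f"behavior field '{name}' has length {len(getattr(self, name))}, "
                    f"expected {n}"
                )
        if np.any(~np.isfinite(self.position[~self.recording_gap])):
            raise ValueError("NaN/inf in position outside recording gaps")
        if np.any(~np.isfinite(self.speed[~self.recording_gap])):
            raise ValueError("NaN/inf in speed outside recording gaps")
        if np.any(self.speed[~self.recording_gap] < 0):
            raise ValueError("speed must be non-negative")
        valid = self.position[~self.recording_gap]
        if valid.size and (valid.min() < 0 or valid.max() >= self.track_length_cm):
            raise ValueError("position must lie in [0, track_length)")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t))) if len(self.t) > 1 else np.nan


@dataclass
class CellTraces:
    """Fluorescence traces for all cells of a session (cells x frames)."""

    raw_f: np.ndarray                      # arbitrary units
    fs: float = 10.0                       # Hz, effective per-plane rate
    dff: np.ndarray | None = None          # filled by the signals stage
    transient_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw_f = np.atleast_2d(np.asarray(self.raw_f, dtype=float))
        if not np.all(np.isfinite(self.raw_f)):
            raise ValueError("raw_f must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.dff is not None:
            self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
            if self.dff.shape != self.raw_f.shape:
                raise SessionFormatError("dff shape must match raw_f")
        if self.transient_mask is not None:
            self.transient_mask = np.atleast_2d(
                np.asarray(self.transient_mask, dtype=bool)
            )
            if self.transient_mask.shape != self.raw_f.shape:
                raise SessionFormatError("transient_mask shape must match raw_f")
            if self.dff is None and self.transient_mask.any():
                raise ValueError("transient_mask set without dff")

    @property
    def n_cells(self) -> int:
        return self.raw_f.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raw_f.shape[1]


@dataclass
class CellMeta:
    cell_id: str
    animal_id: str = "animal0"
    session_id: str = "session0"
    region: str = "DG"            # {DG, CA2/3, CA1}
    cell_class: str = "principal"  # {PV, SOM, principal, axon}


@dataclass
class Session:
    """One imaging session with shared timebase between behavior and traces."""

    behavior: BehaviorTrace
    traces: CellTraces
    meta: list[CellMeta] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)   # {"seed": int, "config_hash": str}

    def __post_init__(self) -> None:
        if self.behavior.n_frames != self.traces.n_frames:
            raise SessionFormatError(
                f"behavior has {self.behavior.n_frames} frames but traces have "
                f"{self.traces.n_frames}"
            )
        if self.meta:
            if len(self.meta) != self.traces.n_cells:
                raise SessionFormatError("meta length must equal number of cells")
            ids = {(m.cell_id, m.session_id) for m in self.meta}
            if len(ids) != len(self.meta):
                raise SessionFormatError("(cell_id, session_id) must be unique")

    @property
    def n_cells(self) -> int:
        return self.traces.n_cells

    @property
    def n_frames(self) -> int:
        return self.behavior.n_frames


_BEHAVIOR_KEYS = ("t", "position", "speed", "context_id", "trial_index", "recording_gap")
_META_KEYS = ("cell_id", "animal_id", "session_id", "region", "cell_class")


def write_session(session: Session, path: str | Path, overwrite: bool = False) -> None:
    """Write a session to an HDF5 container (bit-stable for identical input)."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        beh = f.create_group("behavior")
        b = session.behavior
        beh.create_dataset("t", data=b.t)
        beh.create_dataset("position", data=b.position)
        beh.create_dataset("speed", data=b.speed)
        beh.create_dataset("context_id", data=b.context_id.astype(object), dtype=str_dt)
        beh.create_dataset("trial_index", data=b.trial_index)
        beh.create_dataset("recording_gap", data=b.recording_gap)
        beh.attrs["track_length_cm"] = b.track_length_cm

        tr = f.create_group("traces")
        tr.create_dataset("raw_f", data=session.traces.raw_f)
        tr.create_dataset("fs", data=float(session.traces.fs))
        if session.traces.dff is not None:
            tr.create_dataset("dff", data=session.traces.dff)
        if session.traces.transient_mask is not None:
            tr.create_dataset("transient_mask", data=session.traces.transient_mask)

        meta = f.create_group("meta")
        for key in _META_KEYS:
            vals = np.array([getattr(m, key) for m in session.meta], dtype=object)
            meta.create_dataset(key, data=vals, dtype=str_dt)

        for key, val in session.provenance.items():
            f.attrs[f"provenance_{key}"] = val


def read_session(path: str | Path) -> Session:
    """Read a session written by :func:`write_session`.

    Raises :class:`SessionFormatError` naming the first missing dataset, and
    ``ValueError`` if position or speed contain NaN outside recording gaps.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        for group, keys in (("behavior", _BEHAVIOR_KEYS), ("traces", ("raw_f", "fs"))):
            if group not in f:
                raise SessionFormatError(f"missing group '/{group}'")
            for key in keys:
                if key not in f[group]:
                    raise SessionFormatError(f"missing dataset '/{group}/{key}'")
        beh = f["behavior"]
        behavior = BehaviorTrace(
            t=beh["t"][()],
            position=beh["position"][()],
            speed=beh["speed"][()],
            context_id=np.array([s.decode() if isinstance(s, bytes) else s
                                 for s in beh["context_id"][()]]),
            trial_index=beh["trial_index"][()],
            recording_gap=beh["recording_gap"][()].astype(bool),
            track_length_cm=float(beh.attrs.get("track_length_cm", 400.0)),
        )
        tr = f["traces"]
        traces = CellTraces(
            raw_f=tr["raw_f"][()],
            fs=float(tr["fs"][()]),
            dff=tr["dff"][()] if "dff" in tr else None,
            transient_mask=tr["transient_mask"][()].astype(bool)
            if "transient_mask" in tr else None,
        )
        meta: list[CellMeta] = []
        if "meta" in f and "cell_id" in f["meta"]:
            cols = {}
            for key in _META_KEYS:
                vals = f["meta"][key][()]
                cols[key] = [v.decode() if isinstance(v, bytes) else v for v in vals]
            meta = [
                CellMeta(**{k: cols[k][i] for k in _META_KEYS})
                for i in range(len(cols["cell_id"]))
            ]
        provenance = {
            key[len("provenance_"):]: (val.item() if hasattr(val, "item") else val)
            for key, val in f.attrs.items()
            if key.startswith("provenance_")
        }
    return Session(behavior=behavior, traces=traces, meta=meta, provenance=provenance)
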