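"""Synthetic session generator with known ground truth.

Emulates head-fixed virtual-track sessions: lap-based running with pauses
on a 4-m circular track, alternating familiar/novel context blocks (60-s
blocks, or fixed-lap blocks for the chemogenetic-style design) separated by
short teleport gaps, and cells whose firing combines

* a baseline rate,
* a linear running-speed term (positive, negative, or absent),
* a von-Mises place field on the circular track, and
* a multiplicative context gain applied in the novel context,

``rate(t) = max(0, baseline + slope * speed(t)) * (1 + gain * f_vm(pos(t)))
* context_gain(context(t))``.

Spikes are drawn as an inhomogeneous Poisson process and rendered into raw
fluorescence through a GCaMP6f-like difference-of-exponentials kernel with
slow multiplicative baseline drift and shot noise. Every generated cell's
true parameters are returned as :class:`GroundTruth`, so downstream metric
recovery can be tested against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .config import AnalysisConfig
from .session import BehaviorTrace, CellMeta, CellTraces, Session

__all__ = [
    "SimParams",
    "NoiseModel",
    "GroundTruth",
    "simulate_behavior",
    "sample_population",
    "simulate_spikes",
    "render_fluorescence",
    "simulate_session",
    "von_mises_field",
    "fwhm_to_kappa",
]


@dataclass
class NoiseModel:
    """Forward model from spikes to raw fluorescence.

    ``kernel_rise``/``kernel_decay`` are the time constants of the
    difference-of-exponentials indicator kernel (defaults 0.1 s / 0.7 s,
    GCaMP6f-like). ``spike_amplitude`` scales the unit-peak kernel per
    spike in dF/F units; ``shot_noise_sd`` is additive noise in dF/F units;
    drift is a slow multiplicative baseline wander.
    """

    kernel_rise: float = 0.1          # s
    kernel_decay: float = 0.7         # s
    drift_amplitude: float = 0.1      # fraction of baseline (SD of drift)
    drift_timescale: float = 60.0     # s
    shot_noise_sd: float = 0.15       # dF/F units
    photon_baseline: float = 100.0    # arbitrary units
    spike_amplitude: float = 1.0      # dF/F units per spike (unit-peak kernel)

    def __post_init__(self) -> None:
        for name in ("kernel_rise", "kernel_decay", "drift_amplitude",
                     "drift_timescale", "shot_noise_sd", "photon_baseline",
                     "spike_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.kernel_decay <= self.kernel_rise:
            raise ValueError("kernel_decay must exceed kernel_rise")


@dataclass
class SimParams:
    """Stated world of the generator.

    Defaults: 60-s alternating context blocks, 10 min total on each track,
    <10-s blanked teleports, mean moving speed in the 10-20 cm/s range.
    ``block_mode='laps'`` switches to the fixed-lap design (15 laps per
    context per condition).
    """

    n_cells: int = 50
    block_mode: str = "time"          # "time" (60-s blocks) or "laps"
    block_s: float = 60.0
    n_blocks: int = 20                # 10 min familiar + 10 min novel
    laps_per_block: int = 15
    gap_s: float = 5.0                # blanked teleport between blocks
    contexts: tuple[str, str] = ("familiar", "novel")

    # speed process (Ornstein-Uhlenbeck with a run/pause switch)
    run_speed_cm_s: float = 15.0
    speed_tau_s: float = 2.0
    speed_sigma: float = 6.0
    pause_rate_hz: float = 0.05       # run -> pause switching rate
    resume_rate_hz: float = 0.5       # pause -> run switching rate
    min_run_speed_cm_s: float = 2.5   # floor while in the run state

    # population mixture
    frac_speed_positive: float = 0.4
    frac_speed_negative: float = 0.3
    frac_speed_none: float = 0.3
    place_fraction: float = 0.3

    # per-cell parameter distributions (log-normal medians / sigmas)
    baseline_rate_median: float = 0.3       # events/s
    baseline_rate_sigma: float = 0.5
    speed_slope_median: float = 0.02        # (events/s) per (cm/s)
    speed_slope_sigma: float = 0.4
    field_width_median_cm: float = 40.0     # FWHM
    field_width_sigma: float = 0.3
    field_gain_shape: float = 2.0           # gamma, mean = shape*scale
    field_gain_scale: float = 1.5
    context_gain_sigma: float = 0.4         # log-normal around 1

    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        fr = self.frac_speed_positive + self.frac_speed_negative + self.frac_speed_none
        if abs(fr - 1.0) > 1e-9:
            raise ValueError("speed-class fractions must sum to 1")
        if not 0 <= self.place_fraction <= 1:
            raise ValueError("place_fraction must be in [0, 1]")
        if self.block_mode not in ("time", "laps"):
            raise ValueError("block_mode must be 'time' or 'laps'")
        if self.block_s <= 0 or self.n_blocks <= 0 or self.gap_s < 0:
            raise ValueError("non-positive block structure")


@dataclass
class GroundTruth:
    """True per-cell parameters of a simulated population."""

    baseline_rate: np.ndarray     # events/s
    speed_slope: np.ndarray       # (events/s)/(cm/s), signed
    field_center: np.ndarray      # cm in [0, L)
    field_width: np.ndarray       # cm (FWHM)
    field_gain: np.ndarray        # dimensionless >= 0
    context_gain: np.ndarray      # multiplier in the novel context
    spike_times: list[np.ndarray] | None = None   # s, per cell

    @property
    def n_cells(self) -> int:
        return len(self.baseline_rate)


def fwhm_to_kappa(width_cm: float | np.ndarray, track_length_cm: float) -> np.ndarray:
    """Von-Mises concentration giving a field of the requested FWHM (cm)."""
    half_angle = np.pi * np.asarray(width_cm, dtype=float) / track_length_cm
    return np.log(2.0) / (1.0 - np.cos(half_angle))


def von_mises_field(position_cm: np.ndarray, center_cm: float, width_cm: float,
                    track_length_cm: float) -> np.ndarray:
    """Unit-peak von-Mises bump on the circular track, FWHM ``width_cm``."""
    theta = 2 * np.pi * (np.asarray(position_cm, dtype=float) - center_cm) / track_length_cm
    kappa = fwhm_to_kappa(width_cm, track_length_cm)
    return np.exp(kappa * (np.cos(theta) - 1.0))


def _speed_process(n: int, dt: float, p: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Run/pause two-state OU speed trace, cm/s, clipped at the run floor."""
    v = np.empty(n)
    running = True
    cur = p.run_speed_cm_s
    a = dt / p.speed_tau_s
    noise = p.speed_sigma * math.sqrt(dt) * rng.standard_normal(n)
    switch = rng.random(n)
    for i in range(n):
        if running and switch[i] < p.pause_rate_hz * dt:
            running = False
        elif not running and switch[i] < p.resume_rate_hz * dt:
            running = True
        target = p.run_speed_cm_s if running else 0.0
        cur = cur + a * (target - cur) + noise[i]
        cur = max(cur, p.min_run_speed_cm_s) if running else max(cur, 0.0)
        v[i] = cur
    return v


def simulate_behavior(params: SimParams, cfg: AnalysisConfig,
                      rng: np.random.Generator) -> BehaviorTrace:
    """Simulate lap-based running over alternating context blocks.

    Position is the integral of the speed trace (wrapped to the track
    length); each block restarts at the track start ("teleport"). Blocks
    are separated by ``gap_s`` of recording-gap frames carrying no
    behavior. In time mode a trial is one context block; in laps mode a
    trial is one lap.
    """
    dt = 1.0 / cfg.fs_hz
    L = cfg.track_length_cm
    n_gap = int(round(params.gap_s * cfg.fs_hz))
    t_list, pos_list, spd_list, ctx_list, trial_list, gap_list = [], [], [], [], [], []
    t0 = 0.0
    trial_counter = 0

    for b in range(params.n_blocks):
        ctx = params.contexts[b % len(params.contexts)]
        if params.block_mode == "time":
            n = int(round(params.block_s * cfg.fs_hz))
            if n < 1:
                raise ValueError("block duration must cover at least one frame")
            v = _speed_process(n, dt, params, rng)
            unwrapped = np.cumsum(v) * dt
            trial = np.full(n, trial_counter)
            trial_counter += 1
        else:  # fixed number of laps; cap the block at a generous duration
            n_max = int(params.laps_per_block * L / params.min_run_speed_cm_s * cfg.fs_hz)
            v = _speed_process(n_max, dt, params, rng)
            unwrapped = np.cumsum(v) * dt
            done = np.searchsorted(unwrapped, params.laps_per_block * L)
            n = min(done + 1, n_max)
            v, unwrapped = v[:n], unwrapped[:n]
            lap = np.minimum(
                (unwrapped // L).astype(np.int64), params.laps_per_block - 1
            )
            trial = trial_counter + lap
            trial_counter = int(trial[-1]) + 1
        pos = np.mod(unwrapped, L)
        t_list.append(t0 + dt * np.arange(n))
        pos_list.append(pos)
        spd_list.append(v)
        ctx_list.append(np.full(n, ctx, dtype="U32"))
        trial_list.append(trial)
        gap_list.append(np.zeros(n, dtype=bool))
        t0 = t_list[-1][-1] + dt
        if n_gap and b < params.n_blocks - 1:
            t_list.append(t0 + dt * np.arange(n_gap))
            pos_list.append(np.zeros(n_gap))
            spd_list.append(np.zeros(n_gap))
            ctx_list.append(np.full(n_gap, ctx, dtype="U32"))
            trial_list.append(np.full(n_gap, trial_counter - 1))
            gap_list.append(np.ones(n_gap, dtype=bool))
            t0 = t_list[-1][-1] + dt

    return BehaviorTrace(
        t=np.concatenate(t_list),
        position=np.concatenate(pos_list),
        speed=np.concatenate(spd_list),
        context_id=np.concatenate(ctx_list),
        trial_index=np.concatenate(trial_list),
        recording_gap=np.concatenate(gap_list),
        track_length_cm=L,
    )


def sample_population(params: SimParams, cfg: AnalysisConfig,
                      rng: np.random.Generator) -> GroundTruth:
    """Draw per-cell ground-truth parameters from the configured mixture."""
    n = params.n_cells
    classes = rng.choice(
        3, size=n,
        p=[params.frac_speed_positive, params.frac_speed_negative,
           params.frac_speed_none],
    )
    slope_mag = params.speed_slope_median * np.exp(
        params.speed_slope_sigma * rng.standard_normal(n)
    )
    slope = np.where(classes == 0, slope_mag, np.where(classes == 1, -slope_mag, 0.0))
    is_place = rng.random(n) < params.place_fraction
    gain = np.where(
        is_place,
        rng.gamma(params.field_gain_shape, params.field_gain_scale, size=n),
        0.0,
    )
    return GroundTruth(
        baseline_rate=params.baseline_rate_median
        * np.exp(params.baseline_rate_sigma * rng.standard_normal(n)),
        speed_slope=slope,
        field_center=rng.uniform(0.0, cfg.track_length_cm, size=n),
        field_width=params.field_width_median_cm
        * np.exp(params.field_width_sigma * rng.standard_normal(n)),
        field_gain=gain,
        context_gain=np.exp(params.context_gain_sigma * rng.standard_normal(n)),
    )


def cell_rate(behavior: BehaviorTrace, gt: GroundTruth, i: int,
              novel_label: str = "novel") -> np.ndarray:
    """Instantaneous firing rate (events/s) of cell ``i`` along the session."""
    base = np.maximum(0.0, gt.baseline_rate[i] + gt.speed_slope[i] * behavior.speed)
    if gt.field_gain[i] > 0:
        bump = von_mises_field(behavior.position, gt.field_center[i],
                               gt.field_width[i], behavior.track_length_cm)
        base = base * (1.0 + gt.field_gain[i] * bump)
    gain = np.where(behavior.context_id == novel_label, gt.context_gain[i], 1.0)
    rate = base * gain
    rate[behavior.recording_gap] = np.maximum(0.0, gt.baseline_rate[i])
    return rate


def simulate_spikes(behavior: BehaviorTrace, gt: GroundTruth,
                    rng: np.random.Generator, novel_label: str = "novel") -> GroundTruth:
    """Draw inhomogeneous Poisson spikes for every cell (frame-resolution rate).

    Counts per frame are Poisson(rate * dt) with spike times jittered
    uniformly inside the frame; as the session grows the empirical rate in
    any window converges to the theoretical rate.
    """
    dt = behavior.dt
    spike_times: list[np.ndarray] = []
    for i in range(gt.n_cells):
        rate = cell_rate(behavior, gt, i, novel_label=novel_label)
        counts = rng.poisson(rate * dt)
        idx = np.repeat(np.arange(behavior.n_frames), counts)
        times = behavior.t[idx] + rng.uniform(0.0, dt, size=idx.size)
        spike_times.append(np.sort(times))
    gt.spike_times = spike_times
    return gt


def _kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference of exponentials normalized to unit peak; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    raw = np.where(t >= 0, np.exp(-t / decay) - np.exp(-t / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * math.log(decay / rise)
    peak = math.exp(-t_peak / decay) - math.exp(-t_peak / rise)
    return raw / peak


def render_fluorescence(spike_times: list[np.ndarray], noise: NoiseModel,
                        fs: float, n_frames: int,
                        rng: np.random.Generator) -> CellTraces:
    """Render spike trains into raw fluorescence traces.

    ``raw_f = B * (1 + drift(t)) * (1 + a * sum_k kernel(t - t_k)) + noise``
    with ``B`` the photon baseline, ``a`` the per-spike amplitude, a
    unit-peak difference-of-exponentials kernel and Gaussian shot noise of
    SD ``shot_noise_sd * B``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    dt = 1.0 / fs
    t_grid = dt * np.arange(n_frames)
    # truncating at 25 decay constants leaves a tail < 1e-10 of the peak
    support = int(math.ceil(25.0 * noise.kernel_decay * fs)) + 1
    raw = np.empty((len(spike_times), n_frames))
    for i, times in enumerate(spike_times):
        sig = np.zeros(n_frames)
        for ts in np.asarray(times, dtype=float):
            j0 = int(math.ceil(ts * fs))
            if j0 >= n_frames:
                continue
            j1 = min(j0 + support, n_frames)
            sig[j0:j1] += _kernel(t_grid[j0:j1] - ts, noise.kernel_rise,
                                  noise.kernel_decay)
        if noise.drift_amplitude > 0:
            # stationary AR(1): x_k = a x_{k-1} + sqrt(1-a^2) eps_k, SD 1
            a = math.exp(-dt / noise.drift_timescale)
            eps = rng.standard_normal(n_frames)
            eps[0] /= math.sqrt(1 - a * a)
            drift = noise.drift_amplitude * math.sqrt(1 - a * a) * lfilter(
                [1.0], [1.0, -a], eps
            )
        else:
            drift = np.zeros(n_frames)
        trace = noise.photon_baseline * (1.0 + drift) * (1.0 + noise.spike_amplitude * sig)
        if noise.shot_noise_sd > 0:
            trace = trace + noise.shot_noise_sd * noise.photon_baseline \
                * rng.standard_normal(n_frames)
        raw[i] = trace
    return CellTraces(raw_f=raw, fs=fs)


def simulate_session(params: SimParams, cfg: AnalysisConfig,
                     seed: int) -> tuple[Session, GroundTruth]:
    """End-to-end generation of one session plus its ground truth."""
    rng = np.random.default_rng(seed)
    behavior = simulate_behavior(params, cfg, rng)
    gt = sample_population(params, cfg, rng)
    gt = simulate_spikes(behavior, gt, rng)
    traces = render_fluorescence(gt.spike_times, params.noise, cfg.fs_hz,
                                 behavior.n_frames, rng)
    meta = [CellMeta(cell_id=f"cell{i:04d}", session_id=f"sim-{seed}")
            for i in range(params.n_cells)]
    from .config import config_hash
    session = Session(
        behavior=behavior, traces=traces, meta=meta,
        provenance={"seed": int(seed), "config_hash": config_hash(cfg)},
    )
    return session, gt
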