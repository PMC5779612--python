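"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the study's raw data with ground truth attached:

* an alternating wake/sleep bout process with day/night modulation,
  producing a labeled single-fly trajectory in a 65-mm tube;
* grayscale video frames of a bright fly blob on a noisy dark background
  (the tracker's input);
* per-minute midline beam-crossing counts (Drosophila Activity Monitor
  style, the sleep scorer's input);
* membrane-potential traces with Poisson spikes at UP/DOWN-state rates
  (~17 Hz vs < 1 Hz on baselines ~11 mV apart) and EPSP trains whose rate
  rises inside photostimulation windows.

Every generator is a deterministic function of its parameters and an
integer seed; per-fly sub-streams derive from one global seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .ephys import VmTrace
from .sleep import ActivitySeries
from .tracker import FrameStack

__all__ = [
    "BehaviorParams",
    "ArenaSpec",
    "VideoParams",
    "EphysParams",
    "SpikeShape",
    "EpspShape",
    "LabeledTrajectory",
    "simulate_behavior",
    "render_frames",
    "beam_counts",
    "crossing_counts",
    "midline_crossing_times",
    "simulate_vm",
    "fly_rng",
    "write_trajectory_csv",
    "write_dam_tsv",
]

SECONDS_PER_DAY = 86_400.0


def fly_rng(seed: int, fly_index: int = 0) -> np.random.Generator:
    """Deterministic per-fly random stream derived from one global seed."""
    return np.random.default_rng([int(seed), int(fly_index)])


# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------

@dataclass
class BehaviorParams:
    """Two-state (wake/sleep) renewal process with diel modulation.

    Bout lengths are drawn from ``bout_length_law`` ("exponential" or
    "lognormal" with log-sd ``dispersion``).  Sleep bouts carry a hard
    ``min_sleep_s`` minimum (the draw is shifted so the mean is
    preserved), keeping every generated sleep bout scoreable under the
    5-min rule; with ``enforce_min_sleep=False`` sub-minimum draws are
    emitted as kind ``"rest"`` without the asleep label.
    ``diel_modulation`` multiplies the sleep-initiation hazard per clock
    hour, so wake bouts stretch in hours where it is low and sleep can
    never start in hours where it is zero.
    """

    wake_bout_mean: float = 600.0  # s
    sleep_bout_mean: float = 1200.0  # s
    bout_length_law: str = "exponential"
    dispersion: float = 0.5  # log-sd for the lognormal law
    move_rate_awake: float = 0.2  # movements per second while awake
    step_mean_mm: float = 4.0  # mean per-movement displacement
    lights_on: float = 8.0  # clock hour
    lights_off: float = 20.0
    diel_modulation: tuple[float, ...] = tuple([1.0] * 24)
    start_clock_h: float = 8.0  # clock time at t = 0
    min_sleep_s: float = 300.0
    enforce_min_sleep: bool = True
    tube_length_mm: float = 65.0
    y_center_mm: float = 5.0
    y_jitter_mm: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wake_bout_mean <= 0:
            raise ValueError("wake_bout_mean must be positive")
        if self.sleep_bout_mean < self.min_sleep_s:
            raise ValueError(
                f"sleep_bout_mean must be >= {self.min_sleep_s} s so that "
                "generated sleep bouts are scoreable"
            )
        if self.bout_length_law not in ("exponential", "lognormal"):
            raise ValueError("bout_length_law must be 'exponential' or 'lognormal'")
        if len(self.diel_modulation) != 24 or any(m < 0 for m in self.diel_modulation):
            raise ValueError("diel_modulation needs 24 non-negative entries")


@dataclass
class ArenaSpec:
    """Geometry and acquisition parameters of the single-fly tube arena."""

    tube_length_mm: float = 65.0
    tube_width_mm: float = 10.0
    px_per_mm: float = 4.0
    frame_rate: float = 5.0  # Hz
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.tube_length_mm <= 0 or self.px_per_mm <= 0:
            raise ValueError("tube_length_mm and px_per_mm must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass
class VideoParams:
    """Appearance of the rendered fly blob and imaging noise."""

    blob_radius_mm: float = 0.6  # Gaussian sigma of the blob (~fly-sized)
    blob_intensity: float = 120.0  # gray levels above background
    noise_sigma: float = 3.0  # gray levels
    background_level: float = 20.0
    background_drift: float = 0.0  # gray levels per frame

    def __post_init__(self) -> None:
        if self.noise_sigma > 0 and self.blob_intensity <= 3 * self.noise_sigma:
            raise ValueError("blob_intensity must exceed 3 x noise_sigma for detectability")


@dataclass
class SpikeShape:
    amplitude_mV: float = 45.0
    width_ms: float = 0.5  # Gaussian sigma


@dataclass
class EpspShape:
    amplitude_mV: float = 4.0
    rise_ms: float = 1.5
    decay_ms: float = 8.0


@dataclass
class EphysParams:
    """Defaults mirror the recorded helicon/R2 statistics: UP firing at
    16.9 Hz, DOWN < 1 Hz, baselines 10.9 mV apart, EPSPs at 9.44 Hz
    rising to 15.33 Hz under photostimulation with a 5.30-mV evoked
    depolarization."""

    up_rate: float = 16.9  # Hz
    down_rate: float = 0.5  # Hz, must stay below 1
    baseline_separation: float = 10.9  # mV
    epsp_rate_baseline: float = 9.44  # Hz
    epsp_rate_stim: float = 15.33  # Hz
    evoked_depol: float = 5.30  # mV during stimulation windows
    resting_mV: float = -62.0  # DOWN-state baseline
    spike_template: SpikeShape = field(default_factory=SpikeShape)
    epsp_template: EpspShape = field(default_factory=EpspShape)
    sample_rate: float = 10_000.0  # Hz
    noise_sigma: float = 0.4  # mV

    def __post_init__(self) -> None:
        if not self.down_rate < 1.0:
            raise ValueError("down_rate must be < 1 Hz (the DOWN-state criterion)")
        if not self.up_rate > self.down_rate:
            raise ValueError("up_rate must exceed down_rate")
        if self.sample_rate < 10_000.0:
            raise ValueError("sample_rate must be at least 10 kHz")


@dataclass
class LabeledTrajectory:
    """Time-stamped fly positions with ground-truth state and bout labels."""

    t: np.ndarray  # s, strictly increasing
    x_mm: np.ndarray  # along the tube, in [0, tube_length]
    y_mm: np.ndarray  # across the tube
    asleep: np.ndarray  # bool per sample
    bouts: list[tuple[float, float, str]]  # (start, end, "wake"|"sleep"|"rest")
    tube_length_mm: float
    start_clock_h: float = 8.0
    move_times: np.ndarray = field(default_factory=lambda: np.empty(0))  # truth movement times, s

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.asleep = np.asarray(self.asleep, dtype=bool)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.x_mm < -1e-9) or np.any(self.x_mm > self.tube_length_mm + 1e-9):
            raise ValueError("x positions must lie within [0, tube_length]")

    def __len__(self) -> int:
        return len(self.t)


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def _draw_duration(rng: np.random.Generator, law: str, mean: float, dispersion: float) -> float:
    if mean <= 0:
        return 0.0
    if law == "exponential":
        return float(rng.exponential(mean))
    mu = math.log(mean) - dispersion**2 / 2.0
    return float(rng.lognormal(mu, dispersion))


def _modulated_wake_length(
    t0: float, need: float, diel: tuple[float, ...], start_clock_h: float
) -> float:
    """Wall-clock wake duration that consumes hazard exposure ``need``.

    The sleep-initiation hazard is scaled by the diel multiplier of the
    current clock hour, so the wake bout ends once the time-integral of
    the multiplier reaches the drawn exposure.  Returns inf when the
    modulation is zero everywhere (sleep can never start).
    """
    if all(m == 0 for m in diel):
        return math.inf
    t = t0
    remaining = need
    while True:
        clock = (start_clock_h * 3600.0 + t) % SECONDS_PER_DAY
        hour = int(clock // 3600.0)
        to_boundary = 3600.0 - (clock % 3600.0)
        m = diel[hour]
        if m > 0 and m * to_boundary >= remaining:
            return t + remaining / m - t0
        remaining -= m * to_boundary
        t += to_boundary


def simulate_behavior(
    params: BehaviorParams,
    duration: float,
    seed: int | None = None,
    sample_hz: float = 5.0,
) -> LabeledTrajectory:
    """Simulate an alternating wake/sleep bout process with movements.

    The fly alternates wake and quiescent bouts drawn from the configured
    law.  During wake, movements occur as a Poisson process at
    ``move_rate_awake``; each movement displaces the fly along the tube
    by a signed exponential step (reflected at the walls) and jitters its
    transverse position.  During sleep (and rest) the position is frozen,
    so displacement is exactly zero inside every truth sleep bout.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    # --- bout skeleton -----------------------------------------------------
    # The alternation is started a few mean cycles before t = 0 so that the
    # observed window samples the stationary regime rather than a process
    # that always begins awake (which would bias the asleep fraction low).
    burn_in = 10.0 * (params.wake_bout_mean + params.sleep_bout_mean)
    raw_bouts: list[tuple[float, float, str]] = []
    t = -burn_in
    while t < duration:
        need = _draw_duration(rng, params.bout_length_law, params.wake_bout_mean, params.dispersion)
        w = _modulated_wake_length(t, need, params.diel_modulation, params.start_clock_h)
        w_end = min(t + w, duration)
        if w_end > t:
            raw_bouts.append((t, w_end, "wake"))
        t = w_end
        if t >= duration:
            break
        if params.enforce_min_sleep:
            q = params.min_sleep_s + _draw_duration(
                rng, params.bout_length_law,
                params.sleep_bout_mean - params.min_sleep_s, params.dispersion,
            )
            kind = "sleep"
        else:
            q = _draw_duration(rng, params.bout_length_law, params.sleep_bout_mean, params.dispersion)
            kind = "sleep" if q >= params.min_sleep_s else "rest"
        raw_bouts.append((t, min(t + q, duration), kind))
        t = min(t + q, duration)
    bouts = [
        (max(s, 0.0), e, kind) for s, e, kind in raw_bouts if e > 0.0
    ]

    # --- movements within wake bouts --------------------------------------
    L = params.tube_length_mm
    move_times: list[float] = []
    move_x: list[float] = [L / 2.0]  # position after each movement; [0] = start
    move_y: list[float] = [params.y_center_mm]
    for b_start, b_end, kind in bouts:
        if kind != "wake" or params.move_rate_awake <= 0:
            continue
        tm = b_start + rng.exponential(1.0 / params.move_rate_awake)
        while tm < b_end:
            step = rng.exponential(params.step_mean_mm) * (1 if rng.random() < 0.5 else -1)
            x = move_x[-1] + step
            while x < 0 or x > L:  # reflect at the tube walls
                x = -x if x < 0 else 2 * L - x
            move_times.append(tm)
            move_x.append(x)
            move_y.append(
                float(np.clip(
                    params.y_center_mm + rng.normal(0, params.y_jitter_mm),
                    0.0, 2 * params.y_center_mm,
                ))
            )
            tm += rng.exponential(1.0 / params.move_rate_awake)

    # --- sample the piecewise-constant path --------------------------------
    ts = np.arange(0.0, duration, 1.0 / sample_hz)
    idx = np.searchsorted(np.asarray(move_times), ts, side="right")
    xs = np.asarray(move_x)[idx]
    ys = np.asarray(move_y)[idx]
    asleep = np.zeros(len(ts), dtype=bool)
    for b_start, b_end, kind in bouts:
        if kind == "sleep":
            asleep |= (ts >= b_start) & (ts < b_end)
    return LabeledTrajectory(
        ts, xs, ys, asleep, bouts, tube_length_mm=L,
        start_clock_h=params.start_clock_h, move_times=np.asarray(move_times),
    )


# ---------------------------------------------------------------------------
# Video rendering
# ---------------------------------------------------------------------------

def render_frames(
    traj: LabeledTrajectory,
    arena: ArenaSpec,
    vparams: VideoParams,
    seed: int = 0,
) -> FrameStack:
    """Render one grayscale frame per trajectory sample.

    A Gaussian blob of sigma ``blob_radius_mm`` and peak
    ``blob_intensity`` gray levels is drawn at the true position on a
    (possibly drifting) background with additive Gaussian noise, then
    quantized to the arena bit depth.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    W = int(round(arena.tube_length_mm * arena.px_per_mm))
    H = int(round(arena.tube_width_mm * arena.px_per_mm))
    if np.any(traj.y_mm < -1e-9) or np.any(traj.y_mm > arena.tube_width_mm + 1e-9):
        raise ValueError("trajectory y positions fall outside the arena")
    if np.any(traj.x_mm > arena.tube_length_mm + 1e-9):
        raise ValueError("trajectory x positions fall outside the arena")
    sigma_px = vparams.blob_radius_mm * arena.px_per_mm
    xx = np.arange(W)[None, :]
    yy = np.arange(H)[:, None]
    maxval = 255 if arena.bit_depth == 8 else 65_535
    dtype = np.uint8 if arena.bit_depth == 8 else np.uint16
    frames = np.empty((len(traj), H, W), dtype=dtype)
    for i in range(len(traj)):
        cx = traj.x_mm[i] * arena.px_per_mm
        cy = traj.y_mm[i] * arena.px_per_mm
        img = np.full((H, W), vparams.background_level + vparams.background_drift * i)
        img += vparams.blob_intensity * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma_px**2)
        )
        if vparams.noise_sigma > 0:
            img += rng.normal(0.0, vparams.noise_sigma, size=(H, W))
        frames[i] = np.clip(np.rint(img), 0, maxval).astype(dtype)
    # frame times follow the trajectory sampling; report its mean rate
    rate = 1.0 / float(np.mean(np.diff(traj.t))) if len(traj) > 1 else arena.frame_rate
    return FrameStack(frames, frame_rate=rate, px_per_mm=arena.px_per_mm)


# ---------------------------------------------------------------------------
# Beam counts
# ---------------------------------------------------------------------------

def midline_crossing_times(traj: LabeledTrajectory) -> np.ndarray:
    """Times at which the fly crosses the tube midline (x = L/2).

    A sample sitting exactly on the midline keeps its previous side, so
    touching the beam without passing it does not count.
    """
    side = np.sign(traj.x_mm - traj.tube_length_mm / 2.0)
    for i in range(1, len(side)):
        if side[i] == 0:
            side[i] = side[i - 1]
    crossings = np.flatnonzero(side[1:] * side[:-1] < 0) + 1
    return traj.t[crossings]


def crossing_counts(traj: LabeledTrajectory, bin_s: float) -> np.ndarray:
    """Midline crossings per bin of arbitrary width (totals conserved)."""
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    times = midline_crossing_times(traj)
    n_bins = int(math.ceil((traj.t[-1] + 1e-9) / bin_s))
    counts = np.zeros(max(n_bins, 1), dtype=int)
    for t in times:
        counts[min(int(t // bin_s), len(counts) - 1)] += 1
    return counts


def beam_counts(
    traj: LabeledTrajectory,
    start: str | pd.Timestamp | None = None,
    fly_id: str = "fly0",
    lights_on: float = 8.0,
    lights_off: float = 20.0,
) -> ActivitySeries:
    """Per-minute midline-crossing counts, emulating a beam monitor."""
    counts = crossing_counts(traj, 60.0)
    if start is None:
        h = int(traj.start_clock_h)
        m = int(round((traj.start_clock_h - h) * 60))
        start = pd.Timestamp(f"2021-01-01 {h:02d}:{m:02d}")
    return ActivitySeries.from_counts(
        counts, start=start, fly_id=fly_id, lights_on=lights_on, lights_off=lights_off
    )


# ---------------------------------------------------------------------------
# Membrane potential
# ---------------------------------------------------------------------------

def _poisson_times(rng: np.random.Generator, rate: float, start: float, end: float) -> np.ndarray:
    if rate <= 0 or end <= start:
        return np.empty(0)
    n = rng.poisson(rate * (end - start))
    return np.sort(rng.uniform(start, end, size=n))


def _add_kernel(vm: np.ndarray, times: np.ndarray, kernel: np.ndarray, fs: float) -> None:
    for t in times:
        i = int(round(t * fs))
        k0 = max(0, -i)  # clip kernels that start before the trace
        i = max(i, 0)
        j = min(i + len(kernel) - k0, len(vm))
        if i < len(vm) and j > i:
            vm[i:j] += kernel[k0 : k0 + (j - i)]


def simulate_vm(
    eparams: EphysParams,
    state_schedule: list[tuple[float, float, str]],
    stim_windows: list[tuple[float, float]],
    duration: float,
    seed: int = 0,
) -> tuple[VmTrace, dict]:
    """Simulate a membrane-potential trace with ground-truth event times.

    The baseline follows the UP/DOWN schedule (levels ``resting_mV`` and
    ``resting_mV + baseline_separation``, smoothed at the transitions);
    spikes are Poisson at the per-state rate; EPSPs are Poisson at
    ``epsp_rate_baseline`` outside and ``epsp_rate_stim`` inside the
    stimulation windows, which also depolarize the baseline by
    ``evoked_depol``.  Returns the trace and a truth dict with the spike
    and EPSP times and the schedule.
    """
    sched = sorted(state_schedule, key=lambda s: s[0])
    pos = 0.0
    for s, e, lab in sched:
        if lab not in ("UP", "DOWN"):
            raise ValueError(f"unknown state label {lab!r}")
        if s < pos - 1e-9:
            raise ValueError("state schedule segments overlap")
        if s > pos + 1e-9:
            raise ValueError("state schedule leaves a gap")
        pos = e
    if abs(pos - duration) > 1e-6:
        raise ValueError("state schedule must cover [0, duration]")

    rng = np.random.default_rng(seed)
    fs = eparams.sample_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    level = np.full(n, eparams.resting_mV)
    for s, e, lab in sched:
        if lab == "UP":
            level[int(s * fs) : int(e * fs)] += eparams.baseline_separation
    for s, e in stim_windows:
        level[int(s * fs) : int(e * fs)] += eparams.evoked_depol
    vm = gaussian_filter1d(level, sigma=max(1.0, 0.02 * fs))  # ~20 ms transitions

    spike_times = np.sort(
        np.concatenate(
            [
                _poisson_times(rng, eparams.up_rate if lab == "UP" else eparams.down_rate, s, e)
                for s, e, lab in sched
            ]
        )
    ) if sched else np.empty(0)
    sp = eparams.spike_template
    half = int(round(4 * sp.width_ms / 1000.0 * fs))
    k_t = (np.arange(2 * half + 1) - half) / fs
    spike_kernel = sp.amplitude_mV * np.exp(-(k_t**2) / (2 * (sp.width_ms / 1000.0) ** 2))
    _add_kernel(vm, spike_times - half / fs, spike_kernel, fs)

    ep = eparams.epsp_template
    bounds = sorted({0.0, duration} | {b for w in stim_windows for b in w[:2]})
    epsp_parts = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = (lo + hi) / 2.0
        inside = any(s <= mid < e for s, e in stim_windows)
        rate = eparams.epsp_rate_stim if inside else eparams.epsp_rate_baseline
        epsp_parts.append(_poisson_times(rng, rate, lo, hi))
    epsp_times = np.sort(np.concatenate(epsp_parts)) if epsp_parts else np.empty(0)
    tau_r, tau_d = ep.rise_ms / 1000.0, ep.decay_ms / 1000.0
    k_t = np.arange(int(6 * tau_d * fs)) / fs
    shape = np.exp(-k_t / tau_d) - np.exp(-k_t / tau_r)
    epsp_kernel = ep.amplitude_mV * shape / shape.max()
    _add_kernel(vm, epsp_times, epsp_kernel, fs)

    if eparams.noise_sigma > 0:
        vm = vm + rng.normal(0.0, eparams.noise_sigma, size=n)

    trace = VmTrace(vm, fs, [(s, e, "optogenetic") for s, e in stim_windows])
    truth = {
        "spike_times": spike_times,
        "epsp_times": epsp_times,
        "schedule": sched,
        "stim_windows": list(stim_windows),
    }
    return trace, truth


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_trajectory_csv(traj: LabeledTrajectory, path: str | Path, fly_id: str = "fly0") -> None:
    pd.DataFrame(
        {
            "fly_id": fly_id,
            "t_s": traj.t,
            "x_mm": traj.x_mm,
            "y_mm": traj.y_mm,
            "truth_state": np.where(traj.asleep, "asleep", "awake"),
        }
    ).to_csv(path, index=False)


def write_dam_tsv(series_list: list[ActivitySeries], path: str | Path) -> None:
    """Write channels to a DAM-style TSV: index, date, time, status, counts."""
    if not series_list:
        raise ValueError("need at least one activity series")
    idx = series_list[0].counts.index
    for s in series_list[1:]:
        if not s.counts.index.equals(idx):
            raise ValueError("all channels must share one time base")
    with Path(path).open("w") as fh:
        for i, ts in enumerate(idx):
            cols = [str(i + 1), ts.strftime("%d %b %y"), ts.strftime("%H:%M:%S"), "1"]
            cols += [str(int(s.counts.iloc[i])) for s in series_list]
            fh.write("\t".join(cols) + "\n")


def write_vm_truth_json(truth: dict, path: str | Path) -> None:
    out = {
        "spike_times": [float(x) for x in truth["spike_times"]],
        "epsp_times": [float(x) for x in truth["epsp_times"]],
        "schedule": [[float(s), float(e), lab] for s, e, lab in truth["schedule"]],
        "stim_windows": [[float(s), float(e)] for s, e in truth["stim_windows"]],
    }
    Path(path).write_text(json.dumps(out))
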