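"""Event detection and state-conditioned statistics for membrane potential.

Helicon-class central-complex neurons are bistable: a DOWN state with near
silence (firing rate < 1 Hz) and an UP state of persistent firing (~17 Hz)
sitting on a baseline depolarized by ~11 mV.  This module detects spikes
and EPSPs in whole-cell recordings sampled at 10-20 kHz, segments traces
into UP/DOWN states by a hysteretic firing-rate rule, associates stimuli
with locomotor bouts, and quantifies state-conditioned movement rates and
stimulus-driven EPSP rate modulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "VmTrace",
    "StateSegment",
    "AssociationTable",
    "SpikeDetectConfig",
    "EpspDetectConfig",
    "RateModulation",
    "StateRates",
    "detect_spikes",
    "detect_epsps",
    "segment_states",
    "stimulus_bout_association",
    "state_conditioned_rates",
    "epsp_rate_modulation",
    "read_vm_csv",
    "write_vm_csv",
]

MIN_SAMPLE_RATE = 10_000.0  # Hz; below this detection quality is flagged


@dataclass
class VmTrace:
    """Uniformly sampled membrane potential with stimulus annotations.

    ``stim_windows`` is a list of ``(start_s, end_s, kind)`` with kind
    ``"visual"`` or ``"optogenetic"``; windows must lie within the trace.
    """

    vm_mV: np.ndarray
    sample_rate: float
    stim_windows: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vm_mV = np.asarray(self.vm_mV, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        dur = self.duration
        for s, e, _kind in self.stim_windows:
            if not (0 <= s < e <= dur + 1e-9):
                raise ValueError(f"stimulus window ({s}, {e}) outside trace extent")

    @property
    def duration(self) -> float:
        return len(self.vm_mV) / self.sample_rate

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.vm_mV)) / self.sample_rate


@dataclass
class StateSegment:
    start: float
    end: float
    label: str  # "UP" | "DOWN"
    mean_rate: float = float("nan")  # Hz within the segment
    mean_baseline: float = float("nan")  # mV, median of the raw trace

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class AssociationTable:
    """Bookkeeping for stimulus-evoked vs self-initiated locomotor bouts."""

    n_stimuli: int
    n_associated: int
    n_self_initiated: int
    n_self_up: int
    n_self_down: int
    up_time: float
    down_time: float
    association_window: float

    def __post_init__(self) -> None:
        if self.n_associated > self.n_stimuli:
            raise ValueError("associated count cannot exceed stimulus count")
        if self.n_self_up + self.n_self_down > self.n_self_initiated:
            raise ValueError("UP/DOWN self-initiated counts cannot exceed the total")

    @property
    def probability(self) -> float | None:
        """P(stimulus elicits a bout); None when there are no stimuli."""
        if self.n_stimuli == 0:
            return None
        return self.n_associated / self.n_stimuli


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

@dataclass
class SpikeDetectConfig:
    """Spike detector settings.

    The trace is high-pass filtered (Butterworth, ``highpass_hz``) and
    positive threshold crossings are kept subject to a refractory period.
    ``threshold_mV`` may be a number or ``"auto"`` (``auto_k`` times the
    MAD-based noise estimate of the filtered trace — deterministic).
    """

    highpass_hz: float = 100.0
    threshold_mV: float | str = "auto"
    auto_k: float = 5.0
    min_threshold_mV: float = 5.0  # floor for "auto" on near-noiseless traces
    refractory_ms: float = 2.0


def _highpass(vm: np.ndarray, sample_rate: float, cutoff: float) -> np.ndarray:
    sos = signal.butter(2, cutoff, btype="highpass", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, vm)


def detect_spikes(trace: VmTrace, cfg: SpikeDetectConfig | None = None) -> np.ndarray:
    """Detect spike times (s) by thresholding the high-passed trace.

    Deterministic for a fixed trace and config.  Sampling below 10 kHz is
    allowed but flagged with a warning, since narrow spikes may be missed.
    """
    cfg = cfg or SpikeDetectConfig()
    if trace.sample_rate < MIN_SAMPLE_RATE:
        warnings.warn(
            f"sample rate {trace.sample_rate:.0f} Hz is below the recommended "
            f"{MIN_SAMPLE_RATE:.0f} Hz; spike detection may be unreliable",
            stacklevel=2,
        )
    if len(trace.vm_mV) < 10:
        return np.empty(0)
    hp = _highpass(trace.vm_mV, trace.sample_rate, cfg.highpass_hz)
    if cfg.threshold_mV == "auto":
        mad = np.median(np.abs(hp - np.median(hp)))
        thr = max(cfg.auto_k * 1.4826 * mad, cfg.min_threshold_mV)
    else:
        thr = float(cfg.threshold_mV)
    above = hp > thr
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    # refine each crossing to the local peak, then enforce refractoriness
    refr = cfg.refractory_ms / 1000.0
    times: list[float] = []
    win = max(1, int(round(cfg.refractory_ms / 1000.0 * trace.sample_rate)))
    for i in onsets:
        j = i + np.argmax(hp[i : i + win])
        t = j / trace.sample_rate
        if not times or t - times[-1] >= refr:
            times.append(t)
    return np.asarray(times)


@dataclass
class EpspDetectConfig:
    """EPSP detector: rising-slope template crossing with an amplitude floor.

    An EPSP onset produces a stereotyped positive deflection in the
    smoothed derivative of Vm (height ~ amplitude / rise time), which
    stays distinct even when a second event rides on the decay of the
    first, so closely spaced events remain resolvable down to
    ``min_separation_ms`` (~the rise time).  ``min_slope_mV_per_ms``
    sets the amplitude floor in slope units.
    """

    smooth_ms: float = 1.0
    min_slope_mV_per_ms: float = 0.6
    min_separation_ms: float = 3.0
    lowpass_hz: float = 500.0


def detect_epsps(trace: VmTrace, cfg: EpspDetectConfig | None = None) -> np.ndarray:
    """Detect EPSP onset times (s) as peaks of the smoothed Vm derivative."""
    cfg = cfg or EpspDetectConfig()
    if len(trace.vm_mV) < 10:
        return np.empty(0)
    fs = trace.sample_rate
    sos = signal.butter(2, cfg.lowpass_hz, btype="lowpass", fs=fs, output="sos")
    lp = signal.sosfiltfilt(sos, trace.vm_mV)
    smooth_n = max(1.0, cfg.smooth_ms / 1000.0 * fs)
    from scipy.ndimage import gaussian_filter1d

    dvdt = gaussian_filter1d(np.gradient(lp) * fs, smooth_n) / 1000.0  # mV/ms
    dist = max(1, int(round(cfg.min_separation_ms / 1000.0 * fs)))
    peaks, _props = signal.find_peaks(
        dvdt, height=cfg.min_slope_mV_per_ms, distance=dist
    )
    return peaks / fs


# ---------------------------------------------------------------------------
# UP/DOWN segmentation
# ---------------------------------------------------------------------------

def segment_states(
    spike_times,
    duration: float,
    trace: VmTrace | None = None,
    window: float = 5.0,
    down_ceiling: float = 1.0,
    up_floor: float = 2.0,
    step: float | None = None,
) -> list[StateSegment]:
    """Segment a recording into UP and DOWN states from its firing rate.

    The spike rate in sliding windows is thresholded with hysteresis:
    the trace enters DOWN when the rate falls below ``down_ceiling``
    (1 Hz — the near-silence criterion) and returns to UP only above
    ``up_floor``, which prevents label chatter around the boundary.
    Adjacent same-label windows merge; segments tile [0, duration].
    When ``trace`` is given, each segment's median membrane potential is
    recorded so the ~11-mV baseline separation can corroborate the labels.
    """
    if window < 1.0:
        raise ValueError("window must be at least 1 s")
    if duration < window:
        raise ValueError("trace shorter than one window")
    if not (0 < down_ceiling < up_floor):
        raise ValueError("need 0 < down_ceiling < up_floor")
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    step = step if step is not None else window / 5.0
    centers = np.arange(window / 2.0, duration - window / 2.0 + 1e-9, step)
    if len(centers) == 0:
        centers = np.array([duration / 2.0])
    lo = np.searchsorted(spikes, centers - window / 2.0)
    hi = np.searchsorted(spikes, centers + window / 2.0)
    rates = (hi - lo) / window

    labels = np.empty(len(centers), dtype=object)
    state = "UP" if rates[0] > down_ceiling else "DOWN"
    for k, r in enumerate(rates):
        if state == "UP" and r < down_ceiling:
            state = "DOWN"
        elif state == "DOWN" and r > up_floor:
            state = "UP"
        labels[k] = state

    # merge runs into segments; boundaries at midpoints between window centers
    segs: list[StateSegment] = []
    run_start_idx = 0
    for k in range(1, len(labels) + 1):
        if k == len(labels) or labels[k] != labels[run_start_idx]:
            seg_start = 0.0 if run_start_idx == 0 else float(
                (centers[run_start_idx - 1] + centers[run_start_idx]) / 2.0
            )
            seg_end = duration if k == len(labels) else float((centers[k - 1] + centers[k]) / 2.0)
            segs.append(StateSegment(seg_start, seg_end, str(labels[run_start_idx])))
            run_start_idx = k

    for s in segs:
        n = np.searchsorted(spikes, s.end) - np.searchsorted(spikes, s.start)
        s.mean_rate = n / s.duration if s.duration > 0 else float("nan")
        if trace is not None:
            i0 = int(s.start * trace.sample_rate)
            i1 = max(i0 + 1, int(s.end * trace.sample_rate))
            s.mean_baseline = float(np.median(trace.vm_mV[i0:i1]))
    return segs


# ---------------------------------------------------------------------------
# Stimulus/bout statistics
# ---------------------------------------------------------------------------

def stimulus_bout_association(
    stim_times,
    bout_onsets,
    association_window: float = 1.0,
    segments: list[StateSegment] | None = None,
) -> AssociationTable:
    """Associate stimuli with locomotor bouts and classify the remainder.

    A stimulus is associated when at least one bout onset falls within
    ``association_window`` seconds after it.  Bout onsets not captured by
    any stimulus window are self-initiated; when UP/DOWN ``segments`` are
    supplied, self-initiated bouts are attributed to the containing state
    and the per-state occupancy times are reported alongside.

    With zero stimuli the association probability is undefined
    (``table.probability is None``), never reported as 0.
    """
    stim = np.sort(np.asarray(stim_times, dtype=float))
    bouts = np.sort(np.asarray(bout_onsets, dtype=float))
    if not np.array_equal(stim, np.asarray(stim_times, dtype=float)):
        raise ValueError("stimulus times must be sorted")
    if not np.array_equal(bouts, np.asarray(bout_onsets, dtype=float)):
        raise ValueError("bout onsets must be sorted")

    n_assoc = 0
    for s in stim:
        k = np.searchsorted(bouts, s, side="right")
        if k < len(bouts) and bouts[k] <= s + association_window:
            n_assoc += 1
    evoked = np.zeros(len(bouts), dtype=bool)
    for s in stim:
        evoked |= (bouts > s) & (bouts <= s + association_window)
    self_onsets = bouts[~evoked]

    n_up = n_down = 0
    up_t = down_t = 0.0
    if segments is not None:
        for seg in segments:
            if seg.label == "UP":
                up_t += seg.duration
            else:
                down_t += seg.duration
        for b in self_onsets:
            lab = next(
                (seg.label for seg in segments if seg.start <= b < seg.end), None
            )
            if lab == "UP":
                n_up += 1
            elif lab == "DOWN":
                n_down += 1
    return AssociationTable(
        n_stimuli=len(stim),
        n_associated=n_assoc,
        n_self_initiated=len(self_onsets),
        n_self_up=n_up,
        n_self_down=n_down,
        up_time=up_t,
        down_time=down_t,
        association_window=association_window,
    )


@dataclass
class StateRates:
    """Self-initiated movement rates conditioned on membrane state."""

    rate_up: float  # events per second of UP time
    rate_down: float
    fold: float | None  # rate_up / rate_down; None when undefined
    fold_nearest: int | None  # nearest whole fold, for "~N-fold" reporting


def state_conditioned_rates(
    segments: list[StateSegment], self_initiated_onsets
) -> StateRates:
    """Per-state event rates and their UP/DOWN fold change.

    The fold is flagged undefined (None, never infinity) when there is no
    DOWN time or no DOWN event to divide by.
    """
    onsets = np.asarray(self_initiated_onsets, dtype=float)
    up_t = sum(s.duration for s in segments if s.label == "UP")
    down_t = sum(s.duration for s in segments if s.label == "DOWN")
    n_up = n_down = 0
    for b in onsets:
        lab = next((s.label for s in segments if s.start <= b < s.end), None)
        if lab == "UP":
            n_up += 1
        elif lab == "DOWN":
            n_down += 1
    rate_up = n_up / up_t if up_t > 0 else float("nan")
    rate_down = n_down / down_t if down_t > 0 else float("nan")
    if down_t <= 0 or n_down == 0 or up_t <= 0:
        fold = None
        fold_nearest = None
    else:
        fold = rate_up / rate_down
        fold_nearest = int(round(fold))
    return StateRates(rate_up, rate_down, fold, fold_nearest)


@dataclass
class RateModulation:
    """EPSP rate inside vs outside stimulation windows."""

    baseline_rate: float  # Hz
    stim_rate: float  # Hz
    percent_change: float  # 100 * (stim - baseline) / baseline
    peristimulus: pd.DataFrame  # columns: time_s (rel. to window start), rate_hz


def epsp_rate_modulation(
    epsp_times,
    stim_windows: list[tuple[float, float]],
    duration: float,
    dead_time_s: float = 0.0,
    peri_pre: float = 1.0,
    peri_post: float = 3.0,
    peri_bin: float = 0.25,
) -> RateModulation:
    """Quantify stimulus-driven modulation of the EPSP rate.

    Rates are events per second of time inside vs outside the windows;
    the percent change is relative to baseline.  A peristimulus rate
    curve (events binned relative to window onset, averaged over windows)
    accompanies the scalar summary.

    When the event train comes from a detector that cannot resolve
    events closer than its minimum separation, pass that separation as
    ``dead_time_s``: observed rates are then corrected for the
    non-paralyzable dead time (``rate = observed / (1 - observed * tau)``),
    removing the rate-dependent undercount that would otherwise bias the
    percent change toward zero.
    """
    events = np.sort(np.asarray(epsp_times, dtype=float))
    stim_t = sum(e - s for s, e in stim_windows)
    base_t = duration - stim_t
    if base_t <= 0:
        raise ValueError("no baseline time outside stimulation windows")
    in_stim = np.zeros(len(events), dtype=bool)
    for s, e in stim_windows:
        in_stim |= (events >= s) & (events < e)
    stim_rate = in_stim.sum() / stim_t if stim_t > 0 else float("nan")
    base_rate = (~in_stim).sum() / base_t

    def _correct(r: float) -> float:
        if dead_time_s <= 0 or not np.isfinite(r):
            return r
        loss = 1.0 - r * dead_time_s
        if loss <= 0:
            raise ValueError("observed rate saturates the dead time")
        return r / loss

    stim_rate = _correct(stim_rate)
    base_rate = _correct(base_rate)
    if base_rate <= 0:
        raise ValueError("zero baseline rate; percent change undefined")
    pct = 100.0 * (stim_rate - base_rate) / base_rate

    edges = np.arange(-peri_pre, peri_post + peri_bin / 2, peri_bin)
    acc = np.zeros(len(edges) - 1)
    for s, _e in stim_windows:
        rel = events - s
        acc += np.histogram(rel, bins=edges)[0]
    n_win = max(1, len(stim_windows))
    peri = pd.DataFrame(
        {"time_s": edges[:-1] + peri_bin / 2, "rate_hz": acc / (n_win * peri_bin)}
    )
    return RateModulation(float(base_rate), float(stim_rate), float(pct), peri)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_vm_csv(trace: VmTrace, path: str | Path) -> None:
    pd.DataFrame({"t_s": trace.t, "vm_mV": trace.vm_mV}).to_csv(path, index=False)


def read_vm_csv(path: str | Path, windows_path: str | Path | None = None) -> VmTrace:
    """Read a Vm trace CSV (t_s, vm_mV) plus optional window CSV
    (start_s, end_s, kind)."""
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace must contain at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("trace must be uniformly sampled")
    windows = []
    if windows_path is not None:
        wdf = pd.read_csv(windows_path)
        windows = [
            (float(r["start_s"]), float(r["end_s"]), str(r.get("kind", "optogenetic")))
            for _, r in wdf.iterrows()
        ]
    return VmTrace(df["vm_mV"].to_numpy(), sample_rate=1.0 / float(dt[0]), stim_windows=windows)
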