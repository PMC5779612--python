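"""Open- and closed-loop optogenetic stimulation control and dose accounting.

The closed-loop protocol delivers blocks of 3 light pulses (3 ms at 20 Hz)
triggered after 3 min of inactivity and repeated every 30 s until the next
movement occurs; the open-loop protocol is a continuous 20-Hz pulse train.
Both are deterministic functions of the movement schedule and the
configuration — no randomness enters the controller.  Light-dose
accounting bins illuminated time into 15-min bins, mirroring the
activity/photostimulation raster displays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StimConfig",
    "StimulationLog",
    "run_closed_loop",
    "run_open_loop",
    "light_dose",
]


@dataclass
class StimConfig:
    mode: str = "closed"  # "open" | "closed"
    pulse_width_ms: float = 3.0
    pulse_rate: float = 20.0  # Hz within a block / open-loop train
    pulses_per_block: int = 3
    inactivity_trigger: float = 180.0  # s of rest before the first block
    block_interval: float = 30.0  # s between block onsets while resting
    cancellation: str = "immediate"  # "immediate" | "block"

    def __post_init__(self) -> None:
        if self.mode not in ("open", "closed"):
            raise ValueError("mode must be 'open' or 'closed'")
        if self.pulse_width_ms * self.pulse_rate > 1000.0:
            raise ValueError("duty cycle exceeds 100%: pulse_width * pulse_rate > 1 s/s")
        for name in ("pulse_width_ms", "pulse_rate", "inactivity_trigger", "block_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pulses_per_block < 1:
            raise ValueError("pulses_per_block must be >= 1")
        if self.cancellation not in ("immediate", "block"):
            raise ValueError("cancellation must be 'immediate' or 'block'")


@dataclass
class StimulationLog:
    """Emitted light pulses: individual pulse onsets and block onsets (s)."""

    pulse_onsets: np.ndarray
    block_onsets: np.ndarray

    def __post_init__(self) -> None:
        self.pulse_onsets = np.asarray(self.pulse_onsets, dtype=float)
        self.block_onsets = np.asarray(self.block_onsets, dtype=float)
        if np.any(np.diff(self.pulse_onsets) <= 0):
            raise ValueError("pulse onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.pulse_onsets)

    def to_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for t in self.block_onsets:
                fh.write(json.dumps({"t": float(t), "kind": "block"}) + "\n")
            for t in self.pulse_onsets:
                fh.write(json.dumps({"t": float(t), "kind": "pulse"}) + "\n")


def run_closed_loop(
    movement_times, cfg: StimConfig, duration: float
) -> StimulationLog:
    """Closed-loop controller: inactivity-triggered, movement-cancelled blocks.

    For every maximal inactivity gap ``(g_start, g_end)`` between
    consecutive movements (the recording start counts as the start of a
    gap, the recording end closes the last one), block onsets are placed
    at ``g_start + inactivity_trigger + k * block_interval`` while they
    fall strictly before ``g_end`` (a block scheduled exactly at the
    movement is not emitted).  Each block expands into
    ``pulses_per_block`` pulses spaced ``1/pulse_rate``; with
    ``cancellation="immediate"`` pulses at or after the terminating
    movement are dropped, with ``"block"`` a started block completes.

    Stimulation pulses are not movements: they never reset the
    inactivity timer.
    """
    mt = np.asarray(movement_times, dtype=float)
    if np.any(np.diff(mt) < 0):
        raise ValueError("movement times must be sorted")
    if len(mt) and (mt[0] < 0 or mt[-1] > duration):
        raise ValueError("movement times must lie within [0, duration]")
    bounds = np.concatenate(([0.0], mt, [duration]))
    pulses: list[float] = []
    blocks: list[float] = []
    spacing = 1.0 / cfg.pulse_rate
    for g_start, g_end in zip(bounds[:-1], bounds[1:]):
        t = g_start + cfg.inactivity_trigger
        while t < g_end:
            blocks.append(t)
            for k in range(cfg.pulses_per_block):
                p = t + k * spacing
                if cfg.cancellation == "immediate" and p >= g_end:
                    break
                pulses.append(p)
            t += cfg.block_interval
    return StimulationLog(np.asarray(pulses), np.asarray(blocks))


def run_open_loop(cfg: StimConfig, duration: float) -> StimulationLog:
    """Continuous pulse train at ``pulse_rate``: onsets k/rate for
    k = 0 ... floor(duration * rate) - 1."""
    if duration < 0:
        raise ValueError("duration must be non-negative")
    n = int(np.floor(duration * cfg.pulse_rate))
    onsets = np.arange(n) / cfg.pulse_rate
    return StimulationLog(onsets, onsets.copy())


def light_dose(
    log: StimulationLog, cfg: StimConfig, duration: float, bin: float = 900.0
) -> tuple[np.ndarray, int]:
    """Per-bin illuminated-time fraction and the total pulse count.

    Each pulse contributes its full width to the bin containing its
    onset, so summed dose times bin length recovers pulse count times
    pulse width exactly (conservation).
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    n_bins = int(np.ceil(duration / bin))
    dose = np.zeros(max(n_bins, 1))
    width_s = cfg.pulse_width_ms / 1000.0
    idx = np.floor(log.pulse_onsets / bin).astype(int)
    for i in idx:
        if 0 <= i < len(dose):
            dose[i] += width_s
    return dose / bin, len(log)


def dose_matrix(
    logs: dict[str, StimulationLog], cfg: StimConfig, duration: float, bin: float = 900.0
) -> pd.DataFrame:
    """Fly x 15-min-bin dose fractions, one row per stimulation log."""
    rows = {fly: light_dose(lg, cfg, duration, bin)[0] for fly, lg in logs.items()}
    return pd.DataFrame.from_dict(rows, orient="index")
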