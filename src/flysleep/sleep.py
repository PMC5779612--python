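"""Sleep scoring and behavioral summaries for per-minute fly activity data.

Fly sleep is defined operationally: any period of behavioral inactivity
lasting at least five minutes counts as a sleep bout.  Activity arrives as
per-minute infrared beam-crossing counts (Drosophila Activity Monitor
format) or as movement-event counts derived from video tracking; both are
represented by :class:`ActivitySeries` and scored by the same
:func:`score_sleep`.

The module also quantifies homeostatic rebound after deprivation (sleep
lost against a baseline-matched 24-h window, sleep regained cumulatively
during recovery) and the visual-arousal assay (the percentage of sleeping
flies awakened by a light pulse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ActivitySeries",
    "SleepBout",
    "SleepSummary",
    "ReboundResult",
    "ArousalResult",
    "score_sleep",
    "summarize",
    "cohort_summary",
    "rebound",
    "arousal_assay",
    "read_activity",
    "write_bouts_csv",
    "events_to_activity",
    "activity_raster",
]

BIN_SECONDS = 60  # DAM granularity: one count bin per minute


def _sem(values) -> float:
    """Standard error of the mean with the n-1 denominator."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(np.std(v, ddof=1) / math.sqrt(v.size))


@dataclass
class ActivitySeries:
    """Per-minute activity counts for one fly, on a wall clock.

    Parameters
    ----------
    fly_id : str
        Identifier of the animal (monitor channel or synthetic index).
    counts : pandas.Series
        Non-negative integer counts indexed by a contiguous, uniform
        1-minute :class:`~pandas.DatetimeIndex` (bin start times).
    lights_on, lights_off : float
        Photoperiod boundaries as clock hours; the default 8:00-20:00
        encodes the standard 12 h light : 12 h dark schedule.
    """

    fly_id: str
    counts: pd.Series
    lights_on: float = 8.0
    lights_off: float = 20.0

    def __post_init__(self) -> None:
        idx = self.counts.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValueError("counts must be indexed by a DatetimeIndex")
        if len(idx) >= 2:
            deltas = np.diff(idx.asi8) / 1e9
            if not np.allclose(deltas, BIN_SECONDS):
                raise ValueError(
                    "activity bins must be contiguous 1-min intervals; "
                    "found a gap or irregular spacing"
                )
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("activity counts must be non-negative")

    @classmethod
    def from_counts(
        cls,
        counts,
        start: str | pd.Timestamp = "2021-01-01 08:00",
        fly_id: str = "fly0",
        lights_on: float = 8.0,
        lights_off: float = 20.0,
    ) -> "ActivitySeries":
        """Build a series from a plain count vector and a start time."""
        counts = np.asarray(counts, dtype=int)
        idx = pd.date_range(start=start, periods=len(counts), freq="1min")
        return cls(fly_id, pd.Series(counts, index=idx), lights_on, lights_off)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def start(self) -> pd.Timestamp:
        return self.counts.index[0]

    @property
    def end(self) -> pd.Timestamp:
        """End of the last bin (exclusive)."""
        return self.counts.index[-1] + pd.Timedelta(seconds=BIN_SECONDS)

    def is_day(self, t: pd.Timestamp) -> bool:
        h = t.hour + t.minute / 60 + t.second / 3600
        if self.lights_on < self.lights_off:
            return self.lights_on <= h < self.lights_off
        return h >= self.lights_on or h < self.lights_off


@dataclass
class SleepBout:
    """A maximal run of zero-activity minutes of scoreable length.

    ``phase`` is assigned from the bout onset time; ``truncated`` marks
    bouts clipped by the start or end of the recording (kept, but excluded
    from bout-duration means by default).
    """

    start: pd.Timestamp
    end: pd.Timestamp  # exclusive
    phase: str  # "day" | "night"
    truncated: bool = False

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0

    def contains(self, t: pd.Timestamp) -> bool:
        return self.start <= t < self.end


def score_sleep(activity: ActivitySeries, min_sleep_duration: int = 5) -> list[SleepBout]:
    """Score sleep bouts as runs of zero-count minutes of minimum length.

    A maximal run of consecutive zero-count bins lasting at least
    ``min_sleep_duration`` minutes becomes one bout; shorter quiescence is
    wake.  The activity index is validated for contiguity on construction,
    so no silent imputation can occur here.
    """
    if min_sleep_duration < 1:
        raise ValueError("min_sleep_duration must be >= 1 minute")
    counts = np.asarray(activity.counts)
    idx = activity.counts.index
    quiet = counts == 0
    bouts: list[SleepBout] = []
    n = len(counts)
    i = 0
    while i < n:
        if not quiet[i]:
            i += 1
            continue
        j = i
        while j < n and quiet[j]:
            j += 1
        if j - i >= min_sleep_duration:
            start = idx[i]
            end = idx[j - 1] + pd.Timedelta(seconds=BIN_SECONDS)
            truncated = i == 0 or j == n
            phase = "day" if activity.is_day(start) else "night"
            bouts.append(SleepBout(start, end, phase, truncated))
        i = j
    return bouts


@dataclass
class SleepSummary:
    """Per-fly sleep summary: hourly time course and bout statistics."""

    hourly_min: np.ndarray  # minutes asleep per clock hour, shape (24,)
    total_min: float
    day_bout_mean_min: float
    night_bout_mean_min: float
    n_day_bouts: int
    n_night_bouts: int


def _overlap_minutes(bout: SleepBout, h_start: pd.Timestamp, h_end: pd.Timestamp) -> float:
    lo = max(bout.start, h_start)
    hi = min(bout.end, h_end)
    return max(0.0, (hi - lo).total_seconds() / 60.0)


def summarize(
    bouts: list[SleepBout],
    span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    include_truncated: bool = False,
) -> SleepSummary:
    """Summarize scored bouts into an hourly time course and bout means.

    Each bout credits its overlap minutes to every clock hour it touches
    (so the 24-entry hourly vector sums to total sleep), while phase
    membership for bout-duration means follows the onset rule.  Boundary-
    truncated bouts contribute sleep time but are excluded from duration
    means unless ``include_truncated`` is set.
    """
    hourly = np.zeros(24)
    for b in bouts:
        # walk the clock hours the bout spans
        h = b.start.floor("h")
        while h < b.end:
            h_next = h + pd.Timedelta(hours=1)
            hourly[h.hour] += _overlap_minutes(b, h, h_next)
            h = h_next
    usable = bouts if include_truncated else [b for b in bouts if not b.truncated]
    day = [b.duration_min for b in usable if b.phase == "day"]
    night = [b.duration_min for b in usable if b.phase == "night"]
    return SleepSummary(
        hourly_min=hourly,
        total_min=float(sum(b.duration_min for b in bouts)),
        day_bout_mean_min=float(np.mean(day)) if day else float("nan"),
        night_bout_mean_min=float(np.mean(night)) if night else float("nan"),
        n_day_bouts=len(day),
        n_night_bouts=len(night),
    )


def cohort_summary(summaries: list[SleepSummary]) -> pd.DataFrame:
    """Group mean +/- SEM over per-fly summaries (test-ready table)."""
    rows = []
    for name, getter in [
        ("total_sleep_min", lambda s: s.total_min),
        ("day_bout_mean_min", lambda s: s.day_bout_mean_min),
        ("night_bout_mean_min", lambda s: s.night_bout_mean_min),
    ]:
        vals = [getter(s) for s in summaries]
        vals = [v for v in vals if not math.isnan(v)]
        rows.append(
            {
                "measure": name,
                "mean": float(np.mean(vals)) if vals else float("nan"),
                "sem": _sem(vals),
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ReboundResult:
    """Deprivation-rebound accounting against a baseline-matched window."""

    baseline_sleep_24h_min: float
    baseline_matched_window_min: float
    sleep_during_deprivation_min: float
    sleep_lost_min: float
    regained_cumulative_min: pd.Series  # cumulative, per recovery hour
    percent_recovered: float | None  # None when sleep_lost <= 0


def _hourly_sleep(activity: ActivitySeries, min_sleep: int) -> pd.Series:
    """Minutes asleep per absolute hour, from scored bouts."""
    bouts = score_sleep(activity, min_sleep)
    hours = pd.date_range(activity.start.floor("h"), activity.end, freq="1h")[:-1]
    vals = []
    for h in hours:
        h_next = h + pd.Timedelta(hours=1)
        vals.append(sum(_overlap_minutes(b, h, h_next) for b in bouts))
    return pd.Series(vals, index=hours)


def rebound(
    baseline: ActivitySeries,
    deprivation: ActivitySeries,
    recovery: ActivitySeries,
    min_sleep_duration: int = 5,
) -> ReboundResult:
    """Quantify sleep lost to deprivation and regained during recovery.

    The 24-h ``baseline`` period immediately precedes ``deprivation``
    (typically 12 h overnight), which immediately precedes ``recovery``.
    Sleep lost is baseline sleep in the clock window matching deprivation
    minus sleep achieved during deprivation; sleep regained is the
    cumulative hour-by-hour excess of recovery sleep over the baseline
    sleep in the matched clock hour.
    """
    if baseline.end != deprivation.start or deprivation.end != recovery.start:
        raise ValueError(
            "baseline, deprivation and recovery must be contiguous and "
            "clock-aligned (each starting where the previous ends)"
        )
    base_bouts = score_sleep(baseline, min_sleep_duration)
    dep_bouts = score_sleep(deprivation, min_sleep_duration)
    baseline_total = sum(b.duration_min for b in base_bouts)
    dep_sleep = sum(b.duration_min for b in dep_bouts)

    # baseline sleep in the clock window matching the deprivation period
    offset = pd.Timedelta(hours=24)
    matched_lo = deprivation.start - offset
    matched_hi = deprivation.end - offset
    matched = sum(
        _overlap_minutes(b, matched_lo, matched_hi) for b in base_bouts
    )
    lost = matched - dep_sleep

    base_hourly = _hourly_sleep(baseline, min_sleep_duration)
    rec_hourly = _hourly_sleep(recovery, min_sleep_duration)
    diffs = []
    for h, rec_min in rec_hourly.items():
        # baseline hour with the same clock time, one or more days earlier
        days_back = math.floor((h - baseline.start).total_seconds() / 86400.0)
        h_match = h - pd.Timedelta(hours=24 * days_back)
        base_min = float(base_hourly.get(h_match, 0.0))
        diffs.append(rec_min - base_min)
    regained = pd.Series(np.cumsum(diffs), index=rec_hourly.index)
    pct = 100.0 * float(regained.iloc[-1]) / lost if lost > 0 else None
    return ReboundResult(
        baseline_sleep_24h_min=float(baseline_total),
        baseline_matched_window_min=float(matched),
        sleep_during_deprivation_min=float(dep_sleep),
        sleep_lost_min=float(lost),
        regained_cumulative_min=regained,
        percent_recovered=pct,
    )


@dataclass
class ArousalResult:
    """Percentage of sleeping flies awakened per arousal probe."""

    pulse_times: list[pd.Timestamp]
    n_asleep: list[int]
    n_awakened: list[int]
    percent_per_pulse: list[float]  # NaN where no fly was asleep
    defined: bool  # False when no fly was asleep at any pulse

    @property
    def percent_pooled(self) -> float:
        tot_asleep = sum(self.n_asleep)
        if tot_asleep == 0:
            return float("nan")
        return 100.0 * sum(self.n_awakened) / tot_asleep


def arousal_assay(
    activities: list[ActivitySeries],
    pulse_times: list[pd.Timestamp],
    response_window_min: int = 3,
    min_sleep_duration: int = 5,
) -> ArousalResult:
    """Visual-arousal assay: fraction of sleeping flies woken by each pulse.

    For each light pulse the denominator is the set of flies asleep (inside
    a scored bout) at pulse onset; the numerator is those registering at
    least one activity count within the response window (default: the 3-min
    pulse itself).  Flies already awake at onset enter neither count.
    """
    bouts_per_fly = [score_sleep(a, min_sleep_duration) for a in activities]
    n_asleep, n_awake, pct = [], [], []
    for p in pulse_times:
        asleep_ids = [
            i
            for i, bouts in enumerate(bouts_per_fly)
            if any(b.contains(p) for b in bouts)
        ]
        responded = 0
        w_end = p + pd.Timedelta(minutes=response_window_min)
        for i in asleep_ids:
            c = activities[i].counts
            sel = c[(c.index >= p) & (c.index < w_end)]
            if (np.asarray(sel) > 0).any():
                responded += 1
        n_asleep.append(len(asleep_ids))
        n_awake.append(responded)
        pct.append(100.0 * responded / len(asleep_ids) if asleep_ids else float("nan"))
    return ArousalResult(
        pulse_times=list(pulse_times),
        n_asleep=n_asleep,
        n_awakened=n_awake,
        percent_per_pulse=pct,
        defined=any(n > 0 for n in n_asleep),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_activity(path: str | Path, dialect: str = "auto", **kwargs) -> list[ActivitySeries]:
    """Read activity data in DAM-style TSV or the simple CSV dialect.

    DAM-style TSV: tab-separated, one row per minute — index, date
    (``%d %b %y``), time (``%H:%M:%S``), status code, then one integer
    count column per channel.  Simple CSV: ``timestamp,fly_id,count``.
    ``dialect`` may be ``"dam"``, ``"csv"`` or ``"auto"`` (detected from
    the delimiter and column count of the first line).
    """
    path = Path(path)
    if dialect == "auto":
        first = path.open().readline()
        dialect = "dam" if "\t" in first and len(first.split("\t")) >= 5 else "csv"
    if dialect == "dam":
        df = pd.read_csv(path, sep="\t", header=None)
        when = pd.to_datetime(
            df[1].astype(str) + " " + df[2].astype(str), format="%d %b %y %H:%M:%S"
        )
        out = []
        for ch in range(4, df.shape[1]):
            s = pd.Series(df[ch].to_numpy(dtype=int), index=pd.DatetimeIndex(when))
            out.append(ActivitySeries(fly_id=f"ch{ch - 3}", counts=s, **kwargs))
        return out
    df = pd.read_csv(path)
    out = []
    for fly_id, grp in df.groupby("fly_id", sort=False):
        s = pd.Series(
            grp["count"].to_numpy(dtype=int),
            index=pd.DatetimeIndex(pd.to_datetime(grp["timestamp"])),
        )
        out.append(ActivitySeries(fly_id=str(fly_id), counts=s, **kwargs))
    return out


def write_bouts_csv(bouts: list[SleepBout], path: str | Path, fly_id: str = "fly0") -> None:
    pd.DataFrame(
        {
            "fly_id": fly_id,
            "start": [b.start for b in bouts],
            "end": [b.end for b in bouts],
            "duration_min": [b.duration_min for b in bouts],
            "phase": [b.phase for b in bouts],
            "truncated": [b.truncated for b in bouts],
        }
    ).to_csv(path, index=False)


def events_to_activity(
    event_times_s,
    duration_s: float,
    start: str | pd.Timestamp = "2021-01-01 08:00",
    fly_id: str = "fly0",
    **kwargs,
) -> ActivitySeries:
    """Convert tracker movement-event times (s) into per-minute pseudo-counts.

    This is the bridge between video tracking and the DAM-style scorer: a
    movement event in a minute increments that minute's count, so both
    input paths share one sleep-scoring rule.
    """
    n_bins = int(math.ceil(duration_s / BIN_SECONDS))
    counts = np.zeros(n_bins, dtype=int)
    for t in np.asarray(event_times_s, dtype=float):
        b = int(t // BIN_SECONDS)
        if 0 <= b < n_bins:
            counts[b] += 1
    return ActivitySeries.from_counts(counts, start=start, fly_id=fly_id, **kwargs)


def activity_raster(activities: list[ActivitySeries], bin_min: int = 15) -> pd.DataFrame:
    """Fly x time-bin matrix of the fraction of time spent moving.

    Mirrors the 15-min color-coded raster display: within each bin, the
    fraction of minutes with at least one count.
    """
    rows = {}
    for a in activities:
        moving = (np.asarray(a.counts) > 0).astype(float)
        n_bins = len(moving) // bin_min
        rows[a.fly_id] = moving[: n_bins * bin_min].reshape(n_bins, bin_min).mean(axis=1)
    return pd.DataFrame.from_dict(rows, orient="index")
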