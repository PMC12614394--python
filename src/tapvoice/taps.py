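"""Finger-tapping analysis: alternation filtering, inter-tap intervals,
time-frame segmentation and per-frame dysrhythmia (interval SD).

The tapping task asks the subject to tap two on-screen buttons alternately
with index and middle finger for 20 s. The raw signal is a timestamped
stream of (time, side) events. Analysis keeps only properly alternating
taps, computes the intervals between consecutive retained taps, splits the
trial into five equal 4 s time frames (TF1..TF5), and summarises rhythm
stability as the sample SD of intervals within each frame.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SIDES = ("left", "right")

#: protocol durations in seconds
TASK_DURATIONS = {"tapping": 20.0, "phonation": 10.0, "speech": 5.0}
N_FRAMES = 5


@dataclass(frozen=True)
class TapEvent:
    t: float
    side: str

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")


@dataclass
class TapTrial:
    subject_id: str
    hand: str
    session: int
    events: list[TapEvent]
    duration: float = TASK_DURATIONS["tapping"]

    def times(self) -> np.ndarray:
        return np.array([e.t for e in self.events], dtype=float)

    def sides(self) -> list[str]:
        return [e.side for e in self.events]


@dataclass
class IntervalSeries:
    """Consecutive-tap intervals; each item keyed by the later tap's time."""

    t_end: np.ndarray
    dt: np.ndarray

    def __len__(self) -> int:
        return len(self.dt)


@dataclass(frozen=True)
class TimeFrameSpec:
    task_kind: str
    duration: float

    @classmethod
    def for_task(cls, task_kind: str) -> "TimeFrameSpec":
        if task_kind not in TASK_DURATIONS:
            raise ValueError(f"unknown task kind {task_kind!r}")
        return cls(task_kind=task_kind, duration=TASK_DURATIONS[task_kind])

    @property
    def frame_length(self) -> float:
        return self.duration / N_FRAMES

    @property
    def boundaries(self) -> list[tuple[float, float]]:
        """Five half-open [start, end) intervals partitioning [0, duration)."""
        w = self.frame_length
        return [(k * w, (k + 1) * w) for k in range(N_FRAMES)]


def assign_time_frame(t: float, spec: TimeFrameSpec) -> int:
    """Map a timestamp to its time frame 1..5.

    Frames are half-open [start, end); the trial-end instant t == duration
    folds into TF5 so the partition covers the closed task interval.
    """
    if t < 0 or t > spec.duration:
        raise ValueError(f"t={t} outside [0, {spec.duration}]")
    if t == spec.duration:
        return N_FRAMES
    return int(t / spec.frame_length) + 1


def assign_time_frames(t: np.ndarray, spec: TimeFrameSpec) -> np.ndarray:
    """Vectorised assign_time_frame."""
    t = np.asarray(t, dtype=float)
    if t.size and (t.min() < 0 or t.max() > spec.duration):
        raise ValueError("timestamps outside [0, duration]")
    tf = np.minimum((t / spec.frame_length).astype(int) + 1, N_FRAMES)
    return tf


def filter_alternating(trial: TapTrial) -> TapTrial:
    """Keep only taps whose side alternates with the previously *retained* tap.

    The first tap is always retained; a run of same-side taps collapses to
    its first element. Timestamps are untouched. Idempotent.
    """
    ts = trial.times()
    if np.any(np.diff(ts) < 0):
        raise ValueError("tap events must be sorted by time")
    kept: list[TapEvent] = []
    last_side: str | None = None
    for ev in trial.events:
        if ev.side != last_side:
            kept.append(ev)
            last_side = ev.side
    return replace(trial, events=kept)


def compute_intervals(filtered: TapTrial) -> IntervalSeries:
    """Intervals between consecutive retained taps, keyed by the later tap."""
    ts = filtered.times()
    if len(ts) < 2:
        return IntervalSeries(t_end=np.empty(0), dt=np.empty(0))
    return IntervalSeries(t_end=ts[1:], dt=np.diff(ts))


def interval_sd_per_tf(
    series: IntervalSeries, spec: TimeFrameSpec
) -> dict[int, float]:
    """Sample SD (n−1) of intervals within each frame; NaN below 2 intervals.

    An interval belongs to the frame containing its later tap, which keeps
    boundary-spanning intervals single-valued.
    """
    out = {k: float("nan") for k in range(1, N_FRAMES + 1)}
    if len(series) == 0:
        return out
    tf = assign_time_frames(series.t_end, spec)
    for k in range(1, N_FRAMES + 1):
        vals = series.dt[tf == k]
        if len(vals) >= 2:
            out[k] = float(np.std(vals, ddof=1))
    return out


def tap_summary(trial: TapTrial, spec: TimeFrameSpec | None = None) -> pd.DataFrame:
    """Long-format feature records for one raw tap trial.

    Emits total_taps (tf=0, counted after alternation filtering),
    interval_sd for tf 1..5, and mean_variability (tf=0, the arithmetic
    mean of the five per-frame SDs, ignoring undefined frames).
    """
    spec = spec or TimeFrameSpec.for_task("tapping")
    filtered = filter_alternating(trial)
    series = compute_intervals(filtered)
    sds = interval_sd_per_tf(series, spec)
    rows = [
        {"feature": "total_taps", "tf": 0, "value": float(len(filtered.events))},
    ]
    for k in range(1, N_FRAMES + 1):
        rows.append({"feature": "interval_sd", "tf": k, "value": sds[k]})
    per_tf = np.array([sds[k] for k in range(1, N_FRAMES + 1)])
    mean_var = float(np.nanmean(per_tf)) if not np.all(np.isnan(per_tf)) else float("nan")
    rows.append({"feature": "mean_variability", "tf": 0, "value": mean_var})
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", trial.subject_id)
    df.insert(1, "task", "tapping")
    df.insert(2, "trial", f"s{trial.session}_{trial.hand}")
    return df


# ---------------------------------------------------------------------------
# CSV I/O  (header: t_sec,side)

def write_tap_csv(trial: TapTrial, path: str | Path) -> None:
    df = pd.DataFrame({"t_sec": trial.times(), "side": trial.sides()})
    df.to_csv(path, index=False, float_format="%.6f")


def read_tap_csv(
    path: str | Path, subject_id: str, hand: str, session: int
) -> TapTrial:
    df = pd.read_csv(path, comment="#")
    events = [TapEvent(float(t), str(s)) for t, s in zip(df["t_sec"], df["side"])]
    return TapTrial(subject_id=subject_id, hand=hand, session=session, events=events)


def extract_tap_features(
    trials: Iterable[TapTrial], spec: TimeFrameSpec | None = None
) -> pd.DataFrame:
    """tap_summary over many trials, concatenated into one long table."""
    frames = [tap_summary(tr, spec) for tr in trials]
    if not frames:
        return pd.DataFrame(
            columns=["subject_id", "task", "trial", "feature", "tf", "value"]
        )
    return pd.concat(frames, ignore_index=True)
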