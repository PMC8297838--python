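"""Movement / resting bout segmentation of calibrated tracks.

A recording is partitioned into an alternating sequence of *movement* bouts
and *resting* periods.  An individual is resting when it is still or performs
only very small movements (speed at most 1 cm/s); a candidate movement bout is
a maximal run of frames faster than that, and only candidates whose path
length exceeds 2 cm count as movement — shorter dashes are treated as noise
and absorbed into the surrounding rest.

Speeds are computed over a short centred window (default 0.25 s) to suppress
pixel-level jitter; the window is exposed because trackers differ in noise
level, and ``window=None`` falls back to raw inter-frame displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory_io import Track

RESTING_SPEED_DEFAULT = 0.01  # m/s: "very small movements" boundary
MIN_MOVEMENT_LENGTH_DEFAULT = 0.02  # m: movement must exceed 2 cm
SPEED_WINDOW_DEFAULT = 0.25  # s


@dataclass(frozen=True)
class Thresholds:
    """Segmentation thresholds.

    min_movement_length : metres — a movement bout's path must be strictly
        longer than this (2 cm default); shorter fast dashes are absorbed
        into resting.
    resting_speed : metres/second — frames at or below this speed are
        stationary (1 cm/s default).
    speed_window : seconds — centred smoothing window for the speed series;
        ``None`` disables smoothing (raw finite differences).
    """

    min_movement_length: float = MIN_MOVEMENT_LENGTH_DEFAULT
    resting_speed: float = RESTING_SPEED_DEFAULT
    speed_window: float | None = SPEED_WINDOW_DEFAULT

    def __post_init__(self) -> None:
        if self.min_movement_length <= 0 or self.resting_speed <= 0:
            raise ValueError("thresholds must be positive")
        if self.speed_window is not None and self.speed_window <= 0:
            raise ValueError("speed_window must be positive or None")

    def scaled(self, c: float) -> "Thresholds":
        """Thresholds matching a track whose positions were scaled by c."""
        return Thresholds(
            min_movement_length=self.min_movement_length * c,
            resting_speed=self.resting_speed * c,
            speed_window=self.speed_window,
        )


@dataclass(frozen=True)
class Bout:
    """One movement bout or resting period."""

    kind: str  # "movement" | "resting"
    start_time: float
    end_time: float
    path_length: float

    def __post_init__(self) -> None:
        if self.kind not in ("movement", "resting"):
            raise ValueError(f"unknown bout kind {self.kind!r}")
        if self.end_time <= self.start_time:
            raise ValueError("bout must have positive duration")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class BoutSequence:
    """Contiguous, alternating partition of a recording into bouts."""

    bouts: list[Bout]
    total_duration: float

    def __post_init__(self) -> None:
        t = 0.0
        prev_kind = None
        for bout in self.bouts:
            if not np.isclose(bout.start_time, t, atol=1e-9):
                raise ValueError("bouts must be contiguous from time 0")
            if bout.kind == prev_kind:
                raise ValueError("adjacent bouts must alternate kinds")
            prev_kind = bout.kind
            t = bout.end_time
        if self.bouts and not np.isclose(t, self.total_duration, atol=1e-9):
            raise ValueError("bouts must cover the full recording")

    def __iter__(self):
        return iter(self.bouts)

    def __len__(self) -> int:
        return len(self.bouts)

    def movement_bouts(self) -> list[Bout]:
        return [b for b in self.bouts if b.kind == "movement"]

    def resting_bouts(self) -> list[Bout]:
        return [b for b in self.bouts if b.kind == "resting"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [b.kind for b in self.bouts],
                "start_s": [b.start_time for b in self.bouts],
                "end_s": [b.end_time for b in self.bouts],
                "duration_s": [b.duration for b in self.bouts],
                "path_length_m": [b.path_length for b in self.bouts],
            }
        )


def frame_speeds(track: Track, window: float | None = SPEED_WINDOW_DEFAULT) -> np.ndarray:
    """Per-frame speed as path length over a centred window.

    For frame i the speed is the trajectory path length inside a window of
    ``window`` seconds centred on the frame, divided by the (possibly
    truncated, at the recording ends) window duration.  ``window=None`` or a
    window of one frame step reduces to the symmetric finite difference of
    cumulative path length.  Returns an array with one entry per frame.
    """
    if track.n_frames < 2:
        raise ValueError("speed needs at least two frames")
    times = track.times
    dt = float(np.median(np.diff(times)))
    cum = np.concatenate([[0.0], np.cumsum(track.step_lengths())])
    if window is None:
        half = 1
    else:
        half = max(1, int(round(window / dt / 2.0)))
    n = track.n_frames
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n - 1)
    hi = np.clip(idx + half, 0, n - 1)
    return (cum[hi] - cum[lo]) / (times[hi] - times[lo])


def segment_bouts(track: Track, thresholds: Thresholds = Thresholds()) -> BoutSequence:
    """Partition a track into alternating movement and resting bouts.

    Frames faster than ``resting_speed`` are moving; maximal moving runs
    become candidate movement bouts; candidates whose path length does not
    exceed ``min_movement_length`` are absorbed into the surrounding rest
    (ties at exactly the threshold count as resting).  A recording that
    starts or ends mid-movement keeps the partial bout if it passes the
    length test.
    """
    if track.n_frames < 2:
        raise ValueError("track too short to segment")
    speeds = frame_speeds(track, thresholds.speed_window)
    moving = speeds > thresholds.resting_speed
    cum = np.concatenate([[0.0], np.cumsum(track.step_lengths())])
    times = track.times

    # run-length encode the frame classification
    change = np.flatnonzero(np.diff(moving.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    kinds = moving[starts].copy()

    # each run spans [its first frame, the next run's first frame];
    # the last run ends at the final frame
    ends = np.concatenate([starts[1:], [track.n_frames - 1]])

    # absorb sub-threshold movement candidates into rest
    run_paths = cum[ends] - cum[starts]
    kinds[(kinds) & (run_paths <= thresholds.min_movement_length)] = False

    # merge adjacent runs of equal kind after absorption
    keep = np.concatenate([[True], kinds[1:] != kinds[:-1]])
    starts, kinds = starts[keep], kinds[keep]
    ends = np.concatenate([starts[1:], [track.n_frames - 1]])

    # a trailing zero-duration run (single final frame) merges backwards
    if len(starts) > 1 and starts[-1] == track.n_frames - 1:
        starts, kinds = starts[:-1], kinds[:-1]
        ends = np.concatenate([starts[1:], [track.n_frames - 1]])

    bouts = [
        Bout(
            kind="movement" if k else "resting",
            start_time=float(times[s]),
            end_time=float(times[e]),
            path_length=float(cum[e] - cum[s]),
        )
        for s, e, k in zip(starts, ends, kinds)
    ]
    return BoutSequence(bouts=bouts, total_duration=float(times[-1] - times[0]))


def bout_table(
    tracks: list[Track], thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Long-form bout table over many tracks (one row per bout)."""
    frames = []
    for track in tracks:
        tab = segment_bouts(track, thresholds).to_frame()
        tab.insert(0, "cricket_id", track.cricket_id)
        tab.insert(1, "day", track.day)
        frames.append(tab)
    if not frames:
        return pd.DataFrame(
            columns=[
                "cricket_id",
                "day",
                "kind",
                "start_s",
                "end_s",
                "duration_s",
                "path_length_m",
            ]
        )
    return pd.concat(frames, ignore_index=True)
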