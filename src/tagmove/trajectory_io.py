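"""Reading, writing, calibrating and repairing arena trajectories.

Trajectories arrive as per-frame tables exported by a multi-individual video
tracker: one row per (frame, individual) with pixel or metre coordinates.
This module converts them into calibrated :class:`Track` objects (positions in
metres in the arena frame, times in seconds) and repairs short tracking
dropouts by linear interpolation.

The CSV dialect is ``frame,id,x,y`` — frame 0-based integers, comma-separated,
UTF-8.  Metadata tables carry the experiment covariates (temperature category,
day, tag weight, animal weight) keyed by individual id and day.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: column order of the trajectory CSV dialect
TRAJECTORY_COLUMNS = ["frame", "id", "x", "y"]

#: column order of the experiment metadata CSV
METADATA_COLUMNS = [
    "cricket_id",
    "group",
    "temperature_category",
    "temperature_c",
    "day",
    "weight_category",
    "tag_weight_mg",
    "animal_weight_mg",
]

TEMPERATURE_CATEGORIES = ("low", "intermediate", "high")
WEIGHT_CATEGORIES = ("control", "light", "medium", "heavy")


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory table violates the dialect contract."""


@dataclass
class Track:
    """Calibrated trajectory of one individual.

    Attributes
    ----------
    cricket_id : str
        Individual label, stable across days.
    times : ndarray of float
        Frame times in seconds, strictly increasing, uniform at 1/fps
        (after gap filling).
    positions : ndarray, shape (n, 2)
        (x, y) positions in metres in the arena frame.
    day : int or None
        Recording day (1-based) when known; joins against metadata.
    """

    cricket_id: str
    times: np.ndarray
    positions: np.ndarray
    day: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.n_frames else 0.0

    def step_lengths(self) -> np.ndarray:
        """Euclidean distance between consecutive frames (length n-1)."""
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def path_length(self) -> float:
        return float(self.step_lengths().sum())


@dataclass
class Calibration:
    """Pixel-to-metre conversion for one recording setup.

    Exactly one of ``px_per_metre`` / ``arena_corner_pixels`` must be given.
    ``arena_corner_pixels`` lists the four arena corners in pixel coordinates
    in the order corresponding to world corners (0,0), (W,0), (W,D), (0,D);
    an affine map is least-squares fitted to the correspondences, so any image
    y-flip or rotation is absorbed.  With the scalar ``px_per_metre`` route,
    ``y_axis="down"`` flips image rows into world y-up via the arena depth.
    """

    fps: float = 24.0
    px_per_metre: float | None = None
    arena_corner_pixels: np.ndarray | None = None
    arena_size: tuple[float, float] = (1.2, 0.8)
    y_axis: str = "up"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if (self.px_per_metre is None) == (self.arena_corner_pixels is None):
            raise ValueError(
                "exactly one of px_per_metre / arena_corner_pixels required"
            )
        if self.y_axis not in ("up", "down"):
            raise ValueError("y_axis must be 'up' or 'down'")
        if self.arena_corner_pixels is not None:
            self.arena_corner_pixels = np.asarray(
                self.arena_corner_pixels, dtype=float
            )
            if self.arena_corner_pixels.shape != (4, 2):
                raise ValueError("arena_corner_pixels must be four (x, y) points")

    def _affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Least-squares affine (A, b): world = pixels @ A.T + b."""
        w, d = self.arena_size
        world = np.array([[0.0, 0.0], [w, 0.0], [w, d], [0.0, d]])
        px = self.arena_corner_pixels
        design = np.column_stack([px, np.ones(4)])
        coef, *_ = np.linalg.lstsq(design, world, rcond=None)
        return coef[:2].T, coef[2]

    def to_metres(self, xy_px: np.ndarray) -> np.ndarray:
        """Map an (n, 2) pixel array into arena-frame metres."""
        xy_px = np.asarray(xy_px, dtype=float)
        if self.px_per_metre is not None:
            xy = xy_px / self.px_per_metre
            if self.y_axis == "down":
                xy = xy.copy()
                xy[:, 1] = self.arena_size[1] - xy[:, 1]
            return xy
        a_mat, b_vec = self._affine()
        return xy_px @ a_mat.T + b_vec

    @property
    def implied_px_per_metre(self) -> float:
        """Mean scale of the calibration map (pixels per metre)."""
        if self.px_per_metre is not None:
            return self.px_per_metre
        a_mat, _ = self._affine()
        sx, sy = np.linalg.norm(a_mat[:, 0]), np.linalg.norm(a_mat[:, 1])
        return float(2.0 / (sx + sy)) if (sx + sy) else float("nan")

    @classmethod
    def from_yaml(cls, path) -> "Calibration":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "arena_size" in raw:
            raw["arena_size"] = tuple(raw["arena_size"])
        if raw.get("arena_corner_pixels") is not None:
            raw["arena_corner_pixels"] = np.asarray(raw["arena_corner_pixels"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {
            "fps": float(self.fps),
            "px_per_metre": None
            if self.px_per_metre is None
            else float(self.px_per_metre),
            "arena_corner_pixels": None
            if self.arena_corner_pixels is None
            else self.arena_corner_pixels.tolist(),
            "arena_size": list(self.arena_size),
            "y_axis": self.y_axis,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def read_tracks(path_or_buf, calibration: Calibration) -> list[Track]:
    """Read a trajectory CSV and return one calibrated Track per individual.

    Rows need not be sorted; frames must be unique within each id.  Positions
    are converted to metres and times to seconds (``frame / fps``).
    """
    table = pd.read_csv(path_or_buf)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in table.columns]
    if missing:
        raise TrajectoryFormatError(f"trajectory table missing columns: {missing}")
    if table.empty:
        warnings.warn("empty trajectory table: returning no tracks", stacklevel=2)
        return []
    if table.duplicated(subset=["id", "frame"]).any():
        dupes = table[table.duplicated(subset=["id", "frame"])]
        raise TrajectoryFormatError(
            f"duplicate (id, frame) rows, e.g. {dupes.iloc[0][['id', 'frame']].tolist()}"
        )
    tracks = []
    for cid, sub in table.groupby("id", sort=True):
        sub = sub.sort_values("frame")
        xy = calibration.to_metres(sub[["x", "y"]].to_numpy(dtype=float))
        times = sub["frame"].to_numpy(dtype=float) / calibration.fps
        tracks.append(Track(cricket_id=str(cid), times=times, positions=xy))
    return tracks


def write_tracks(tracks: list[Track], path, fps: float = 24.0) -> None:
    """Write calibrated tracks in the ``frame,id,x,y`` dialect (metres).

    Coordinates are printed at 6 significant digits; reading the file back
    with an identity calibration reproduces the tracks to that precision.
    """
    frames = []
    for track in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "frame": np.rint(track.times * fps).astype(int),
                    "id": track.cricket_id,
                    "x": track.positions[:, 0],
                    "y": track.positions[:, 1],
                }
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    )
    out.to_csv(path, index=False, float_format="%.6g")


def fill_gaps(track: Track, max_gap: int = 12, fps: float = 24.0) -> list[Track]:
    """Repair missing frames by linear interpolation; split at long dropouts.

    Gaps of at most ``max_gap`` missing frames are filled by linearly
    interpolating both coordinates.  Longer gaps are not invented: the track
    is split into separate segments and a warning is emitted.  The default of
    12 frames is half a second at 24 fps.
    """
    frames = np.rint(track.times * fps).astype(int)
    jumps = np.diff(frames)
    if np.any(jumps <= 0):
        raise ValueError("track frames must be strictly increasing")
    split_at = np.flatnonzero(jumps > max_gap + 1) + 1
    if len(split_at):
        warnings.warn(
            f"track {track.cricket_id}: {len(split_at)} gap(s) longer than "
            f"{max_gap} frames; splitting",
            stacklevel=2,
        )
    segments = []
    for idx in np.split(np.arange(len(frames)), split_at):
        seg_frames = frames[idx]
        full = np.arange(seg_frames[0], seg_frames[-1] + 1)
        x = np.interp(full, seg_frames, track.positions[idx, 0])
        y = np.interp(full, seg_frames, track.positions[idx, 1])
        segments.append(
            replace(
                track,
                times=full / fps,
                positions=np.column_stack([x, y]),
            )
        )
    return segments


def read_metadata(path_or_buf) -> pd.DataFrame:
    """Read the experiment metadata CSV and validate its invariants."""
    meta = pd.read_csv(path_or_buf)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise TrajectoryFormatError(f"metadata missing columns: {missing}")
    validate_metadata(meta)
    return meta


def validate_metadata(meta: pd.DataFrame) -> None:
    bad_cat = set(meta["weight_category"]) - set(WEIGHT_CATEGORIES)
    if bad_cat:
        raise ValueError(f"unknown weight categories: {sorted(bad_cat)}")
    bad_temp = set(meta["temperature_category"]) - set(TEMPERATURE_CATEGORIES)
    if bad_temp:
        raise ValueError(f"unknown temperature categories: {sorted(bad_temp)}")
    control = meta["weight_category"] == "control"
    if not np.allclose(meta.loc[control, "tag_weight_mg"], 0.0):
        raise ValueError("control rows must have tag_weight_mg == 0")
    if (meta.loc[~control, "tag_weight_mg"] <= 0).any():
        raise ValueError("tagged rows must have tag_weight_mg > 0")
    if not meta["day"].isin([1, 2, 3]).all():
        raise ValueError("day must be in {1, 2, 3}")
    if (meta["animal_weight_mg"] <= 0).any():
        raise ValueError("animal_weight_mg must be positive")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.loc[:, METADATA_COLUMNS].to_csv(path, index=False)
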