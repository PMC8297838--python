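"""Per-recording movement properties and the cohort property table.

Six summary statistics describe each individual's 10-minute recording:

================== ===========================================================
movementLength     mean path length of single movement bouts (m)
movementLengthMax  longest single movement bout (m)
movementSum        total path length over all movement bouts (m) — the
                   overall distance travelled
movementSpeed      mean over movement bouts of bout path/bout duration (m/s)
restingDuration    mean resting period duration (s)
restingFrequency   number of resting periods (count)
================== ===========================================================

``movementSpeed`` averages per-bout speeds rather than dividing total distance
by total moving time; the pooled ratio is emitted as an extra column
(``movementSpeedPooled``) for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .segmentation import BoutSequence, Thresholds, segment_bouts
from .trajectory_io import Track

PROPERTY_NAMES = [
    "movementLength",
    "movementLengthMax",
    "movementSum",
    "movementSpeed",
    "restingDuration",
    "restingFrequency",
]


@dataclass(frozen=True)
class MovementProperties:
    movementLength: float
    movementLengthMax: float
    movementSum: float
    movementSpeed: float
    restingDuration: float
    restingFrequency: int
    #: pooled alternative: total movement path / total moving time
    movementSpeedPooled: float = 0.0
    #: True when the recording contained no movement bout at all
    no_movement: bool = False

    def __post_init__(self) -> None:
        if self.restingFrequency < 0 or any(
            getattr(self, name) < 0 for name in PROPERTY_NAMES[:5]
        ):
            raise ValueError("movement properties must be non-negative")


def compute_properties(bouts: BoutSequence) -> MovementProperties:
    """Summarise one bout sequence into the six movement properties.

    A recording with no movement bout reports zeros for the four movement
    statistics and is flagged via ``no_movement`` (such individuals stay in
    the cohort table rather than being dropped).
    """
    moves = bouts.movement_bouts()
    rests = bouts.resting_bouts()
    if moves:
        lengths = np.array([b.path_length for b in moves])
        speeds = np.array([b.path_length / b.duration for b in moves])
        total_time = sum(b.duration for b in moves)
        move_stats = (
            float(lengths.mean()),
            float(lengths.max()),
            float(lengths.sum()),
            float(speeds.mean()),
            float(lengths.sum() / total_time),
        )
    else:
        move_stats = (0.0, 0.0, 0.0, 0.0, 0.0)
    rest_durations = [b.duration for b in rests]
    return MovementProperties(
        movementLength=move_stats[0],
        movementLengthMax=move_stats[1],
        movementSum=move_stats[2],
        movementSpeed=move_stats[3],
        movementSpeedPooled=move_stats[4],
        restingDuration=float(np.mean(rest_durations)) if rests else 0.0,
        restingFrequency=len(rests),
        no_movement=not moves,
    )


def properties_table(
    tracks: list[Track],
    metadata: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """One row per individual-day: movement properties joined to covariates.

    Every track's (cricket_id, day) must appear exactly once in ``metadata``;
    unmatched tracks raise with the offending ids listed.  Rows are ordered
    deterministically by (cricket_id, day).
    """
    meta_cols = [c for c in metadata.columns]
    if not tracks:
        cols = meta_cols + PROPERTY_NAMES + ["movementSpeedPooled", "no_movement"]
        return pd.DataFrame(columns=list(dict.fromkeys(cols)))
    keyed = metadata.set_index(["cricket_id", "day"])
    if keyed.index.has_duplicates:
        raise ValueError("metadata has duplicate (cricket_id, day) rows")
    rows = []
    missing = []
    for track in tracks:
        key = (track.cricket_id, track.day)
        if key not in keyed.index:
            missing.append(key)
            continue
        props = compute_properties(segment_bouts(track, thresholds))
        row = dict(zip(["cricket_id", "day"], key))
        row.update(keyed.loc[key].to_dict())
        row.update(asdict(props))
        rows.append(row)
    if missing:
        raise KeyError(
            f"tracks without metadata for (cricket_id, day): {sorted(missing)}"
        )
    table = pd.DataFrame(rows).sort_values(["cricket_id", "day"])
    return table.reset_index(drop=True)
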