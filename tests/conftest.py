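import numpy as np
import pandas as pd
import pytest

from tagmove import Track


def make_track(positions, fps=24.0, cricket_id="t", day=1):
    positions = np.asarray(positions, dtype=float)
    times = np.arange(len(positions)) / fps
    return Track(cricket_id=cricket_id, times=times, positions=positions, day=day)


def piecewise_track(segments, fps=24.0, start=(0.1, 0.1)):
    """Build a track from (kind, duration_s, speed_m_s) segments.

    Movement segments go in a straight line at the given speed; rest
    segments sit perfectly still.  The first frame of each segment
    continues from the previous position.
    """
    pos = [np.asarray(start, dtype=float)]
    heading = 0.0
    for kind, duration, speed in segments:
        n = int(round(duration * fps))
        step = (speed / fps if kind == "move" else 0.0) * np.array(
            [np.cos(heading), np.sin(heading)]
        )
        for _ in range(n):
            pos.append(pos[-1] + step)
        heading += np.pi / 2  # turn between segments to stay in-bounds
    return make_track(np.array(pos), fps=fps)


def random_bout_track(rng, n_frames=200, fps=24.0):
    """Random alternating still/moving track for oracle comparisons."""
    pos = [rng.uniform(0.2, 0.6, size=2)]
    while len(pos) < n_frames:
        moving = rng.random() < 0.5
        k = int(rng.integers(1, 40))
        if moving:
            speed = rng.uniform(0.02, 0.12)
            heading = rng.uniform(0, 2 * np.pi)
            step = (speed / fps) * np.array([np.cos(heading), np.sin(heading)])
        else:
            step = np.zeros(2)
        for _ in range(k):
            jitter = rng.normal(0, 1e-5, size=2)
            pos.append(pos[-1] + step + jitter)
    return make_track(np.array(pos[:n_frames]), fps=fps)


def synthetic_properties_table(seed=0, n_per_cat=45, days=3, effects=None):
    """Cheap properties-table stand-in: draws property values directly from
    lognormal distributions instead of simulating trajectories.  Useful for
    testing the statistics layer in isolation."""
    from tagmove.properties import PROPERTY_NAMES

    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    base = {
        "movementLength": 0.08,
        "movementLengthMax": 0.4,
        "movementSum": 17.0,
        "movementSpeed": 0.066,
        "restingDuration": 2.0,
        "restingFrequency": 110,
    }
    for cat, tag in [("control", 0.0), ("light", 199.0), ("medium", 549.0), ("heavy", 759.0)]:
        for i in range(n_per_cat):
            cid = f"{cat}{i:03d}"
            animal = rng.normal(768, 117)
            ind_mult = rng.lognormal(0, 0.15)
            for day in range(1, days + 1):
                row = {
                    "cricket_id": cid,
                    "group": "g1",
                    "temperature_category": ["low", "intermediate", "high"][i % 3],
                    "temperature_c": 24.0,
                    "day": day,
                    "weight_category": cat,
                    "tag_weight_mg": tag,
                    "animal_weight_mg": animal,
                }
                mult = ind_mult * effects.get(cat, 1.0)
                for prop in PROPERTY_NAMES:
                    noise = rng.lognormal(0, 0.1)
                    row[prop] = base[prop] * mult * noise
                rows.append(row)
    return pd.DataFrame(rows)
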