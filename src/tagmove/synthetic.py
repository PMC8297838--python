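"""Seeded synthetic arena experiments with bout–rest movement structure.

Real recordings are 10-minute top-view videos of 20 crickets in a
1.2 x 0.8 m arena, repeated over 3 days at three temperatures, with 5
untagged controls and 5 individuals per tag-weight category in every group.
No raw trajectories from the original experiment are available, so this
module generates trajectories with the same structure: each individual
alternates resting periods (exponential durations, sub-threshold wobble)
with movement bouts (gamma-distributed path length walked at a roughly
constant speed along a correlated random walk with reflecting walls).

Tag weight and temperature act multiplicatively on the behavioural rates —
log-linearly in tag mass — so injected effects have closed-form expected
values and the full analysis pipeline can be exercised in recovery, power
and type-I experiments.  All randomness flows from one integer seed through
``numpy`` seed sequences; every (temperature, group, individual, day) cell
owns an independent substream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .segmentation import RESTING_SPEED_DEFAULT
from .trajectory_io import (
    TEMPERATURE_CATEGORIES,
    WEIGHT_CATEGORIES,
    Track,
)


@dataclass(frozen=True)
class BehaviorParams:
    """Generative parameters of one individual's bout–rest behaviour.

    Defaults are tuned so that the full pipeline lands its control-group
    medians near the reported control values (total distance ~ 16-20 m,
    mean rest ~ 2 s, ~ 100-150 rests, bout speed ~ 0.065 m/s in 10 min).

    mean_bout_length : m — mean of the gamma path-length distribution.
    bout_length_shape : gamma shape (1 = exponential; < 1 very skewed).
    mean_bout_speed : m/s — within-bout walking speed.
    mean_rest_duration : s — mean of the exponential rest duration; ``inf``
        degenerates to an all-rest track.
    rest_jitter_speed : m/s — bound on apparent speed of the sub-threshold
        wobble while resting; must stay below the 0.01 m/s resting
        threshold so generated rests are detectable by construction.
    turning_sd : rad/step — heading persistence of the correlated random
        walk during movement.
    position_noise_sd : m — tracker localisation noise added to every frame.
    bout_speed_cv : within-individual between-bout speed variation.
    individual_cv : between-individual lognormal variation of speed, bout
        length and rest duration (behavioural heterogeneity of the cohort).
    """

    mean_bout_length: float = 0.09
    bout_length_shape: float = 1.2
    mean_bout_speed: float = 0.08
    mean_rest_duration: float = 2.0
    rest_jitter_speed: float = 0.003
    turning_sd: float = 0.35
    position_noise_sd: float = 8e-5
    bout_speed_cv: float = 0.15
    individual_cv: float = 0.15

    def __post_init__(self) -> None:
        for name in ("mean_bout_length", "bout_length_shape", "mean_bout_speed",
                     "mean_rest_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.rest_jitter_speed <= 0 or self.rest_jitter_speed >= RESTING_SPEED_DEFAULT:
            raise ValueError(
                "rest_jitter_speed must lie in (0, resting threshold "
                f"{RESTING_SPEED_DEFAULT} m/s) so rests stay detectable"
            )
        if self.position_noise_sd < 0 or self.turning_sd < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class EffectModel:
    """Multiplicative treatment effects on the behavioural rates.

    A tag of mass w mg scales speed by ``speed_multiplier_per_mg ** w`` (and
    likewise bout length and rest duration); a temperature category scales
    the same three rates by its multiplier triple
    ``(speed, bout_length, rest_duration)``.  A per-mg multiplier of 1 and a
    unit triple are the identity, so untagged individuals at a neutral
    category are unaffected.
    """

    speed_multiplier_per_mg: float = 1.0
    bout_length_multiplier_per_mg: float = 1.0
    rest_duration_multiplier_per_mg: float = 1.0
    temperature_multipliers: dict = field(
        default_factory=lambda: {
            cat: (1.0, 1.0, 1.0) for cat in TEMPERATURE_CATEGORIES
        }
    )

    def __post_init__(self) -> None:
        for name in ("speed_multiplier_per_mg", "bout_length_multiplier_per_mg",
                     "rest_duration_multiplier_per_mg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for cat, triple in self.temperature_multipliers.items():
            if len(triple) != 3 or any(m <= 0 for m in triple):
                raise ValueError(f"bad multiplier triple for {cat!r}")


def neutral_effects() -> EffectModel:
    """Identity effect model: no tag or temperature influence."""
    return EffectModel()


def representative_effects() -> EffectModel:
    """Qualitatively realistic effects: heavier tags slow individuals down,
    shorten their bouts and lengthen their rests (roughly -25% speed, -30%
    bout length, +50% rest duration at 760 mg); low temperature lengthens
    bouts and shortens rests while high temperature does the opposite."""
    per_mg = lambda total, mass=760.0: math.exp(math.log(total) / mass)
    return EffectModel(
        speed_multiplier_per_mg=per_mg(0.75),
        bout_length_multiplier_per_mg=per_mg(0.70),
        rest_duration_multiplier_per_mg=per_mg(1.50),
        temperature_multipliers={
            "low": (0.97, 1.30, 0.75),
            "intermediate": (1.0, 1.0, 1.0),
            "high": (1.0, 0.60, 1.40),
        },
    )


def apply_effects(
    params: BehaviorParams,
    tag_mass: float,
    temperature_category: str,
    effects: EffectModel,
) -> BehaviorParams:
    """Scale behaviour by a tag mass and a temperature category."""
    if tag_mass < 0:
        raise ValueError("tag_mass must be non-negative")
    try:
        t_speed, t_len, t_rest = effects.temperature_multipliers[temperature_category]
    except KeyError:
        raise KeyError(
            f"temperature category {temperature_category!r} unknown to the "
            f"effect model ({sorted(effects.temperature_multipliers)})"
        ) from None
    return replace(
        params,
        mean_bout_speed=params.mean_bout_speed
        * t_speed
        * effects.speed_multiplier_per_mg**tag_mass,
        mean_bout_length=params.mean_bout_length
        * t_len
        * effects.bout_length_multiplier_per_mg**tag_mass,
        mean_rest_duration=params.mean_rest_duration
        * t_rest
        * effects.rest_duration_multiplier_per_mg**tag_mass,
    )


@dataclass(frozen=True)
class SyntheticExperimentDesign:
    """Layout of a synthetic arena experiment (defaults: the real design).

    Three replicate groups of 20 individuals per temperature (5 control + 5
    per tag-weight category), recorded 10 minutes a day at 24 fps on 3
    consecutive days in a 1.2 x 0.8 m arena.
    """

    n_groups_per_temperature: int = 3
    individuals_per_group: int = 20
    temperature_levels: tuple[float, ...] = (19.5, 24.0, 28.3)
    days: int = 3
    tag_mass_distributions: dict = field(
        default_factory=lambda: {
            "light": (198.7, 2.1),
            "medium": (549.2, 7.3),
            "heavy": (758.6, 6.9),
        }
    )
    animal_mass_distribution: tuple[float, float] = (768.0, 117.0)
    day_mass_jitter_sd: float = 8.0  # mg day-to-day weighing/physiology noise
    recording_duration: float = 600.0
    fps: float = 24.0
    arena: tuple[float, float] = (1.2, 0.8)

    def __post_init__(self) -> None:
        n_cats = len(self.tag_mass_distributions) + 1
        if self.individuals_per_group % n_cats:
            raise ValueError(
                f"individuals_per_group must be divisible by {n_cats} weight categories"
            )
        if len(self.temperature_levels) > len(TEMPERATURE_CATEGORIES):
            raise ValueError("at most three temperature levels supported")
        n_frames = self.recording_duration * self.fps
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("recording_duration x fps must be an integer frame count")
        if self.recording_duration <= 0 or self.fps <= 0:
            raise ValueError("duration and fps must be positive")
        if any(a <= 0 for a in self.arena):
            raise ValueError("arena dimensions must be positive")

    @property
    def temperature_categories(self) -> tuple[str, ...]:
        # levels are assigned low/intermediate/high in ascending order
        order = np.argsort(self.temperature_levels)
        cats = [None] * len(self.temperature_levels)
        for rank, idx in enumerate(order):
            cats[idx] = TEMPERATURE_CATEGORIES[rank] if len(
                self.temperature_levels
            ) == 3 else TEMPERATURE_CATEGORIES[min(rank, 2)]
        return tuple(cats)

    @property
    def weight_categories(self) -> tuple[str, ...]:
        return ("control",) + tuple(self.tag_mass_distributions)


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(key)))


def simulate_track(
    params: BehaviorParams,
    duration: float,
    fps: float,
    arena: tuple[float, float] = (1.2, 0.8),
    seed: int | np.random.Generator = 0,
) -> Track:
    """Simulate one individual's calibrated track.

    The track alternates exponential rests (anchored wobble whose per-frame
    displacement never exceeds ``rest_jitter_speed / fps``) with movement
    bouts of gamma path length, walked at a per-bout lognormal speed along a
    correlated random walk; walls reflect.  ``duration * fps + 1`` frames
    are returned; identical seeds give identical tracks.
    """
    if duration <= 0 or fps <= 0:
        raise ValueError("duration and fps must be positive")
    if any(a <= 0 for a in arena):
        raise ValueError("arena dimensions must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_frames = int(round(duration * fps)) + 1
    arena = np.asarray(arena, dtype=float)
    pos = np.empty((n_frames, 2))
    pos[0] = rng.uniform([0, 0], arena)
    wobble_r = params.rest_jitter_speed / (2.0 * fps)
    speed_sigma = math.sqrt(math.log(1.0 + params.bout_speed_cv**2))

    filled = 1
    resting = True  # recordings start mid-rest
    heading = rng.uniform(0.0, 2.0 * math.pi)
    while filled < n_frames:
        remaining = n_frames - filled
        anchor = pos[filled - 1]
        if resting:
            if math.isinf(params.mean_rest_duration):
                k = remaining
            else:
                dur = rng.exponential(params.mean_rest_duration)
                k = min(remaining, max(1, int(round(dur * fps))))
            theta = rng.uniform(0.0, 2.0 * math.pi, size=k)
            radius = wobble_r * np.sqrt(rng.uniform(0.0, 1.0, size=k))
            offsets = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
            pos[filled : filled + k] = np.clip(anchor + offsets, 0.0, arena)
        else:
            length = _draw_bout_length(params, rng)
            speed = params.mean_bout_speed * math.exp(
                rng.normal(-0.5 * speed_sigma**2, speed_sigma)
            )
            k = min(remaining, max(2, int(round(length / speed * fps))))
            heading = rng.uniform(0.0, 2.0 * math.pi)
            turns = rng.normal(0.0, params.turning_sd, size=k)
            angles = heading + np.cumsum(turns)
            steps = (speed / fps) * np.column_stack([np.cos(angles), np.sin(angles)])
            raw = anchor + np.cumsum(steps, axis=0)
            # reflecting walls: fold the unconstrained walk into the box
            folded = np.abs(np.mod(raw, 2.0 * arena) - arena)
            pos[filled : filled + k] = arena - folded
        filled += k
        resting = not resting

    if params.position_noise_sd > 0:
        pos += rng.normal(0.0, params.position_noise_sd, size=pos.shape)
        np.clip(pos, 0.0, arena, out=pos)
    times = np.arange(n_frames) / fps
    return Track(cricket_id="sim", times=times, positions=pos)


def _draw_bout_length(params: BehaviorParams, rng: np.random.Generator) -> float:
    return float(
        rng.gamma(params.bout_length_shape, params.mean_bout_length / params.bout_length_shape)
    )


def sample_bout_lengths(params: BehaviorParams, n: int, seed: int = 0) -> np.ndarray:
    """Draw n path lengths from the generator's bout-length distribution
    (gamma with the configured mean and shape); used for calibration checks."""
    rng = np.random.default_rng(seed)
    return np.array([_draw_bout_length(params, rng) for _ in range(n)])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(100):
        value = rng.normal(mean, sd)
        if value > 0:
            return float(value)
    raise RuntimeError("could not draw a positive mass")


def _individual_params(
    base: BehaviorParams, rng: np.random.Generator
) -> BehaviorParams:
    """Between-individual behavioural heterogeneity (lognormal multipliers)."""
    cv = base.individual_cv
    if cv <= 0:
        return base
    sigma = math.sqrt(math.log(1.0 + cv**2))
    draw = lambda: math.exp(rng.normal(-0.5 * sigma**2, sigma))
    return replace(
        base,
        mean_bout_speed=base.mean_bout_speed * draw(),
        mean_bout_length=base.mean_bout_length * draw(),
        mean_rest_duration=base.mean_rest_duration * draw(),
    )


def simulate_arms(
    n_per_category: dict,
    base: BehaviorParams = BehaviorParams(),
    effects: EffectModel = neutral_effects(),
    temperature_category: str = "intermediate",
    temperature_c: float = 24.0,
    days: int = 1,
    duration: float = 600.0,
    fps: float = 24.0,
    arena: tuple[float, float] = (1.2, 0.8),
    seed: int = 0,
) -> tuple[list[Track], pd.DataFrame]:
    """Simulate unbalanced comparison arms at a single temperature.

    ``n_per_category`` maps weight categories to arm sizes, e.g.
    ``{"control": 45, "heavy": 15}``.  Used for power and false-positive
    experiments where the pooled arm sizes matter but the full group
    structure does not.  Tag masses are drawn from the default design's
    category distributions.
    """
    default_masses = SyntheticExperimentDesign().tag_mass_distributions
    animal_dist = SyntheticExperimentDesign().animal_mass_distribution
    tracks: list[Track] = []
    records = []
    for c_idx, (category, n) in enumerate(sorted(n_per_category.items())):
        if category != "control" and category not in default_masses:
            raise KeyError(f"unknown weight category {category!r}")
        for i in range(n):
            cid = f"{category}{i + 1:02d}"
            rng_ind = _rng_for(seed, c_idx, i, 10_000)
            tag_mass = (
                0.0
                if category == "control"
                else _truncated_normal(rng_ind, *default_masses[category])
            )
            animal_mass = _truncated_normal(rng_ind, *animal_dist)
            params = apply_effects(
                _individual_params(base, rng_ind), tag_mass, temperature_category, effects
            )
            for day in range(1, days + 1):
                track = simulate_track(
                    params, duration, fps, arena, seed=_rng_for(seed, c_idx, i, day)
                )
                track.cricket_id = cid
                track.day = day
                tracks.append(track)
                records.append(
                    {
                        "cricket_id": cid,
                        "group": "arm",
                        "temperature_category": temperature_category,
                        "temperature_c": temperature_c,
                        "day": day,
                        "weight_category": category,
                        "tag_weight_mg": round(tag_mass, 1),
                        "animal_weight_mg": round(animal_mass, 1),
                    }
                )
    return tracks, pd.DataFrame(records)


def simulate_experiment(
    design: SyntheticExperimentDesign,
    base: BehaviorParams = BehaviorParams(),
    effects: EffectModel = neutral_effects(),
    seed: int = 0,
) -> tuple[list[Track], pd.DataFrame]:
    """Simulate a full multi-day arena experiment.

    Returns one track per individual per day (cricket ids stable across
    days) and the metadata table of experiment covariates.  Tag and animal
    masses are drawn from the design's normal distributions truncated to
    positive values; each individual keeps its tag mass while its body mass
    wanders slightly from day to day.
    """
    tracks: list[Track] = []
    records = []
    weight_cats = design.weight_categories
    per_cat = design.individuals_per_group // len(weight_cats)
    for t_idx, (temp_c, temp_cat) in enumerate(
        zip(design.temperature_levels, design.temperature_categories)
    ):
        for g_idx in range(design.n_groups_per_temperature):
            for i_idx in range(design.individuals_per_group):
                category = weight_cats[i_idx // per_cat]
                cid = f"T{t_idx + 1}G{g_idx + 1}C{i_idx + 1:02d}"
                rng_ind = _rng_for(seed, t_idx, g_idx, i_idx, 10_000)
                if category == "control":
                    tag_mass = 0.0
                else:
                    tag_mass = _truncated_normal(
                        rng_ind, *design.tag_mass_distributions[category]
                    )
                animal_mass = _truncated_normal(
                    rng_ind, *design.animal_mass_distribution
                )
                params = apply_effects(
                    _individual_params(base, rng_ind), tag_mass, temp_cat, effects
                )
                for day in range(1, design.days + 1):
                    rng_day = _rng_for(seed, t_idx, g_idx, i_idx, day)
                    track = simulate_track(
                        params,
                        design.recording_duration,
                        design.fps,
                        design.arena,
                        seed=rng_day,
                    )
                    track.cricket_id = cid
                    track.day = day
                    tracks.append(track)
                    records.append(
                        {
                            "cricket_id": cid,
                            "group": f"T{t_idx + 1}G{g_idx + 1}",
                            "temperature_category": temp_cat,
                            "temperature_c": temp_c,
                            "day": day,
                            "weight_category": category,
                            "tag_weight_mg": round(tag_mass, 1),
                            "animal_weight_mg": round(animal_mass, 1),
                        }
                    )
                    if design.day_mass_jitter_sd > 0:
                        animal_mass = max(
                            1.0,
                            animal_mass
                            + rng_ind.normal(0.0, design.day_mass_jitter_sd),
                        )
    metadata = pd.DataFrame(records)
    return tracks, metadata
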