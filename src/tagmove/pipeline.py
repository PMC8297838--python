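"""Pipeline orchestration: configuration, report emission, rounding.

``run`` chains the stages — synthetic simulation (or reading tracker CSVs),
gap repair, bout segmentation, movement properties, the comparison battery,
slope and body-mass analyses and the mixed model — and writes the report
bundle: property and bout tables, median tables with significance flags,
percent changes, slope and body-mass results, the mixed-model coefficient
table and a machine-readable JSON summary.

Report rounding is centralised here: lengths and speeds to 3 decimals,
durations and distances to 2, counts to integers, percents to the nearest
integer — matching the precision the reference report tables use.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mixed_model as mm
from . import stats as tstats
from .properties import PROPERTY_NAMES, properties_table
from .segmentation import Thresholds, bout_table
from .synthetic import (
    BehaviorParams,
    EffectModel,
    SyntheticExperimentDesign,
    neutral_effects,
    simulate_experiment,
)
from .trajectory_io import (
    Calibration,
    Track,
    fill_gaps,
    read_metadata,
    read_tracks,
    write_metadata,
    write_tracks,
)

logger = logging.getLogger(__name__)

#: decimals per property in the printed report tables
_PROPERTY_DECIMALS = {
    "movementLength": 3,
    "movementLengthMax": 3,
    "movementSum": 2,
    "movementSpeed": 3,
    "restingDuration": 2,
    "restingFrequency": 0,
}


class PipelineDataError(RuntimeError):
    """A stage failed on the provided data (missing inputs, join errors...)."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    output_dir: str = "results"
    trajectories: str | None = None  # directory of trajectory CSVs (analyze mode)
    metadata: str | None = None  # metadata CSV path (analyze mode)
    calibration: Calibration = field(
        default_factory=lambda: Calibration(px_per_metre=1.0)
    )
    thresholds: Thresholds = field(default_factory=Thresholds)
    max_gap_frames: int = 12
    alpha: float = 0.05
    design: SyntheticExperimentDesign = field(
        default_factory=SyntheticExperimentDesign
    )
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    effects: EffectModel = field(default_factory=neutral_effects)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub_cls in [
            ("calibration", Calibration),
            ("thresholds", Thresholds),
            ("design", SyntheticExperimentDesign),
            ("behavior", BehaviorParams),
            ("effects", EffectModel),
        ]:
            if key in raw:
                sub = raw.pop(key)
                if key == "design":
                    for tup in ("temperature_levels", "animal_mass_distribution", "arena"):
                        if tup in sub:
                            sub[tup] = tuple(sub[tup])
                    if "tag_mass_distributions" in sub:
                        sub["tag_mass_distributions"] = {
                            k: tuple(v) for k, v in sub["tag_mass_distributions"].items()
                        }
                if key == "effects" and "temperature_multipliers" in sub:
                    sub["temperature_multipliers"] = {
                        k: tuple(v) for k, v in sub["temperature_multipliers"].items()
                    }
                if key == "calibration" and "arena_size" in sub:
                    sub["arena_size"] = tuple(sub["arena_size"])
                kwargs[key] = sub_cls(**sub)
        kwargs.update(raw)
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""

        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (np.ndarray, tuple)):
                return [encode(v) for v in obj]
            if isinstance(obj, dict):
                return {k: encode(v) for k, v in obj.items()}
            return obj
        payload = encode(self)
        for path_field in ("output_dir", "trajectories", "metadata"):
            payload.pop(path_field, None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _package_version() -> str:
    try:
        return _pkg_version("tagmove")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def round_report(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the central report rounding to any property columns present."""
    out = table.copy()
    for col, dec in _PROPERTY_DECIMALS.items():
        if col in out.columns:
            out[col] = out[col].round(dec) if dec else out[col].round().astype("Int64")
    if "percent_change" in out.columns:
        out["percent_change"] = out["percent_change"].round().astype("Int64")
    return out


def simulate(config: PipelineConfig, out_dir: Path) -> tuple[list[Track], pd.DataFrame]:
    """Simulate the configured experiment and write tracks + metadata."""
    out_dir.mkdir(parents=True, exist_ok=True)
    tracks, metadata = simulate_experiment(
        config.design, config.behavior, config.effects, seed=config.seed
    )
    traj_dir = out_dir / "trajectories"
    traj_dir.mkdir(exist_ok=True)
    by_group_day: dict[tuple[str, int], list[Track]] = {}
    meta_keyed = metadata.set_index(["cricket_id", "day"])["group"]
    for track in tracks:
        group = meta_keyed.loc[(track.cricket_id, track.day)]
        by_group_day.setdefault((group, track.day), []).append(track)
    for (group, day), group_tracks in sorted(by_group_day.items()):
        write_tracks(
            group_tracks, traj_dir / f"{group}_day{day}.csv", fps=config.design.fps
        )
    write_metadata(metadata, out_dir / "metadata.csv")
    logger.info("simulated %d tracks", len(tracks))
    return tracks, metadata


def load_inputs(config: PipelineConfig) -> tuple[list[Track], pd.DataFrame]:
    """Read tracker CSVs + metadata for analyze mode, repairing short gaps."""
    if not config.trajectories or not config.metadata:
        raise PipelineDataError("analyze mode needs trajectories and metadata paths")
    traj_dir = Path(config.trajectories)
    files = sorted(traj_dir.glob("*.csv")) if traj_dir.is_dir() else []
    if not files:
        raise PipelineDataError(f"no trajectory CSVs found under {traj_dir}")
    metadata = read_metadata(config.metadata)
    meta_days = metadata.set_index(["cricket_id", "day"]).index
    tracks: list[Track] = []
    for path in files:
        day = _day_from_name(path.stem)
        for track in read_tracks(path, config.calibration):
            track.day = day
            for segment in fill_gaps(
                track, max_gap=config.max_gap_frames, fps=config.calibration.fps
            ):
                tracks.append(segment)
    missing = [
        (t.cricket_id, t.day) for t in tracks if (t.cricket_id, t.day) not in meta_days
    ]
    if missing:
        raise PipelineDataError(f"tracks without metadata rows: {sorted(set(missing))}")
    return tracks, metadata


def _day_from_name(stem: str) -> int:
    # trajectory files are named <group>_day<k>.csv
    marker = "day"
    idx = stem.rfind(marker)
    if idx == -1:
        raise PipelineDataError(
            f"cannot infer recording day from file name {stem!r} (expected *_day<k>)"
        )
    return int(stem[idx + len(marker):])


def analyze(
    tracks: list[Track],
    metadata: pd.DataFrame,
    config: PipelineConfig,
    out_dir: Path,
) -> dict:
    """Run segmentation -> properties -> statistics and write the bundle."""
    out_dir.mkdir(parents=True, exist_ok=True)
    props = properties_table(tracks, metadata, config.thresholds)
    round_report(props).to_csv(out_dir / "properties.csv", index=False)
    bouts = bout_table(tracks, config.thresholds)
    bouts.to_csv(out_dir / "bouts.csv", index=False, float_format="%.4f")

    comparisons = {}
    for stratify in ("pooled", "by_temperature"):
        comp = tstats.compare_to_control(props, stratify=stratify)
        round_report(comp).to_csv(out_dir / f"comparisons_{stratify}.csv", index=False)
        med = tstats.medians_table(props, stratify=stratify)
        med.round(3).to_csv(out_dir / f"medians_{stratify}.csv")
        comparisons[stratify] = comp

    slope_tests = []
    for prop in PROPERTY_NAMES:
        slopes, tests = tstats.slope_analysis(props, prop)
        slope_tests.append(tests)
    slope_tests = pd.concat(slope_tests, ignore_index=True)
    slope_tests.to_csv(out_dir / "slope_tests.csv", index=False, float_format="%.5g")

    mass = tstats.body_mass_tests(metadata)
    mass.to_csv(out_dir / "body_mass.csv", index=False, float_format="%.5g")

    fit = mm.fit_movement_sum_model(props)
    fit.coefficients.to_csv(
        out_dir / "mixed_model_coefficients.csv", index=False, float_format="%.4f"
    )
    fit.anova.to_csv(out_dir / "mixed_model_anova.csv", index=False, float_format="%.4f")

    summary = {
        "version": _package_version(),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_tracks": len(tracks),
        "n_individuals": int(metadata["cricket_id"].nunique()),
        "significant_tests": {
            name: int(comp["significant"].sum()) for name, comp in comparisons.items()
        },
        "n_tests": {name: int(len(comp)) for name, comp in comparisons.items()},
        "distance_reduction_per_100mg_low": mm.distance_reduction_per_100mg(
            fit.coefficients, "low"
        ),
        "random_intercept_variance": fit.random_intercept_variance,
        "residual_variance": fit.residual_variance,
        "random_effect_p": fit.random_effect_p,
        "slope_tests_significant": int((slope_tests["p_value"] < config.alpha).sum()),
    }
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def run(config: PipelineConfig, mode: str = "full") -> dict:
    """Run the pipeline: ``simulate``, ``analyze`` or ``full``."""
    if mode not in ("simulate", "analyze", "full"):
        raise ValueError("mode must be simulate, analyze or full")
    out_dir = Path(config.output_dir)
    logger.info(
        "tagmove %s run, seed=%d, config=%s",
        mode, config.seed, config.config_hash(),
    )
    if mode == "simulate":
        simulate(config, out_dir)
        return {"mode": mode, "output_dir": str(out_dir)}
    if mode == "analyze":
        tracks, metadata = load_inputs(config)
    else:
        tracks, metadata = simulate(config, out_dir)
    return analyze(tracks, metadata, config, out_dir)
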