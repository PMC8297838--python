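# tagmove

Researchers attach tags — radio transmitters, RFID chips, sensor payloads —
to insects to track them, and the tag's weight can itself change the
behaviour being measured. `tagmove` implements the trajectory-analysis
pipeline for quantifying that effect in a laboratory arena experiment:
groups of flightless crickets (untagged controls plus light ≈ 199 mg,
medium ≈ 549 mg and heavy ≈ 759 mg dummy tags) filmed from above for
10 minutes a day over 3 days at three temperatures, with per-frame
(x, y) positions per individual from an identity-preserving video tracker.

The package takes those per-frame trajectories and:

1. **calibrates** pixels to metres and repairs short tracking dropouts
   (`trajectory_io`);
2. **segments** each track into *movement bouts* (continuous locomotion
   longer than 2 cm) and *resting periods* (still or ≤ 1 cm/s)
   (`segmentation`);
3. **measures** six properties per individual-recording: `movementLength`,
   `movementLengthMax`, `movementSum`, `movementSpeed`, `restingDuration`,
   `restingFrequency` (`properties`);
4. **compares** each tagged group to the controls with two-sided
   Mann–Whitney U tests per property × day (pooled over temperature and
   stratified by it), Benjamini–Yekutieli-adjusted within each analysis
   family, plus per-individual day-slope comparisons and paired Wilcoxon
   body-mass tests (`stats`);
5. **models** distance travelled with a random-intercept linear mixed
   model, `movementSum ~ temperature * tag_weight + temperature *
   animal_weight + (1 | cricket_id)`, fitted by REML with
   Satterthwaite-type degrees of freedom, and derives the distance lost
   per 100 mg of tag (`mixed_model`).

Because the original videos and trajectories are unavailable, a seeded
synthetic generator (`synthetic`) reproduces the experiment's structure —
exponential rests alternating with gamma-length movement bouts walked as a
correlated random walk, with multiplicative tag and temperature effects —
so every stage is testable end to end. See `docs/methods.md` for models,
thresholds and assumptions.

## Worked example

```python
from tagmove import (BehaviorParams, SyntheticExperimentDesign,
                     compare_to_control, properties_table,
                     representative_effects, simulate_experiment)

tracks, metadata = simulate_experiment(
    SyntheticExperimentDesign(), BehaviorParams(),
    representative_effects(), seed=0)          # 540 tracks, 180 crickets
props = properties_table(tracks, metadata)     # 540 rows x 6 properties
comp = compare_to_control(props, stratify="pooled")
speed = comp.query("property == 'movementSpeed' and day == 1")
print(speed[["weight_category", "median_control", "median_tag",
             "percent_change", "p_adjusted", "significant"]].round(4)
      .to_string(index=False))
```

prints (seed 0):

```
weight_category  median_control  median_tag  percent_change  p_adjusted  significant
          light          0.0638      0.0591         -7.4119      0.2408        False
         medium          0.0638      0.0519        -18.6417      0.0000         True
          heavy          0.0638      0.0497        -22.0905      0.0000         True
```

i.e. with the qualitatively realistic effect model, medium and heavy tags
reduce median movement speed by ~19% and ~22% and survive the BY
adjustment, while the light tag does not. The same run's mixed model
(`analysis/03_mixed_model.py`) estimates a tag-weight slope of
−0.0093 m/mg at the intermediate temperature with a −0.0032 low-temperature
interaction: about 1.25 m of distance lost per 100 mg of tag in a
10-minute recording at low temperature.

The numbered scripts under `analysis/` run the same chain as a narrative —
`01_simulate_and_measure.py`, `02_compare_groups.py`, `03_mixed_model.py`,
`04_attachment_duration_and_mass.py` — writing their tables to `results/`.
A `tagmove` CLI (`simulate` / `analyze` / `full`, with `--config`,
`--seed`, `--out`) wraps the pipeline for tracker-exported CSVs.

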