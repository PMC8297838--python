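"""Reference summary values reported for the original tag-load experiment.

The raw trajectories of the original cricket experiment were never deposited;
what is available are its printed summaries: group medians of the six
movement properties (by day and tag-weight category, pooled over temperature
and stratified by it) and the fitted coefficient table of the
distance-travelled mixed model.  Those printed values are inputs for worked
examples — e.g. Discussion-style percent changes of tagged medians against
control, or the distance reduction per 100 mg of tag implied by the model
coefficients — and for cross-checking this package's report layout.
"""

from __future__ import annotations

import io

import pandas as pd

# Group medians without regard to temperature: rows day x property,
# columns weight category.  Lengths/speeds in metres and m/s, durations in
# seconds, restingFrequency a count.
_POOLED_MEDIANS_CSV = """\
day,property,control,light,medium,heavy
1,movementLength,0.075,0.070,0.071,0.065
2,movementLength,0.078,0.070,0.073,0.072
3,movementLength,0.080,0.077,0.076,0.068
1,movementLengthMax,0.386,0.305,0.289,0.273
2,movementLengthMax,0.384,0.311,0.276,0.287
3,movementLengthMax,0.406,0.385,0.317,0.297
1,movementSum,15.63,12.21,11.79,9.19
2,movementSum,19.84,16.08,15.66,12.04
3,movementSum,18.97,17.63,13.34,11.73
1,movementSpeed,0.064,0.057,0.056,0.051
2,movementSpeed,0.066,0.061,0.055,0.050
3,movementSpeed,0.069,0.065,0.059,0.050
1,restingDuration,2.03,2.14,2.76,2.87
2,restingDuration,1.40,1.66,1.94,2.59
3,restingDuration,1.86,1.72,2.23,2.31
1,restingFrequency,101,118,105,109
2,restingFrequency,111,109,107,109
3,restingFrequency,106,111,109,111
"""

# Medians stratified by temperature category.
_STRATIFIED_MEDIANS_CSV = """\
temperature_category,day,property,control,light,medium,heavy
low,1,movementLength,0.104,0.082,0.084,0.086
low,2,movementLength,0.092,0.079,0.075,0.077
low,3,movementLength,0.105,0.072,0.076,0.070
low,1,movementLengthMax,0.515,0.443,0.327,0.341
low,2,movementLengthMax,0.451,0.311,0.257,0.283
low,3,movementLengthMax,0.528,0.396,0.291,0.334
low,1,movementSum,22.05,17.07,13.47,10.69
low,2,movementSum,22.56,16.08,11.33,11.28
low,3,movementSum,21.87,16.35,12.15,11.73
low,1,movementSpeed,0.067,0.056,0.048,0.051
low,2,movementSpeed,0.063,0.050,0.048,0.042
low,3,movementSpeed,0.065,0.048,0.044,0.040
low,1,restingDuration,1.45,1.53,2.34,2.92
low,2,restingDuration,1.25,1.50,2.18,2.60
low,3,restingDuration,1.49,1.31,2.11,2.66
low,1,restingFrequency,105,127,119,105
low,2,restingFrequency,105,113,116,98
low,3,restingFrequency,111,121,114,101
intermediate,1,movementLength,0.069,0.076,0.063,0.063
intermediate,2,movementLength,0.075,0.071,0.078,0.074
intermediate,3,movementLength,0.076,0.085,0.084,0.075
intermediate,1,movementLengthMax,0.345,0.304,0.283,0.247
intermediate,2,movementLengthMax,0.326,0.372,0.309,0.319
intermediate,3,movementLengthMax,0.365,0.449,0.354,0.303
intermediate,1,movementSum,16.32,12.32,14.43,9.19
intermediate,2,movementSum,19.70,18.17,15.90,14.91
intermediate,3,movementSum,18.04,22.91,17.84,12.98
intermediate,1,movementSpeed,0.066,0.061,0.064,0.055
intermediate,2,movementSpeed,0.067,0.064,0.060,0.053
intermediate,3,movementSpeed,0.069,0.073,0.065,0.055
intermediate,1,restingDuration,2.02,1.97,2.57,2.28
intermediate,2,restingDuration,1.49,1.75,1.81,1.66
intermediate,3,restingDuration,1.96,1.55,1.95,1.96
intermediate,1,restingFrequency,107,116,103,117
intermediate,2,restingFrequency,115,109,107,119
intermediate,3,restingFrequency,106,106,116,109
high,1,movementLength,0.059,0.057,0.054,0.059
high,2,movementLength,0.066,0.063,0.061,0.071
high,3,movementLength,0.065,0.069,0.068,0.062
high,1,movementLengthMax,0.241,0.311,0.230,0.224
high,2,movementLengthMax,0.295,0.267,0.276,0.282
high,3,movementLengthMax,0.291,0.295,0.310,0.282
high,1,movementSum,7.97,10.36,7.39,6.93
high,2,movementSum,17.56,15.39,16.64,11.60
high,3,movementSum,11.40,16.47,10.73,10.05
high,1,movementSpeed,0.061,0.054,0.056,0.047
high,2,movementSpeed,0.066,0.063,0.061,0.053
high,3,movementSpeed,0.069,0.070,0.066,0.053
high,1,restingDuration,4.38,2.62,3.54,4.08
high,2,restingDuration,1.65,1.72,1.71,2.65
high,3,restingDuration,2.92,2.07,2.59,2.36
high,1,restingFrequency,80,102,97,92
high,2,restingFrequency,99,103,100,105
high,3,restingFrequency,98,114,104,111
"""

# Reported coefficient table of the distance-travelled mixed model
# (movementSum in metres; tag and animal weight in mg; temperature reference
# level: intermediate).
_MIXED_MODEL_COEFFICIENTS_CSV = """\
term,Estimate,Std. Error,df,t value,Pr(>|t|)
(Intercept),0.8481,2.4375,294.7989,0.3479,0.7281
high temperature,-10.4746,3.5562,349.7777,-2.9455,0.0034
low temperature,10.8655,3.2454,258.9370,3.3480,0.0009
tag weight,-0.0077,0.0012,167.3106,-6.3737,0.0000
animal weight,0.0217,0.0031,303.1101,7.1041,0.0000
high temperature:tag weight,0.0052,0.0017,168.0552,3.0456,0.0027
low temperature:tag weight,-0.0063,0.0017,166.9246,-3.6653,0.0003
high temperature:animal weight,0.0077,0.0044,360.8046,1.7496,0.0810
low temperature:animal weight,-0.0109,0.0039,268.4809,-2.7685,0.0060
"""


def reported_pooled_medians() -> pd.DataFrame:
    """Movement-property medians by day and weight category (pooled)."""
    return pd.read_csv(io.StringIO(_POOLED_MEDIANS_CSV))


def reported_stratified_medians() -> pd.DataFrame:
    """Movement-property medians stratified by temperature category."""
    return pd.read_csv(io.StringIO(_STRATIFIED_MEDIANS_CSV))


def reported_mixed_model_coefficients() -> pd.DataFrame:
    """Reported fixed-effect table of the distance-travelled mixed model."""
    return pd.read_csv(io.StringIO(_MIXED_MODEL_COEFFICIENTS_CSV))
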