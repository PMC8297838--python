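#!/usr/bin/env python
"""Attachment-duration slopes and body-mass change.

Fits a per-individual least-squares line of each movement property against
day number and compares the tagged categories' slope distributions with the
control's; then runs the paired Wilcoxon tests of body-mass change between
consecutive days.
"""

from pathlib import Path

import pandas as pd

from tagmove import body_mass_tests, slope_analysis
from tagmove.properties import PROPERTY_NAMES

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    props = pd.read_csv(RESULTS / "properties.csv")
    tests = []
    for prop in PROPERTY_NAMES:
        _, t = slope_analysis(props, prop)
        tests.append(t)
    tests = pd.concat(tests, ignore_index=True)
    tests.to_csv(RESULTS / "slope_tests.csv", index=False, float_format="%.5g")
    sig = tests[tests["p_value"] < 0.05]
    print(f"slope comparisons vs control: {len(sig)}/{len(tests)} significant")
    for _, row in sig.iterrows():
        print(
            f"  {row['property']} {row['weight_category']}: median slope "
            f"{row['median_slope_tag']:.4g}/day vs control "
            f"{row['median_slope_control']:.4g}/day (p = {row['p_value']:.3g})"
        )

    meta = pd.read_csv(RESULTS / "metadata.csv")
    mass = body_mass_tests(meta)
    mass.to_csv(RESULTS / "body_mass.csv", index=False, float_format="%.5g")
    overall = mass[mass["stratum"] == "all"]
    for _, row in overall.iterrows():
        print(
            f"body mass days {row['day_pair']}: median shift "
            f"{row['median_shift_mg']:+.1f} mg (p = {row['p_value']:.3g})"
        )


if __name__ == "__main__":
    main()
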