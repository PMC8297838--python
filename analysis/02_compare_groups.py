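#!/usr/bin/env python
"""Compare tagged groups to controls with the Mann-Whitney/BY battery.

Runs the two comparison families on the measured property table — pooled
over temperature (54 tests) and stratified by temperature (162 tests) —
writes the comparison and median tables, and reports how many comparisons
stay significant after Benjamini-Yekutieli adjustment.
"""

from pathlib import Path

import pandas as pd

from tagmove import compare_to_control, medians_table
from tagmove.pipeline import round_report

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    props = pd.read_csv(RESULTS / "properties.csv")
    for stratify in ("pooled", "by_temperature"):
        comp = compare_to_control(props, stratify=stratify)
        round_report(comp).to_csv(RESULTS / f"comparisons_{stratify}.csv", index=False)
        medians_table(props, stratify=stratify).round(3).to_csv(
            RESULTS / f"medians_{stratify}.csv"
        )
        sig = comp[comp["significant"]]
        print(f"{stratify}: {len(sig)}/{len(comp)} comparisons significant")
        if stratify == "by_temperature":
            per_temp = sig.groupby("stratum").size()
            print("  by stratum:", dict(per_temp))
        speed = sig[sig["property"] == "movementSpeed"]
        for _, row in speed.iterrows():
            print(
                f"  movementSpeed {row['weight_category']} day {row['day']} "
                f"({row['stratum']}): {row['percent_change']:+.0f}% "
                f"(adj p = {row['p_adjusted']:.3g})"
            )


if __name__ == "__main__":
    main()
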