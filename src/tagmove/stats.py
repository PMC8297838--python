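"""Group-comparison statistics for the tag-load experiment.

The comparison battery is nonparametric throughout: the movement properties
are skewed (Shapiro–Wilk flags non-normality in many strata), so tagged
groups are compared to the untagged control with two-sided Mann–Whitney U
tests, and the p-values of each analysis family are adjusted with the
Benjamini–Yekutieli false-discovery-rate step-up, which is valid under
arbitrary dependence between the tests.

Beyond the per-day comparisons the module provides Discussion-style percent
changes of group medians, per-individual day-slope analysis (does a property
drift over the three days of tag attachment?), and paired Wilcoxon tests of
body-mass change between consecutive days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .properties import PROPERTY_NAMES
from .trajectory_io import TEMPERATURE_CATEGORIES, WEIGHT_CATEGORIES

ALPHA = 0.05
#: combined-sample-size boundary between the exact and normal-approximation
#: branches of the Mann-Whitney test
EXACT_MAX_N = 20
TAG_CATEGORIES = [c for c in WEIGHT_CATEGORIES if c != "control"]


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test of two independent samples.

    Uses the exact null distribution when the combined sample size is at
    most 20 and the data contain no ties, and the tie-corrected normal
    approximation otherwise (identical samples therefore give exactly
    p = 1).  Returns ``(U, p)`` with U counted for the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # degenerate: every observation identical
        return float(a.size * b.size / 2.0), 1.0
    no_ties = len(np.unique(pooled)) == pooled.size
    if no_ties and pooled.size <= EXACT_MAX_N:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def adjust_by(p_values) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjustment (arbitrary dependence).

    With m tests and harmonic constant c(m) = sum_{k<=m} 1/k, the sorted
    p(i) maps to min over j >= i of min(1, m c(m) p(j) / j); values are
    returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=ALPHA, method="fdr_by")[1]


def normality_check(values) -> tuple[bool, float]:
    """Shapiro–Wilk screen: is this sample incompatible with normality?

    Returns ``(non_normal, p)`` with ``non_normal = p < 0.05``.  The flag
    only documents why the nonparametric branch is used — it never switches
    the downstream test.  Degenerate constant samples are flagged non-normal.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(values) == 0:
        return True, 0.0
    with np.errstate(all="ignore"):
        res = sps.shapiro(values)
    return bool(res.pvalue < ALPHA), float(res.pvalue)


def percent_change(median_control: float, median_tag: float) -> float:
    """Percent change of a tagged group's median relative to control."""
    if median_control == 0:
        raise ZeroDivisionError("control median is zero; percent change undefined")
    return (median_tag - median_control) / median_control * 100.0


@dataclass(frozen=True)
class ComparisonResult:
    property: str
    day: int
    stratum: str  # temperature category or "pooled"
    weight_category: str
    n_control: int
    n_tag: int
    median_control: float
    median_tag: float
    u_statistic: float
    p_raw: float
    p_adjusted: float = np.nan

    @property
    def significant(self) -> bool:
        return bool(self.p_adjusted < ALPHA)


def _compare_stratum(table: pd.DataFrame, stratum: str) -> list[ComparisonResult]:
    present = [c for c in TAG_CATEGORIES if (table["weight_category"] == c).any()]
    results = []
    for prop in PROPERTY_NAMES:
        for day in sorted(table["day"].unique()):
            sub = table[table["day"] == day]
            control = sub.loc[sub["weight_category"] == "control", prop].to_numpy()
            if control.size == 0:
                raise ValueError(
                    f"no control individuals in stratum {stratum!r}, day {day}"
                )
            for category in present:
                tagged = sub.loc[sub["weight_category"] == category, prop].to_numpy()
                if tagged.size == 0:
                    raise ValueError(
                        f"no {category!r} individuals in stratum {stratum!r}, day {day}"
                    )
                u, p = mann_whitney_u(tagged, control)
                results.append(
                    ComparisonResult(
                        property=prop,
                        day=int(day),
                        stratum=stratum,
                        weight_category=category,
                        n_control=int(control.size),
                        n_tag=int(tagged.size),
                        median_control=float(np.median(control)),
                        median_tag=float(np.median(tagged)),
                        u_statistic=u,
                        p_raw=p,
                    )
                )
    return results


def compare_to_control(
    table: pd.DataFrame, stratify: str = "pooled"
) -> pd.DataFrame:
    """Mann–Whitney comparisons of each tagged category against control.

    ``stratify="pooled"`` ignores temperature (6 properties x days x 3 tag
    categories, i.e. 54 tests over 3 days); ``stratify="by_temperature"``
    repeats the battery inside each temperature category.  The BY adjustment
    is applied across the whole run — one analysis family per call.
    """
    if stratify not in ("pooled", "by_temperature"):
        raise ValueError("stratify must be 'pooled' or 'by_temperature'")
    if stratify == "pooled":
        results = _compare_stratum(table, "pooled")
    else:
        results = []
        for temp in TEMPERATURE_CATEGORIES:
            sub = table[table["temperature_category"] == temp]
            if not sub.empty:
                results.extend(_compare_stratum(sub, temp))
    out = pd.DataFrame([vars(r) for r in results])
    out["p_adjusted"] = adjust_by(out["p_raw"].to_numpy())
    out["significant"] = out["p_adjusted"] < ALPHA
    out["percent_change"] = [
        percent_change(c, t) if c != 0 else np.nan
        for c, t in zip(out["median_control"], out["median_tag"])
    ]
    return out


def medians_table(table: pd.DataFrame, stratify: str = "pooled") -> pd.DataFrame:
    """Group medians laid out day x property in rows, weight category in
    columns (nested inside temperature when stratified)."""
    group_cols = ["day", "weight_category"]
    if stratify == "by_temperature":
        group_cols = ["temperature_category"] + group_cols
    med = (
        table.groupby(group_cols, observed=True)[PROPERTY_NAMES]
        .median()
        .reset_index()
        .melt(id_vars=group_cols, var_name="property", value_name="median")
    )
    index_cols = ["day", "property"]
    col_cols = [c for c in group_cols if c != "day"]
    wide = med.pivot_table(
        index=index_cols, columns=col_cols, values="median", observed=True
    )
    order = [c for c in WEIGHT_CATEGORIES]
    if stratify == "by_temperature":
        wide = wide.reindex(
            columns=pd.MultiIndex.from_product(
                [order, list(TEMPERATURE_CATEGORIES)][::-1]
            )
        )
    else:
        wide = wide.reindex(columns=order)
    prop_order = pd.CategoricalIndex(
        wide.index.get_level_values("property"), categories=PROPERTY_NAMES, ordered=True
    )
    wide = wide.set_index(
        pd.MultiIndex.from_arrays(
            [wide.index.get_level_values("day"), prop_order], names=["day", "property"]
        )
    ).sort_index()
    return wide


@dataclass(frozen=True)
class SlopeResult:
    cricket_id: str
    property: str
    weight_category: str
    slope: float


def slope_analysis(
    table: pd.DataFrame, property_name: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual day slopes of one property, compared across categories.

    For each individual with at least two days of data an ordinary
    least-squares line of the property against day number is fitted; the
    slope distributions of the tagged categories are then compared to the
    control's with a two-sided rank-sum test.  Returns ``(slopes, tests)``.
    """
    slopes = []
    for (cid, cat), sub in table.groupby(["cricket_id", "weight_category"], observed=True):
        if sub["day"].nunique() < 2:
            import warnings

            warnings.warn(f"individual {cid} has <2 days; excluded from slopes")
            continue
        days = sub["day"].to_numpy(float)
        vals = sub[property_name].to_numpy(float)
        # closed-form OLS slope (exactly zero for constant values)
        slope = float(
            np.sum((days - days.mean()) * (vals - vals.mean()))
            / np.sum((days - days.mean()) ** 2)
        )
        slopes.append(SlopeResult(cid, property_name, str(cat), slope))
    slope_df = pd.DataFrame([vars(s) for s in slopes])
    control = slope_df.loc[slope_df["weight_category"] == "control", "slope"].to_numpy()
    tests = []
    for category in TAG_CATEGORIES:
        tagged = slope_df.loc[slope_df["weight_category"] == category, "slope"].to_numpy()
        if tagged.size == 0:
            continue
        if np.ptp(np.concatenate([tagged, control])) == 0:
            u, p = float(tagged.size * control.size / 2.0), 1.0
        else:
            u, p = mann_whitney_u(tagged, control)
        tests.append(
            {
                "property": property_name,
                "weight_category": category,
                "median_slope_control": float(np.median(control)),
                "median_slope_tag": float(np.median(tagged)),
                "u_statistic": u,
                "p_value": p,
            }
        )
    return slope_df, pd.DataFrame(tests)


def body_mass_tests(metadata: pd.DataFrame) -> pd.DataFrame:
    """Paired Wilcoxon tests of body-mass change between consecutive days.

    Individuals are paired across days via cricket_id; unpaired individuals
    are dropped with a warning.  Median within-individual shifts (mg) are
    reported overall and per weight category.
    """
    wide = metadata.pivot_table(
        index=["cricket_id", "weight_category"],
        columns="day",
        values="animal_weight_mg",
        observed=True,
    )
    missing = wide.index[wide.isna().any(axis=1)]
    if len(missing):
        import warnings

        warnings.warn(
            f"{len(missing)} individual(s) lack a weight on some day; dropped"
        )
        wide = wide.dropna()
    results = []
    strata = [("all", wide)] + [
        (cat, wide.xs(cat, level="weight_category"))
        for cat in WEIGHT_CATEGORIES
        if cat in wide.index.get_level_values("weight_category")
    ]
    for stratum, sub in strata:
        for d1, d2 in [(1, 2), (2, 3)]:
            if d1 not in sub.columns or d2 not in sub.columns:
                continue
            diff = (sub[d2] - sub[d1]).to_numpy(dtype=float)
            if np.all(diff == 0):
                p = 1.0
            else:
                p = float(
                    sps.wilcoxon(diff, alternative="two-sided", zero_method="wilcox").pvalue
                )
            results.append(
                {
                    "stratum": stratum,
                    "day_pair": f"{d1}-{d2}",
                    "n": int(diff.size),
                    "median_shift_mg": float(np.median(diff)),
                    "p_value": p,
                }
            )
    return pd.DataFrame(results)
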