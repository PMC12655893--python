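"""Group comparisons, percent-change / fold-ratio arithmetic, significance stars.

Physiological indicators (SPAD, MDA, SOD, POD, CAT, dry weight) are compared
between the tolerant (T) and sensitive (S) variety *within* a soil stratum
(normal N or saline-alkaline A) by a two-sided t-test — Welch by default,
pooled-variance Student available by flag. Significance coding follows the
usual four-star convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .io import check_samples_in_design, logger, read_soil


def percent_change(value: float, reference: float) -> float:
    """Signed percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (value - reference) / reference


def fold_ratio(
    numerator: float,
    denominator: float,
    censored: tuple[bool, bool] = (False, False),
) -> float:
    """Raw fold ratio numerator/denominator; round to 1 decimal for reporting.

    Detection-limit censored inputs are refused: a bound is not a value.
    """
    if any(censored):
        raise ValueError("cannot form a fold ratio from censored values")
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return numerator / denominator


def soil_fold_ratios(
    soil: pd.DataFrame, numerator: str = "A", denominator: str = "N"
) -> pd.DataFrame:
    """Per-property fold ratios between two soils from a tidy soil table.

    Censored properties are excluded with a warning. Returns columns
    property, fold_raw, fold (rounded to 1 decimal).
    """
    wide_val = soil.pivot(index="property", columns="soil_id", values="value")
    wide_cen = soil.pivot(index="property", columns="soil_id", values="censored")
    rows = []
    for prop in wide_val.index:
        if wide_cen.loc[prop, [numerator, denominator]].any():
            logger.warning("property %r censored; excluded from fold ratios", prop)
            continue
        raw = fold_ratio(wide_val.loc[prop, numerator], wide_val.loc[prop, denominator])
        rows.append({"property": prop, "fold_raw": raw, "fold": round(raw, 1)})
    return pd.DataFrame(rows)


def example_soil_table() -> pd.DataFrame:
    """Packaged example soil-chemistry table (saline-alkaline vs normal soil)."""
    with resources.as_file(
        resources.files("rhizojip") / "data" / "soil_table.csv"
    ) as p:
        return read_soil(p)


def star_code(p: float) -> str:
    """Significance stars: **** <1e-4, *** <1e-3, ** <0.01, * <0.05, else ns."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p value {p} outside [0, 1]")
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


@dataclass
class GroupComparison:
    """T-vs-S comparison of one indicator within one soil stratum."""

    indicator: str
    stratum: str
    mean_t: float
    sd_t: float
    n_t: int
    mean_s: float
    sd_s: float
    n_s: int
    t: float
    p: float
    stars: str


def compare_groups(
    physiology: pd.DataFrame,
    design: pd.DataFrame,
    indicator: str,
    stratum: str,
    welch: bool = True,
) -> GroupComparison:
    """Two-sided t-test of variety T vs S within one soil stratum.

    Both groups constant and equal is reported as t = 0, p = 1.
    """
    check_samples_in_design(physiology["sample_id"], design, "physiology")
    merged = physiology.merge(design, on="sample_id")
    sub = merged[(merged["indicator"] == indicator) & (merged["soil"] == stratum)]
    x_t = sub.loc[sub["variety"] == "T", "value"].to_numpy(float)
    x_s = sub.loc[sub["variety"] == "S", "value"].to_numpy(float)
    if len(x_t) < 2 or len(x_s) < 2:
        raise ValueError(
            f"need >= 2 samples per variety for {indicator!r} in soil {stratum!r}"
        )
    if np.ptp(np.concatenate([x_t, x_s])) == 0.0:
        t_stat, p = 0.0, 1.0  # identical constant groups: no evidence either way
    else:
        t_stat, p = stats.ttest_ind(x_t, x_s, equal_var=not welch)
        t_stat, p = float(t_stat), float(p)
        if np.isnan(p):  # zero variance both sides but different means
            t_stat, p = float("inf") * np.sign(x_t.mean() - x_s.mean()), 0.0
    return GroupComparison(
        indicator=indicator, stratum=stratum,
        mean_t=float(x_t.mean()), sd_t=float(x_t.std(ddof=1)), n_t=len(x_t),
        mean_s=float(x_s.mean()), sd_s=float(x_s.std(ddof=1)), n_s=len(x_s),
        t=t_stat, p=p, stars=star_code(min(max(p, 0.0), 1.0)),
    )


def compare_all(
    physiology: pd.DataFrame, design: pd.DataFrame, welch: bool = True
) -> pd.DataFrame:
    """Run compare_groups over every (indicator, stratum) pair present."""
    rows = []
    for indicator in sorted(physiology["indicator"].unique()):
        for stratum in ("N", "A"):
            if design.loc[design["soil"] == stratum].empty:
                continue
            try:
                gc = compare_groups(physiology, design, indicator, stratum, welch)
            except ValueError:
                continue
            rows.append(gc.__dict__)
    return pd.DataFrame(rows)
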