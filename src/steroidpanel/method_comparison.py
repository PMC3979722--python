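"""Comparator-vs-reference method comparison: regression, Bland-Altman
percent differences and group-wise discrepancy tests.

The discrepancy metric is the pairwise percent difference
``100 x (comparator - reference) / pair mean`` — the difference expressed as
a percentage of the mean level measured by the two assays — summarized by
its mean and SD with limits of agreement at mean +/- 2 SD. The regression is
ordinary least squares of the comparator (RIA) on the reference (LC-MS/MS);
Deming regression is available as an option for when both axes carry
comparable error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def percent_difference(ria, lcms):
    """Percent difference of a pair: 100 x (ria - lcms) / ((ria + lcms)/2).

    Antisymmetric in its arguments and invariant to a common rescaling.
    """
    ria = np.asarray(ria, dtype=float)
    lcms = np.asarray(lcms, dtype=float)
    mean = (ria + lcms) / 2.0
    if np.any(mean <= 0):
        raise ValueError("pair mean must be positive")
    out = 100.0 * (ria - lcms) / mean
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MethodComparisonSummary:
    analyte: str
    n: int
    slope: float
    intercept: float
    r: float
    mean_pct_diff: float
    sd_pct_diff: float
    loa_low: float   # mean - 2 SD
    loa_high: float  # mean + 2 SD


def bland_altman_summary(
    pairs: pd.DataFrame,
    analyte: str | None = None,
    regression: str = "ols",
) -> MethodComparisonSummary:
    """Bland-Altman and regression summary for one analyte's pairs.

    `pairs` needs columns ria_value and lcms_value (and optionally analyte,
    used for labelling/filtering). Limits of agreement are mean +/- 2 SD of
    the percent differences.
    """
    if analyte is not None and "analyte" in pairs.columns:
        pairs = pairs[pairs["analyte"] == analyte]
    if len(pairs) < 3:
        raise ValueError("need >=3 pairs for a method-comparison summary")
    ria = pairs["ria_value"].to_numpy(float)
    lcms = pairs["lcms_value"].to_numpy(float)
    pct = percent_difference(ria, lcms)
    mean_pct = float(np.mean(pct))
    sd_pct = float(np.std(pct, ddof=1))
    slope, intercept, r = _fit_line(lcms, ria, regression)
    label = analyte or (pairs["analyte"].iloc[0] if "analyte" in pairs.columns else "")
    return MethodComparisonSummary(
        analyte=str(label), n=len(pairs),
        slope=slope, intercept=intercept, r=r,
        mean_pct_diff=mean_pct, sd_pct_diff=sd_pct,
        loa_low=mean_pct - 2.0 * sd_pct, loa_high=mean_pct + 2.0 * sd_pct,
    )


def _fit_line(x: np.ndarray, y: np.ndarray, regression: str) -> tuple[float, float, float]:
    r = float(stats.pearsonr(x, y).statistic) if np.ptp(x) > 0 else np.nan
    if regression == "ols":
        fit = stats.linregress(x, y)
        return float(fit.slope), float(fit.intercept), float(fit.rvalue)
    if regression == "deming":
        # equal-error-variance Deming fit
        sxx = np.var(x, ddof=1)
        syy = np.var(y, ddof=1)
        sxy = np.cov(x, y, ddof=1)[0, 1]
        slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
        return float(slope), float(np.mean(y) - slope * np.mean(x)), r
    raise ValueError(f"unknown regression {regression!r}")


def compare_by_analyte(pairs: pd.DataFrame, regression: str = "ols") -> pd.DataFrame:
    """bland_altman_summary for every analyte in a long pairs table."""
    rows = []
    for analyte, block in pairs.groupby("analyte", sort=False):
        s = bland_altman_summary(block, regression=regression)
        rows.append(vars(s) if not hasattr(s, "__dataclass_fields__") else s.__dict__)
    return pd.DataFrame(rows)


def compare_discrepancy_by_group(
    pairs: pd.DataFrame,
    group_col: str = "group",
    phase_filter: str | None = None,
    phase_col: str = "phase",
) -> tuple[float, float]:
    """Welch two-sample t test of percent differences between the two groups.

    `phase_filter` optionally restricts to rows whose cycle-phase column
    matches (e.g. follicular-only progesterone pairs).
    """
    if phase_filter is not None:
        if phase_col not in pairs.columns:
            raise ValueError(f"no {phase_col!r} column to filter on")
        pairs = pairs[pairs[phase_col] == phase_filter]
    groups = list(dict.fromkeys(pairs[group_col]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    pct = percent_difference(pairs["ria_value"].to_numpy(float),
                             pairs["lcms_value"].to_numpy(float))
    ga = pct[(pairs[group_col] == groups[0]).to_numpy()]
    gb = pct[(pairs[group_col] == groups[1]).to_numpy()]
    if ga.size < 2 or gb.size < 2:
        raise ValueError("each group needs >=2 pairs")
    t, p = stats.ttest_ind(ga, gb, equal_var=False)
    return float(t), float(p)
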