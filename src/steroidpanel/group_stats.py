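"""Group comparison machinery: median (2.5, 97.5) summaries, Mann-Whitney
rank-sum tests, and age/BMI-adjusted significance via logistic regression.

The adjusted p mirrors the study design: group membership (case vs control)
is the binary outcome, regressed on the analyte concentration with age and
BMI as covariates; the Wald p of the analyte coefficient is reported. The
reverse direction (analyte as outcome, OLS on group + covariates) is exposed
as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .analytes import DEFAULT_LOQ, PANEL_STEROIDS


class Summary(NamedTuple):
    median: float
    p2_5: float
    p97_5: float


def summarize(values) -> Summary:
    """Empirical median and 2.5/97.5th percentiles (linear interpolation)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    med, lo, hi = np.percentile(arr, [50.0, 2.5, 97.5])
    return Summary(float(med), float(lo), float(hi))


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"


def rank_sum_test(x, y) -> RankSumResult:
    """Two-sided Mann-Whitney rank-sum test.

    Uses the exact null distribution when the combined sample size is <= 12
    and there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    if x.size + y.size <= 12 and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "asymptotic"
    return RankSumResult(float(res.statistic), float(min(res.pvalue, 1.0)), method)


@dataclass(frozen=True)
class AdjustedResult:
    p_value: float
    coef: float
    se: float
    log_likelihood: float
    covariates: tuple[str, ...]
    separation_flag: bool  # True -> estimate at/near boundary, p unreliable


def adjusted_p(
    data: pd.DataFrame,
    analyte: str,
    covariates: Sequence[str] = ("age", "bmi"),
    group_col: str = "group",
    case_label: str | None = None,
    direction: str = "group-outcome",
) -> AdjustedResult:
    """Covariate-adjusted significance of a group difference in one analyte.

    direction="group-outcome" (default): logistic regression of group on
    (analyte, covariates); Wald p for the analyte coefficient.
    direction="analyte-outcome": OLS of analyte on (group indicator,
    covariates); p for the group coefficient.
    """
    labels = pd.unique(data[group_col])
    if len(labels) < 2:
        raise ValueError("outcome is constant: only one group present")
    if len(labels) > 2:
        raise ValueError(f"expected 2 groups, found {list(labels)}")
    case = case_label or ("pcos" if "pcos" in set(labels) else labels[0])
    y = (data[group_col] == case).astype(float).to_numpy()

    if direction == "analyte-outcome":
        X = sm.add_constant(
            np.column_stack([y, data[list(covariates)].to_numpy(float)])
        )
        fit = sm.OLS(data[analyte].to_numpy(float), X).fit()
        return AdjustedResult(
            p_value=float(fit.pvalues[1]), coef=float(fit.params[1]),
            se=float(fit.bse[1]), log_likelihood=float(fit.llf),
            covariates=tuple(covariates), separation_flag=False,
        )
    if direction != "group-outcome":
        raise ValueError(f"unknown direction {direction!r}")

    X = sm.add_constant(data[[analyte, *covariates]].to_numpy(float))
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # perfect separation raises in some versions
            if "separation" in str(exc).lower():
                raise ValueError(
                    "complete separation: adjusted p is not estimable"
                ) from exc
            raise
        separation = any("separation" in str(w.message).lower() for w in caught)
    se = float(fit.bse[1])
    if not np.isfinite(se) or abs(fit.params[1]) > 50:
        separation = True
    return AdjustedResult(
        p_value=float(fit.pvalues[1]), coef=float(fit.params[1]), se=se,
        log_likelihood=float(fit.llf), covariates=tuple(covariates),
        separation_flag=separation,
    )


def build_table1(
    cohort: pd.DataFrame,
    loq_table: dict[str, float] | None = None,
    group_col: str = "group",
    extra_variables: Sequence[str] = ("lh", "fsh", "dheas"),
) -> pd.DataFrame:
    """Cohort comparison table: per-variable group summaries and p values.

    Rows: age, BMI, every panel steroid present, then any of
    `extra_variables` present. Steroid columns are LOQ-substituted before
    summarizing. The age row carries no adjusted p (age is a covariate); the
    BMI row is adjusted for age only; analytes for age + BMI.
    """
    from .assay_qc import substitute_loq_table

    data = substitute_loq_table(cohort, loq_table if loq_table is not None else DEFAULT_LOQ)
    groups = list(dict.fromkeys(data[group_col]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    if "pcos" in groups and groups[0] != "pcos":
        groups = ["pcos", [g for g in groups if g != "pcos"][0]]
    ga, gb = groups

    variables: list[tuple[str, tuple[str, ...] | None]] = [("age", None), ("bmi", ("age",))]
    for analyte in PANEL_STEROIDS:
        if analyte in data.columns:
            variables.append((analyte, ("age", "bmi")))
    for extra in extra_variables:
        if extra in data.columns:
            variables.append((extra, ("age", "bmi")))

    rows = []
    for name, covs in variables:
        if name not in data.columns:
            raise ValueError(f"cohort table lacks required column {name!r}")
        xa = data.loc[data[group_col] == ga, name].to_numpy(float)
        xb = data.loc[data[group_col] == gb, name].to_numpy(float)
        sa, sb = summarize(xa), summarize(xb)
        p_raw = rank_sum_test(xa, xb).p_value
        if covs is None:
            p_adj = np.nan
        else:
            p_adj = adjusted_p(data, name, covariates=covs, group_col=group_col).p_value
        rows.append({
            "variable": name,
            f"{ga}_median": sa.median, f"{ga}_p2_5": sa.p2_5, f"{ga}_p97_5": sa.p97_5,
            f"{gb}_median": sb.median, f"{gb}_p2_5": sb.p2_5, f"{gb}_p97_5": sb.p97_5,
            "p_raw": p_raw, "p_adjusted": p_adj,
        })
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Optional FDR adjustment (off by default everywhere)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out
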