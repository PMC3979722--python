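"""Assay validation metrics: precision (CV), calibration linearity, recovery,
and the limit-of-quantification substitution rule.

Values below an analyte's LOQ are replaced by the LOQ itself before any
downstream statistic — the censoring convention used throughout the package.
Precision is summarized as intra-run CV (within a single run) and total
inter-run CV from a one-way variance decomposition over runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .analytes import DEFAULT_LOQ, PANEL_STEROIDS


def loq_substitute(value, loq: float):
    """Replace values below the LOQ with the LOQ: ``max(value, loq)``.

    Idempotent and monotone non-decreasing in `value`; accepts scalars or
    arrays.
    """
    if loq <= 0:
        raise ValueError(f"LOQ must be positive, got {loq}")
    result = np.maximum(np.asarray(value, dtype=float), loq)
    return float(result) if np.isscalar(value) else result


def substitute_loq_table(
    profiles: pd.DataFrame, loq_table: dict[str, float] | None = None
) -> pd.DataFrame:
    """Apply LOQ substitution to every panel-analyte column present."""
    table = DEFAULT_LOQ if loq_table is None else loq_table
    out = profiles.copy()
    for analyte, loq in table.items():
        if analyte in out.columns:
            out[analyte] = loq_substitute(out[analyte].to_numpy(float), loq)
    return out


def intra_run_cv(replicates) -> float:
    """Within-run CV: 100 x sample SD / mean over one run's replicates."""
    arr = np.asarray(replicates, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 replicates for a CV")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("replicate mean must be positive")
    return float(100.0 * arr.std(ddof=1) / mean)


def inter_run_cv(
    replicates: pd.DataFrame,
    value_col: str = "value",
    run_col: str = "run",
    between_only: bool = False,
) -> float:
    """Total (inter-run) CV from one-way variance components over runs.

    sigma_within^2 is the pooled within-run mean square; sigma_between^2 the
    (MSB - MSW)/n0 moment estimate truncated at zero. Total CV is
    100 x sqrt(sigma_w^2 + sigma_b^2) / grand mean. With ``between_only``,
    only the between-run component enters the numerator (alternative reading
    of "inter-assay CV").
    """
    groups = [g.to_numpy(float) for _, g in replicates.groupby(run_col)[value_col]]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >=2 runs with >=2 replicates each")
    n_i = np.array([g.size for g in groups], dtype=float)
    N, k = n_i.sum(), len(groups)
    grand = np.concatenate(groups).mean()
    if grand <= 0:
        raise ValueError("grand mean must be positive")
    msw = sum((g.size - 1) * g.var(ddof=1) for g in groups) / (N - k)
    means = np.array([g.mean() for g in groups])
    msb = float(np.sum(n_i * (means - grand) ** 2) / (k - 1))
    n0 = (N - np.sum(n_i**2) / N) / (k - 1)
    sigma_b2 = max(0.0, (msb - msw) / n0)
    var = sigma_b2 if between_only else sigma_b2 + msw
    return float(100.0 * np.sqrt(var) / grand)


def qc_summary(
    replicates: pd.DataFrame,
    level_col: str = "level",
    run_col: str = "run",
    value_col: str = "value",
) -> pd.DataFrame:
    """Per-pool-level precision summary: pooled intra-run CV and total CV."""
    rows = []
    for level, block in replicates.groupby(level_col, sort=False):
        per_run = [g.to_numpy(float) for _, g in block.groupby(run_col)[value_col]]
        grand = block[value_col].mean()
        msw = sum((g.size - 1) * g.var(ddof=1) for g in per_run) / sum(
            g.size - 1 for g in per_run
        )
        rows.append({
            "level": level,
            "intra_run_cv": float(100.0 * np.sqrt(msw) / grand),
            "inter_run_cv": inter_run_cv(block, value_col, run_col),
            "n_runs": len(per_run),
            "n_reps": int(block.shape[0]),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LinearityResult:
    r: float
    slope: float
    intercept: float
    passed: bool  # r > 0.99


def calibration_linearity(series) -> LinearityResult:
    """Pearson correlation (and OLS line) of measured vs nominal.

    The acceptance rule for a multiplexed steroid assay is r > 0.99 across
    the calibration range.
    """
    nominal, measured = _series_arrays(series)
    if np.unique(nominal).size < 2:
        raise ValueError("nominal levels are constant; linearity undefined")
    fit = stats.linregress(nominal, measured)
    r = float(fit.rvalue)
    return LinearityResult(r, float(fit.slope), float(fit.intercept), r > 0.99)


def recovery(series) -> pd.DataFrame:
    """Per-level recovery 100 x measured/nominal with a +/-10% pass flag.

    The returned frame has a ``passed`` column per level; overall acceptance
    is ``df["passed"].all()``.
    """
    nominal, measured = _series_arrays(series)
    if np.any(nominal <= 0):
        raise ValueError("nominal levels must be positive")
    pct = 100.0 * measured / nominal
    return pd.DataFrame({
        "nominal": nominal,
        "measured": measured,
        "recovery_pct": pct,
        "passed": (pct >= 90.0) & (pct <= 110.0),
    })


def _series_arrays(series):
    """Accept a CalibrationSeries, a DataFrame with nominal/measured, or a pair."""
    if hasattr(series, "points"):
        frame = series.points
    elif isinstance(series, pd.DataFrame):
        frame = series
    else:
        nominal, measured = series
        frame = pd.DataFrame({"nominal": nominal, "measured": measured})
    nominal = frame["nominal"].to_numpy(float)
    measured = frame["measured"].to_numpy(float)
    if nominal.size < 5:
        raise ValueError("need >=5 calibration points")
    if np.any(np.diff(nominal) < 0):
        raise ValueError("nominal levels must be non-decreasing")
    return nominal, measured


def default_loq_table(overrides: dict[str, float] | None = None) -> dict[str, float]:
    """The panel LOQ table (ng/dL), with optional per-analyte overrides."""
    table = dict(DEFAULT_LOQ)
    if overrides:
        for analyte, loq in overrides.items():
            if analyte not in PANEL_STEROIDS:
                raise ValueError(f"unknown panel analyte {analyte!r}")
            if loq <= 0:
                raise ValueError(f"LOQ must be positive, got {loq} for {analyte}")
            table[analyte] = float(loq)
    return table
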