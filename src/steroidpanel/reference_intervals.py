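"""Cycle-day-dependent hormone reference bands.

The band-fitting procedure for daily-sampled control cycles:

1. substitute values below the LOQ by the LOQ;
2. estimate a Box-Cox exponent lambda on the pooled control observations
   (profile likelihood over a fixed grid; lambda=0 means log);
3. fit a cubic smoothing spline (smoothing chosen by generalized
   cross-validation) of the transformed values against raw cycle day;
4. model the residual SD as either a constant or a quadratic polynomial in
   cycle day, chosen by an F test;
5. back-transform mean and mean +/- 2 SD to original units. Under the
   transformed-normal model the upper curve is the ~97.5% limit
   (mean + 2 SD covers the 97.72th percentile).

Single-day samples (e.g. cases sampled once) are then flagged as
below/within/above the band at their cycle day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, special, stats

from .assay_qc import loq_substitute

LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)


def boxcox_transform(x, lam: float):
    """Box-Cox forward transform; lam=0 is the natural log."""
    return special.boxcox(np.asarray(x, dtype=float), lam)


def boxcox_inverse(y, lam: float):
    """Exact inverse of the forward transform on its valid domain.

    Out-of-domain points (where lam*y + 1 <= 0) are clipped to the domain
    boundary, which maps to 0+ for lam > 0.
    """
    y = np.asarray(y, dtype=float)
    if lam == 0:
        return np.exp(y)
    y = np.clip(y, (-1.0 / lam + 1e-12) if lam > 0 else -np.inf,
                np.inf if lam > 0 else (-1.0 / lam - 1e-12))
    return special.inv_boxcox(y, lam)


def estimate_lambda(values, grid=LAMBDA_GRID) -> float:
    """Box-Cox exponent by profile likelihood over a fixed grid.

    Requires positive values (apply LOQ substitution first) and n >= 10.
    A constant sample carries no shape information: lambda is defined as 1
    with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("need >=10 observations to estimate lambda")
    if np.any(x <= 0):
        raise ValueError("values must be positive; apply LOQ substitution first")
    if np.ptp(x) == 0:
        warnings.warn("constant sample: transform exponent set to 1", stacklevel=2)
        return 1.0
    llf = [stats.boxcox_llf(lam, x) for lam in grid]
    return float(grid[int(np.argmax(llf))])


@dataclass(frozen=True)
class MeanCurve:
    """Smooth mean of the transformed hormone versus cycle day."""

    grid_days: np.ndarray
    fitted: np.ndarray
    _predictor: object  # BSpline or poly1d

    def predict(self, day):
        return np.asarray(self._predictor(np.asarray(day, dtype=float)))


def fit_mean_curve(day, y) -> MeanCurve:
    """Cubic smoothing spline of transformed values against cycle day.

    Observations sharing a day are averaged and the spline is fitted to the
    per-day means with counts as weights; the smoothing parameter is chosen
    by generalized cross-validation. With fewer than 5 distinct days (the
    spline's minimum) an exact low-degree polynomial through the day means
    is used instead. Returns fitted values on every integer day in range.
    """
    day = np.asarray(day, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 20:
        raise ValueError("need >=20 observations to fit a mean curve")
    uniq, inverse, counts = np.unique(day, return_inverse=True, return_counts=True)
    if uniq.size < 3:
        raise ValueError("need >=3 distinct cycle days")
    means = np.bincount(inverse, weights=y) / counts
    if uniq.size >= 5:
        predictor = interpolate.make_smoothing_spline(uniq, means, w=counts.astype(float))
    else:
        predictor = np.poly1d(np.polyfit(uniq, means, deg=uniq.size - 1,
                                         w=np.sqrt(counts)))
    grid = np.arange(int(np.floor(uniq.min())), int(np.ceil(uniq.max())) + 1, dtype=float)
    return MeanCurve(grid_days=grid, fitted=np.asarray(predictor(grid)),
                     _predictor=predictor)


@dataclass(frozen=True)
class SDModel:
    """Residual-SD model: constant, or quadratic polynomial in cycle day."""

    kind: str                      # "constant" | "polynomial"
    sd: float | None = None        # constant model
    coef: tuple | None = None      # highest-degree-first polynomial coefficients
    floor: float = 1e-9

    def predict(self, day):
        day = np.asarray(day, dtype=float)
        if self.kind == "constant":
            return np.full_like(day, self.sd)
        return np.maximum(np.polyval(self.coef, day), self.floor)


def fit_sd_model(day, residuals, model: str = "auto", alpha: float = 0.05) -> SDModel:
    """Choose between a fixed residual SD and a quadratic SD-vs-day model.

    Per-day sample SDs (days with >=2 residuals) are regressed on day; the
    quadratic is preferred over the constant when a nested F test rejects at
    `alpha`. Too few multi-observation days force the constant model, whose
    SD is the pooled residual SD. Polynomial predictions are floored at a
    small positive fraction of the pooled SD.
    """
    day = np.asarray(day, dtype=float)
    resid = np.asarray(residuals, dtype=float)
    pooled = float(np.std(resid, ddof=1)) if resid.size > 1 else 0.0
    constant = SDModel(kind="constant", sd=pooled)
    if model == "constant":
        return constant

    uniq, inverse, counts = np.unique(day, return_inverse=True, return_counts=True)
    keep = counts >= 2
    if keep.sum() < 3 or pooled == 0.0:
        if model == "poly":
            warnings.warn("too few days for a polynomial SD model; using constant",
                          stacklevel=2)
        return constant
    day_sd = np.array([
        np.std(resid[inverse == i], ddof=1) for i in np.flatnonzero(keep)
    ])
    days_kept = uniq[keep]
    floor = max(1e-9, 0.05 * pooled)
    if model == "poly" or keep.sum() < 4:
        if keep.sum() >= 3:
            coef = tuple(np.polyfit(days_kept, day_sd, deg=2))
            if model == "poly":
                return SDModel(kind="polynomial", coef=coef, floor=floor)
        return constant

    rss0 = float(np.sum((day_sd - day_sd.mean()) ** 2))
    coef = np.polyfit(days_kept, day_sd, deg=2)
    rss1 = float(np.sum((day_sd - np.polyval(coef, days_kept)) ** 2))
    m = day_sd.size
    if rss1 <= 0:
        p = 0.0
    else:
        f = ((rss0 - rss1) / 2.0) / (rss1 / (m - 3))
        p = float(stats.f.sf(f, 2, m - 3))
    if p < alpha:
        return SDModel(kind="polynomial", coef=tuple(coef), floor=floor)
    # constant model SD from the regression-mean residuals, not the day SDs
    return constant


@dataclass(frozen=True)
class ReferenceBand:
    """Fitted cycle-day band: back-transformed mean and +/- 2 SD curves."""

    analyte: str
    grid_days: np.ndarray
    mean_curve: np.ndarray
    lower_curve: np.ndarray
    upper_curve: np.ndarray
    lam: float
    sd_model: SDModel
    mean_model: MeanCurve
    n_subjects: int
    #: True where mean + 2 SD reaches the transform's asymptote (lam < 0):
    #: the back-transformed upper limit is effectively unbounded there
    upper_saturated: np.ndarray | None = None

    def curves_at(self, day) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(lower, mean, upper) at the nearest grid day(s)."""
        idx = np.clip(
            np.searchsorted(self.grid_days, np.asarray(day, dtype=float)),
            0, self.grid_days.size - 1,
        )
        near = np.where(
            (idx > 0)
            & (np.abs(self.grid_days[np.maximum(idx - 1, 0)] - np.asarray(day, float))
               < np.abs(self.grid_days[idx] - np.asarray(day, float))),
            idx - 1, idx,
        )
        return self.lower_curve[near], self.mean_curve[near], self.upper_curve[near]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({
            "cycle_day": self.grid_days.astype(int),
            "mean": self.mean_curve,
            "lower": self.lower_curve,
            "upper": self.upper_curve,
        })
        if self.upper_saturated is not None and self.upper_saturated.any():
            frame["upper_saturated"] = self.upper_saturated
        return frame


def build_reference_band(
    cycle_data: pd.DataFrame,
    analyte: str,
    loq: float | None = None,
    sd_model: str = "auto",
    day_col: str = "cycle_day",
) -> ReferenceBand:
    """Fit the full band pipeline for one analyte from daily control data."""
    if analyte not in cycle_data.columns:
        raise ValueError(f"cycle table lacks analyte column {analyte!r}")
    day = cycle_data[day_col].to_numpy(float)
    raw = cycle_data[analyte].to_numpy(float)
    values = loq_substitute(raw, loq) if loq is not None else raw
    lam = estimate_lambda(values)
    transformed = boxcox_transform(values, lam)
    mean_model = fit_mean_curve(day, transformed)
    residuals = transformed - mean_model.predict(day)
    sdm = fit_sd_model(day, residuals, model=sd_model)
    sd_grid = sdm.predict(mean_model.grid_days)
    mean_t = mean_model.fitted
    lower = boxcox_inverse(mean_t - 2.0 * sd_grid, lam)
    upper = boxcox_inverse(mean_t + 2.0 * sd_grid, lam)
    center = boxcox_inverse(mean_t, lam)
    saturated = (np.asarray(mean_t + 2.0 * sd_grid) >= -1.0 / lam - 1e-9
                 if lam < 0 else np.zeros_like(mean_t, dtype=bool))
    n_subjects = (cycle_data["subject_id"].nunique()
                  if "subject_id" in cycle_data.columns else len(cycle_data))
    return ReferenceBand(
        analyte=analyte, grid_days=mean_model.grid_days,
        mean_curve=np.maximum(center, 0.0),
        lower_curve=np.maximum(lower, 0.0),
        upper_curve=np.maximum(upper, 0.0),
        lam=lam, sd_model=sdm, mean_model=mean_model, n_subjects=int(n_subjects),
        upper_saturated=saturated,
    )


def flag_against_band(
    band: ReferenceBand,
    samples: pd.DataFrame,
    value_col: str | None = None,
    day_col: str = "cycle_day",
) -> pd.Series:
    """Classify single-day samples as below/within/above the band.

    Sample days outside the band's grid use the nearest grid day.
    """
    value_col = value_col or band.analyte
    values = samples[value_col].to_numpy(float)
    lower, _, upper = band.curves_at(samples[day_col].to_numpy(float))
    out = np.where(values > upper, "above", np.where(values < lower, "below", "within"))
    return pd.Series(out, index=samples.index, name="flag")
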