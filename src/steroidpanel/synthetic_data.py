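"""Synthetic cohort, cycle, paired-assay, QC and calibration generators.

The generators emulate the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any external data:

* between-subject steroid concentrations are log-normal per analyte,
  parameterized by the target median and 97.5th percentile (right-skewed,
  strictly positive); a Gaussian copula on the log scale induces a single
  configurable rank correlation between pathway-adjacent analytes;
* daily cycle series follow a per-analyte mean function (baseline plus
  midcycle and midluteal Gaussian bumps, positioned as fractions of each
  subject's 25-35 day cycle length) with multiplicative log-normal residual
  noise and up to 4 missing days per subject;
* paired comparator/reference assays apply a multiplicative log-normal bias
  (comparator = reference x exp(N(log bias, scatter)));
* QC replicates combine between-run and within-run multiplicative noise at
  configured CVs; calibration series apply multiplicative noise (scalar CV
  or a per-level CV profile) to nominal levels.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import analytes as an

_Z975 = 1.959963984540054  # standard normal 97.5th percentile

# each generator draws from its own domain-keyed stream so that passing the
# same integer seed to two different generators never yields correlated draws
_STREAM_KEYS = {"cohort": 1, "cycle": 2, "assays": 3, "qc": 4, "calibration": 5}


def _rng(seed: int, domain: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(_STREAM_KEYS[domain],)))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyteSpec:
    """Distribution targets for one analyte: median and 97.5th percentile.

    The between-subject family is log-normal; a two-parameter family cannot
    match three quantiles, so `p2_5_target` is diagnostic only (not fitted).
    """

    name: str
    median_target: float
    p97_5_target: float
    p2_5_target: float | None = None
    loq: float = 25.0
    unit: str = "ng/dL"

    def __post_init__(self) -> None:
        if self.median_target <= 0 or self.p97_5_target <= 0:
            raise ValueError(f"{self.name}: targets must be positive")
        if self.loq <= 0:
            raise ValueError(f"{self.name}: LOQ must be positive")
        if self.p97_5_target < self.median_target:
            raise ValueError(
                f"{self.name}: p97_5_target ({self.p97_5_target}) is below "
                f"median_target ({self.median_target})"
            )
        if self.p2_5_target is not None and self.p2_5_target > self.median_target:
            raise ValueError(
                f"{self.name}: p2_5_target ({self.p2_5_target}) exceeds "
                f"median_target ({self.median_target})"
            )

    @property
    def log_mu(self) -> float:
        return float(np.log(self.median_target))

    @property
    def log_sigma(self) -> float:
        return float((np.log(self.p97_5_target) - np.log(self.median_target)) / _Z975)


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of the cross-sectional cohort generator."""

    n_pcos: int
    n_control: int
    pcos_specs: tuple[AnalyteSpec, ...]
    control_specs: tuple[AnalyteSpec, ...]
    correlation: float = 0.3
    seed: int = 0
    # (median, p97.5) log-normal targets for the demographic covariates
    age_targets_pcos: tuple[float, float] = an.AGE_TARGETS_PCOS
    age_targets_control: tuple[float, float] = an.AGE_TARGETS_CONTROL
    bmi_targets_pcos: tuple[float, float] = an.BMI_TARGETS_PCOS
    bmi_targets_control: tuple[float, float] = an.BMI_TARGETS_CONTROL

    def __post_init__(self) -> None:
        if self.n_pcos <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")
        if [s.name for s in self.pcos_specs] != [s.name for s in self.control_specs]:
            raise ValueError("PCOS and control specs must cover the same analytes")


def _default_specs(targets: Mapping[str, tuple[float, float, float]]) -> tuple[AnalyteSpec, ...]:
    specs = []
    for name, (median, p2_5, p97_5) in targets.items():
        specs.append(AnalyteSpec(
            name=name, median_target=median, p97_5_target=p97_5,
            p2_5_target=min(p2_5, median),
            loq=an.DEFAULT_LOQ.get(name, 25.0),
            unit="IU/L" if name in an.GONADOTROPINS else "ng/dL",
        ))
    return tuple(specs)


def default_cohort_config(
    n_pcos: int = an.N_PCOS,
    n_control: int = an.N_CONTROL,
    correlation: float = 0.3,
    seed: int = 0,
) -> CohortConfig:
    """Cohort config calibrated to the published group medians/percentiles."""
    return CohortConfig(
        n_pcos=n_pcos, n_control=n_control,
        pcos_specs=_default_specs(an.PCOS_TARGETS),
        control_specs=_default_specs(an.CONTROL_TARGETS),
        correlation=correlation, seed=seed,
    )


def _copula_cholesky(names: Sequence[str], rho: float) -> np.ndarray:
    """Cholesky factor of the log-scale copula correlation matrix.

    `rho` is placed on every pathway-adjacent steroid pair (precursor-product
    pairs of the default enzyme map); other pairs are independent. The matrix
    is repaired by eigenvalue clipping if the adjacency pattern makes it
    indefinite at high rho.
    """
    from .pathway_analysis import default_pathway_spec

    k = len(names)
    R = np.eye(k)
    if rho > 0:
        index = {name: i for i, name in enumerate(names)}
        for a, b in default_pathway_spec().adjacent_pairs:
            if a in index and b in index:
                i, j = index[a], index[b]
                R[i, j] = R[j, i] = rho
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(R)
        R = (v * np.clip(w, 1e-8, None)) @ v.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        return np.linalg.cholesky(R)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a two-group cohort of steroid profiles.

    Returns one row per subject: subject_id, group, age, bmi and one column
    per analyte (ng/dL; IU/L for LH/FSH). Values below the LOQ are kept raw;
    censoring/substitution is a downstream pipeline stage.
    """
    rng = _rng(config.seed, "cohort")

    def _lognormal(n, median, p97_5):
        sigma = (np.log(p97_5) - np.log(median)) / _Z975
        return np.exp(np.log(median) + sigma * rng.standard_normal(n))

    frames = []
    blocks = [
        ("pcos", config.n_pcos, config.pcos_specs,
         config.age_targets_pcos, config.bmi_targets_pcos),
        ("control", config.n_control, config.control_specs,
         config.age_targets_control, config.bmi_targets_control),
    ]
    for group, n, specs, age_targets, bmi_targets in blocks:
        names = [s.name for s in specs]
        mus = np.array([s.log_mu for s in specs])
        sigmas = np.array([s.log_sigma for s in specs])
        L = _copula_cholesky(names, config.correlation)
        z = rng.standard_normal((n, len(names))) @ L.T
        values = np.exp(mus + sigmas * z)
        frame = pd.DataFrame(values, columns=names)
        frame.insert(0, "bmi", _lognormal(n, *bmi_targets))
        frame.insert(0, "age", _lognormal(n, *age_targets))
        frame.insert(0, "group", group)
        frame.insert(0, "subject_id",
                     [f"{group[0].upper()}{i + 1:04d}" for i in range(n)])
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# daily cycle series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CyclicMean:
    """Mean trajectory over the cycle: baseline + midcycle + luteal bumps.

    Bump centers are fractions of the subject's cycle length, so the
    midcycle surge tracks each subject's own cycle; widths are in days.
    """

    baseline: float
    mid_amp: float = 0.0
    mid_frac: float = 0.48
    mid_width: float = 1.5
    luteal_amp: float = 0.0
    luteal_frac: float = 0.75
    luteal_width: float = 4.0

    def __call__(self, day, cycle_length: float):
        day = np.asarray(day, dtype=float)
        out = np.full_like(day, self.baseline)
        if self.mid_amp:
            c = self.mid_frac * cycle_length
            out = out + self.mid_amp * np.exp(-0.5 * ((day - c) / self.mid_width) ** 2)
        if self.luteal_amp:
            c = self.luteal_frac * cycle_length
            out = out + self.luteal_amp * np.exp(-0.5 * ((day - c) / self.luteal_width) ** 2)
        return out

    def peak_day(self, cycle_length: float) -> float:
        """Argmax of the noiseless mean (center of the dominant bump)."""
        days = np.arange(1.0, cycle_length + 1.0)
        return float(days[np.argmax(self(days, cycle_length))])


@dataclass(frozen=True)
class CycleModelConfig:
    """Parameterization of the daily-sampling normative cohort generator."""

    n_subjects: int = an.N_CYCLE_CONTROLS
    analyte_means: Mapping[str, CyclicMean] = field(default_factory=dict)
    cycle_length_range: tuple[int, int] = (25, 35)
    residual_cv: float = 0.2
    max_missing_days: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        lo, hi = self.cycle_length_range
        if lo < 25 or hi > 35 or lo > hi:
            raise ValueError("cycle_length_range must lie within [25, 35]")
        if self.residual_cv < 0:
            raise ValueError("residual_cv must be non-negative")
        if self.max_missing_days < 0:
            raise ValueError("max_missing_days must be non-negative")


def default_cycle_config(seed: int = 0, residual_cv: float = 0.2) -> CycleModelConfig:
    """Cycle config for the four hormones tracked daily in controls.

    Shapes emulate the normative follicular/midcycle/luteal pattern: an LH
    surge at midcycle, a luteal rise of 17OH-progesterone, and shallow
    midcycle modulation of testosterone and androstenedione around their
    control medians.
    """
    return CycleModelConfig(
        analyte_means={
            "lh": CyclicMean(baseline=8.0, mid_amp=32.0, mid_frac=0.48, mid_width=1.2),
            "17oh_progesterone": CyclicMean(
                baseline=35.0, mid_amp=55.0, mid_frac=0.48, mid_width=2.5,
                luteal_amp=80.0, luteal_frac=0.75, luteal_width=4.0,
            ),
            "testosterone": CyclicMean(baseline=22.0, mid_amp=8.0, mid_frac=0.48,
                                       mid_width=4.0),
            "androstenedione": CyclicMean(baseline=100.0, mid_amp=30.0, mid_frac=0.48,
                                          mid_width=4.0),
        },
        residual_cv=residual_cv,
        seed=seed,
    )


def generate_cycle_series(config: CycleModelConfig) -> pd.DataFrame:
    """Daily hormone series across one cycle per subject.

    Day 1 is the first day of menses; each subject has an integer cycle
    length drawn from `cycle_length_range` and loses 0..max_missing_days
    random days. With residual_cv=0 the values equal the configured mean
    function exactly.
    """
    if not config.analyte_means:
        raise ValueError("config.analyte_means is empty")
    rng = _rng(config.seed, "cycle")
    sigma = float(np.sqrt(np.log1p(config.residual_cv**2)))
    lo, hi = config.cycle_length_range
    frames = []
    for i in range(config.n_subjects):
        length = int(rng.integers(lo, hi + 1))
        days = np.arange(1, length + 1)
        n_miss = int(rng.integers(0, config.max_missing_days + 1))
        if n_miss:
            missing = rng.choice(days, size=n_miss, replace=False)
            days = np.setdiff1d(days, missing)
        frame = pd.DataFrame({
            "subject_id": f"N{i + 1:04d}",
            "cycle_length": length,
            "cycle_day": days,
        })
        for name, mean_fn in config.analyte_means.items():
            mean = mean_fn(days, length)
            if sigma > 0:
                noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, days.size))
            else:
                noise = 1.0
            frame[name] = mean * noise
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# paired comparator/reference assays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayBiasConfig:
    """Multiplicative comparator-vs-reference bias model.

    `bias` is the geometric mean ratio comparator/reference; `scatter` the
    SD of the log ratio. Either can be a scalar (all analytes) or a
    per-analyte mapping.
    """

    bias: float | Mapping[str, float] = 1.0
    scatter: float | Mapping[str, float] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for b in self._values(self.bias):
            if b <= 0:
                raise ValueError("bias ratio must be positive")
        for s in self._values(self.scatter):
            if s < 0:
                raise ValueError("scatter must be non-negative")

    @staticmethod
    def _values(x):
        return x.values() if isinstance(x, Mapping) else (x,)

    def for_analyte(self, analyte: str) -> tuple[float, float]:
        b = self.bias[analyte] if isinstance(self.bias, Mapping) else self.bias
        s = self.scatter[analyte] if isinstance(self.scatter, Mapping) else self.scatter
        return float(b), float(s)


def simulate_paired_assays(
    profiles: pd.DataFrame,
    config: AssayBiasConfig,
    analytes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Measure each profile with both methods.

    The reference (LC-MS/MS) value is the profile value; the comparator
    (RIA/immunoassay) value multiplies it by exp(N(log bias, scatter)).
    Returns a long table: analyte, subject_id, group, lcms_value, ria_value.
    """
    if profiles.empty:
        raise ValueError("profiles table is empty")
    if analytes is None:
        candidates = (an.PANEL_STEROIDS if not isinstance(config.bias, Mapping)
                      else tuple(config.bias))
        analytes = [a for a in candidates if a in profiles.columns]
    if not analytes:
        raise ValueError("no analyte columns to pair")
    rng = _rng(config.seed, "assays")
    rows = []
    for analyte in analytes:
        ref = profiles[analyte].to_numpy(float)
        b, s = config.for_analyte(analyte)
        ratio = np.exp(rng.normal(np.log(b), s, ref.size)) if s > 0 else b
        rows.append(pd.DataFrame({
            "analyte": analyte,
            "subject_id": profiles.get("subject_id", pd.RangeIndex(ref.size)),
            "group": profiles.get("group", "all"),
            "lcms_value": ref,
            "ria_value": ref * ratio,
        }))
    return pd.concat(rows, ignore_index=True)


def expected_percent_difference(bias: float, scatter: float, n_nodes: int = 201) -> tuple[float, float]:
    """Analytic mean and SD of the percent difference implied by a bias model.

    The pairwise percent difference 200(R-1)/(R+1), with R = bias x
    exp(scatter Z), is integrated against the standard normal by
    Gauss-Hermite quadrature.
    """
    if scatter == 0:
        m = 200.0 * (bias - 1.0) / (bias + 1.0)
        return m, 0.0
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = weights / np.sqrt(2.0 * np.pi)
    r = bias * np.exp(scatter * nodes)
    pd_vals = 200.0 * (r - 1.0) / (r + 1.0)
    mean = float(np.sum(w * pd_vals))
    var = float(np.sum(w * (pd_vals - mean) ** 2))
    return mean, float(np.sqrt(var))


def calibrate_assay_bias(
    target_mean_pct: float, target_sd_pct: float = 0.0, seed: int = 0
) -> AssayBiasConfig:
    """Solve for (bias, scatter) whose percent-difference distribution has the
    given mean and SD (both in percent of the pair mean).

    Percent differences are bounded in (-200, 200), so targets must respect
    that; the solve is a nested bracketing root find on the analytic moments.
    """
    if not -200.0 < target_mean_pct < 200.0:
        raise ValueError("mean percent difference must lie in (-200, 200)")
    if target_sd_pct < 0:
        raise ValueError("SD must be non-negative")

    def bias_for(scatter: float) -> float:
        f = lambda lb: expected_percent_difference(np.exp(lb), scatter)[0] - target_mean_pct
        return float(np.exp(optimize.brentq(f, np.log(1e-3), np.log(1e3), xtol=1e-12)))

    if target_sd_pct == 0:
        return AssayBiasConfig(bias=bias_for(0.0), scatter=0.0, seed=seed)

    def sd_err(scatter: float) -> float:
        b = bias_for(scatter)
        return expected_percent_difference(b, scatter)[1] - target_sd_pct

    scatter = float(optimize.brentq(sd_err, 1e-6, 3.0, xtol=1e-10))
    return AssayBiasConfig(bias=bias_for(scatter), scatter=scatter, seed=seed)


# ---------------------------------------------------------------------------
# QC replicates and calibration series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCPoolSpec:
    """One quality-control pool: target mean and CV components (percent)."""

    mean: float
    cv_within: float
    cv_between: float = 0.0

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("pool mean must be positive")
        if self.cv_within < 0 or self.cv_between < 0:
            raise ValueError("CV targets must be non-negative")


def generate_qc_replicates(
    pools: Mapping[str, QCPoolSpec],
    n_runs: int = 5,
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate table (level, run, rep, value) with configured variance
    components: a per-run multiplicative log-normal effect at cv_between and
    within-run log-normal noise at cv_within. CVs of 0 are exact (degenerate).
    """
    if n_runs < 1 or n_reps < 1:
        raise ValueError("n_runs and n_reps must be >= 1")
    rng = _rng(seed, "qc")
    rows = []
    for level, spec in pools.items():
        sb = float(np.sqrt(np.log1p((spec.cv_between / 100.0) ** 2)))
        sw = float(np.sqrt(np.log1p((spec.cv_within / 100.0) ** 2)))
        for run in range(1, n_runs + 1):
            run_mean = spec.mean * (np.exp(rng.normal(-0.5 * sb**2, sb)) if sb else 1.0)
            vals = run_mean * (np.exp(rng.normal(-0.5 * sw**2, sw, n_reps)) if sw else 1.0)
            rows.append(pd.DataFrame({
                "level": level, "run": run,
                "rep": np.arange(1, n_reps + 1),
                "value": np.broadcast_to(vals, (n_reps,)),
            }))
    return pd.concat(rows, ignore_index=True)


def calibrate_enzyme_percent(
    target_medians: Mapping[str, float],
    enzyme: str = "3b_hsd",
    base_config: CohortConfig | None = None,
    pilot_seed: int = 0,
) -> CohortConfig:
    """Rescale product-analyte targets so the per-subject product:precursor
    percent for `enzyme` has the requested post-LOQ-substitution median.

    A pilot cohort is drawn once per group; because scaling a product
    analyte's log-normal median by k scales its pre-censoring draws by k
    exactly (same seed), the pilot percent median as a function of k can be
    evaluated without re-simulation, and the scale solving each group's
    target is found by bracketing root search. Returns a new config with the
    product medians/percentiles rescaled.
    """
    from .pathway_analysis import default_pathway_spec

    config = base_config or default_cohort_config(seed=pilot_seed)
    precursors, products = default_pathway_spec().enzymes[enzyme]
    pilot = generate_cohort(config)

    def scaled_median(block: pd.DataFrame, specs, k: float) -> float:
        loq = {s.name: s.loq for s in specs}
        num = sum(np.maximum(k * block[a].to_numpy(), loq[a]) for a in sorted(products))
        den = sum(np.maximum(block[a].to_numpy(), loq[a]) for a in sorted(precursors))
        return float(np.median(100.0 * num / den))

    new_specs: dict[str, tuple[AnalyteSpec, ...]] = {}
    for group, specs in (("pcos", config.pcos_specs),
                         ("control", config.control_specs)):
        if group not in target_medians:
            new_specs[group] = specs
            continue
        block = pilot[pilot.group == group]
        target = target_medians[group]
        k = optimize.brentq(
            lambda k_: scaled_median(block, specs, k_) - target, 1e-3, 1e3,
            xtol=1e-10)
        new_specs[group] = tuple(
            AnalyteSpec(
                name=s.name, median_target=s.median_target * k,
                p97_5_target=s.p97_5_target * k,
                p2_5_target=None if s.p2_5_target is None else s.p2_5_target * k,
                loq=s.loq, unit=s.unit,
            ) if s.name in products else s
            for s in specs
        )
    from dataclasses import replace

    return replace(config, pcos_specs=new_specs["pcos"],
                   control_specs=new_specs["control"])


#: default calibration levels spanning the assay range (ng/dL)
DEFAULT_CALIBRATION_LEVELS: tuple[float, ...] = (25.0, 100.0, 1000.0, 5000.0, 10000.0)


@dataclass(frozen=True)
class CalibrationSeries:
    analyte: str
    points: pd.DataFrame  # columns: nominal, measured


def study_cv_profile(levels: Sequence[float],
                     cv_low: float = 0.131, cv_high: float = 0.046) -> np.ndarray:
    """Per-level CV profile, log-interpolated across the calibration range.

    Multiplexed LC-MS/MS precision is worst near the quantification limit
    and best at the top of the range; this profile spans the assay's stated
    inter-run CV extremes (13.1% at the bottom, 4.6% at the top).
    """
    levels = np.asarray(levels, dtype=float)
    return np.interp(np.log(levels),
                     [np.log(levels.min()), np.log(levels.max())],
                     [cv_low, cv_high])


def generate_calibration(
    levels: Sequence[float] = DEFAULT_CALIBRATION_LEVELS,
    cv: float | Sequence[float] = 0.0,
    seed: int = 0,
    analyte: str = "testosterone",
) -> CalibrationSeries:
    """Calibration series: measured = nominal x multiplicative noise at `cv`.

    `cv` is a fraction (0.131 = 13.1%), scalar or per-level. The noise is
    mean-one log-normal, so recovery is centred at 100%. Fewer than 5
    distinct positive levels cannot assess linearity and are rejected.
    """
    nominal = np.asarray(sorted(levels), dtype=float)
    if np.unique(nominal).size < 5:
        raise ValueError("need >=5 distinct calibration levels")
    if np.any(nominal <= 0):
        raise ValueError("calibration levels must be positive")
    cv_arr = np.broadcast_to(np.asarray(cv, dtype=float), nominal.shape)
    if np.any(cv_arr < 0):
        raise ValueError("CV must be non-negative")
    rng = _rng(seed, "calibration")
    sigma = np.sqrt(np.log1p(cv_arr**2))
    factor = np.where(sigma > 0,
                      np.exp(rng.normal(0.0, 1.0, nominal.size) * sigma) / np.sqrt(1 + cv_arr**2),
                      1.0)
    return CalibrationSeries(
        analyte=analyte,
        points=pd.DataFrame({"nominal": nominal, "measured": nominal * factor}),
    )
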