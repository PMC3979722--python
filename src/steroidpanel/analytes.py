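"""Panel definitions: analyte names, units, quantification limits, cohort targets.

The package models a multiplexed LC-MS/MS serum panel of 13 steroids measured
in women with PCOS and in regularly cycling controls, plus the gonadotropins
LH/FSH and the sulfated adrenal androgen DHEAS carried alongside the panel.

All steroid concentrations are normalized to ng/dL internally; LH and FSH are
IU/L. Cohort calibration targets below are the published group medians and
2.5/97.5th percentiles the synthetic generator is asked to emulate, already
reconciled to ng/dL (cortisol/cortisone were reported in ug/dL, progesterone
in ng/mL; see docs/methods.md for the reconciliation).
"""

from __future__ import annotations

PANEL_STEROIDS: tuple[str, ...] = (
    "pregnenolone",
    "17oh_pregnenolone",
    "progesterone",
    "17oh_progesterone",
    "dhea",
    "androstenedione",
    "testosterone",
    "deoxycorticosterone",
    "corticosterone",
    "18oh_corticosterone",
    "11_deoxycortisol",
    "cortisol",
    "cortisone",
)

GONADOTROPINS: tuple[str, ...] = ("lh", "fsh")

#: measured on the same samples but not part of the 13-analyte LC-MS/MS panel
EXTRA_ANALYTES: tuple[str, ...] = ("dheas",)

ALL_ANALYTES: tuple[str, ...] = PANEL_STEROIDS + GONADOTROPINS + EXTRA_ANALYTES

#: multiplicative factors to ng/dL
UNIT_FACTORS: dict[str, float] = {
    "ng/dL": 1.0,
    "ug/dL": 1000.0,
    "µg/dL": 1000.0,
    "ng/mL": 100.0,
    "IU/L": 1.0,  # gonadotropins: activity units, no mass conversion
}

# Lower quantification boundaries (ng/dL). Values visible as reporting floors
# in the published cohort table where censoring reached the median; the
# remaining analytes default to the lower calibration bound of the assay
# (25 ng/dL; cortisol's stated range starts at 0.05 ug/dL = 50 ng/dL).
DEFAULT_LOQ: dict[str, float] = {
    "pregnenolone": 35.0,
    "deoxycorticosterone": 16.0,
    "11_deoxycortisol": 15.0,
    "17oh_progesterone": 17.0,
    "18oh_corticosterone": 7.8,
    "cortisol": 50.0,
    "testosterone": 25.0,
    "androstenedione": 25.0,
    "17oh_pregnenolone": 25.0,
    "progesterone": 25.0,
    "dhea": 25.0,
    "corticosterone": 25.0,
    "cortisone": 25.0,
}

# Published cohort targets: analyte -> (median, p2.5, p97.5) in ng/dL
# (IU/L for LH/FSH). For the three analytes whose printed median sits on the
# LOQ floor (pregnenolone, deoxycorticosterone, 11-deoxycortisol) the latent
# pre-censoring median is unidentified beyond "<= LOQ"; the generator uses
# 0.7 x LOQ so that the majority of simulated values fall below the LOQ, as
# the printed floors imply.
_CENSORED_MEDIAN_FRACTION = 0.7

PCOS_TARGETS: dict[str, tuple[float, float, float]] = {
    "testosterone": (49.2, 16.2, 125.3),
    "androstenedione": (202.9, 98.2, 476.2),
    "17oh_progesterone": (79.6, 17.0, 175.5),
    "17oh_pregnenolone": (477.8, 44.4, 2219.1),
    "pregnenolone": (35.0 * _CENSORED_MEDIAN_FRACTION, 17.0, 615.2),
    "progesterone": (12.0, 8.0, 29.0),          # ng/mL x 100
    "deoxycorticosterone": (16.0 * _CENSORED_MEDIAN_FRACTION, 8.0, 48.4),
    "corticosterone": (151.2, 32.1, 605.5),
    "11_deoxycortisol": (15.0 * _CENSORED_MEDIAN_FRACTION, 7.0, 57.4),
    "cortisol": (11300.0, 5200.0, 28700.0),     # ug/dL x 1000
    "cortisone": (2030.0, 970.0, 2800.0),       # ug/dL x 1000
    "18oh_corticosterone": (39.9, 7.8, 85.6),
    "dhea": (502.5, 165.7, 1217.0),
    "dheas": (171000.0, 75000.0, 366000.0),     # ug/dL x 1000
    "lh": (27.6, 10.8, 90.4),
    "fsh": (10.7, 4.7, 16.9),
}

CONTROL_TARGETS: dict[str, tuple[float, float, float]] = {
    "testosterone": (24.2, 10.0, 58.8),
    "androstenedione": (106.2, 68.9, 223.2),
    "17oh_progesterone": (44.3, 17.0, 142.5),
    "17oh_pregnenolone": (333.0, 33.0, 3550.3),
    "pregnenolone": (35.0 * _CENSORED_MEDIAN_FRACTION, 17.0, 168.9),
    "progesterone": (13.0, 8.0, 88.0),
    "deoxycorticosterone": (16.0 * _CENSORED_MEDIAN_FRACTION, 8.0, 69.5),
    "corticosterone": (201.8, 64.9, 747.8),
    "11_deoxycortisol": (15.0 * _CENSORED_MEDIAN_FRACTION, 7.0, 48.6),
    "cortisol": (13400.0, 5800.0, 22600.0),
    "cortisone": (1970.0, 1030.0, 2730.0),
    # printed identically to the PCOS row in the source table; treated as
    # genuinely identical (see docs/methods.md)
    "18oh_corticosterone": (39.9, 7.8, 85.6),
    "dhea": (389.8, 67.5, 1093.8),
    "dheas": (194000.0, 36000.0, 378000.0),
    "lh": (10.3, 6.0, 21.9),
    "fsh": (10.4, 6.6, 16.6),
}

#: study group sizes
N_PCOS = 52
N_CONTROL = 42
#: daily-sampling normative cohort size
N_CYCLE_CONTROLS = 32

# (median, p97.5) targets; groups were BMI-matched on average
AGE_TARGETS_PCOS = (25.0, 38.0)
AGE_TARGETS_CONTROL = (30.0, 40.0)
BMI_TARGETS_PCOS = (26.6, 48.4)
BMI_TARGETS_CONTROL = (27.8, 33.3)


def unit_factor(unit: str) -> float:
    """Return the multiplicative factor converting `unit` to ng/dL."""
    try:
        return UNIT_FACTORS[unit]
    except KeyError:
        raise ValueError(
            f"unknown unit {unit!r}; accepted units: {sorted(UNIT_FACTORS)}"
        ) from None
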