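"""Steroidogenesis pathway encoding and product:precursor ratio statistics.

Product-to-precursor concentration ratios, expressed as percentages, are a
steady-state proxy for the relative activity of the steroidogenic enzymes:
for each enzyme the summed concentration of its immediate products is divided
by the summed concentration of its immediate substrates, x100. They are
concentration proxies only, not kinetic measurements.

The default enzyme map is a documented reconstruction (the published ratio
table does not list the analyte sets behind each row); it is validated at
load time and user-editable via YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .analytes import PANEL_STEROIDS, unit_factor
from .assay_qc import substitute_loq_table
from .group_stats import rank_sum_test, summarize


@dataclass(frozen=True)
class PathwaySpec:
    """Map from each enzyme to its (precursor, product) analyte sets.

    `androgen_precursors` is the analyte set summed for the "total androgens
    and their precursors" statistic.
    """

    enzymes: dict[str, tuple[frozenset[str], frozenset[str]]]
    androgen_precursors: frozenset[str]
    unit_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        panel = set(PANEL_STEROIDS)
        for enzyme, (precursors, products) in self.enzymes.items():
            if not precursors or not products:
                raise ValueError(f"{enzyme}: precursor and product sets must be non-empty")
            if precursors & products:
                raise ValueError(f"{enzyme}: precursor and product sets overlap")
            unknown = (precursors | products) - panel
            if unknown:
                raise ValueError(f"{enzyme}: non-panel analytes {sorted(unknown)}")
        if not self.androgen_precursors:
            raise ValueError("androgen_precursors must be non-empty")
        unknown = set(self.androgen_precursors) - panel
        if unknown:
            raise ValueError(f"androgen_precursors: non-panel analytes {sorted(unknown)}")

    @property
    def adjacent_pairs(self) -> frozenset[tuple[str, str]]:
        """Unordered precursor-product pairs across all enzymes (for copulas)."""
        pairs = set()
        for precursors, products in self.enzymes.values():
            for p in precursors:
                for q in products:
                    pairs.add(tuple(sorted((p, q))))
        return frozenset(pairs)

    def to_yaml(self, path) -> None:
        doc = {
            "enzymes": {
                name: {"precursors": sorted(pre), "products": sorted(pro)}
                for name, (pre, pro) in self.enzymes.items()
            },
            "androgen_precursors": sorted(self.androgen_precursors),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PathwaySpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        enzymes = {
            name: (frozenset(block["precursors"]), frozenset(block["products"]))
            for name, block in doc["enzymes"].items()
        }
        return cls(enzymes=enzymes,
                   androgen_precursors=frozenset(doc["androgen_precursors"]))


def default_pathway_spec() -> PathwaySpec:
    """Default enzyme map over the 13-analyte panel.

    Parallel delta-5/delta-4 branches are summed; DHEAS is excluded from all
    ratios (sulfated storage pool, no enzyme row uses it).
    """
    return PathwaySpec(
        enzymes={
            "3b_hsd": (
                frozenset({"pregnenolone", "17oh_pregnenolone", "dhea"}),
                frozenset({"progesterone", "17oh_progesterone", "androstenedione"}),
            ),
            "17a_hydroxylase": (
                frozenset({"pregnenolone", "progesterone"}),
                frozenset({"17oh_pregnenolone", "17oh_progesterone"}),
            ),
            "17_20_lyase": (
                frozenset({"17oh_pregnenolone", "17oh_progesterone"}),
                frozenset({"dhea", "androstenedione"}),
            ),
            "17b_hsd": (
                frozenset({"androstenedione"}),
                frozenset({"testosterone"}),
            ),
            "21_hydroxylase": (
                frozenset({"progesterone", "17oh_progesterone"}),
                frozenset({"deoxycorticosterone", "11_deoxycortisol"}),
            ),
            "11b_hydroxylase": (
                frozenset({"deoxycorticosterone", "11_deoxycortisol"}),
                frozenset({"corticosterone", "cortisol"}),
            ),
        },
        androgen_precursors=frozenset({
            "pregnenolone", "17oh_pregnenolone", "dhea",
            "17oh_progesterone", "androstenedione", "testosterone",
        }),
    )


def normalize_units(profiles: pd.DataFrame, units: dict[str, str]) -> pd.DataFrame:
    """Convert analyte columns to ng/dL using the declared per-column units.

    Raises on a unit with no conversion entry. Columns without a declared
    unit are left untouched (assumed already ng/dL).
    """
    out = profiles.copy()
    for column, unit in units.items():
        if column not in out.columns:
            continue
        out[column] = out[column] * unit_factor(unit)
    return out


def enzyme_percent(profiles: pd.DataFrame, enzyme: str, spec: PathwaySpec) -> pd.Series:
    """Per-subject percent product-to-precursor for one enzyme.

    Expects unit-normalized, LOQ-substituted concentrations (the substitution
    guarantees a strictly positive precursor sum).
    """
    if enzyme not in spec.enzymes:
        raise KeyError(f"unknown enzyme {enzyme!r}; known: {sorted(spec.enzymes)}")
    precursors, products = spec.enzymes[enzyme]
    missing = (precursors | products) - set(profiles.columns)
    if missing:
        raise ValueError(f"{enzyme}: profile table lacks analytes {sorted(missing)}")
    num = profiles[sorted(products)].sum(axis=1)
    den = profiles[sorted(precursors)].sum(axis=1)
    if (den <= 0).any():
        raise ValueError("nonpositive precursor sum; apply LOQ substitution first")
    return 100.0 * num / den


def total_androgen_precursors(profiles: pd.DataFrame, spec: PathwaySpec) -> pd.Series:
    """Per-subject summed concentration of androgens and their precursors (ng/dL)."""
    cols = sorted(spec.androgen_precursors)
    missing = set(cols) - set(profiles.columns)
    if missing:
        raise ValueError(f"profile table lacks analytes {sorted(missing)}")
    return profiles[cols].sum(axis=1)


def pathway_panel(
    cohort: pd.DataFrame,
    spec: PathwaySpec | None = None,
    loq_table: dict[str, float] | None = None,
    group_col: str = "group",
    include_total: bool = True,
) -> pd.DataFrame:
    """Per-enzyme ratio summaries and between-group rank-sum tests.

    Applies LOQ substitution first (pass ``loq_table=None`` to use the panel
    defaults, or an explicit mapping). Returns one row per enzyme with group
    medians, (2.5, 97.5) percentiles and the two-sided rank-sum p value;
    single-subject groups yield ``p=NaN`` with ``degenerate=True``.
    """
    spec = spec or default_pathway_spec()
    data = substitute_loq_table(cohort, loq_table)
    groups = list(dict.fromkeys(data[group_col]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    # conventional ordering: case group first when labelled
    if "pcos" in groups and groups[0] != "pcos":
        groups = ["pcos", groups[0] if groups[0] != "pcos" else groups[1]]
    ga, gb = groups
    rows = []

    def _row(name: str, values: pd.Series) -> dict:
        xa = values[data[group_col] == ga].to_numpy(float)
        xb = values[data[group_col] == gb].to_numpy(float)
        sa, sb = summarize(xa), summarize(xb)
        degenerate = min(xa.size, xb.size) < 2
        p = np.nan if degenerate else rank_sum_test(xa, xb).p_value
        return {
            "statistic": name,
            f"{ga}_median": sa.median, f"{ga}_p2_5": sa.p2_5, f"{ga}_p97_5": sa.p97_5,
            f"{gb}_median": sb.median, f"{gb}_p2_5": sb.p2_5, f"{gb}_p97_5": sb.p97_5,
            "p_value": p,
            "n_" + ga: xa.size, "n_" + gb: xb.size,
            "degenerate": degenerate,
        }

    for enzyme in spec.enzymes:
        rows.append(_row(enzyme, enzyme_percent(data, enzyme, spec)))
    if include_total:
        rows.append(_row("total_androgens_precursors",
                         total_androgen_precursors(data, spec)))
    return pd.DataFrame(rows)
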