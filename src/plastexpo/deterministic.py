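"""Deterministic screening assessment: per-category exposure ranges and MOE.

For every (category, chemical) pair retained by the inclusion filter,
the maximum-exposure scenario evaluates both dose equations at the
category's maximum detected concentration, and the minimum-exposure
scenario at the 0.01% w/w (100 mg/kg) inclusion-threshold
concentration.  Using the threshold (rather than the lowest observed
value) as the minimum makes the per-chemical minima identical across
categories, which is the convention these screening minima follow.

Ingestion applies only to the mouthing-relevant categories
(accessories, stationery, toy); dermal contact applies to all six.
The margin of exposure is MOE = reference_dose / dose, with MOE < 100
flagged as the screening concern level.

Internally everything is computed at full precision; display rounding
(2 significant figures, scientific notation) happens only in
:func:`format_table3`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .chemistry import ChemicalSpec, registry
from .dermal import (
    ANCHOR_CONTENT_FRACTION,
    ExposureFactorSet,
    content_to_cart,
    dermal_daily_dose,
    dermal_intermediates,
)
from .ingestion import (
    MigrationRatePolicy,
    TWO_LEVEL_POLICY,
    assign_migration_rate,
    ingestion_daily_dose,
)
from .survey import ProductRecord, summarize

__all__ = [
    "MOUTHING_CATEGORIES",
    "MOE_SCREENING_THRESHOLD",
    "DoseResult",
    "moe",
    "category_exposure_range",
    "table3_report",
    "format_table3",
    "migration_sensitivity",
    "format_sig2",
]

#: Categories for which oral ingestion by mouthing is assessed.
MOUTHING_CATEGORIES = frozenset({"accessories", "stationery", "toy"})

#: Screening concern level: MOE below this value is flagged.
MOE_SCREENING_THRESHOLD = 100.0


@dataclass(frozen=True)
class DoseResult:
    """One dose estimate: (category, chemical, route, scenario) with MOE.

    ``moe`` is ``None`` when the dose is zero (no-exposure: MOE
    undefined, deliberately not infinity).
    """

    category: str
    chemical: str
    route: str  # ingestion | dermal | total
    scenario: str  # max | min
    dose: float
    moe: float | None
    flagged: bool  # True when MOE < screening threshold

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


def moe(reference_dose: float, dose: float) -> float | None:
    """Margin of exposure = reference_dose / dose; None for zero dose."""
    if reference_dose <= 0:
        raise ValueError("reference dose must be > 0")
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0:
        return None
    return reference_dose / dose


def _result(category, chemical, route, scenario, dose, rfd) -> DoseResult:
    m = moe(rfd, dose)
    return DoseResult(
        category, chemical, route, scenario, dose, m,
        flagged=(m is not None and m < MOE_SCREENING_THRESHOLD),
    )


def category_exposure_range(
    records: Iterable[ProductRecord],
    chemical: str,
    category: str,
    factors: ExposureFactorSet,
    policy: MigrationRatePolicy = TWO_LEVEL_POLICY,
    chem_registry: Mapping[str, ChemicalSpec] | None = None,
) -> list[DoseResult]:
    """Max/min scenario doses per route for one (category, chemical).

    ``records`` must already be passed through the inclusion filter.
    Returns an empty list when the chemical is absent from the category.
    """
    reg = chem_registry if chem_registry is not None else registry()
    chem = reg[chemical.upper()]
    cell = [
        s for s in summarize(records)
        if s.category == category and s.chemical == chem.abbreviation
    ]
    if not cell:
        return []
    content_max = cell[0].conc_max / 1e6  # mg/kg -> mass fraction
    content_min = ANCHOR_CONTENT_FRACTION

    inter = dermal_intermediates(chem, factors)
    results: list[DoseResult] = []
    for scenario, content in (("max", content_max), ("min", content_min)):
        total = 0.0
        if category in MOUTHING_CATEGORIES:
            mr = assign_migration_rate(content, policy)
            d_ing = ingestion_daily_dose(mr, factors)
            results.append(
                _result(category, chem.abbreviation, "ingestion", scenario,
                        d_ing, chem.reference_dose)
            )
            total += d_ing
        c_art = content_to_cart(content, factors.rho_article)
        d_derm = dermal_daily_dose(c_art, factors, inter)
        results.append(
            _result(category, chem.abbreviation, "dermal", scenario,
                    d_derm, chem.reference_dose)
        )
        total += d_derm
        results.append(
            _result(category, chem.abbreviation, "total", scenario,
                    total, chem.reference_dose)
        )
    return results


def table3_report(
    records: Iterable[ProductRecord],
    factors: ExposureFactorSet,
    policy: MigrationRatePolicy = TWO_LEVEL_POLICY,
    chem_registry: Mapping[str, ChemicalSpec] | None = None,
) -> pd.DataFrame:
    """Wide exposure-range report, one row per (category, chemical).

    Columns: reference_dose, ingestion/dermal/total max & min doses
    (NaN for routes that do not apply), MOE for the total max and min
    scenarios, and the screening flag.  Values are unrounded; use
    :func:`format_table3` for the 2-significant-figure display table.
    """
    reg = chem_registry if chem_registry is not None else registry()
    records = list(records)
    rows = []
    for s in summarize(records):
        res = category_exposure_range(
            records, s.chemical, s.category, factors, policy, reg
        )
        by = {(r.route, r.scenario): r for r in res}
        row = {
            "category": s.category,
            "chemical": s.chemical,
            "reference_dose": reg[s.chemical].reference_dose,
        }
        for route in ("ingestion", "dermal", "total"):
            for scen in ("max", "min"):
                r = by.get((route, scen))
                row[f"{route}_{scen}"] = r.dose if r is not None else float("nan")
        row["moe_max"] = by[("total", "max")].moe
        row["moe_min"] = by[("total", "min")].moe
        row["flagged"] = by[("total", "max")].flagged
        rows.append(row)
    columns = [
        "category", "chemical", "reference_dose",
        "ingestion_max", "ingestion_min", "dermal_max", "dermal_min",
        "total_max", "total_min", "moe_max", "moe_min", "flagged",
    ]
    return pd.DataFrame(rows, columns=columns)


def format_sig2(x: float | None) -> str:
    """Format to 2 significant figures in scientific notation ('' for None/NaN)."""
    if x is None or pd.isna(x):
        return ""
    return f"{float(x):.1e}"


def format_table3(report: pd.DataFrame) -> pd.DataFrame:
    """Display copy of the report with 2-significant-figure formatting."""
    out = report.copy()
    num = [c for c in out.columns if c not in ("category", "chemical", "flagged")]
    for c in num:
        out[c] = out[c].map(format_sig2)
    return out


def migration_sensitivity(
    records: Iterable[ProductRecord],
    factors: ExposureFactorSet,
    levels: Iterable[float] = (10.0, 0.1, 1e-3, 1e-4),
    experimental_mr: float | None = None,
    chem_registry: Mapping[str, ChemicalSpec] | None = None,
) -> pd.DataFrame:
    """Ingestion dose and MOE across discrete migration-rate levels.

    Recomputes the ingestion dose of every mouthing-relevant
    (category, chemical) cell at each MR level (plus an optional
    user-supplied experimental MR), quantifying the span the discrete
    assignment induces: the dose ratio between 10 and 1e-4 mg/cm2/h is
    exactly 1e5 by linearity.
    """
    reg = chem_registry if chem_registry is not None else registry()
    mrs = [("assigned", mr) for mr in levels]
    if experimental_mr is not None:
        mrs.append(("experimental", float(experimental_mr)))
    rows = []
    for s in summarize(records):
        if s.category not in MOUTHING_CATEGORIES:
            continue
        rfd = reg[s.chemical].reference_dose
        for kind, mr in mrs:
            dose = ingestion_daily_dose(mr, factors)
            rows.append(
                {
                    "category": s.category,
                    "chemical": s.chemical,
                    "mr_kind": kind,
                    "mr": mr,
                    "ingestion_dose": dose,
                    "moe": moe(rfd, dose),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["category", "chemical", "mr_kind", "mr", "ingestion_dose", "moe"],
    )
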