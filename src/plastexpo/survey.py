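"""Product-survey data model, I/O, censoring filters and summaries.

A survey is a list of :class:`ProductRecord`, one per purchased product,
each holding per-chemical concentration measurements with a detected /
non-detected flag.  Concentrations are stored internally in mg/kg; the
CSV schema also accepts % w/w (1% w/w = 10,000 mg/kg).

Two explicit censoring operations are provided and never applied
implicitly:

* :func:`substitute_nondetects` — left-censored values set to LOQ/2
  (used before fitting concentration distributions for the Monte Carlo
  engine);
* :func:`filter_for_exposure` — retain only measurements detected
  strictly above the 100 mg/kg screening inclusion threshold (used for
  the deterministic assessment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .chemistry import CHEMICAL_ABBREVIATIONS, ChemicalSpec, registry

__all__ = [
    "CATEGORIES",
    "INCLUSION_THRESHOLD_MG_KG",
    "Measurement",
    "ProductRecord",
    "CategorySummary",
    "SurveyValidationError",
    "read_survey",
    "write_survey",
    "substitute_nondetects",
    "filter_for_exposure",
    "summarize",
]

#: The six product categories of the survey.
CATEGORIES = ("accessories", "mat", "shoes", "stationery", "toilet", "toy")

#: Screening inclusion threshold (mg/kg); measurements must be detected
#: strictly above it to enter the deterministic exposure assessment.
INCLUSION_THRESHOLD_MG_KG = 100.0

_CSV_COLUMNS = [
    "product_id",
    "category",
    "subcategory",
    "chemical",
    "concentration",
    "unit",
    "detected",
]


class SurveyValidationError(ValueError):
    """Schema or content error in a survey file, with offending line numbers."""


@dataclass(frozen=True)
class Measurement:
    """One chemical measurement on one product.

    ``concentration`` is in mg/kg and is ``None`` for non-detects until
    an explicit substitution is applied; ``detected`` preserves the
    original censoring flag through any substitution.
    """

    concentration: float | None
    detected: bool

    def __post_init__(self) -> None:
        if self.concentration is not None and self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class ProductRecord:
    """One surveyed product and its per-chemical measurements."""

    product_id: str
    category: str
    subcategory: str
    measurements: dict[str, Measurement] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not in {CATEGORIES}"
            )

    def detected_chemicals(self) -> list[str]:
        return [c for c, m in self.measurements.items() if m.detected]


@dataclass(frozen=True)
class CategorySummary:
    """Detection count and concentration range for one (category, chemical)."""

    category: str
    chemical: str
    n_detected: int
    conc_max: float
    conc_min: float

    def __post_init__(self) -> None:
        if self.n_detected < 0:
            raise ValueError("n_detected must be >= 0")
        if self.conc_min > self.conc_max:
            raise ValueError("conc_min must be <= conc_max")


def _to_mg_per_kg(value: float, unit: str) -> float:
    if unit == "mg_per_kg":
        return value
    if unit == "percent_ww":
        return value * 10_000.0
    raise ValueError(f"unknown unit {unit!r}")


def read_survey(path) -> list[ProductRecord]:
    """Read a long-format survey CSV into product records.

    One row per (product, chemical) measurement.  Non-detect rows leave
    ``concentration`` empty.  Malformed rows are reported with their
    1-based file line numbers (header = line 1).
    """
    table = pd.read_csv(path, dtype={"product_id": str, "subcategory": str})
    missing = [c for c in _CSV_COLUMNS if c not in table.columns]
    if missing:
        raise SurveyValidationError(f"missing required column(s): {missing}")

    errors: list[str] = []
    records: dict[str, ProductRecord] = {}
    valid_chems = set(CHEMICAL_ABBREVIATIONS)
    for i, row in enumerate(table.itertuples(index=False)):
        line = i + 2
        if row.category not in CATEGORIES:
            errors.append(f"line {line}: unknown category {row.category!r}")
            continue
        chem = str(row.chemical).upper()
        if chem not in valid_chems:
            errors.append(f"line {line}: unknown chemical {row.chemical!r}")
            continue
        detected = bool(int(row.detected))
        conc = None
        if not pd.isna(row.concentration):
            try:
                conc = _to_mg_per_kg(float(row.concentration), str(row.unit))
            except ValueError as exc:
                errors.append(f"line {line}: {exc}")
                continue
            if conc < 0:
                errors.append(f"line {line}: negative concentration")
                continue
        if detected and conc is None:
            errors.append(f"line {line}: detected row without a concentration")
            continue
        rec = records.get(row.product_id)
        if rec is None:
            subcat = "" if pd.isna(row.subcategory) else str(row.subcategory)
            rec = ProductRecord(str(row.product_id), str(row.category), subcat)
            records[row.product_id] = rec
        rec.measurements[chem] = Measurement(conc, detected)

    if errors:
        raise SurveyValidationError(
            f"{len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    return list(records.values())


def write_survey(records: Iterable[ProductRecord], path) -> None:
    """Write records in the same long CSV schema that :func:`read_survey` reads."""
    rows = []
    for rec in records:
        for chem in CHEMICAL_ABBREVIATIONS:
            m = rec.measurements.get(chem)
            if m is None:
                continue
            rows.append(
                {
                    "product_id": rec.product_id,
                    "category": rec.category,
                    "subcategory": rec.subcategory,
                    "chemical": chem,
                    "concentration": "" if m.concentration is None
                    else repr(float(m.concentration)),
                    "unit": "mg_per_kg",
                    "detected": int(m.detected),
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def substitute_nondetects(
    records: Iterable[ProductRecord],
    chem_registry: Mapping[str, ChemicalSpec] | None = None,
) -> list[ProductRecord]:
    """Set every non-detect concentration to LOQ/2 for its chemical.

    Detected measurements are untouched; the censoring flag is
    preserved, so the operation is idempotent.
    """
    reg = chem_registry if chem_registry is not None else registry()
    out = []
    for rec in records:
        meas = {}
        for chem, m in rec.measurements.items():
            if m.detected:
                meas[chem] = m
            else:
                meas[chem] = Measurement(reg[chem].loq / 2.0, False)
        out.append(ProductRecord(rec.product_id, rec.category, rec.subcategory, meas))
    return out


def filter_for_exposure(
    records: Iterable[ProductRecord],
    threshold: float = INCLUSION_THRESHOLD_MG_KG,
) -> list[ProductRecord]:
    """Retain measurements detected strictly above the inclusion threshold.

    Products left with no retained measurement are dropped.  The
    operation is idempotent.
    """
    out = []
    for rec in records:
        kept = {
            chem: m
            for chem, m in rec.measurements.items()
            if m.detected and m.concentration is not None and m.concentration > threshold
        }
        if kept:
            out.append(
                ProductRecord(rec.product_id, rec.category, rec.subcategory, kept)
            )
    return out


def summarize(records: Iterable[ProductRecord]) -> list[CategorySummary]:
    """Per (category, chemical) detection count and concentration range.

    Only detected measurements with a stored concentration contribute.
    Combinations with no such measurement are simply absent.  The caller
    controls any prior filtering.
    """
    acc: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        for chem, m in rec.measurements.items():
            if m.detected and m.concentration is not None:
                acc.setdefault((rec.category, chem), []).append(m.concentration)
    out = []
    for (cat, chem) in sorted(acc):
        vals = acc[(cat, chem)]
        out.append(CategorySummary(cat, chem, len(vals), max(vals), min(vals)))
    return out
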