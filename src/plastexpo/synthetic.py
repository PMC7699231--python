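"""Seeded synthetic product surveys with prescribed margins.

The study this package emulates surveyed 3345 children's products in
six categories; no product-level dataset is deposited, only margins:
per-(category, chemical) detection counts, category maximum
concentrations, the number of products with at least one detection
(387) and with exactly one (286), and two co-occurrence rules (DEHP is
present in every multi-plasticizer product except two shoes products
with DBP+DINP; DEP occurs only as the single chemical of 10 toys).

:func:`generate_survey` constructs a product-level survey that matches
every one of those margins exactly.  The combinatorial assignment is
deterministic (largest-remainder apportionment with canonical
tie-breaking), so only the concentration draws consume randomness and
the same seed reproduces the survey byte-for-byte.  Detected
concentrations are drawn from a truncated lognormal on
(100 mg/kg, category maximum], with the maximum itself assigned to
exactly one product per cell so every category maximum is reproduced
exactly.  The true concentration distributions are unknown (only box
plots are published); the lognormal is a documented stand-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .chemistry import CHEMICAL_ABBREVIATIONS
from .survey import CATEGORIES, Measurement, ProductRecord

__all__ = [
    "SurveyBlueprint",
    "BlueprintError",
    "MarginCheck",
    "default_blueprint",
    "generate_survey",
    "validate_margins",
]


class BlueprintError(ValueError):
    """Blueprint constraints are unsatisfiable; names the first violation."""


def _max_mgkg(percent: float) -> float:
    """Cell maximum in mg/kg from % w/w, rounded to kill float dust."""
    return round(percent * 10_000.0, 6)


@dataclass(frozen=True)
class SurveyBlueprint:
    """All margins the generated survey must reproduce exactly."""

    category_sizes: dict[str, int]
    detection_counts: dict[str, dict[str, int]]  # category -> chemical -> n
    maxima_percent: dict[str, dict[str, float]]  # category -> chemical -> % w/w
    subcategories: dict[str, tuple[str, ...]]
    n_any_detection: int = 387
    n_single_detection: int = 286
    n_special_shoes: int = 2  # DBP+DINP pairs without DEHP
    #: pre-truncation log-sd for cells whose maximum exceeds 1% w/w,
    #: placed so roughly a quarter of detected values exceed 1%
    log_sigma_high: float = 1.5

    def chemical_totals(self) -> dict[str, int]:
        totals = {c: 0 for c in CHEMICAL_ABBREVIATIONS}
        for counts in self.detection_counts.values():
            for chem, n in counts.items():
                totals[chem] += n
        return totals


def default_blueprint() -> SurveyBlueprint:
    """The packaged blueprint: the surveyed margins of the 3345-product study."""
    return SurveyBlueprint(
        category_sizes={
            "accessories": 605, "mat": 110, "shoes": 176,
            "stationery": 785, "toilet": 38, "toy": 1631,
        },
        detection_counts={
            "accessories": {"DBP": 6, "DEHA": 15, "DEHP": 51, "DINP": 29},
            "mat": {"DBP": 1, "DEHP": 6, "DINP": 1},
            "shoes": {"DBP": 36, "DEHP": 30, "DINP": 29},
            "stationery": {"DBP": 11, "DEHA": 6, "DEHP": 126, "DIBP": 1, "DINP": 54},
            "toilet": {"DEHP": 5, "DINP": 9},
            "toy": {"DBP": 12, "DEHA": 9, "DEHP": 46, "DEP": 10, "DIBP": 13, "DINP": 19},
        },
        maxima_percent={
            "accessories": {"DBP": 0.35, "DEHA": 0.59, "DEHP": 22.90, "DINP": 15.52},
            "mat": {"DBP": 0.01, "DEHP": 20.13, "DINP": 0.06},
            "shoes": {"DBP": 33.12, "DEHP": 38.95, "DINP": 14.34},
            "stationery": {"DBP": 0.16, "DEHA": 0.20, "DEHP": 33.68,
                           "DIBP": 0.01, "DINP": 40.52},
            "toilet": {"DEHP": 8.41, "DINP": 4.83},
            "toy": {"DBP": 8.03, "DEHA": 0.08, "DEHP": 28.11,
                    "DEP": 0.92, "DIBP": 27.20, "DINP": 4.68},
        },
        subcategories={
            "accessories": ("clothes", "jewelry", "mobile accessories",
                            "household stuffs", "DIY tools"),
            "mat": ("non-slip mat", "play mat"),
            "shoes": ("roller shoes", "sandals", "summer shoes",
                      "indoor shoes", "shower sandals"),
            "stationery": ("beauty and personal care", "kitchen stuffs",
                           "office products", "painting and drawing supplies",
                           "tools and furniture"),
            "toilet": ("potty toilet",),
            "toy": ("gift and party goods", "play figures", "certain toys",
                    "arts and crafts", "preschool games", "aquatic toys",
                    "other infant toys"),
        },
    )


def _apportion(total: int, weights: dict[str, float], caps: dict[str, int]) -> dict[str, int]:
    """Largest-remainder apportionment of ``total`` with per-key caps.

    Deterministic: ties broken by descending remainder then key order.
    """
    keys = sorted(weights)
    wsum = sum(weights[k] for k in keys)
    if total > sum(caps[k] for k in keys):
        raise BlueprintError(f"cannot apportion {total} under caps {caps}")
    if total == 0 or wsum == 0:
        alloc = {k: 0 for k in keys}
    else:
        quota = {k: total * weights[k] / wsum for k in keys}
        alloc = {k: min(int(math.floor(quota[k])), caps[k]) for k in keys}
        order = sorted(keys, key=lambda k: (-(quota[k] - math.floor(quota[k])), k))
        while sum(alloc.values()) < total:
            progressed = False
            for k in order:
                if alloc[k] < caps[k]:
                    alloc[k] += 1
                    progressed = True
                    if sum(alloc.values()) == total:
                        break
            if not progressed:  # pragma: no cover - guarded above
                raise BlueprintError("apportionment failed under caps")
    return alloc


def _plan_category(cat: str, bp: SurveyBlueprint, m: int, x: int) -> list[tuple[str, ...]]:
    """Chemical composition of every detected product in one category.

    Returns a list of chemical tuples, one per product with >= 1
    detection, in a canonical deterministic order: DEHP-multis,
    special shoes pairs, DEP singles, then singles per chemical.
    """
    counts = dict(bp.detection_counts[cat])
    specials = bp.n_special_shoes if cat == "shoes" else 0
    dep_singles = counts.pop("DEP", 0) if cat == "toy" else 0
    dehp = counts.pop("DEHP", 0)
    others = dict(counts)
    if specials:
        for chem in ("DBP", "DINP"):
            if others.get(chem, 0) < specials:
                raise BlueprintError(
                    f"{cat}: need {specials} {chem} for special DBP+DINP products"
                )
            others[chem] -= specials

    # allocate each other-chemical's share of the x multi slots
    caps = {c: min(n, m) for c, n in others.items() if n > 0}
    weights = {c: float(others[c]) for c in caps}
    shares = _apportion(x, weights, caps) if m else {c: 0 for c in caps}

    multis: list[list[str]] = [["DEHP"] for _ in range(m)]
    offset = 0
    for chem in sorted(shares):
        for i in range(shares[chem]):
            multis[(offset + i) % m].append(chem)
        offset += shares[chem]
    if any(len(p) < 2 for p in multis):
        raise BlueprintError(f"{cat}: a multi-plasticizer product got no partner")

    products: list[tuple[str, ...]] = [tuple(p) for p in multis]
    products += [("DBP", "DINP")] * specials
    products += [("DEP",)] * dep_singles
    products += [("DEHP",)] * (dehp - m)
    for chem in sorted(others):
        products += [(chem,)] * (others[chem] - shares.get(chem, 0))
    return products


def _plan_assignment(bp: SurveyBlueprint) -> dict[str, list[tuple[str, ...]]]:
    """Solve the margin constraints into per-category product compositions."""
    totals = bp.chemical_totals()
    total_det = sum(totals.values())
    n_multi = bp.n_any_detection - bp.n_single_detection
    n_dehp_multi = n_multi - bp.n_special_shoes
    # non-DEHP slots inside DEHP-multis, across all categories
    x_total = total_det - bp.n_single_detection - n_dehp_multi - 2 * bp.n_special_shoes
    if x_total < n_dehp_multi:
        raise BlueprintError(
            f"not enough co-detections: {x_total} slots for {n_dehp_multi} multi products"
        )

    caps_m, slot_caps = {}, {}
    for cat in CATEGORIES:
        counts = dict(bp.detection_counts.get(cat, {}))
        if cat == "toy":
            counts.pop("DEP", None)
        dehp = counts.pop("DEHP", 0)
        if cat == "shoes":
            for chem in ("DBP", "DINP"):
                counts[chem] = counts.get(chem, 0) - bp.n_special_shoes
        others_sum = sum(v for v in counts.values() if v > 0)
        caps_m[cat] = min(dehp, others_sum)
        slot_caps[cat] = counts

    m_alloc = _apportion(n_dehp_multi, {c: float(v) for c, v in caps_m.items()}, caps_m)
    extra_caps = {
        cat: sum(min(n, m_alloc[cat]) for n in slot_caps[cat].values() if n > 0)
        - m_alloc[cat]
        for cat in CATEGORIES
    }
    extra_alloc = _apportion(
        x_total - n_dehp_multi,
        {c: float(max(v, 0)) for c, v in extra_caps.items()},
        {c: max(v, 0) for c, v in extra_caps.items()},
    )

    plan = {}
    for cat in CATEGORIES:
        plan[cat] = _plan_category(
            cat, bp, m_alloc[cat], m_alloc[cat] + extra_alloc[cat]
        )
        if len(plan[cat]) > bp.category_sizes.get(cat, 0):
            raise BlueprintError(
                f"{cat}: {len(plan[cat])} detected products exceed "
                f"category size {bp.category_sizes.get(cat, 0)}"
            )
    return plan


def _draw_concentrations(
    k: int, max_mgkg: float, sigma_high: float, rng: np.random.Generator
) -> np.ndarray:
    """k concentrations in (100, max], right-skewed, the first equal to max."""
    if max_mgkg < 100.0:
        raise BlueprintError(f"cell maximum {max_mgkg} mg/kg below inclusion threshold")
    out = np.empty(k)
    out[0] = max_mgkg
    if k == 1:
        return out
    lo, hi = math.log(100.0), math.log(max_mgkg)
    if hi <= lo + 1e-12:  # maximum sits exactly at the threshold
        out[:] = max_mgkg
        return out
    if max_mgkg > 10_000.0:
        # mode of the policy-relevant regime: ~25% of draws above 1% w/w
        sigma = sigma_high
        mu = math.log(10_000.0) - 0.674 * sigma
    else:
        mu = 0.5 * (lo + hi)
        sigma = max((hi - lo) / 4.0, 0.05)
    a, b = (lo + 1e-9 - mu) / sigma, (hi - mu) / sigma
    out[1:] = np.exp(truncnorm.rvs(a, b, loc=mu, scale=sigma, size=k - 1,
                                   random_state=rng))
    return out


def generate_survey(
    blueprint: SurveyBlueprint | None = None, seed: int = 0
) -> list[ProductRecord]:
    """Generate a full synthetic survey satisfying every blueprint margin.

    Product composition is solved deterministically; the seed controls
    only concentrations (below each cell's maximum) and cosmetic
    subcategory labels.  Non-detected measurements are emitted with a
    missing concentration and ``detected=False``.
    """
    bp = blueprint if blueprint is not None else default_blueprint()
    plan = _plan_assignment(bp)
    rng = np.random.default_rng(seed)

    records: list[ProductRecord] = []
    conc_table: dict[str, dict[int, dict[str, float]]] = {}
    for cat in CATEGORIES:
        compositions = plan.get(cat, [])
        # per-cell concentration draws, first carrier gets the exact maximum
        cell_products: dict[str, list[int]] = {}
        for idx, chems in enumerate(compositions):
            for chem in chems:
                cell_products.setdefault(chem, []).append(idx)
        cat_conc: dict[int, dict[str, float]] = {}
        for chem in sorted(cell_products):
            idxs = cell_products[chem]
            if len(idxs) != bp.detection_counts[cat].get(chem, 0):
                raise BlueprintError(
                    f"{cat}/{chem}: planned {len(idxs)} != "
                    f"margin {bp.detection_counts[cat].get(chem, 0)}"
                )
            max_mgkg = _max_mgkg(bp.maxima_percent[cat][chem])
            values = _draw_concentrations(len(idxs), max_mgkg, bp.log_sigma_high, rng)
            for idx, val in zip(idxs, values):
                cat_conc.setdefault(idx, {})[chem] = float(val)
        conc_table[cat] = cat_conc

        size = bp.category_sizes[cat]
        subcats = bp.subcategories.get(cat, ("",))
        labels = rng.choice(len(subcats), size=size)
        for i in range(size):
            detected = conc_table[cat].get(i, {}) if i < len(compositions) else {}
            measurements = {}
            for chem in CHEMICAL_ABBREVIATIONS:
                if chem in detected:
                    measurements[chem] = Measurement(detected[chem], True)
                else:
                    measurements[chem] = Measurement(None, False)
            records.append(
                ProductRecord(
                    product_id=f"{cat}-{i + 1:04d}",
                    category=cat,
                    subcategory=subcats[labels[i]],
                    measurements=measurements,
                )
            )
    return records


@dataclass
class MarginCheck:
    """Itemized comparison of one blueprint margin against a survey."""

    constraint: str
    expected: float
    observed: float

    @property
    def ok(self) -> bool:
        return self.expected == self.observed


@dataclass
class MarginReport:
    checks: list[MarginCheck] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.ok for c in self.checks)

    def failures(self) -> list[MarginCheck]:
        return [c for c in self.checks if not c.ok]

    def summary(self) -> str:
        lines = [f"{len(self.checks)} constraints, "
                 f"{len(self.failures())} failed"]
        for c in self.failures():
            lines.append(f"  FAIL {c.constraint}: {c.observed} != {c.expected}")
        return "\n".join(lines)


def validate_margins(
    records: list[ProductRecord], blueprint: SurveyBlueprint | None = None
) -> MarginReport:
    """Compare every blueprint margin against a survey; itemized diffs."""
    bp = blueprint if blueprint is not None else default_blueprint()
    rep = MarginReport()
    add = rep.checks.append

    by_cat: dict[str, list[ProductRecord]] = {c: [] for c in CATEGORIES}
    for rec in records:
        by_cat[rec.category].append(rec)
    for cat in CATEGORIES:
        add(MarginCheck(f"category size {cat}",
                        bp.category_sizes.get(cat, 0), len(by_cat[cat])))

    # per-cell detection counts and maxima
    for cat in CATEGORIES:
        counts: dict[str, int] = {}
        maxima: dict[str, float] = {}
        for rec in by_cat[cat]:
            for chem, m in rec.measurements.items():
                if m.detected:
                    counts[chem] = counts.get(chem, 0) + 1
                    if m.concentration is not None:
                        maxima[chem] = max(maxima.get(chem, 0.0), m.concentration)
        for chem in CHEMICAL_ABBREVIATIONS:
            expected = bp.detection_counts.get(cat, {}).get(chem, 0)
            add(MarginCheck(f"count {cat}/{chem}", expected, counts.get(chem, 0)))
            if expected:
                add(MarginCheck(
                    f"max {cat}/{chem} (mg/kg)",
                    _max_mgkg(bp.maxima_percent[cat][chem]),
                    maxima.get(chem, float("nan")),
                ))

    totals = bp.chemical_totals()
    observed_totals = {c: 0 for c in CHEMICAL_ABBREVIATIONS}
    n_any = n_single = 0
    special = 0
    dehp_rule_ok = 1
    for rec in records:
        det = rec.detected_chemicals()
        for c in det:
            observed_totals[c] += 1
        if det:
            n_any += 1
        if len(det) == 1:
            n_single += 1
        if len(det) > 1 and "DEHP" not in det:
            if rec.category == "shoes" and sorted(det) == ["DBP", "DINP"]:
                special += 1
            else:
                dehp_rule_ok = 0
        if "DEP" in det and (rec.category != "toy" or len(det) != 1):
            add(MarginCheck(f"DEP single-toy rule ({rec.product_id})", 1, 0))
    for chem in CHEMICAL_ABBREVIATIONS:
        add(MarginCheck(f"total {chem}", totals[chem], observed_totals[chem]))
    add(MarginCheck("products with >=1 detection", bp.n_any_detection, n_any))
    add(MarginCheck("products with exactly 1 detection",
                    bp.n_single_detection, n_single))
    add(MarginCheck("special shoes DBP+DINP products", bp.n_special_shoes, special))
    add(MarginCheck("DEHP present in all other multi products", 1, dehp_rule_ok))
    return rep
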