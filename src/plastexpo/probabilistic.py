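"""Monte Carlo exposure estimation across product categories and age groups.

Each iteration draws child anthropometrics (BW, hand skin area SA,
mouthing contact area CA, mouthing duration), a per-category daily
activity duration ED (h/d), and a per-(category, chemical) article
concentration; evaluates the ingestion and dermal dose equations per
category; and sums exposure over the six categories per route.  Totals
are summed per iteration (not per summary statistic), and the median
and 95th percentile over iterations are reported with their MOEs
(MOE at the 95th-percentile dose pairs with that dose, so MOE_p95 <=
MOE_median).

Concentration distributions are fitted per (category, chemical) as
lognormals matching the log-mean and log-SD of the survey sample with
non-detects substituted at LOQ/2, so the induced migration-rate
distribution is the two-point image of the concentration distribution
under the content policy.  Hands are the only dermal contact surface.
Ingestion is assessed for the mouthing-relevant categories
(accessories, stationery, toy) only.

Randomness: one master seed; a dedicated child stream per (age group,
parameter) derived through ``numpy.random.SeedSequence.spawn`` in a
fixed order, so results are bit-reproducible for a given seed.
Percentiles use the empirical quantile with linear interpolation
between order statistics (numpy default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .chemistry import CHEMICAL_ABBREVIATIONS, ChemicalSpec, registry
from .dermal import (
    ExposureFactorSet,
    default_factors,
    fraction_absorbed,
    lag_time,
    permeability,
    volatility_ratio,
)
from .deterministic import MOUTHING_CATEGORIES
from .ingestion import MigrationRatePolicy, TWO_LEVEL_POLICY
from .survey import CATEGORIES, ProductRecord

__all__ = [
    "DistributionSpec",
    "AgeGroupProfile",
    "MCResult",
    "fit_concentration_distribution",
    "load_profiles",
    "default_profiles",
    "run_mc",
    "summarize_mc",
]

logger = logging.getLogger(__name__)

_PROFILE_PARAMS = ("BW", "SA", "CA", "D_mouthing")


@dataclass(frozen=True)
class DistributionSpec:
    """A samplable parameter distribution.

    kinds: ``point`` (params: value); ``normal`` (mean, sd);
    ``truncated_normal`` (mean, sd, optional lower/upper — defaults
    max(0, mean-3sd) and mean+3sd); ``lognormal`` (mu, sigma on the log
    scale).
    """

    kind: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.kind not in ("point", "normal", "truncated_normal", "lognormal"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        scale = {"normal": "sd", "truncated_normal": "sd", "lognormal": "sigma"}
        key = scale.get(self.kind)
        if key is not None and self.params[key] < 0:
            raise ValueError("scale parameter must be >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.kind == "point":
            return np.full(n, float(p["value"]))
        if self.kind == "normal":
            return rng.normal(p["mean"], p["sd"], size=n)
        if self.kind == "lognormal":
            return rng.lognormal(p["mu"], p["sigma"], size=n)
        # truncated normal
        mean, sd = float(p["mean"]), float(p["sd"])
        if sd == 0:
            return np.full(n, mean)
        lower = float(p.get("lower", max(0.0, mean - 3.0 * sd)))
        upper = float(p.get("upper", mean + 3.0 * sd))
        a, b = (lower - mean) / sd, (upper - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


@dataclass(frozen=True)
class AgeGroupProfile:
    """Parameter distributions for one age group.

    ``ed`` maps each product category to the daily duration (h/d) of
    the activity associated with it (stay-in-home for accessories,
    stay-out-of-home for shoes, playing for mat and toy, study for
    stationery, personal sanitation for toilet).
    """

    label: str
    bw: DistributionSpec
    sa: DistributionSpec
    ca: DistributionSpec
    d_mouthing: DistributionSpec
    ed: Mapping[str, DistributionSpec]

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORIES if c not in self.ed]
        if missing:
            raise ValueError(f"profile {self.label!r} missing ED for {missing}")


@dataclass(frozen=True)
class MCResult:
    """Summary of one (chemical, age group, route) dose distribution."""

    chemical: str
    age_group: str
    route: str
    median: float
    p95: float
    moe_median: float
    moe_p95: float
    n_iterations: int
    seed: int

    def __post_init__(self) -> None:
        if self.median > self.p95 * (1 + 1e-12):
            raise ValueError("median must not exceed the 95th percentile")


def _spec_from_dict(d: Mapping) -> DistributionSpec:
    d = dict(d)
    kind = d.pop("kind")
    return DistributionSpec(kind, d)


def load_profiles(path=None) -> dict[str, AgeGroupProfile]:
    """Load age-group profiles from a YAML file (default: packaged)."""
    if path is None:
        source = resources.files("plastexpo.data").joinpath("profiles.yaml")
        with resources.as_file(source) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    profiles = {}
    for label, block in raw["age_groups"].items():
        profiles[str(label)] = AgeGroupProfile(
            label=str(label),
            bw=_spec_from_dict(block["BW"]),
            sa=_spec_from_dict(block["SA"]),
            ca=_spec_from_dict(block["CA"]),
            d_mouthing=_spec_from_dict(block["D_mouthing"]),
            ed={cat: _spec_from_dict(s) for cat, s in block["ED"].items()},
        )
    return profiles


def default_profiles() -> dict[str, AgeGroupProfile]:
    """The packaged placeholder profiles for the 0-2 and 3-12 year groups."""
    return load_profiles()


def fit_concentration_distribution(
    records: Iterable[ProductRecord],
    chemical: str,
    category: str,
    chem_registry: Mapping[str, ChemicalSpec] | None = None,
) -> DistributionSpec | None:
    """Fit a lognormal to a category's concentrations, non-detects at LOQ/2.

    Every product in the category contributes one value: its detected
    concentration, or LOQ/2 when the chemical was not detected (or not
    measured).  A degenerate sample collapses to a point distribution.
    Returns ``None`` ("insufficient data") for fewer than two products.
    """
    reg = chem_registry if chem_registry is not None else registry()
    chem = chemical.upper()
    half_loq = reg[chem].loq / 2.0
    values = []
    for rec in records:
        if rec.category != category:
            continue
        m = rec.measurements.get(chem)
        if m is not None and m.detected and m.concentration is not None:
            values.append(m.concentration)
        else:
            values.append(half_loq)
    if len(values) < 2:
        logger.warning(
            "insufficient data for %s/%s (%d products); cell skipped",
            category, chem, len(values),
        )
        return None
    arr = np.asarray(values)
    logs = np.log(arr)
    if np.allclose(arr, arr[0]):
        return DistributionSpec("point", {"value": float(arr[0])})
    return DistributionSpec(
        "lognormal",
        {"mu": float(logs.mean()), "sigma": float(logs.std(ddof=1))},
    )


def _vector_mr(content: np.ndarray, policy: MigrationRatePolicy) -> np.ndarray:
    conds = [content >= thr for thr in policy.thresholds]
    return np.select(conds, policy.rates, default=policy.fallback_rate)


def run_mc(
    records: Iterable[ProductRecord],
    profiles: Mapping[str, AgeGroupProfile] | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    policy: MigrationRatePolicy = TWO_LEVEL_POLICY,
    base_factors: ExposureFactorSet | None = None,
    chem_registry: Mapping[str, ChemicalSpec] | None = None,
    concentration_overrides: Mapping[tuple[str, str], DistributionSpec] | None = None,
    mouthing_categories: frozenset[str] = MOUTHING_CATEGORIES,
) -> list[MCResult]:
    """Monte Carlo dose summation over all product categories.

    ``base_factors`` supplies the non-sampled physical parameters
    (diffusion coefficient D, temperature, gas-phase mass transfer h,
    constant a, stratum-corneum thickness, article density); it
    defaults to the calibrated ``default-child`` preset.
    ``concentration_overrides`` replaces fitted concentration
    distributions per (category, chemical) cell.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    records = list(records)
    profiles = profiles if profiles is not None else default_profiles()
    reg = chem_registry if chem_registry is not None else registry()
    factors = base_factors if base_factors is not None else default_factors()
    overrides = dict(concentration_overrides or {})

    # concentration distribution per cell (shared across age groups)
    cells: dict[tuple[str, str], DistributionSpec] = {}
    for cat in CATEGORIES:
        for chem in CHEMICAL_ABBREVIATIONS:
            spec = overrides.get((cat, chem))
            if spec is None:
                spec = fit_concentration_distribution(records, chem, cat, reg)
            if spec is None:
                raise ValueError(
                    f"no concentration distribution for {cat}/{chem}: "
                    "survey has fewer than 2 products in the category"
                )
            cells[(cat, chem)] = spec

    # chemical-level scalars
    chem_const = {}
    for chem in CHEMICAL_ABBREVIATIONS:
        c = reg[chem]
        k_p = permeability(c.k_lip, c.k_pol, c.k_aq)
        chem_const[chem] = {
            "t_lag": lag_time(c.mw, factors.h_sc),
            "chi": volatility_ratio(factors.h, c.p_vap, c.mw, k_p, c.s_w, factors.t),
            "rfd": c.reference_dose,
        }

    group_labels = sorted(profiles)
    master = np.random.SeedSequence(seed)
    group_seeds = master.spawn(len(group_labels))

    results: list[MCResult] = []
    for label, gseed in zip(group_labels, group_seeds):
        prof = profiles[label]
        stream_names = list(_PROFILE_PARAMS)
        stream_names += [f"ED:{cat}" for cat in CATEGORIES]
        stream_names += [f"C:{cat}:{chem}" for (cat, chem) in sorted(cells)]
        rngs = {
            name: np.random.default_rng(s)
            for name, s in zip(stream_names, gseed.spawn(len(stream_names)))
        }

        bw = prof.bw.sample(rngs["BW"], n_iter)
        sa = prof.sa.sample(rngs["SA"], n_iter)
        ca = prof.ca.sample(rngs["CA"], n_iter)
        dm = prof.d_mouthing.sample(rngs["D_mouthing"], n_iter)
        ed = {cat: prof.ed[cat].sample(rngs[f"ED:{cat}"], n_iter)
              for cat in CATEGORIES}

        ing = {chem: np.zeros(n_iter) for chem in CHEMICAL_ABBREVIATIONS}
        derm = {chem: np.zeros(n_iter) for chem in CHEMICAL_ABBREVIATIONS}
        for (cat, chem), spec in sorted(cells.items()):
            conc = spec.sample(rngs[f"C:{cat}:{chem}"], n_iter)  # mg/kg
            content = conc / 1e6
            ed_c = ed[cat]  # h/d of activity = daily article contact time
            if cat in mouthing_categories:
                mr = _vector_mr(content, policy)
                ing[chem] += mr * ca * (dm / 60.0) * ed_c / bw
            cc = chem_const[chem]
            fa = (3.0 + cc["chi"] * (1.0 - np.exp(-factors.a * ed_c / cc["t_lag"]))) \
                / (3.0 * (1.0 + cc["chi"]))
            l = 2.0 * np.sqrt(factors.d * ed_c) * 100.0  # cm
            c_art = content * factors.rho_article * 1000.0  # mg/cm3
            derm[chem] += c_art * (sa / bw) * l * fa

        for chem in CHEMICAL_ABBREVIATIONS:
            routes = {
                "ingestion": ing[chem],
                "dermal": derm[chem],
                "total": ing[chem] + derm[chem],
            }
            med_i = float(np.median(ing[chem]))
            med_d = float(np.median(derm[chem]))
            if med_d > 0 and not (10.0 <= med_i / med_d <= 1000.0):
                warnings.warn(
                    f"{chem}/{label}: median ingestion/dermal ratio "
                    f"{med_i / med_d:.3g} outside the expected 10-1000 band",
                    stacklevel=2,
                )
            rfd = chem_const[chem]["rfd"]
            for route, draws in routes.items():
                med = float(np.median(draws))
                p95 = float(np.percentile(draws, 95))
                results.append(
                    MCResult(
                        chemical=chem,
                        age_group=label,
                        route=route,
                        median=med,
                        p95=p95,
                        moe_median=rfd / med if med > 0 else float("nan"),
                        moe_p95=rfd / p95 if p95 > 0 else float("nan"),
                        n_iterations=n_iter,
                        seed=seed,
                    )
                )
    return results


def summarize_mc(results: Iterable[MCResult]) -> pd.DataFrame:
    """Wide report: one row per (chemical, age group), route columns.

    MOE columns pair each statistic with its own dose (MOE at the
    95th-percentile total dose is the lower, more protective value).
    """
    rows: dict[tuple[str, str], dict] = {}
    for r in results:
        key = (r.chemical, r.age_group)
        row = rows.setdefault(
            key, {"chemical": r.chemical, "age_group": r.age_group}
        )
        row[f"{r.route}_median"] = r.median
        row[f"{r.route}_p95"] = r.p95
        if r.route == "total":
            row["moe_median"] = r.moe_median
            row["moe_p95"] = r.moe_p95
            row["n_iterations"] = r.n_iterations
            row["seed"] = r.seed
    columns = [
        "chemical", "age_group",
        "ingestion_median", "ingestion_p95",
        "dermal_median", "dermal_p95",
        "total_median", "total_p95",
        "moe_median", "moe_p95",
        "n_iterations", "seed",
    ]
    return pd.DataFrame(
        [rows[k] for k in sorted(rows)], columns=columns
    )
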