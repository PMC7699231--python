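"""Registry of the six plasticizers surveyed in children's products.

Five phthalate esters (DBP, DEHP, DEP, DIBP, DINP) and one adipate
alternative (DEHA) are tracked.  Each entry carries the physicochemical
properties needed by the dermal micro-model (molecular weight, vapor
pressure, water solubility, log Kow), the GC-MS limit of quantitation of
the survey assay, and a toxicological reference dose with its basis.

Skin-permeability pathway components
------------------------------------
The overall stratum-corneum permeability coefficient is a series
combination ``K_p = 1 / (1/(K_lip + K_pol) + 1/K_aq)``.  The three
pathway components are not measured quantities here; they are estimated
from MW and log Kow with the standard EPA-style correlations used by
screening-level consumer-exposure models:

* lipid pathway, Potts & Guy (1992):
  ``K_lip = 10**(-2.80 + 0.66*log_Kow - 0.0056*MW)``  [cm/h]
* polar (aqueous-pore) pathway, EPA dermal guidance constant:
  ``K_pol = 1.5e-5``  [cm/h]
* aqueous boundary layer, Cleek & Bunge (1993):
  ``K_aq = 2.6 / sqrt(MW)``  [cm/h]

All three can be overridden per chemical (``load_registry(overrides=...)``)
so that literature values can be pinned when available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "ChemicalSpec",
    "UnknownChemicalError",
    "CHEMICAL_ABBREVIATIONS",
    "permeability_components",
    "load_registry",
    "registry",
    "get_chemical",
]

#: Canonical (alphabetical) order of the six registered plasticizers.
CHEMICAL_ABBREVIATIONS = ("DBP", "DEHA", "DEHP", "DEP", "DIBP", "DINP")

K_POL_CONSTANT = 1.5e-5  # cm/h, polar-pore pathway


class UnknownChemicalError(KeyError):
    """Raised when an abbreviation is not one of the six registered chemicals."""


@dataclass(frozen=True)
class ChemicalSpec:
    """Identity, properties, LOQ and reference dose of one plasticizer.

    Units: ``mw`` mg/mmol (= g/mol); ``p_vap`` Torr; ``s_w`` mg/mL;
    ``log_kow`` dimensionless (log10); ``k_lip``/``k_pol``/``k_aq`` cm/h;
    ``loq`` mg/kg; ``reference_dose`` mg/kg/d.
    """

    abbreviation: str
    full_name: str
    mw: float
    p_vap: float
    s_w: float
    log_kow: float
    k_lip: float
    k_pol: float
    k_aq: float
    loq: float
    reference_dose: float
    rfd_basis: str

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.abbreviation}: MW must be > 0")
        if self.p_vap < 0:
            raise ValueError(f"{self.abbreviation}: vapor pressure must be >= 0")
        if self.s_w <= 0:
            raise ValueError(f"{self.abbreviation}: water solubility must be > 0")
        for name in ("k_lip", "k_pol", "k_aq", "loq", "reference_dose"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.abbreviation}: {name} must be > 0")


def permeability_components(mw: float, log_kow: float) -> tuple[float, float, float]:
    """Estimate (K_lip, K_pol, K_aq) in cm/h from MW and log Kow.

    Uses the correlations documented in the module docstring.  K_aq is
    strictly decreasing in MW; K_lip is increasing in log Kow.
    """
    if mw <= 0:
        raise ValueError("MW must be > 0")
    k_lip = 10.0 ** (-2.80 + 0.66 * log_kow - 0.0056 * mw)
    k_aq = 2.6 / math.sqrt(mw)
    return k_lip, K_POL_CONSTANT, k_aq


def load_registry(
    path=None,
    overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> dict[str, ChemicalSpec]:
    """Build the chemical registry from the packaged (or a user) CSV.

    ``overrides`` maps abbreviation -> {field: value} and is merged after
    the permeability components are computed, so users can pin literature
    K values or swap property estimates.
    """
    if path is None:
        source = resources.files("plastexpo.data").joinpath("chemicals.csv")
        with resources.as_file(source) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)

    reg: dict[str, ChemicalSpec] = {}
    for row in table.itertuples(index=False):
        k_lip, k_pol, k_aq = permeability_components(row.mw, row.log_kow)
        spec = ChemicalSpec(
            abbreviation=row.abbreviation,
            full_name=row.full_name,
            mw=float(row.mw),
            p_vap=float(row.p_vap),
            s_w=float(row.s_w),
            log_kow=float(row.log_kow),
            k_lip=k_lip,
            k_pol=k_pol,
            k_aq=k_aq,
            loq=float(row.loq),
            reference_dose=float(row.reference_dose),
            rfd_basis=str(row.rfd_basis),
        )
        reg[spec.abbreviation] = spec

    if overrides:
        for abbr, fields in overrides.items():
            key = abbr.upper()
            if key not in reg:
                raise UnknownChemicalError(
                    f"unknown chemical {abbr!r}; valid: {sorted(reg)}"
                )
            reg[key] = replace(reg[key], **dict(fields))

    if set(reg) != set(CHEMICAL_ABBREVIATIONS):
        raise ValueError(
            f"registry must contain exactly {CHEMICAL_ABBREVIATIONS}, got {sorted(reg)}"
        )
    return reg


_REGISTRY: dict[str, ChemicalSpec] | None = None


def registry() -> dict[str, ChemicalSpec]:
    """The default registry, loaded once from the packaged data file."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_registry()
    return _REGISTRY


def get_chemical(abbreviation: str) -> ChemicalSpec:
    """Look up one of the six plasticizers (case-insensitive)."""
    key = str(abbreviation).upper()
    reg = registry()
    if key not in reg:
        raise UnknownChemicalError(
            f"unknown chemical {abbreviation!r}; "
            f"valid abbreviations: {', '.join(CHEMICAL_ABBREVIATIONS)}"
        )
    return reg[key]
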