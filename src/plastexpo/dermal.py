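"""Dermal absorption micro-model and daily dermal dose.

The dose from skin contact with a plasticized article is

    dose = C_art * (SA/BW) * l * FA * ED/AT        [mg/kg/d]

where ``C_art`` is the chemical concentration in the article (mg/cm3),
``l`` the average distance a diffusing molecule travels during one
contact (cm), and ``FA`` the fraction of the chemical loaded onto the
skin that is absorbed rather than evaporating.  The intermediates are

    l     = 2 * sqrt(D * Dur/60)            (m, converted to cm)
    t_lag = h_sc / (6 * 10**(-2.8 - 0.0056*MW))
    K_p   = 1 / ( 1/(K_lip + K_pol) + 1/K_aq )
    chi   = h * p_vap * MW / (K_p * S_w * R * T)
    FA    = (3 + chi*(1 - exp(-a*(Dur/60)/t_lag))) / (3*(1 + chi))

Unit conventions, chosen so every ratio is dimensionless:

* ``D`` is in m2/h and ``Dur`` in min, so ``D*Dur/60`` is m2 and ``l``
  is converted m -> cm (x100).  The linear literal form ``2*D*Dur/60``
  is dimensionally inconsistent and kept only behind the
  ``literal=True`` audit switch of :func:`diffusion_distance`.
* ``h`` (gas-phase mass transfer, m/h) is converted to cm/h (x100)
  before dividing by ``K_p`` (cm/h) in ``chi``.
* The exponent uses ``Dur`` in hours (``Dur/60``) because ``t_lag`` is
  in hours.

The packaged default factor set is *calibrated*: the solid-phase
diffusion coefficient ``D`` is solved so that DEHP at the 0.01% w/w
inclusion-threshold content yields a dermal dose of 8.6e-6 mg/kg/d,
the screening anchor of the deterministic assessment.  Every component
remains user-settable; ``scripts/calibrate.py`` reruns and prints the
calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .chemistry import ChemicalSpec, get_chemical

__all__ = [
    "R_GAS",
    "DERMAL_ANCHOR_DOSE",
    "ANCHOR_CONTENT_FRACTION",
    "ExposureFactorSet",
    "DermalIntermediates",
    "diffusion_distance",
    "lag_time",
    "permeability",
    "volatility_ratio",
    "fraction_absorbed",
    "dermal_intermediates",
    "dermal_daily_dose",
    "content_to_cart",
    "calibrate_diffusion",
    "default_factors",
    "get_preset",
    "FACTOR_PRESETS",
]

#: Real gas constant in mL Torr / (K mmol).
R_GAS = 62.37

#: Dermal screening anchor: DEHP daily dermal dose at the inclusion
#: threshold content (mg/kg/d), used to calibrate the default factors.
DERMAL_ANCHOR_DOSE = 8.6e-6

#: Inclusion-threshold content as a mass fraction (0.01% w/w = 100 mg/kg).
ANCHOR_CONTENT_FRACTION = 1e-4


@dataclass(frozen=True)
class ExposureFactorSet:
    """All non-chemical parameters of the ingestion and dermal dose equations.

    Units: ``ca`` cm2 (mouthing contact area); ``d_mouthing`` min/h;
    ``ed``/``at`` d; ``bw`` kg; ``sa_over_bw`` cm2/kg (hand skin);
    ``dur`` min (daily article contact); ``d`` m2/h (solid-phase
    diffusion); ``t`` K; ``h`` m/h (gas-phase mass transfer); ``a``
    dimensionless; ``h_sc`` cm (stratum corneum thickness, default
    15 um); ``rho_article`` g/cm3 (article density for % w/w -> mg/cm3).
    """

    ca: float
    d_mouthing: float
    ed: float
    at: float
    bw: float
    sa_over_bw: float
    dur: float
    d: float
    t: float
    h: float
    a: float = 1.0
    h_sc: float = 1.5e-3
    rho_article: float = 1.2

    def __post_init__(self) -> None:
        positive = (
            "ca", "d_mouthing", "ed", "at", "bw", "sa_over_bw",
            "dur", "d", "t", "h", "h_sc", "rho_article",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"factor {name} must be > 0")
        if self.a < 0:
            raise ValueError("factor a must be >= 0")
        if self.ed > self.at:
            raise ValueError("exposure duration ED must not exceed averaging time AT")


@dataclass(frozen=True)
class DermalIntermediates:
    """Computed dermal quantities: l (cm), t_lag (h), K_p (cm/h), chi, FA."""

    l: float
    t_lag: float
    k_p: float
    chi: float
    fa: float

    def __post_init__(self) -> None:
        if self.l < 0 or self.t_lag <= 0 or self.k_p <= 0 or self.chi < 0:
            raise ValueError("invalid dermal intermediates")
        if not (0.0 < self.fa <= 1.0):
            raise ValueError(f"FA must be in (0, 1], got {self.fa}")


def diffusion_distance(d: float, dur: float, *, literal: bool = False) -> float:
    """Average diffusion distance per contact, in cm.

    ``d`` in m2/h, ``dur`` in min.  Default is the diffusion-length
    reading ``2*sqrt(D*Dur/60)`` (metres, converted to cm).  The
    ``literal`` switch evaluates the linear form ``2*D*Dur/60`` instead
    (and still multiplies by 100), for auditing only: that form is not
    dimensionally a length.
    """
    if d < 0 or dur < 0:
        raise ValueError("D and Dur must be >= 0")
    if literal:
        return 2.0 * d * dur / 60.0 * 100.0
    return 2.0 * math.sqrt(d * dur / 60.0) * 100.0


def lag_time(mw: float, h_sc: float) -> float:
    """Stratum-corneum lag time in hours.

    ``t_lag = h_sc / (6 * 10**(-2.8 - 0.0056*MW))`` with ``h_sc`` in cm;
    the denominator has units cm/h.
    """
    if mw <= 0 or h_sc <= 0:
        raise ValueError("MW and h_sc must be > 0")
    return h_sc / (6.0 * 10.0 ** (-2.8 - 0.0056 * mw))


def permeability(k_lip: float, k_pol: float, k_aq: float) -> float:
    """Overall permeability K_p (cm/h): lipid+polar in parallel, aqueous in series."""
    if k_lip <= 0 or k_pol <= 0 or k_aq <= 0:
        raise ValueError("permeability components must be > 0")
    return 1.0 / (1.0 / (k_lip + k_pol) + 1.0 / k_aq)


def volatility_ratio(
    h: float, p_vap: float, mw: float, k_p: float, s_w: float, t: float
) -> float:
    """Evaporation-to-absorption ratio chi (dimensionless).

    ``chi = (h * p_vap * MW) / (K_p * S_w * R * T)`` with ``h`` given in
    m/h and converted to cm/h to match ``K_p``.
    """
    if p_vap < 0:
        raise ValueError("vapor pressure must be >= 0")
    if h <= 0 or mw <= 0 or k_p <= 0 or s_w <= 0 or t <= 0:
        raise ValueError("h, MW, K_p, S_w and T must be > 0")
    h_cm = h * 100.0
    return (h_cm * p_vap * mw) / (k_p * s_w * R_GAS * t)


def fraction_absorbed(chi: float, dur: float, t_lag: float, a: float) -> float:
    """Fraction of the skin load absorbed rather than evaporated.

    ``FA = (3 + chi*(1 - exp(-a*(Dur/60)/t_lag))) / (3*(1 + chi))``;
    ``dur`` in min is converted to hours so the exponent is
    dimensionless.  FA is in (0, 1], equals 1 for a non-volatile
    chemical (chi = 0), and tends to 1/3 for chi -> inf with long
    contact.
    """
    if t_lag <= 0:
        raise ValueError("t_lag must be > 0")
    if chi < 0 or dur < 0 or a < 0:
        raise ValueError("chi, Dur and a must be >= 0")
    dur_h = dur / 60.0
    return (3.0 + chi * (1.0 - math.exp(-a * dur_h / t_lag))) / (3.0 * (1.0 + chi))


def dermal_intermediates(
    chem: ChemicalSpec, factors: ExposureFactorSet
) -> DermalIntermediates:
    """Evaluate l, t_lag, K_p, chi and FA for one chemical and factor set."""
    l = diffusion_distance(factors.d, factors.dur)
    t_lag = lag_time(chem.mw, factors.h_sc)
    k_p = permeability(chem.k_lip, chem.k_pol, chem.k_aq)
    chi = volatility_ratio(factors.h, chem.p_vap, chem.mw, k_p, chem.s_w, factors.t)
    fa = fraction_absorbed(chi, factors.dur, t_lag, factors.a)
    return DermalIntermediates(l, t_lag, k_p, chi, fa)


def dermal_daily_dose(
    c_art: float,
    factors: ExposureFactorSet,
    intermediates: DermalIntermediates,
) -> float:
    """Daily dermal dose in mg/kg/d; strictly linear in ``c_art`` (mg/cm3)."""
    if c_art < 0:
        raise ValueError("C_art must be >= 0")
    return (
        c_art
        * factors.sa_over_bw
        * intermediates.l
        * intermediates.fa
        * factors.ed
        / factors.at
    )


def content_to_cart(content_fraction: float, rho_article: float) -> float:
    """Convert a mass fraction (w/w) to article concentration in mg/cm3."""
    if content_fraction < 0:
        raise ValueError("content must be >= 0")
    return content_fraction * rho_article * 1000.0


def calibrate_diffusion(
    factors: ExposureFactorSet,
    chem: ChemicalSpec | None = None,
    anchor_dose: float = DERMAL_ANCHOR_DOSE,
    content: float = ANCHOR_CONTENT_FRACTION,
) -> ExposureFactorSet:
    """Solve the diffusion coefficient so the anchor dose is reproduced.

    Finds D such that the dermal dose of ``chem`` (default DEHP) at the
    given content equals ``anchor_dose`` with all other factors fixed.
    FA and t_lag do not depend on D, so the solution is closed-form:
    ``l = dose / (C_art * SA/BW * FA * ED/AT)`` and
    ``D = (l/100/2)**2 / (Dur/60)``.
    """
    if chem is None:
        chem = get_chemical("DEHP")
    t_lag = lag_time(chem.mw, factors.h_sc)
    k_p = permeability(chem.k_lip, chem.k_pol, chem.k_aq)
    chi = volatility_ratio(factors.h, chem.p_vap, chem.mw, k_p, chem.s_w, factors.t)
    fa = fraction_absorbed(chi, factors.dur, t_lag, factors.a)
    c_art = content_to_cart(content, factors.rho_article)
    l_needed = anchor_dose / (c_art * factors.sa_over_bw * fa * factors.ed / factors.at)
    d = (l_needed / 100.0 / 2.0) ** 2 / (factors.dur / 60.0)
    return replace(factors, d=d)


# --- packaged presets --------------------------------------------------

def _base_preset(bw: float, sa_hand: float) -> ExposureFactorSet:
    # D and d_mouthing are placeholders here; both are replaced by the
    # anchor calibrations (see calibrate_diffusion and
    # ingestion.calibrate_mouthing).
    return ExposureFactorSet(
        ca=10.0,            # cm2, mouthed surface of a small article
        d_mouthing=4.5,     # min/h, calibrated by ingestion anchor
        ed=365.0,
        at=365.0,
        bw=bw,
        sa_over_bw=sa_hand / bw,
        dur=60.0,           # min/d of article contact
        d=1e-15,            # m2/h, replaced by calibration
        t=298.0,
        h=6.0,              # m/h, indoor gas-phase mass transfer
    )


def default_factors(preset: str = "default-child") -> ExposureFactorSet:
    """Return a named, anchor-calibrated factor preset.

    Presets: ``default-child`` (15 kg, 375 cm2 hand skin),
    ``default-child-0-2`` (11 kg, 300 cm2) and ``default-child-3-12``
    (25 kg, 450 cm2).  Each is calibrated so that (a) DEHP at 0.01% w/w
    gives the 8.6e-6 mg/kg/d dermal anchor and (b) the high-migration
    ingestion scenario gives 5.0e-1 mg/kg/d (see :mod:`.ingestion`).
    """
    from .ingestion import calibrate_mouthing  # local import to avoid a cycle

    try:
        bw, sa = FACTOR_PRESETS[preset]
    except KeyError:
        raise KeyError(
            f"unknown preset {preset!r}; valid: {sorted(FACTOR_PRESETS)}"
        ) from None
    factors = _base_preset(bw, sa)
    factors = calibrate_diffusion(factors)
    factors = calibrate_mouthing(factors)
    return factors


#: preset name -> (body weight kg, hand skin area cm2)
FACTOR_PRESETS = {
    "default-child": (15.0, 375.0),
    "default-child-0-2": (11.0, 300.0),
    "default-child-3-12": (25.0, 450.0),
}


def get_preset(name: str) -> ExposureFactorSet:
    """Alias of :func:`default_factors` for CLI use."""
    return default_factors(name)
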