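"""Mouthing-ingestion dose and content-based migration-rate assignment.

The ingestion dose during mouthing of a plasticized article is

    dose = MR * CA * mouth_hours_per_day * ED / (BW * AT)   [mg/kg/d]

with ``MR`` the migration rate from article to saliva (mg/cm2/h) and
``CA`` the mouthed contact area (cm2).  The printed form of the
equation mixes time units (MR per hour, mouthing duration in min/h,
dose per day); here the mouthing factor is made explicit as

    mouth_hours_per_day = (D_mouthing / 60) * (Dur / 60)

i.e. minutes of mouthing per hour of article use, times hours of use
per day (``Dur`` doubles as the daily contact duration used by the
dermal model).  The packaged child defaults are jointly calibrated so
that the high-migration scenario (MR = 10 mg/cm2/h) yields exactly
5.0e-1 mg/kg/d, the screening-level output anchor; see
:func:`calibrate_mouthing` and ``scripts/calibrate.py``.

Migration rates are not measured but assigned from the chemical content
of the article.  The default two-level policy is 10 mg/cm2/h at or
above 1% w/w and 0.1 mg/cm2/h below; the four-level CEM-style policy
(10, 0.1, 1e-3, 1e-4) is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .dermal import ExposureFactorSet

__all__ = [
    "MigrationRatePolicy",
    "TWO_LEVEL_POLICY",
    "FOUR_LEVEL_POLICY",
    "assign_migration_rate",
    "ingestion_daily_dose",
    "calibrate_mouthing",
    "INGESTION_ANCHOR_DOSE",
    "INGESTION_ANCHOR_MR",
]

#: High-migration ingestion dose anchor (mg/kg/d) used to calibrate the
#: packaged mouthing factors.
INGESTION_ANCHOR_DOSE = 0.5
INGESTION_ANCHOR_MR = 10.0


@dataclass(frozen=True)
class MigrationRatePolicy:
    """Piecewise-constant map from content fraction (w/w) to MR (mg/cm2/h).

    ``thresholds`` are content lower bounds in decreasing order and
    ``rates`` the MR assigned at or above each; contents below the last
    threshold get ``fallback_rate``.
    """

    mode: str
    thresholds: Sequence[float]
    rates: Sequence[float]
    fallback_rate: float

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.rates):
            raise ValueError("thresholds and rates must have equal length")
        if any(r <= 0 for r in (*self.rates, self.fallback_rate)):
            raise ValueError("migration rates must be > 0")
        thr, rates = list(self.thresholds), list(self.rates)
        if thr != sorted(thr, reverse=True) or len(set(thr)) != len(thr):
            raise ValueError("thresholds must be strictly decreasing")
        if rates != sorted(rates, reverse=True) or len(set(rates)) != len(rates):
            raise ValueError("rates must be strictly decreasing")
        if list(self.rates) and self.fallback_rate >= min(self.rates):
            raise ValueError("fallback rate must be below all class rates")


#: Content >= 1% w/w -> 10 mg/cm2/h, below -> 0.1 (the screening default).
TWO_LEVEL_POLICY = MigrationRatePolicy("two_level", (0.01,), (10.0,), 0.1)

#: Four discrete CEM levels.  The two upper classes match the two-level
#: policy; the lower class bounds (0.1% and 0.01% w/w) are a package
#: convention, chosen decade-wise since the source model does not print
#: them.
FOUR_LEVEL_POLICY = MigrationRatePolicy(
    "four_level", (0.01, 0.001, 0.0001), (10.0, 0.1, 1e-3), 1e-4
)


def assign_migration_rate(
    content: float, policy: MigrationRatePolicy = TWO_LEVEL_POLICY
) -> float:
    """Migration rate (mg/cm2/h) for a content given as a mass fraction.

    Boundary convention: a content exactly at a class threshold takes
    the higher rate (content >= 1% w/w -> 10 mg/cm2/h).
    """
    if not 0.0 <= content <= 1.0:
        raise ValueError(f"content must be a fraction in [0, 1], got {content}")
    for thr, rate in zip(policy.thresholds, policy.rates):
        if content >= thr:
            return rate
    return policy.fallback_rate


def ingestion_daily_dose(mr: float, factors: ExposureFactorSet) -> float:
    """Daily ingestion dose in mg/kg/d; strictly linear in ``mr``."""
    if mr < 0:
        raise ValueError("MR must be >= 0")
    mouth_hours = (factors.d_mouthing / 60.0) * (factors.dur / 60.0)
    return mr * factors.ca * mouth_hours * factors.ed / (factors.bw * factors.at)


def calibrate_mouthing(
    factors: ExposureFactorSet,
    anchor_dose: float = INGESTION_ANCHOR_DOSE,
    anchor_mr: float = INGESTION_ANCHOR_MR,
) -> ExposureFactorSet:
    """Solve D_mouthing so the high-migration scenario hits the anchor dose.

    The dose is linear in D_mouthing, so the solution is closed-form.
    """
    base = replace(factors, d_mouthing=60.0)
    dose_at_unit = ingestion_daily_dose(anchor_mr, base)  # dose with 1 h/h mouthing
    return replace(factors, d_mouthing=60.0 * anchor_dose / dose_at_unit)
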