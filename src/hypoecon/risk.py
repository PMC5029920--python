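"""Annual hypoglycemia incidence rates by medication class and cohort.

The mild-event rate is a validated multiplicative risk equation: a
medication-class base rate (events/person-year) scaled by four covariate
multipliers — diabetes duration, HbA1c, body mass index and glomerular
filtration rate — each a power function of the covariate clamped to the
range over which the source model was fitted. Moderate and severe events
are added on top of the mild rate so that the severity distribution of all
events is 95% mild / 4% moderate / 1% severe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import (
    CohortProfile,
    DrugStrategy,
    RiskEquationConstants,
    SeverityModel,
)

__all__ = [
    "RateResult",
    "risk_duration",
    "risk_hba1c",
    "risk_bmi",
    "risk_gfr",
    "mild_rate",
    "severity_split",
    "rates_for",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of the source tables)."""
    scale = 10.0**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class RateResult:
    """Annual event rates (events/person-year) for one strategy x cohort."""

    mild: float
    moderate: float
    severe: float

    @property
    def moderate_severe(self) -> float:
        return self.moderate + self.severe

    @property
    def total(self) -> float:
        return self.mild + self.moderate + self.severe

    def scaled(self, factor: float) -> "RateResult":
        return RateResult(
            self.mild * factor, self.moderate * factor, self.severe * factor
        )


def _clamp(x: float, lo: float, hi: float) -> float:
    return min(max(x, lo), hi)


def risk_duration(duration: float, constants: RiskEquationConstants) -> float:
    """Duration multiplier: base^(min(duration, cap) - offset)."""
    if duration <= 0:
        raise ValueError("diabetes duration must be positive")
    exponent = min(duration, constants.duration_cap) - constants.duration_offset
    return constants.duration_base**exponent


def risk_hba1c(hba1c: float, constants: RiskEquationConstants) -> float:
    """HbA1c multiplier: base^(hba1c - ref); tighter control raises risk."""
    return constants.a1c_base ** (hba1c - constants.a1c_ref)


def risk_bmi(bmi: float, constants: RiskEquationConstants) -> float:
    """BMI multiplier: base^(clamp(bmi, floor, cap) - ref); leaner is riskier."""
    clamped = _clamp(bmi, constants.bmi_floor, constants.bmi_cap)
    return constants.bmi_base ** (clamped - constants.bmi_ref)


def risk_gfr(gfr: float, constants: RiskEquationConstants) -> float:
    """Renal-function multiplier.

    ``scale^(clamp(gfr, floor, ref)^exponent - ref^exponent)``: equal to 1 at
    or above the reference filtration rate and rising as kidney function
    declines, flattening below the floor. With ``gfr_legacy_divisor`` set,
    the result is additionally divided by 1.2 (an alternative reading of the
    source formula, retained for auditability; not the default because it
    cannot reproduce the published rate table).
    """
    if gfr <= 0:
        raise ValueError("glomerular filtration rate must be positive")
    clamped = _clamp(gfr, constants.gfr_floor, constants.gfr_ref)
    exponent = clamped**constants.gfr_exponent - constants.gfr_ref**constants.gfr_exponent
    value = constants.gfr_scale**exponent
    if constants.gfr_legacy_divisor:
        value /= 1.2
    return value


def mild_rate(
    strategy: DrugStrategy,
    cohort: CohortProfile,
    constants: RiskEquationConstants,
) -> float:
    """Annual mild-hypoglycemia rate for one strategy and cohort profile."""
    return (
        strategy.base_rate
        * risk_duration(cohort.diabetes_duration, constants)
        * risk_hba1c(cohort.hba1c, constants)
        * risk_bmi(cohort.bmi, constants)
        * risk_gfr(cohort.gfr, constants)
    )


def severity_split(mild: float, severity: SeverityModel) -> RateResult:
    """Add moderate and severe events on top of a mild rate.

    The mild rate is taken as the p_mild share of all events, so the total
    rate is ``mild / p_mild`` and moderate/severe subdivide the remainder in
    the ratio ``p_moderate : p_severe``.
    """
    if mild < 0:
        raise ValueError("mild rate must be non-negative")
    if severity.p_mild == 0:
        raise ValueError("severity.p_mild must be positive for the split")
    total = mild / severity.p_mild
    return RateResult(
        mild=mild,
        moderate=total * severity.p_moderate,
        severe=total * severity.p_severe,
    )


def rates_for(
    strategy: DrugStrategy,
    cohort: CohortProfile,
    constants: RiskEquationConstants,
    severity: SeverityModel,
) -> RateResult:
    """Full per-severity annual rates for one strategy x cohort."""
    return severity_split(mild_rate(strategy, cohort, constants), severity)
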