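"""Model inputs as validated domain types.

Every quantity the decision model consumes lives here: cohort clinical
profiles, drug strategies, the constants of the mild-hypoglycemia risk
equation, the event severity split, healthcare resource-use probabilities,
unit costs, utilities, and economic settings. A :class:`ParameterBundle`
groups one complete, internally consistent set for a single country and
currency, and can be round-tripped through YAML configuration files.

Packaged defaults for the United States (2015 US$) and Canada (2015 CAN$)
ship under ``hypoecon/data/``.
"""

from __future__ import annotations

import copy
import warnings
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "CohortProfile",
    "DrugStrategy",
    "RiskEquationConstants",
    "SeverityModel",
    "SevereBranchProbabilities",
    "ResourceUseModel",
    "UnitCostTable",
    "DisutilityTable",
    "UtilityModel",
    "EconomicSettings",
    "ParameterBundle",
    "ParameterValidationError",
    "load_parameters",
    "save_parameters",
    "default_parameters",
    "available_countries",
    "STRATEGY_NAMES",
    "COHORT_LABELS",
]

SCHEMA_VERSION = "hypoecon-parameters-1"

STRATEGY_NAMES = (
    "metformin",
    "sulfonylurea",
    "dpp4",
    "tzd",
    "glp1",
    "basal_insulin",
)

COHORT_LABELS = ("65-79", "80plus")

_PROB_SUM_TOL = 1e-9


class ParameterValidationError(ValueError):
    """A parameter file or bundle violates a model invariant."""


class _Base(BaseModel):
    model_config = {"extra": "ignore"}


class CohortProfile(_Base):
    """Age-group average clinical profile feeding the risk equation.

    The incidence model predicts the annual rate of mild hypoglycemia from
    four clinical averages: diabetes duration (years), glycated hemoglobin
    (HbA1c, %), body mass index (kg/m2) and glomerular filtration rate
    (ml/min).
    """

    label: str
    diabetes_duration: float = Field(gt=0, description="years since diagnosis")
    hba1c: float = Field(ge=4.0, le=20.0, description="glycated hemoglobin, %")
    bmi: float = Field(ge=10.0, le=70.0, description="body mass index, kg/m2")
    gfr: float = Field(gt=0, description="glomerular filtration rate, ml/min")


class DrugStrategy(_Base):
    """One glucose-lowering medication class and its therapy profile."""

    name: str
    base_rate: float = Field(
        gt=0, description="base mild-hypoglycemia rate, events/person-year"
    )
    daily_smbg_tests: float = Field(ge=0, description="SMBG tests per day")
    daily_injections: float = Field(ge=0, description="injections per day")
    annual_drug_cost: float = Field(
        ge=0, description="annual acquisition cost incl. dispensing fees"
    )

    @model_validator(mode="after")
    def _known_name(self) -> "DrugStrategy":
        if self.name not in STRATEGY_NAMES:
            raise ValueError(
                f"strategies.{self.name}: unknown strategy name "
                f"(expected one of {STRATEGY_NAMES})"
            )
        return self


class RiskEquationConstants(_Base):
    """Constants of the four multiplicative risk-factor formulas.

    The mild-event rate is the medication-class base rate times four
    multipliers, each a power function of one clinical covariate clamped to
    the range over which the source prediction model was fitted.

    ``gfr_legacy_divisor`` enables an alternative, non-default reading of the
    renal-function formula in which the multiplier is divided by 1.2; it is
    retained for auditability only (see the methods note).
    """

    duration_base: float = Field(default=1.037, gt=0)
    duration_cap: float = 20.0
    duration_offset: float = 9.0
    a1c_base: float = Field(default=0.82, gt=0)
    a1c_ref: float = 7.0
    bmi_base: float = Field(default=0.95, gt=0)
    bmi_floor: float = 21.0
    bmi_cap: float = 35.0
    bmi_ref: float = 33.0
    gfr_scale: float = Field(default=22700.0, gt=0)
    gfr_exponent: float = -0.86655
    gfr_floor: float = 15.0
    gfr_ref: float = 60.0
    gfr_legacy_divisor: bool = False

    @model_validator(mode="after")
    def _floors_below_caps(self) -> "RiskEquationConstants":
        if not self.bmi_floor < self.bmi_cap:
            raise ValueError("risk_constants.bmi_floor must be below bmi_cap")
        if not self.gfr_floor < self.gfr_ref:
            raise ValueError("risk_constants.gfr_floor must be below gfr_ref")
        return self


class SeverityModel(_Base):
    """Severity distribution of hypoglycemic events.

    Mild: resolved without help. Moderate: non-medical third-party help.
    Severe: medical assistance required. The three proportions must sum to 1;
    the default split is 95/4/1.
    """

    p_mild: float = Field(default=0.95, ge=0, le=1)
    p_moderate: float = Field(default=0.04, ge=0, le=1)
    p_severe: float = Field(default=0.01, ge=0, le=1)

    @model_validator(mode="after")
    def _sums_to_one(self) -> "SeverityModel":
        total = self.p_mild + self.p_moderate + self.p_severe
        if abs(total - 1.0) > _PROB_SUM_TOL:
            raise ValueError(
                f"severity: p_mild + p_moderate + p_severe = {total!r}, expected 1"
            )
        return self

    @property
    def p_moderate_severe(self) -> float:
        return self.p_moderate + self.p_severe


class SevereBranchProbabilities(_Base):
    """Care-setting distribution for a severe event (must sum to 1)."""

    gp: float = Field(default=0.26, ge=0, le=1)
    np: float = Field(default=0.13, ge=0, le=1)
    outpatient: float = Field(default=0.20, ge=0, le=1)
    er_only: float = Field(default=0.17, ge=0, le=1)
    hospitalization: float = Field(default=0.24, ge=0, le=1)

    @model_validator(mode="after")
    def _sums_to_one(self) -> "SevereBranchProbabilities":
        total = self.gp + self.np + self.outpatient + self.er_only + self.hospitalization
        if abs(total - 1.0) > _PROB_SUM_TOL:
            raise ValueError(
                f"resource_use.severe_branch: probabilities sum to {total!r}, expected 1"
            )
        return self

    def as_dict(self) -> dict[str, float]:
        return {
            "gp": self.gp,
            "np": self.np,
            "outpatient": self.outpatient,
            "er_only": self.er_only,
            "hospitalization": self.hospitalization,
        }


class ResourceUseModel(_Base):
    """Probabilities and counts of healthcare resource use after events.

    After any event (whatever its severity) a fraction of patients contact a
    healthcare professional (with one quantitative glucose assay per contact)
    and use extra self-monitoring tests. Moderate events may trigger a
    glucagon injection. Severe events fan out over five care settings; the
    transported pathways (emergency room, hospitalization) additionally incur
    ambulance use and EMS-administered glucagon. A fifth of hospitalized
    patients die within the year.
    """

    p_hcp_contact_any_event: float = Field(default=0.14, ge=0, le=1)
    p_assay_per_contact: float = Field(default=1.0, ge=0, le=1)
    n_extra_smbg_after_event: float = Field(default=3.9, ge=0)
    p_glucagon_moderate: float = Field(default=0.02, ge=0, le=1)
    severe_branch: SevereBranchProbabilities = Field(
        default_factory=SevereBranchProbabilities
    )
    p_glucagon_severe: float = Field(default=0.25, ge=0, le=1)
    p_ambulance_severe_transport: float = Field(default=1.0, ge=0, le=1)
    p_death_given_hospitalization: float = Field(default=0.20, ge=0, le=1)


class UnitCostTable(_Base):
    """Unit costs of healthcare resources and therapy supplies.

    All values are in the bundle's currency (2015 US$ or 2015 CAN$) and are
    never converted implicitly.
    """

    country: str
    currency: str
    gp_visit: float = Field(ge=0)
    np_visit: float = Field(ge=0)
    outpatient_visit: float = Field(ge=0)
    er_visit: float = Field(ge=0)
    hospitalization: float = Field(ge=0)
    ambulance: float = Field(ge=0)
    glucagon_kit: float = Field(ge=0)
    blood_glucose_assay: float = Field(ge=0)
    smbg_strip: float = Field(ge=0)
    smbg_lancet: float = Field(ge=0)
    needle: float = Field(ge=0)
    home_monitor_annual: float = Field(ge=0)


class DisutilityTable(_Base):
    """Per-event QALY decrements by severity class and time of day."""

    mild_daytime: float = Field(ge=0)
    mild_nocturnal: float = Field(ge=0)
    moderate_severe_daytime: float = Field(ge=0)
    moderate_severe_nocturnal: float = Field(ge=0)

    def get(self, severity_class: str, time: str) -> float:
        key = f"{severity_class}_{time}"
        try:
            return getattr(self, key)
        except AttributeError:  # pragma: no cover - guarded by callers
            raise KeyError(key) from None


class UtilityModel(_Base):
    """Health-state utilities for the QALY calculation.

    ``u_base`` is the annual utility of uncomplicated type 2 diabetes.
    Each hypoglycemic event subtracts a per-event disutility that depends on
    its severity class (mild vs moderate/severe) and whether it occurs during
    the day or at night; the daytime proportions are 75% for mild and 60% for
    moderate/severe events. A fatal event forfeits a configurable fraction of
    the year's base utility (default: half a year).
    """

    u_base: float = Field(default=0.844, ge=0, le=1)
    disutility_per_event: DisutilityTable
    p_daytime_mild: float = Field(default=0.75, ge=0, le=1)
    p_daytime_modsev: float = Field(default=0.60, ge=0, le=1)
    fatal_event_year_fraction_lost: float = Field(default=0.5, ge=0, le=1)

    def effective_disutility(self, severity_class: str) -> float:
        """Day/night-weighted expected disutility per event of a class."""
        p_day = (
            self.p_daytime_mild
            if severity_class == "mild"
            else self.p_daytime_modsev
        )
        d = self.disutility_per_event
        return p_day * d.get(severity_class, "daytime") + (1.0 - p_day) * d.get(
            severity_class, "nocturnal"
        )


class EconomicSettings(_Base):
    """Willingness-to-pay threshold and horizon conventions.

    The threshold is the national per-capita gross domestic product
    (US$54,630; CAN$53,891, converted from US$50,271 at 1.0720). The model is
    annual: a one-year horizon with no discounting.
    """

    wtp_threshold: float = Field(gt=0, description="currency per QALY")
    exchange_rate_us_to_can: float = Field(default=1.0720, gt=0)
    time_horizon: float = 1.0
    discount_rate: float = 0.0

    @model_validator(mode="after")
    def _annual_model(self) -> "EconomicSettings":
        if self.time_horizon != 1.0:
            raise ValueError("settings.time_horizon must be 1 (annual model)")
        return self


class ParameterBundle(_Base):
    """One complete, validated parameter set for a single country."""

    schema_version: str = SCHEMA_VERSION
    country: str
    currency: str
    cohorts: dict[str, CohortProfile]
    strategies: dict[str, DrugStrategy]
    risk_constants: RiskEquationConstants = Field(
        default_factory=RiskEquationConstants
    )
    severity: SeverityModel = Field(default_factory=SeverityModel)
    resource_use: ResourceUseModel = Field(default_factory=ResourceUseModel)
    unit_costs: UnitCostTable
    utilities: UtilityModel
    settings: EconomicSettings

    @model_validator(mode="after")
    def _consistent(self) -> "ParameterBundle":
        for label, cohort in self.cohorts.items():
            if cohort.label != label:
                raise ValueError(
                    f"cohorts.{label}: label field {cohort.label!r} does not match key"
                )
        for name, strategy in self.strategies.items():
            if strategy.name != name:
                raise ValueError(
                    f"strategies.{name}: name field {strategy.name!r} does not match key"
                )
        if self.unit_costs.country != self.country:
            raise ValueError(
                "unit_costs.country does not match the bundle country"
            )
        if self.unit_costs.currency != self.currency:
            raise ValueError(
                "unit_costs.currency does not match the bundle currency"
            )
        return self

    def copy_deep(self) -> "ParameterBundle":
        """Deep copy for perturbation in sensitivity analyses."""
        return self.model_copy(deep=True)


# ---------------------------------------------------------------------------
# Config I/O


def _collect_unknown_keys(
    data: Mapping, model: type[BaseModel], prefix: str = ""
) -> list[str]:
    unknown: list[str] = []
    fields = model.model_fields
    for key, value in data.items():
        path = f"{prefix}{key}"
        if key not in fields:
            unknown.append(path)
            continue
        ann = fields[key].annotation
        if isinstance(value, Mapping):
            if isinstance(ann, type) and issubclass(ann, BaseModel):
                unknown.extend(_collect_unknown_keys(value, ann, path + "."))
            elif getattr(ann, "__origin__", None) is dict:
                sub = ann.__args__[1]
                if isinstance(sub, type) and issubclass(sub, BaseModel):
                    for k2, v2 in value.items():
                        if isinstance(v2, Mapping):
                            unknown.extend(
                                _collect_unknown_keys(v2, sub, f"{path}.{k2}.")
                            )
    return unknown


def load_parameters(path: str | Path) -> ParameterBundle:
    """Load and validate a parameter bundle from a YAML config file.

    Unknown keys are dropped with a warning listing their paths; any value
    violating a type invariant raises :class:`ParameterValidationError`
    naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ParameterValidationError(f"{path}: config root must be a mapping")
    return parameters_from_dict(data)


def parameters_from_dict(data: Mapping) -> ParameterBundle:
    """Validate a raw mapping into a :class:`ParameterBundle`."""
    unknown = _collect_unknown_keys(data, ParameterBundle)
    if unknown:
        warnings.warn(
            "ignoring unknown config keys: " + ", ".join(sorted(unknown)),
            stacklevel=2,
        )
    try:
        return ParameterBundle.model_validate(data)
    except Exception as exc:  # pydantic ValidationError
        raise ParameterValidationError(str(exc)) from exc


def save_parameters(bundle: ParameterBundle, path: str | Path) -> None:
    """Write a bundle back to YAML (round-trips with :func:`load_parameters`)."""
    path = Path(path)
    payload = bundle.model_dump(mode="json")
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


_COUNTRY_FILES = {"US": "us_2015.yaml", "Canada": "canada_2015.yaml"}


def available_countries() -> tuple[str, ...]:
    return tuple(_COUNTRY_FILES)


def default_parameters(country: str) -> ParameterBundle:
    """Packaged default bundle for ``country`` ("US" or "Canada").

    Probabilities, incidence-rate inputs and utilities carry the published
    base-case values; unit costs and per-event disutilities are synthetic
    defaults calibrated to the published per-person outcomes (see the
    packaged YAML files and the methods note) and are meant to be overridden
    with payer fee-schedule values where available.
    """
    try:
        fname = _COUNTRY_FILES[country]
    except KeyError:
        raise ValueError(
            f"unknown country {country!r}; expected one of {tuple(_COUNTRY_FILES)}"
        ) from None
    ref = resources.files("hypoecon.data").joinpath(fname)
    with resources.as_file(ref) as p:
        return load_parameters(p)
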