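"""Patient-level Monte-Carlo simulation of annual event histories.

Realizes the decision tree as random draws — annual event counts are
Poisson with the analytic per-severity rates, severities and severe-event
care settings are categorical, resource use is Bernoulli, and death is a
Bernoulli thinning of hospitalizations — so every closed-form expectation
in :mod:`hypoecon.tree` has a brute-force empirical counterpart. This
doubles as the package's synthetic-data generator for end-to-end tests and
demos.

Two code paths share one parameterization: a vectorized path returning
per-patient aggregate arrays (suitable for hundreds of thousands of
patient-years), and a record-keeping path (``keep_events=True``) that
builds explicit :class:`PatientYear` event histories for small cohorts.
Death ends QALY accrual at a uniformly distributed time in the remaining
year, matching the analytic half-year expected loss; event and cost streams
are not truncated by death, mirroring the analytic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .params import ParameterBundle
from .risk import rates_for
from .tree import (
    StrategyOutcome,
    annual_therapy_cost,
    evaluate_strategy,
)

__all__ = [
    "EventRecord",
    "PatientYear",
    "SimulatedCohort",
    "simulate_cohort",
    "empirical_summary",
    "to_dataframe",
]


@dataclass(frozen=True)
class EventRecord:
    """One simulated hypoglycemic event."""

    severity: str  # mild | moderate | severe
    daytime: bool
    branch: str | None  # severe events only: care setting
    resources: dict[str, float] = field(default_factory=dict)
    fatal: bool = False


@dataclass(frozen=True)
class PatientYear:
    """One simulated person-year with its full event history."""

    strategy: str
    cohort: str
    events: list[EventRecord]
    total_cost: float
    qaly: float
    died: bool


@dataclass
class SimulatedCohort:
    """Vectorized per-patient aggregates for one strategy x cohort x country."""

    strategy: str
    cohort: str
    country: str
    currency: str
    n_mild: np.ndarray
    n_moderate: np.ndarray
    n_severe: np.ndarray
    n_hospitalized: np.ndarray
    hypo_cost: np.ndarray
    therapy_cost: float
    qaly: np.ndarray
    died: np.ndarray
    records: list[PatientYear] | None = None

    @property
    def n(self) -> int:
        return self.n_mild.shape[0]

    @property
    def total_cost(self) -> np.ndarray:
        return self.hypo_cost + self.therapy_cost


def simulate_cohort(
    n: int,
    strategy: str,
    cohort: str,
    bundle: ParameterBundle,
    seed: int,
    keep_events: bool = False,
) -> SimulatedCohort:
    """Simulate ``n`` independent patient-years.

    Reproducible for a given ``seed``. With ``keep_events`` the per-event
    histories are retained as :class:`PatientYear` records (intended for
    small ``n``; the aggregate arrays are then derived from the records so
    the two views agree exactly).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    strat = bundle.strategies[strategy]
    coh = bundle.cohorts[cohort]
    rates = rates_for(strat, coh, bundle.risk_constants, bundle.severity)
    rng = np.random.default_rng(seed)
    if keep_events:
        return _simulate_records(n, strat.name, coh.label, rates, bundle, rng)
    return _simulate_vectorized(n, strat.name, coh.label, rates, bundle, rng)


def _simulate_vectorized(
    n: int, strategy: str, cohort: str, rates, bundle: ParameterBundle, rng
) -> SimulatedCohort:
    ru = bundle.resource_use
    uc = bundle.unit_costs
    ut = bundle.utilities
    therapy = annual_therapy_cost(bundle.strategies[strategy], uc)

    n_mild = rng.poisson(rates.mild, n)
    n_mod = rng.poisson(rates.moderate, n)
    n_sev = rng.poisson(rates.severe, n)
    n_any = n_mild + n_mod + n_sev

    # follow-up care applies after every event regardless of severity
    contacts = rng.binomial(n_any, ru.p_hcp_contact_any_event)
    assays = rng.binomial(contacts, ru.p_assay_per_contact)
    extra_tests = rng.poisson(ru.n_extra_smbg_after_event * n_any)
    cost = (
        contacts * uc.gp_visit
        + assays * uc.blood_glucose_assay
        + extra_tests * (uc.smbg_strip + uc.smbg_lancet)
    ).astype(float)

    cost += rng.binomial(n_mod, ru.p_glucagon_moderate) * uc.glucagon_kit

    branch = ru.severe_branch
    pvals = np.array(
        [branch.gp, branch.np, branch.outpatient, branch.er_only, branch.hospitalization]
    )
    settings = rng.multinomial(n_sev, pvals)  # (n, 5)
    unit = np.array(
        [uc.gp_visit, uc.np_visit, uc.outpatient_visit, uc.er_visit, uc.hospitalization]
    )
    cost += settings @ unit
    transported = settings[:, 3] + settings[:, 4]
    cost += (
        rng.binomial(transported, ru.p_ambulance_severe_transport) * uc.ambulance
        + rng.binomial(transported, ru.p_glucagon_severe) * uc.glucagon_kit
    )

    n_hosp = settings[:, 4]
    deaths = rng.binomial(n_hosp, ru.p_death_given_hospitalization)
    died = deaths > 0

    day_mild = rng.binomial(n_mild, ut.p_daytime_mild)
    n_modsev = n_mod + n_sev
    day_modsev = rng.binomial(n_modsev, ut.p_daytime_modsev)
    d = ut.disutility_per_event
    disutility = (
        day_mild * d.mild_daytime
        + (n_mild - day_mild) * d.mild_nocturnal
        + day_modsev * d.moderate_severe_daytime
        + (n_modsev - day_modsev) * d.moderate_severe_nocturnal
    )
    death_loss = np.where(died, rng.uniform(0.0, 1.0, n) * ut.u_base, 0.0)
    qaly = ut.u_base - disutility - death_loss

    return SimulatedCohort(
        strategy=strategy,
        cohort=cohort,
        country=bundle.country,
        currency=bundle.currency,
        n_mild=n_mild,
        n_moderate=n_mod,
        n_severe=n_sev,
        n_hospitalized=n_hosp,
        hypo_cost=cost,
        therapy_cost=therapy,
        qaly=qaly,
        died=died,
    )


_BRANCH_NAMES = ("gp", "np", "outpatient", "er_only", "hospitalization")


def _simulate_records(
    n: int, strategy: str, cohort: str, rates, bundle: ParameterBundle, rng
) -> SimulatedCohort:
    ru = bundle.resource_use
    uc = bundle.unit_costs
    ut = bundle.utilities
    d = ut.disutility_per_event
    therapy = annual_therapy_cost(bundle.strategies[strategy], uc)
    branch_p = [
        ru.severe_branch.gp,
        ru.severe_branch.np,
        ru.severe_branch.outpatient,
        ru.severe_branch.er_only,
        ru.severe_branch.hospitalization,
    ]
    branch_cost = [uc.gp_visit, uc.np_visit, uc.outpatient_visit, uc.er_visit, uc.hospitalization]

    records: list[PatientYear] = []
    arrays = {k: np.zeros(n, dtype=int) for k in ("mild", "moderate", "severe", "hosp")}
    hypo_cost = np.zeros(n)
    qaly = np.zeros(n)
    died_arr = np.zeros(n, dtype=bool)

    for i in range(n):
        events: list[EventRecord] = []
        counts = {
            "mild": rng.poisson(rates.mild),
            "moderate": rng.poisson(rates.moderate),
            "severe": rng.poisson(rates.severe),
        }
        cost = 0.0
        disutility = 0.0
        died = False
        for severity, count in counts.items():
            for _ in range(count):
                resources: dict[str, float] = {}
                if rng.random() < ru.p_hcp_contact_any_event:
                    resources["gp_visit"] = uc.gp_visit
                    if rng.random() < ru.p_assay_per_contact:
                        resources["blood_glucose_assay"] = uc.blood_glucose_assay
                tests = int(rng.poisson(ru.n_extra_smbg_after_event))
                if tests:
                    resources["smbg_tests"] = tests * (uc.smbg_strip + uc.smbg_lancet)
                branch = None
                fatal = False
                if severity == "moderate" and rng.random() < ru.p_glucagon_moderate:
                    resources["glucagon_kit"] = uc.glucagon_kit
                if severity == "severe":
                    k = int(rng.choice(5, p=branch_p))
                    branch = _BRANCH_NAMES[k]
                    resources[branch] = branch_cost[k]
                    if branch in ("er_only", "hospitalization"):
                        if rng.random() < ru.p_ambulance_severe_transport:
                            resources["ambulance"] = uc.ambulance
                        if rng.random() < ru.p_glucagon_severe:
                            resources["glucagon_kit"] = (
                                resources.get("glucagon_kit", 0.0) + uc.glucagon_kit
                            )
                    if branch == "hospitalization":
                        arrays["hosp"][i] += 1
                        if rng.random() < ru.p_death_given_hospitalization:
                            fatal = True
                            died = True
                daytime = rng.random() < (
                    ut.p_daytime_mild if severity == "mild" else ut.p_daytime_modsev
                )
                if severity == "mild":
                    disutility += d.mild_daytime if daytime else d.mild_nocturnal
                else:
                    disutility += (
                        d.moderate_severe_daytime
                        if daytime
                        else d.moderate_severe_nocturnal
                    )
                cost += sum(resources.values())
                events.append(
                    EventRecord(
                        severity=severity,
                        daytime=daytime,
                        branch=branch,
                        resources=resources,
                        fatal=fatal,
                    )
                )
        death_loss = rng.uniform(0.0, 1.0) * ut.u_base if died else 0.0
        q = ut.u_base - disutility - death_loss
        arrays["mild"][i] = counts["mild"]
        arrays["moderate"][i] = counts["moderate"]
        arrays["severe"][i] = counts["severe"]
        hypo_cost[i] = cost
        qaly[i] = q
        died_arr[i] = died
        records.append(
            PatientYear(
                strategy=strategy,
                cohort=cohort,
                events=events,
                total_cost=cost + therapy,
                qaly=q,
                died=died,
            )
        )

    return SimulatedCohort(
        strategy=strategy,
        cohort=cohort,
        country=bundle.country,
        currency=bundle.currency,
        n_mild=arrays["mild"],
        n_moderate=arrays["moderate"],
        n_severe=arrays["severe"],
        n_hospitalized=arrays["hosp"],
        hypo_cost=hypo_cost,
        therapy_cost=therapy,
        qaly=qaly,
        died=died_arr,
        records=records,
    )


def _mean_sd_se(x: np.ndarray) -> dict[str, float]:
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.shape[0] > 1 else 0.0
    se = sd / math.sqrt(x.shape[0]) if x.shape[0] else float("nan")
    return {
        "mean": mean,
        "sd": sd,
        "se": se,
        "ci_low": mean - 1.96 * se,
        "ci_high": mean + 1.96 * se,
    }


def empirical_summary(sim: SimulatedCohort) -> dict[str, dict[str, float] | float]:
    """Summary statistics of a simulated cohort.

    Means with standard errors for hypoglycemia cost, total cost and QALYs;
    per-severity event-count means; the empirical severity proportions; the
    hospitalization share of severe events; and the death rate.
    """
    if sim.n == 0:
        raise ValueError("cannot summarize an empty cohort")
    totals = {
        "mild": int(sim.n_mild.sum()),
        "moderate": int(sim.n_moderate.sum()),
        "severe": int(sim.n_severe.sum()),
    }
    n_events = sum(totals.values())
    summary: dict = {
        "hypo_cost": _mean_sd_se(sim.hypo_cost),
        "total_cost": _mean_sd_se(sim.total_cost),
        "qaly": _mean_sd_se(sim.qaly),
        "n_mild": _mean_sd_se(sim.n_mild),
        "n_moderate": _mean_sd_se(sim.n_moderate),
        "n_severe": _mean_sd_se(sim.n_severe),
        "p_died": float(np.mean(sim.died)),
    }
    if n_events:
        summary["severity_proportions"] = {
            k: v / n_events for k, v in totals.items()
        }
    if totals["severe"]:
        summary["hospitalization_share_of_severe"] = (
            int(sim.n_hospitalized.sum()) / totals["severe"]
        )
    return summary


def to_dataframe(sim: SimulatedCohort):
    """Per-patient aggregates as a pandas DataFrame (for export/demos)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "strategy": sim.strategy,
            "cohort": sim.cohort,
            "country": sim.country,
            "n_mild": sim.n_mild,
            "n_moderate": sim.n_moderate,
            "n_severe": sim.n_severe,
            "n_hospitalized": sim.n_hospitalized,
            "hypo_cost": sim.hypo_cost,
            "total_cost": sim.total_cost,
            "qaly": sim.qaly,
            "died": sim.died,
        }
    )
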