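"""Budget impact: national costs of hypoglycemia and disinvestment savings.

Scales per-person model outputs by the number of older adults attaining
very tight glycemic control (HbA1c < 6.5%) with insulin or sulfonylureas,
split by a sulfonylurea:insulin prescription ratio and an age partition.
Three disinvestment scenarios are evaluated: stopping the drugs without
replacement, replacing them with a single (most cost-effective) agent, and
replacing them with a 50/50 mix of two agents.

The population-level "cost of hypoglycemia" uses the hypoglycemia-
attributable component only (events, not therapy); disinvestment savings
compare full annual costs (therapy plus hypoglycemia) because replacing a
drug changes both. Both components are reported side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from pydantic import BaseModel, Field, model_validator

from .tree import StrategyOutcome

__all__ = [
    "PopulationModel",
    "DisinvestmentScenario",
    "split_users",
    "age_partition",
    "population_hypo_cost",
    "disinvestment_savings",
    "default_population",
    "PopulationCostResult",
]

_CURRENT_DRUGS = ("basal_insulin", "sulfonylurea")


class PopulationModel(BaseModel):
    """National cohort of tight-control insulin/sulfonylurea users."""

    country: str
    n_tight_control_users: int = Field(ge=0)
    rx_ratio_su_to_insulin: float = Field(gt=0)
    share_80plus: float = Field(ge=0, le=1)


_DEFAULTS = {
    # U.S.: 1.2 million older adults in very tight control on insulin or
    # sulfonylureas; Canada: the U.S. prevalence projected onto the Canadian
    # older-adult population. Ratio 2.3 = 41%/18% sulfonylurea/insulin use;
    # 26% of users are aged 80 or older in both countries.
    "US": dict(n_tight_control_users=1_200_000, rx_ratio_su_to_insulin=2.3, share_80plus=0.26),
    "Canada": dict(n_tight_control_users=128_626, rx_ratio_su_to_insulin=2.3, share_80plus=0.26),
}


def default_population(country: str) -> PopulationModel:
    try:
        return PopulationModel(country=country, **_DEFAULTS[country])
    except KeyError:
        raise ValueError(f"unknown country {country!r}") from None


class DisinvestmentScenario(BaseModel):
    """One of the three disinvestment options."""

    kind: str  # no_replacement | single_replacement | fifty_fifty_mix
    replacements: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _arity(self) -> "DisinvestmentScenario":
        expected = {"no_replacement": 0, "single_replacement": 1, "fifty_fifty_mix": 2}
        if self.kind not in expected:
            raise ValueError(
                f"scenario.kind must be one of {sorted(expected)}, got {self.kind!r}"
            )
        if len(self.replacements) != expected[self.kind]:
            raise ValueError(
                f"scenario {self.kind!r} requires {expected[self.kind]} "
                f"replacement strategies, got {len(self.replacements)}"
            )
        return self


def split_users(n_total: int, ratio: float) -> tuple[int, int]:
    """(insulin users, sulfonylurea users) from a total and an SU:insulin ratio.

    Insulin users are ``round(n / (1 + ratio))``; the remainder goes to
    sulfonylureas so the two counts always sum to the total.
    """
    if n_total < 0:
        raise ValueError("n_total must be non-negative")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    insulin = round(n_total / (1.0 + ratio))
    return insulin, n_total - insulin


def age_partition(n: int, share_80plus: float) -> tuple[int, int]:
    """(n aged 65-79, n aged 80+); the 80+ count is rounded, remainder to 65-79."""
    if not 0.0 <= share_80plus <= 1.0:
        raise ValueError("share_80plus must lie in [0, 1]")
    n_80 = round(share_80plus * n)
    return n - n_80, n_80


def _outcome_index(
    outcomes: Sequence[StrategyOutcome],
) -> dict[tuple[str, str], StrategyOutcome]:
    return {(o.strategy, o.cohort): o for o in outcomes}


def _user_counts(pop: PopulationModel) -> dict[str, dict[str, int]]:
    insulin, su = split_users(pop.n_tight_control_users, pop.rx_ratio_su_to_insulin)
    counts = {}
    for drug, n in (("basal_insulin", insulin), ("sulfonylurea", su)):
        n_65, n_80 = age_partition(n, pop.share_80plus)
        counts[drug] = {"65-79": n_65, "80plus": n_80}
    return counts


@dataclass(frozen=True)
class PopulationCostResult:
    """National annual costs by drug, with hypoglycemia-only and total views."""

    country: str
    currency: str
    hypo_cost_by_drug: dict[str, float]
    total_cost_by_drug: dict[str, float]
    user_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    hypo_cost_by_cell: dict[tuple[str, str], float] = field(default_factory=dict)
    total_cost_by_cell: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def combined_hypo_cost(self) -> float:
        return sum(self.hypo_cost_by_drug.values())

    @property
    def combined_total_cost(self) -> float:
        return sum(self.total_cost_by_drug.values())


def population_hypo_cost(
    pop: PopulationModel, outcomes: Sequence[StrategyOutcome]
) -> PopulationCostResult:
    """National annual hypoglycemia costs for insulin and sulfonylurea users."""
    index = _outcome_index(outcomes)
    counts = _user_counts(pop)
    hypo: dict[str, float] = {}
    total: dict[str, float] = {}
    hypo_cell: dict[tuple[str, str], float] = {}
    total_cell: dict[tuple[str, str], float] = {}
    currency = outcomes[0].currency if outcomes else ""
    for drug, by_cohort in counts.items():
        h = t = 0.0
        for cohort, n in by_cohort.items():
            try:
                o = index[(drug, cohort)]
            except KeyError:
                raise KeyError(
                    f"missing outcome for strategy {drug!r}, cohort {cohort!r}"
                ) from None
            hypo_cell[(drug, cohort)] = n * o.annual_hypo_cost
            total_cell[(drug, cohort)] = n * o.annual_total_cost
            h += n * o.annual_hypo_cost
            t += n * o.annual_total_cost
        hypo[drug] = h
        total[drug] = t
    return PopulationCostResult(
        country=pop.country,
        currency=currency,
        hypo_cost_by_drug=hypo,
        total_cost_by_drug=total,
        user_counts=counts,
        hypo_cost_by_cell=hypo_cell,
        total_cost_by_cell=total_cell,
    )


def disinvestment_savings(
    pop: PopulationModel,
    outcomes: Sequence[StrategyOutcome],
    scenario: DisinvestmentScenario,
) -> float:
    """Annual savings from disinvesting in insulin and sulfonylureas.

    ``no_replacement`` saves the current users' full annual cost (therapy
    plus hypoglycemia). Replacement scenarios subtract the replacement
    regimen's full annual cost for the same user counts, split equally
    across the named strategies for the 50/50 mix.
    """
    index = _outcome_index(outcomes)
    counts = _user_counts(pop)
    for name in scenario.replacements:
        if not any(key[0] == name for key in index):
            raise KeyError(f"unknown replacement strategy {name!r}")

    current = sum(
        n * index[(drug, cohort)].annual_total_cost
        for drug, by_cohort in counts.items()
        for cohort, n in by_cohort.items()
    )
    if scenario.kind == "no_replacement":
        return current

    share = 1.0 / len(scenario.replacements)
    replacement = sum(
        share * n * index[(repl, cohort)].annual_total_cost
        for drug, by_cohort in counts.items()
        for cohort, n in by_cohort.items()
        for repl in scenario.replacements
    )
    return current - replacement
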