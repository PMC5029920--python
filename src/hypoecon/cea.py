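"""Incremental cost-effectiveness with dominance classification.

Pairwise comparisons of strategy outcomes within one country x cohort:
incremental cost per QALY gained (ICER), dominance (cheaper and more
effective / costlier and less effective), willingness-to-pay screening, and
currency conversion helpers. Comparisons are pairwise against a single
reference strategy; an opt-in efficiency-frontier pruning is provided but
is not applied by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

from .params import EconomicSettings

__all__ = [
    "OutcomeLike",
    "ICERResult",
    "icer",
    "full_comparison",
    "efficiency_frontier",
    "convert_currency",
]

_TIE_TOL = 1e-12


class OutcomeLike(Protocol):
    """Anything carrying the fields a pairwise comparison needs."""

    strategy: str
    cohort: str
    country: str

    @property
    def annual_total_cost(self) -> float: ...

    @property
    def qaly(self) -> float: ...


@dataclass(frozen=True)
class ICERResult:
    """One pairwise incremental comparison.

    ``status`` is one of ``dominant`` (cheaper, more effective),
    ``dominated`` (costlier, less effective), ``equivalent`` (both deltas at
    machine zero) or ``icer``. ``icer_value`` is populated only for
    ``icer`` rows. ``southwest`` flags the cheaper-but-less-effective
    quadrant, where the ratio is a savings-per-QALY-forgone figure rather
    than a conventional ICER.
    """

    strategy: str
    comparator: str
    cohort: str
    country: str
    delta_cost: float
    delta_qaly: float
    status: str
    icer_value: float | None = None
    southwest: bool = False
    cost_effective_at_wtp: bool = False


def _is_zero(x: float, scale: float) -> bool:
    return abs(x) <= _TIE_TOL * max(1.0, abs(scale))


def icer(
    outcome: OutcomeLike,
    comparator: OutcomeLike,
    settings: EconomicSettings,
) -> ICERResult:
    """Compare ``outcome`` against ``comparator`` (same country and cohort)."""
    if outcome.country != comparator.country:
        raise ValueError(
            f"cannot compare outcomes across countries "
            f"({outcome.country!r} vs {comparator.country!r})"
        )
    if outcome.cohort != comparator.cohort:
        raise ValueError(
            f"cannot compare outcomes across cohorts "
            f"({outcome.cohort!r} vs {comparator.cohort!r})"
        )
    dc = outcome.annual_total_cost - comparator.annual_total_cost
    dq = outcome.qaly - comparator.qaly
    zero_cost = _is_zero(dc, comparator.annual_total_cost)
    zero_qaly = _is_zero(dq, comparator.qaly)

    value: float | None = None
    southwest = False
    if zero_cost and zero_qaly:
        status = "equivalent"
    elif (dc <= 0 or zero_cost) and (dq >= 0 or zero_qaly):
        status = "dominant"
    elif (dc >= 0 or zero_cost) and (dq <= 0 or zero_qaly):
        status = "dominated"
    else:
        status = "icer"
        value = dc / dq
        southwest = dc < 0 and dq < 0

    cost_effective = status == "dominant" or (
        status == "icer"
        and not southwest
        and dq > 0
        and value is not None
        and value <= settings.wtp_threshold
    )
    return ICERResult(
        strategy=outcome.strategy,
        comparator=comparator.strategy,
        cohort=outcome.cohort,
        country=outcome.country,
        delta_cost=dc,
        delta_qaly=dq,
        status=status,
        icer_value=value,
        southwest=southwest,
        cost_effective_at_wtp=cost_effective,
    )


def _rank_key(result: ICERResult) -> tuple[int, float]:
    # Decreasing cost-effectiveness: dominant (largest savings first), then
    # rising ICERs, then the southwest quadrant, dominated last.
    if result.status == "dominant":
        return (0, result.delta_cost)
    if result.status == "equivalent":
        return (1, 0.0)
    if result.status == "icer" and not result.southwest:
        return (2, result.icer_value if result.icer_value is not None else math.inf)
    if result.southwest:
        return (3, -(result.icer_value or 0.0))
    return (4, result.delta_cost)


def full_comparison(
    outcomes: Sequence[OutcomeLike],
    reference: str,
    settings: EconomicSettings,
) -> list[ICERResult]:
    """Compare every non-reference strategy against ``reference``.

    Output is ordered by decreasing cost-effectiveness relative to the
    reference (dominant first, then rising ICERs, dominated last).
    """
    by_name = {o.strategy: o for o in outcomes}
    if reference not in by_name:
        raise ValueError(
            f"reference strategy {reference!r} not among outcomes "
            f"({sorted(by_name)})"
        )
    ref = by_name[reference]
    results = [
        icer(o, ref, settings) for o in outcomes if o.strategy != reference
    ]
    return sorted(results, key=_rank_key)


def efficiency_frontier(outcomes: Sequence[OutcomeLike]) -> list[OutcomeLike]:
    """Opt-in frontier pruning: strategies not strictly dominated.

    Returns the cost-sorted subset on the efficiency frontier (increasing
    cost implies increasing effectiveness after removing dominated and
    extended-dominated strategies).
    """
    ranked = sorted(outcomes, key=lambda o: (o.annual_total_cost, -o.qaly))
    frontier: list[OutcomeLike] = []
    for o in ranked:
        if not frontier or o.qaly > frontier[-1].qaly:
            frontier.append(o)
    # extended dominance: ICERs along the frontier must be increasing
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_lo = (mid.annual_total_cost - lo.annual_total_cost) / (
                mid.qaly - lo.qaly
            )
            icer_hi = (hi.annual_total_cost - mid.annual_total_cost) / (
                hi.qaly - mid.qaly
            )
            if icer_lo > icer_hi:
                frontier.pop(i)
                changed = True
                break
    return frontier


def convert_currency(amount: float, rate: float) -> float:
    """Convert an amount between currencies at a fixed exchange rate."""
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    return amount * rate
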