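"""Model/Results front-end over the decision-analytic machinery.

:class:`HypoglycemiaCostModel` is built from a parameter bundle (or a
country's packaged defaults, or a YAML config); ``fit()`` evaluates the
decision tree for every strategy x cohort and returns a
:class:`HypoglycemiaCostResults` carrying the per-person outcomes, with
incremental comparisons, sensitivity analyses, population scaling and
simulation hanging off the results object.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from . import cea as _cea
from . import population as _population
from . import sensitivity as _sensitivity
from .microsim import SimulatedCohort, simulate_cohort
from .params import ParameterBundle, default_parameters, load_parameters
from .risk import round_half_up
from .tree import StrategyOutcome, evaluate_all

__all__ = ["HypoglycemiaCostModel", "HypoglycemiaCostResults"]


class HypoglycemiaCostModel:
    """Annual decision-tree model of drug-induced hypoglycemia.

    Parameters
    ----------
    bundle:
        A validated :class:`~hypoecon.params.ParameterBundle` defining the
        cohorts, medication strategies, event probabilities, costs and
        utilities for one country.

    Examples
    --------
    >>> model = HypoglycemiaCostModel.from_country("US")
    >>> results = model.fit()
    >>> results.rates_table().loc[("65-79", "metformin")]["mild"]
    1.37
    """

    def __init__(self, bundle: ParameterBundle):
        self.bundle = bundle

    @classmethod
    def from_country(cls, country: str) -> "HypoglycemiaCostModel":
        """Model on the packaged defaults for "US" or "Canada"."""
        return cls(default_parameters(country))

    @classmethod
    def from_config(cls, path: str | Path) -> "HypoglycemiaCostModel":
        """Model on a user-provided YAML parameter file."""
        return cls(load_parameters(path))

    def fit(self) -> "HypoglycemiaCostResults":
        """Evaluate the tree for every strategy x cohort."""
        return HypoglycemiaCostResults(self, evaluate_all(self.bundle))


class HypoglycemiaCostResults:
    """Fitted per-person outcomes plus downstream analyses."""

    def __init__(self, model: HypoglycemiaCostModel, outcomes: list[StrategyOutcome]):
        self.model = model
        self.outcomes = outcomes

    @property
    def bundle(self) -> ParameterBundle:
        return self.model.bundle

    def outcome(self, strategy: str, cohort: str) -> StrategyOutcome:
        for o in self.outcomes:
            if o.strategy == strategy and o.cohort == cohort:
                return o
        raise KeyError(f"no outcome for strategy {strategy!r}, cohort {cohort!r}")

    # ---- tables ----------------------------------------------------------

    def frame(self) -> pd.DataFrame:
        """All outcomes as a tidy DataFrame (full precision)."""
        rows = [
            {
                "country": o.country,
                "cohort": o.cohort,
                "strategy": o.strategy,
                "mild_rate": o.rates.mild,
                "moderate_severe_rate": o.rates.moderate_severe,
                "total_rate": o.rates.total,
                "annual_hypo_cost": o.annual_hypo_cost,
                "annual_therapy_cost": o.annual_therapy_cost,
                "annual_total_cost": o.annual_total_cost,
                "qaly": o.qaly,
                "p_fatal": o.p_fatal,
            }
            for o in self.outcomes
        ]
        return pd.DataFrame(rows)

    def rates_table(self, ndigits: int = 2) -> pd.DataFrame:
        """Per-strategy rates rounded for reporting, indexed by cohort/strategy.

        The ``total`` column is the sum of the two independently rounded
        components, matching the reporting convention of published headline
        rates.
        """
        df = self.frame()
        out = pd.DataFrame(
            {
                "mild": df["mild_rate"].map(lambda x: round_half_up(x, ndigits)),
                "moderate_severe": df["moderate_severe_rate"].map(
                    lambda x: round_half_up(x, ndigits)
                ),
            }
        )
        out["total"] = out["mild"] + out["moderate_severe"]
        out.index = pd.MultiIndex.from_frame(df[["cohort", "strategy"]])
        return out

    def icer_table(self, reference: str = "metformin") -> pd.DataFrame:
        """Pairwise comparisons vs a reference strategy, per cohort."""
        rows = []
        for cohort in self.bundle.cohorts:
            cell = [o for o in self.outcomes if o.cohort == cohort]
            for r in _cea.full_comparison(cell, reference, self.bundle.settings):
                rows.append(
                    {
                        "country": r.country,
                        "cohort": r.cohort,
                        "reference": r.comparator,
                        "strategy": r.strategy,
                        "delta_cost": r.delta_cost,
                        "delta_qaly": r.delta_qaly,
                        "status": r.status,
                        "icer": r.icer_value,
                        "cost_effective_at_wtp": r.cost_effective_at_wtp,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable per-person outcome table with ICERs vs metformin."""
        bundle = self.bundle
        lines = [
            f"Drug-induced hypoglycemia decision model — {bundle.country} "
            f"({bundle.currency})",
            f"WTP threshold: {bundle.settings.wtp_threshold:,.0f} per QALY",
            "",
        ]
        header = (
            f"{'cohort':<8} {'strategy':<14} {'mild':>6} {'mod/sev':>8} "
            f"{'hypo$':>9} {'therapy$':>9} {'total$':>9} {'QALY':>7}"
        )
        lines.append(header)
        lines.append("-" * len(header))
        for o in self.outcomes:
            lines.append(
                f"{o.cohort:<8} {o.strategy:<14} "
                f"{round_half_up(o.rates.mild):>6.2f} "
                f"{round_half_up(o.rates.moderate_severe):>8.2f} "
                f"{o.annual_hypo_cost:>9.0f} {o.annual_therapy_cost:>9.0f} "
                f"{o.annual_total_cost:>9.0f} {o.qaly:>7.3f}"
            )
        return "\n".join(lines)

    # ---- downstream analyses --------------------------------------------

    def compare(self, reference: str, cohort: str) -> list[_cea.ICERResult]:
        cell = [o for o in self.outcomes if o.cohort == cohort]
        return _cea.full_comparison(cell, reference, self.bundle.settings)

    def tornado(
        self,
        strategy: str,
        comparator: str,
        cohort: str,
        parameters: Sequence[str | tuple[str, float, float]] | None = None,
        range_fraction: float = 0.25,
    ) -> list[_sensitivity.TornadoEntry]:
        if parameters is None:
            parameters = _sensitivity.default_dsa_parameters(
                self.bundle, strategy, comparator, cohort
            )
        return _sensitivity.one_way_dsa(
            self.bundle, parameters, strategy, comparator, cohort, range_fraction
        )

    def psa(
        self, cohort: str, spec: _sensitivity.PSASpec | None = None
    ) -> _sensitivity.PSAResult:
        return _sensitivity.run_psa(self.bundle, spec or _sensitivity.PSASpec(), cohort)

    def ceac(
        self,
        cohort: str,
        wtp_grid: Sequence[float],
        spec: _sensitivity.PSASpec | None = None,
    ) -> list[_sensitivity.CEACPoint]:
        return _sensitivity.ceac(self.psa(cohort, spec), wtp_grid)

    def simulate(
        self, strategy: str, cohort: str, n: int, seed: int, keep_events: bool = False
    ) -> SimulatedCohort:
        return simulate_cohort(n, strategy, cohort, self.bundle, seed, keep_events)

    def population_costs(
        self, pop: _population.PopulationModel | None = None
    ) -> _population.PopulationCostResult:
        pop = pop or _population.default_population(self.bundle.country)
        return _population.population_hypo_cost(pop, self.outcomes)

    def disinvestment(
        self,
        scenario: _population.DisinvestmentScenario,
        pop: _population.PopulationModel | None = None,
    ) -> float:
        pop = pop or _population.default_population(self.bundle.country)
        return _population.disinvestment_savings(pop, self.outcomes, scenario)
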