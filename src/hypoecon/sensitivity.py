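"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way deterministic analysis recomputes a pairwise ICER with each
parameter swung to the ends of its range (default +/-25% of the base-case
value) while everything else stays at base, yielding tornado-diagram
entries sorted by spread.

Probabilistic analysis redraws the uncertain parameters jointly but
independently — gamma distributions for incidence-rate inputs, costs and
disutilities, a beta distribution for the base utility — re-evaluates every
strategy per iteration, and summarizes the draws as cost-effectiveness
acceptability curves (probability of maximal net monetary benefit as a
function of willingness-to-pay). The +/-25% range is interpreted as a 95%
interval half-width, so each distribution is moment-matched to
``sd = 0.25 * mean / 1.96``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from pydantic import BaseModel

from .cea import OutcomeLike, icer
from .params import ParameterBundle
from .tree import evaluate_strategy

__all__ = [
    "TornadoEntry",
    "PSASpec",
    "PSAResult",
    "CEACPoint",
    "get_parameter",
    "set_parameter",
    "default_dsa_parameters",
    "one_way_dsa",
    "default_psa_parameters",
    "sample_parameters",
    "run_psa",
    "psa_from_summary",
    "ceac",
    "acceptability_at",
]


# ---------------------------------------------------------------------------
# Dotted-path access into a bundle


def _navigate(bundle: ParameterBundle, path: str):
    parts = path.split(".")
    obj = bundle
    for part in parts[:-1]:
        if isinstance(obj, dict):
            obj = obj[part]
        else:
            obj = getattr(obj, part)
    return obj, parts[-1]


def get_parameter(bundle: ParameterBundle, path: str) -> float:
    """Read a scalar parameter by dotted path (dict keys included)."""
    try:
        parent, leaf = _navigate(bundle, path)
        value = parent[leaf] if isinstance(parent, dict) else getattr(parent, leaf)
    except (AttributeError, KeyError) as exc:
        raise KeyError(f"cannot resolve parameter path {path!r}") from exc
    if isinstance(value, (BaseModel, dict)):
        raise KeyError(f"parameter path {path!r} does not point at a scalar")
    return float(value)


def set_parameter(bundle: ParameterBundle, path: str, value: float) -> None:
    """Assign a scalar parameter in place (no cross-field re-validation)."""
    parent, leaf = _navigate(bundle, path)
    if isinstance(parent, dict):
        parent[leaf] = value
    else:
        if leaf not in type(parent).model_fields:
            raise KeyError(f"cannot resolve parameter path {path!r}")
        object.__setattr__(parent, leaf, value)


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity (tornado)


@dataclass(frozen=True)
class TornadoEntry:
    """ICER excursion for one parameter swung low/high, all else at base.

    Dominance at an end is encoded as a signed infinity in the numeric
    fields (-inf dominant, +inf dominated) and labelled in ``status_*``.
    """

    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float
    status_at_low: str
    status_at_high: str
    spread: float


_STATUS_NUMERIC = {"dominant": -math.inf, "dominated": math.inf, "equivalent": 0.0}


def _icer_numeric(result) -> tuple[float, str]:
    if result.status == "icer":
        return result.icer_value, "icer"
    return _STATUS_NUMERIC[result.status], result.status


def default_dsa_parameters(
    bundle: ParameterBundle, strategy: str, comparator: str, cohort: str
) -> list[str]:
    """Every scalar that can move the pairwise ICER: the compared
    strategies' rate and cost inputs, shared unit costs, utilities,
    resource-use probabilities and the cohort covariates. Probability
    vectors constrained to sum to one (severity split, severe-event branch)
    are excluded from the one-way sweep."""
    paths: list[str] = []
    for name in (strategy, comparator):
        paths += [
            f"strategies.{name}.base_rate",
            f"strategies.{name}.annual_drug_cost",
            f"strategies.{name}.daily_smbg_tests",
        ]
    paths += [f"unit_costs.{f}" for f in (
        "gp_visit", "np_visit", "outpatient_visit", "er_visit",
        "hospitalization", "ambulance", "glucagon_kit", "blood_glucose_assay",
        "smbg_strip", "smbg_lancet", "needle", "home_monitor_annual",
    )]
    paths += [
        "utilities.u_base",
        "utilities.disutility_per_event.mild_daytime",
        "utilities.disutility_per_event.mild_nocturnal",
        "utilities.disutility_per_event.moderate_severe_daytime",
        "utilities.disutility_per_event.moderate_severe_nocturnal",
        "resource_use.p_hcp_contact_any_event",
        "resource_use.n_extra_smbg_after_event",
        "resource_use.p_glucagon_moderate",
        "resource_use.p_glucagon_severe",
        "resource_use.p_ambulance_severe_transport",
        "resource_use.p_death_given_hospitalization",
        f"cohorts.{cohort}.diabetes_duration",
        f"cohorts.{cohort}.hba1c",
        f"cohorts.{cohort}.bmi",
        f"cohorts.{cohort}.gfr",
    ]
    return paths


_UNIT_INTERVAL_PATHS = ("utilities.u_base",)


def _default_range(path: str, base: float, fraction: float) -> tuple[float, float]:
    low = base * (1.0 - fraction)
    high = base * (1.0 + fraction)
    if path.startswith("resource_use.p_") or path in _UNIT_INTERVAL_PATHS:
        high = min(high, 1.0)
    return low, high


def one_way_dsa(
    bundle: ParameterBundle,
    parameters: Iterable[str | tuple[str, float, float]],
    strategy: str,
    comparator: str,
    cohort: str,
    range_fraction: float = 0.25,
) -> list[TornadoEntry]:
    """Tornado entries for ``strategy`` vs ``comparator`` in one cohort.

    ``parameters`` is a list of dotted paths, or ``(path, low, high)``
    triples for explicit ranges; unadorned paths default to
    ``base * (1 -/+ range_fraction)``. Entries come back sorted by
    descending spread.
    """
    entries = []
    for item in parameters:
        if isinstance(item, tuple):
            path, low, high = item
        else:
            path = item
            base = get_parameter(bundle, path)
            low, high = _default_range(path, base, range_fraction)
        if not low <= high:
            raise ValueError(f"{path}: low {low!r} exceeds high {high!r}")
        ends = []
        for value in (low, high):
            perturbed = bundle.copy_deep()
            set_parameter(perturbed, path, value)
            result = icer(
                evaluate_strategy(strategy, cohort, perturbed),
                evaluate_strategy(comparator, cohort, perturbed),
                perturbed.settings,
            )
            ends.append(_icer_numeric(result))
        (v_lo, s_lo), (v_hi, s_hi) = ends
        spread = abs(v_hi - v_lo) if math.isfinite(v_hi - v_lo) else math.inf
        entries.append(
            TornadoEntry(
                parameter=path,
                low_value=low,
                high_value=high,
                icer_at_low=v_lo,
                icer_at_high=v_hi,
                status_at_low=s_lo,
                status_at_high=s_hi,
                spread=spread,
            )
        )
    return sorted(entries, key=lambda e: -e.spread)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSASpec:
    """Configuration of the Monte-Carlo parameter-uncertainty analysis."""

    n_iterations: int = 1000
    seed: int = 0
    range_fraction: float = 0.25
    z_value: float = 1.96  # +/- range interpreted as this many-sigma interval

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")
        if not 0.0 < self.range_fraction < 1.0:
            raise ValueError("range_fraction must lie in (0, 1)")

    @property
    def sd_fraction(self) -> float:
        return self.range_fraction / self.z_value


def default_psa_parameters(
    bundle: ParameterBundle,
) -> tuple[list[str], list[str]]:
    """(gamma paths, beta paths) sampled by default.

    Gamma: per-strategy base incidence rates, every unit cost, every annual
    drug cost, every per-event disutility. Beta: the base utility.
    """
    gamma = []
    for name in bundle.strategies:
        gamma.append(f"strategies.{name}.base_rate")
        gamma.append(f"strategies.{name}.annual_drug_cost")
    gamma += [f"unit_costs.{f}" for f in (
        "gp_visit", "np_visit", "outpatient_visit", "er_visit",
        "hospitalization", "ambulance", "glucagon_kit", "blood_glucose_assay",
        "smbg_strip", "smbg_lancet", "needle", "home_monitor_annual",
    )]
    gamma += [
        "utilities.disutility_per_event.mild_daytime",
        "utilities.disutility_per_event.mild_nocturnal",
        "utilities.disutility_per_event.moderate_severe_daytime",
        "utilities.disutility_per_event.moderate_severe_nocturnal",
    ]
    beta = ["utilities.u_base"]
    return gamma, beta


def _gamma_draws(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=n)


def _beta_draws(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    var = sd**2
    if var >= mean * (1.0 - mean):
        raise ValueError("beta moment matching infeasible: variance too large")
    nu = mean * (1.0 - mean) / var - 1.0
    a, b = mean * nu, (1.0 - mean) * nu
    return np.clip(rng.beta(a, b, size=n), None, 1.0)


def sample_parameters(
    bundle: ParameterBundle,
    spec: PSASpec,
    gamma_paths: Sequence[str] | None = None,
    beta_paths: Sequence[str] | None = None,
) -> list[ParameterBundle]:
    """One sampled bundle per iteration, reproducible from the spec seed.

    Gamma draws have mean equal to the base value and standard deviation
    ``sd_fraction * base``; the beta draw is moment-matched the same way and
    truncated to (0, 1]. Non-positive base values cannot parameterize a
    gamma distribution and are held fixed with a warning.
    """
    if gamma_paths is None or beta_paths is None:
        g_default, b_default = default_psa_parameters(bundle)
        gamma_paths = g_default if gamma_paths is None else gamma_paths
        beta_paths = b_default if beta_paths is None else beta_paths
    rng = np.random.default_rng(spec.seed)
    n = spec.n_iterations
    draws: dict[str, np.ndarray] = {}
    for path in gamma_paths:
        base = get_parameter(bundle, path)
        if base <= 0:
            warnings.warn(
                f"{path}: non-positive base value {base!r}; held fixed in PSA",
                stacklevel=2,
            )
            draws[path] = np.full(n, base)
            continue
        draws[path] = _gamma_draws(rng, base, spec.sd_fraction * base, n)
    for path in beta_paths:
        base = get_parameter(bundle, path)
        draws[path] = _beta_draws(rng, base, spec.sd_fraction * base, n)
    sampled = []
    for i in range(n):
        b = bundle.copy_deep()
        for path, values in draws.items():
            set_parameter(b, path, float(values[i]))
        sampled.append(b)
    return sampled


@dataclass
class PSAResult:
    """Per-iteration costs and QALYs for every strategy in one cell."""

    strategies: list[str]
    costs: np.ndarray  # (n_iterations, n_strategies)
    qalys: np.ndarray  # (n_iterations, n_strategies)
    country: str
    cohort: str
    wtp_threshold: float

    @property
    def n_iterations(self) -> int:
        return self.costs.shape[0]


def run_psa(
    bundle: ParameterBundle,
    spec: PSASpec,
    cohort: str,
    gamma_paths: Sequence[str] | None = None,
    beta_paths: Sequence[str] | None = None,
) -> PSAResult:
    """Re-evaluate every strategy under each sampled parameter set."""
    sampled = sample_parameters(bundle, spec, gamma_paths, beta_paths)
    strategies = list(bundle.strategies)
    costs = np.empty((len(sampled), len(strategies)))
    qalys = np.empty_like(costs)
    for i, b in enumerate(sampled):
        for j, name in enumerate(strategies):
            outcome = evaluate_strategy(name, cohort, b)
            costs[i, j] = outcome.annual_total_cost
            qalys[i, j] = outcome.qaly
    return PSAResult(
        strategies=strategies,
        costs=costs,
        qalys=qalys,
        country=bundle.country,
        cohort=cohort,
        wtp_threshold=bundle.settings.wtp_threshold,
    )


def psa_from_summary(
    outcomes: Sequence[OutcomeLike],
    spec: PSASpec,
    u_base: float = 0.844,
    wtp_threshold: float | None = None,
) -> PSAResult:
    """Summary-level PSA over reported per-person costs and QALYs.

    For analyses where only per-strategy total costs and QALYs are known
    (for example, the bundled published base-case outcomes), sample each
    strategy's cost from a gamma distribution centred on its reported value,
    and its QALY as a beta-distributed base utility minus a gamma-distributed
    total annual disutility (``u_base - qaly``), all moment-matched under
    the same +/-25%-as-95%-interval convention.
    """
    if not outcomes:
        raise ValueError("outcomes must be non-empty")
    country = outcomes[0].country
    cohort = outcomes[0].cohort
    rng = np.random.default_rng(spec.seed)
    n = spec.n_iterations
    strategies = [o.strategy for o in outcomes]
    costs = np.empty((n, len(outcomes)))
    qalys = np.empty_like(costs)
    u_draws = _beta_draws(rng, u_base, spec.sd_fraction * u_base, n)
    for j, o in enumerate(outcomes):
        costs[:, j] = _gamma_draws(
            rng, o.annual_total_cost, spec.sd_fraction * o.annual_total_cost, n
        )
        disutility = u_base - o.qaly
        if disutility > 0:
            loss = _gamma_draws(rng, disutility, spec.sd_fraction * disutility, n)
        else:
            loss = np.zeros(n)
        qalys[:, j] = u_draws - loss
    if wtp_threshold is None:
        from .benchmarks import reference_wtp

        wtp_threshold = reference_wtp(country)
    return PSAResult(
        strategies=strategies,
        costs=costs,
        qalys=qalys,
        country=country,
        cohort=cohort,
        wtp_threshold=wtp_threshold,
    )


# ---------------------------------------------------------------------------
# Acceptability curves


@dataclass(frozen=True)
class CEACPoint:
    """Acceptability at one willingness-to-pay value (probabilities sum to 1)."""

    wtp: float
    probability_cost_effective: dict[str, float] = field(default_factory=dict)


def acceptability_at(psa: PSAResult, wtp: float) -> dict[str, float]:
    """Probability each strategy maximizes net monetary benefit at ``wtp``."""
    nmb = psa.qalys * wtp - psa.costs
    winners = np.argmax(nmb, axis=1)
    counts = np.bincount(winners, minlength=len(psa.strategies))
    probs = counts / psa.n_iterations
    return dict(zip(psa.strategies, probs.tolist()))


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    if psa.n_iterations == 0:
        raise ValueError("PSA output is empty")
    grid = list(wtp_grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("wtp_grid must be strictly increasing")
    return [CEACPoint(wtp=w, probability_cost_effective=acceptability_at(psa, w)) for w in grid]
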