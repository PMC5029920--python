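"""CSV writers and run manifests for the command-line tools.

All outputs are UTF-8 CSV with a header row and period decimal separators;
currency symbols never appear in numeric columns. Each CLI run writes a
JSON manifest recording the command, config, seed and produced files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Sequence

import pandas as pd

from .population import PopulationCostResult
from .sensitivity import CEACPoint, TornadoEntry

__all__ = [
    "RunManifest",
    "write_frame",
    "tornado_frame",
    "ceac_frame",
    "population_frame",
]


def _package_version() -> str:
    try:
        return version("hypoecon")
    except PackageNotFoundError:  # pragma: no cover - editable-install edge
        return "unknown"


@dataclass
class RunManifest:
    """Record of one CLI invocation and the files it produced."""

    command: str
    config: str
    seed: int | None = None
    outputs: list[str] = field(default_factory=list)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    package_version: str = field(default_factory=_package_version)

    def add(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def write(self, path: str | Path) -> None:
        for output in self.outputs:
            if not Path(output).exists():
                raise FileNotFoundError(f"manifest lists missing output {output!r}")
        payload = {
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "timestamp": self.timestamp,
            "package_version": self.package_version,
            "outputs": self.outputs,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_frame(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def _fmt_icer(value: float, status: str) -> str:
    if math.isinf(value):
        return status
    return f"{value:.6g}"


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_value": e.low_value,
                "high_value": e.high_value,
                "icer_at_low": e.icer_at_low,
                "icer_at_high": e.icer_at_high,
                "label_at_low": _fmt_icer(e.icer_at_low, e.status_at_low),
                "label_at_high": _fmt_icer(e.icer_at_high, e.status_at_high),
                "spread": e.spread,
            }
            for e in entries
        ]
    )


def ceac_frame(points: Sequence[CEACPoint]) -> pd.DataFrame:
    rows = []
    for p in points:
        row = {"wtp": p.wtp}
        row.update(p.probability_cost_effective)
        rows.append(row)
    return pd.DataFrame(rows)


def population_frame(result: PopulationCostResult) -> pd.DataFrame:
    rows = []
    for drug, by_cohort in result.user_counts.items():
        for cohort, n in by_cohort.items():
            rows.append(
                {
                    "country": result.country,
                    "currency": result.currency,
                    "drug": drug,
                    "cohort": cohort,
                    "users": n,
                    "annual_hypo_cost": result.hypo_cost_by_cell.get((drug, cohort), 0.0),
                    "annual_total_cost": result.total_cost_by_cell.get((drug, cohort), 0.0),
                }
            )
    df = pd.DataFrame(rows)
    # per-drug and combined totals as explicit rows
    totals = []
    for drug in result.user_counts:
        totals.append(
            {
                "country": result.country,
                "currency": result.currency,
                "drug": drug,
                "cohort": "all",
                "users": sum(result.user_counts[drug].values()),
                "annual_hypo_cost": result.hypo_cost_by_drug[drug],
                "annual_total_cost": result.total_cost_by_drug[drug],
            }
        )
    totals.append(
        {
            "country": result.country,
            "currency": result.currency,
            "drug": "combined",
            "cohort": "all",
            "users": sum(
                sum(v.values()) for v in result.user_counts.values()
            ),
            "annual_hypo_cost": result.combined_hypo_cost,
            "annual_total_cost": result.combined_total_cost,
        }
    )
    return pd.concat([df, pd.DataFrame(totals)], ignore_index=True)
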