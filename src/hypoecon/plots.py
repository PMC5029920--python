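"""Tornado-diagram and acceptability-curve plots (matplotlib, file output)."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .sensitivity import CEACPoint, TornadoEntry

__all__ = ["tornado_plot", "ceac_plot"]


def tornado_plot(
    entries: Sequence[TornadoEntry],
    base_icer: float,
    path: str | Path,
    max_bars: int = 12,
    title: str | None = None,
) -> Path:
    """Horizontal-bar tornado diagram of ICER excursions around the base case.

    Dominance endpoints (infinite excursions) are truncated at twice the
    largest finite excursion and annotated.
    """
    shown = [e for e in entries[:max_bars]]
    finite = [
        abs(v - base_icer)
        for e in shown
        for v in (e.icer_at_low, e.icer_at_high)
        if math.isfinite(v)
    ]
    limit = 2.0 * max(finite) if finite else 1.0

    def clip(v: float) -> float:
        if math.isfinite(v):
            return v
        return base_icer + limit * (1 if v > 0 else -1)

    fig, ax = plt.subplots(figsize=(8, 0.45 * len(shown) + 1.5))
    for i, e in enumerate(reversed(shown)):
        lo, hi = clip(e.icer_at_low), clip(e.icer_at_high)
        left, width = min(lo, hi), abs(hi - lo)
        ax.barh(i, width, left=left, height=0.6, color="#4878d0")
        for v, raw in ((lo, e.icer_at_low), (hi, e.icer_at_high)):
            if not math.isfinite(raw):
                ax.annotate(
                    "dominated" if raw > 0 else "dominant",
                    (v, i),
                    fontsize=7,
                    va="center",
                )
    ax.axvline(base_icer, color="k", lw=1, ls="--")
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.parameter for e in reversed(shown)], fontsize=8)
    ax.set_xlabel("incremental cost per QALY gained")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def ceac_plot(
    points: Sequence[CEACPoint], path: str | Path, title: str | None = None
) -> Path:
    """Acceptability probability vs willingness-to-pay, one line per strategy."""
    strategies = list(points[0].probability_cost_effective)
    wtp = [p.wtp for p in points]
    fig, ax = plt.subplots(figsize=(8, 5))
    for name in strategies:
        ax.plot(wtp, [p.probability_cost_effective[name] for p in points], label=name)
    ax.set_xlabel("willingness-to-pay (currency per QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
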