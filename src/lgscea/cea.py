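"""Incremental cost-effectiveness comparison of the two strategies.

Implements the standard decision-analysis identities: the incremental
cost-effectiveness ratio ICER = dC / dE (USD per positive seizure outcome
gained), net monetary benefit NMB = WTP * E - C, simple-dominance
classification, and a device-replacement break-even horizon. Reporting
rounding (whole dollars, two-decimal effectiveness, whole-percent
incremental effectiveness) is applied only at the output layer; every
computation runs on unrounded expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .tree import EvaluationResult

__all__ = [
    "CEAConfig",
    "CEARow",
    "CEATable",
    "UndefinedICERError",
    "icer",
    "nmb",
    "build_ce_table",
    "preferred_strategy",
    "device_replacement_breakeven",
]

#: Default willingness to pay, USD per positive seizure outcome gained.
DEFAULT_WTP = 200_000.0


class UndefinedICERError(ZeroDivisionError):
    """ICER requested for a zero effectiveness difference."""


@dataclass(frozen=True)
class CEAConfig:
    """Analysis settings: WTP threshold and reporting precision."""

    wtp: float = DEFAULT_WTP
    cost_decimals: int = 0
    effect_decimals: int = 2

    def __post_init__(self) -> None:
        if self.wtp < 0:
            raise ValueError(f"willingness to pay must be >= 0, got {self.wtp}")


@dataclass(frozen=True)
class CEARow:
    strategy: str
    cost: float
    effectiveness: float
    incr_cost: float | None = None
    incr_effectiveness: float | None = None
    icer: float | None = None
    #: "" | "dominated" | "dominant" | "tie"
    dominance: str = ""


@dataclass(frozen=True)
class CEATable:
    rows: tuple[CEARow, ...]
    config: CEAConfig = field(default_factory=CEAConfig, compare=False)

    def row(self, strategy: str) -> CEARow:
        for r in self.rows:
            if r.strategy == strategy:
                return r
        raise KeyError(strategy)

    def to_dataframe(self, rounded: bool = True) -> pd.DataFrame:
        """Tabulate in the conventional column order.

        With ``rounded=True``, costs are reported in whole dollars,
        effectiveness to two decimals, and incremental effectiveness
        additionally as a whole percent.
        """
        rec = []
        for r in self.rows:
            d: dict[str, object] = {
                "strategy": r.strategy.upper(),
                "cost": r.cost,
                "incr_cost": r.incr_cost,
                "effectiveness": r.effectiveness,
                "incr_effectiveness": r.incr_effectiveness,
                "icer": r.icer,
                "dominance": r.dominance,
            }
            if rounded:
                d["cost"] = round(r.cost, self.config.cost_decimals)
                d["incr_cost"] = None if r.incr_cost is None else round(r.incr_cost)
                d["effectiveness"] = round(r.effectiveness, self.config.effect_decimals)
                d["incr_effectiveness"] = (
                    None
                    if r.incr_effectiveness is None
                    else round(r.incr_effectiveness, self.config.effect_decimals)
                )
                d["incr_effectiveness_pct"] = (
                    None
                    if r.incr_effectiveness is None
                    else round(100.0 * r.incr_effectiveness)
                )
                d["icer"] = None if r.icer is None else round(r.icer)
            rec.append(d)
        return pd.DataFrame(rec)


def icer(delta_cost: float, delta_effect: float) -> float:
    """Incremental cost-effectiveness ratio: dC / dE.

    Antisymmetric in the comparison direction (both deltas negate).
    Raises :class:`UndefinedICERError` at dE = 0; callers should then
    report dominance by cost instead of a ratio.
    """
    if delta_effect == 0.0:
        raise UndefinedICERError("effectiveness difference is zero; compare costs directly")
    return delta_cost / delta_effect


def nmb(cost: float, effect: float, wtp: float) -> float:
    """Net monetary benefit: wtp * effect - cost."""
    return wtp * effect - cost


def build_ce_table(
    results: Sequence[tuple[str, EvaluationResult]],
    config: CEAConfig | None = None,
) -> CEATable:
    """Order strategies by expected cost and fill the incremental columns.

    Incremental columns are computed against the previous non-dominated row.
    A more expensive row with no effectiveness gain is flagged ``dominated``
    (``tie`` when both deltas vanish); the ICER is reported only when the
    effectiveness difference is positive.
    """
    if len(results) < 2:
        raise ValueError("need at least two strategies to compare")
    config = config or CEAConfig()
    ordered = sorted(results, key=lambda kv: (kv[1].expected_cost, kv[0]))
    rows: list[CEARow] = []
    ref: tuple[str, EvaluationResult] | None = None
    for name, res in ordered:
        if ref is None:
            rows.append(CEARow(name, res.expected_cost, res.expected_effectiveness))
            ref = (name, res)
            continue
        d_cost = res.expected_cost - ref[1].expected_cost
        d_eff = res.expected_effectiveness - ref[1].expected_effectiveness
        if d_eff > 0.0:
            flag = "dominant" if d_cost < 0.0 else ""
            rows.append(
                CEARow(name, res.expected_cost, res.expected_effectiveness,
                       d_cost, d_eff, icer(d_cost, d_eff), flag)
            )
            ref = (name, res)
        elif d_eff == 0.0 and d_cost == 0.0:
            rows.append(
                CEARow(name, res.expected_cost, res.expected_effectiveness,
                       d_cost, d_eff, None, "tie")
            )
        else:
            rows.append(
                CEARow(name, res.expected_cost, res.expected_effectiveness,
                       d_cost, d_eff, None, "dominated")
            )
    return CEATable(tuple(rows), config)


def preferred_strategy(table: CEATable, wtp: float) -> str:
    """Strategy maximizing net monetary benefit at the given WTP.

    Ties break toward the cheaper strategy. Equivalent, for a positive
    effectiveness difference, to comparing the ICER against the WTP.
    """
    best = min(table.rows, key=lambda r: r.cost)
    for r in table.rows:
        if nmb(r.cost, r.effectiveness, wtp) > nmb(best.cost, best.effectiveness, wtp):
            best = r
    return best.strategy


def device_replacement_breakeven(
    delta_cost_0: float, generator_cost: float, interval_years: float
) -> float:
    """Horizon at which cumulative pulse-generator replacements reach dC.

    VNS pulse generators need replacing on a fixed cycle (about every five
    years); the index-cost advantage of VNS over CC erodes by
    ``generator_cost`` per cycle. Returns the smallest horizon H (a
    multiple of ``interval_years``) with
    ``generator_cost * floor(H / interval) >= delta_cost_0`` — a cost-parity
    definition that ignores any effectiveness difference.
    """
    if generator_cost <= 0 or interval_years <= 0:
        raise ValueError("generator_cost and interval_years must be positive")
    if delta_cost_0 <= 0:
        return 0.0
    replacements = math.ceil(delta_cost_0 / generator_cost)
    return replacements * interval_years
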