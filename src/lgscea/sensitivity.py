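"""Deterministic sensitivity analyses and scenario runner.

One-way analysis moves a single parameter to the low and high ends of its
range (all else at base) and records the CC-vs-VNS ICER at each end; the
tornado ranks parameters by the resulting ICER spread. The two-way
analysis varies two parameters jointly over their ranges and maps, at a
fixed willingness to pay, which strategy has the higher net monetary
benefit; because expected cost and effectiveness are affine in every
single input, the frontier between the two regions is a straight line that
is solved in closed form from endpoint evaluations (the grid raster is
only a visual aid).

The default tornado spans the parameters that carry a published base
estimate. The four complication costs have no published estimate (their
bundled bases are calibrated, and their ranges are arbitrary wide scans
rather than uncertainty intervals), so a tornado bar around them is not
meaningful; they are still fully supported by :func:`one_way` and appear
in the pipeline's wide-scan output, flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cea import CEAConfig, CEATable, build_ce_table, nmb
from .parameters import (
    COST_NAMES,
    PROBABILITY_NAMES,
    UNREPORTED_COST_NAMES,
    CostInputs,
    ProbabilityInputs,
    ScenarioLabel,
    ValidationError,
    get_param,
    load_parameters,
    set_param,
    validate,
)
from .tree import EffectivenessPolicy, EvaluationResult, build_strategy_tree, evaluate

__all__ = [
    "ALL_PARAMETERS",
    "ESTIMATED_PARAMETERS",
    "TornadoEntry",
    "TwoWayGrid",
    "evaluate_arms",
    "one_way",
    "tornado",
    "threshold_value",
    "two_way",
    "run_scenario",
]

ALL_PARAMETERS: tuple[str, ...] = PROBABILITY_NAMES + COST_NAMES
#: Parameters with a published base estimate — the default tornado set.
ESTIMATED_PARAMETERS: tuple[str, ...] = tuple(
    n for n in ALL_PARAMETERS if n not in UNREPORTED_COST_NAMES
)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    metric_at_low: float
    metric_at_high: float
    #: "" normally; "dominated" when an excursion made the CC effectiveness
    #: gain vanish and the finite NMB-based stand-in metric was recorded;
    #: "unreported_base" for wide-scan parameters without a published base.
    flag: str = ""

    @property
    def spread(self) -> float:
        return abs(self.metric_at_high - self.metric_at_low)


@dataclass(frozen=True)
class TwoWayGrid:
    x_parameter: str
    y_parameter: str
    x_values: tuple[float, ...]
    y_values: tuple[float, ...]
    wtp: float
    #: favored[i][j] is the strategy label at (y_values[i], x_values[j]).
    favored: tuple[tuple[str, ...], ...]
    #: (x, y) points of the analytic NMB-indifference frontier.
    contour: tuple[tuple[float, float], ...]


def evaluate_arms(
    pi: ProbabilityInputs, ci: CostInputs, policy: EffectivenessPolicy
) -> dict[str, EvaluationResult]:
    """Build and roll back both strategy trees."""
    return {
        arm: evaluate(build_strategy_tree(arm, pi, ci), policy)
        for arm in ("vns", "cc")
    }


def _deltas(
    pi: ProbabilityInputs, ci: CostInputs, policy: EffectivenessPolicy
) -> tuple[float, float]:
    """(cost, effectiveness) differences, CC minus VNS."""
    res = evaluate_arms(pi, ci, policy)
    return (
        res["cc"].expected_cost - res["vns"].expected_cost,
        res["cc"].expected_effectiveness - res["vns"].expected_effectiveness,
    )


def _metric_at(
    name: str,
    value: float,
    pi: ProbabilityInputs,
    ci: CostInputs,
    policy: EffectivenessPolicy,
    wtp: float,
) -> tuple[float, bool]:
    """CC-vs-VNS ICER with one parameter moved; finite fallback if dominated.

    When the excursion removes the effectiveness gain of CC (dE <= 0) the
    ICER is undefined or meaningless; the recorded stand-in is
    ``wtp - dNMB`` (which exceeds the WTP exactly when CC is not worth
    buying), keeping the tornado finite and sortable. Second return value
    marks that fallback.
    """
    pi2, ci2 = set_param(pi, ci, name, value)
    violations = validate(pi2, ci2)
    if violations:
        raise ValidationError([f"{name}={value}: {v}" for v in violations])
    d_cost, d_eff = _deltas(pi2, ci2, policy)
    if d_eff > 0.0:
        return d_cost / d_eff, False
    return wtp - (wtp * d_eff - d_cost), True


def one_way(
    parameter: str,
    pi: ProbabilityInputs,
    ci: CostInputs,
    policy: EffectivenessPolicy,
    config: CEAConfig | None = None,
) -> TornadoEntry:
    """Evaluate the pipeline at both ends of one parameter's range."""
    config = config or CEAConfig()
    pr = get_param(pi, ci, parameter)
    m_low, dom_low = _metric_at(parameter, pr.low, pi, ci, policy, config.wtp)
    m_high, dom_high = _metric_at(parameter, pr.high, pi, ci, policy, config.wtp)
    flag = "dominated" if (dom_low or dom_high) else ""
    if not flag and parameter in UNREPORTED_COST_NAMES:
        flag = "unreported_base"
    return TornadoEntry(parameter, pr.low, pr.high, m_low, m_high, flag)


def tornado(
    pi: ProbabilityInputs,
    ci: CostInputs,
    policy: EffectivenessPolicy,
    config: CEAConfig | None = None,
    parameters: tuple[str, ...] | None = None,
) -> list[TornadoEntry]:
    """One-way analyses for every parameter, widest spread first.

    ``parameters`` defaults to :data:`ESTIMATED_PARAMETERS`; pass
    :data:`ALL_PARAMETERS` to include the wide-scan complication costs.
    Ties in spread break alphabetically.
    """
    names = parameters if parameters is not None else ESTIMATED_PARAMETERS
    entries = [one_way(n, pi, ci, policy, config) for n in names]
    return sorted(entries, key=lambda e: (-e.spread, e.parameter))


def threshold_value(
    parameter: str,
    pi: ProbabilityInputs,
    ci: CostInputs,
    policy: EffectivenessPolicy,
    wtp: float,
) -> float | None:
    """Parameter value inside its range where the two strategies break even.

    Solves dNMB(v) = wtp * dE(v) - dC(v) = 0 exactly from the two endpoint
    evaluations (dNMB is affine in any single input). Returns None when the
    sign does not change across the range.
    """
    pr = get_param(pi, ci, parameter)

    def dnmb(v: float) -> float:
        pi2, ci2 = set_param(pi, ci, parameter, v)
        d_cost, d_eff = _deltas(pi2, ci2, policy)
        return wtp * d_eff - d_cost

    f_lo, f_hi = dnmb(pr.low), dnmb(pr.high)
    if f_lo == f_hi:
        return None
    root = pr.low + (pr.high - pr.low) * (0.0 - f_lo) / (f_hi - f_lo)
    if pr.low <= root <= pr.high:
        return root
    return None


def two_way(
    x: str,
    y: str,
    pi: ProbabilityInputs,
    ci: CostInputs,
    policy: EffectivenessPolicy,
    config: CEAConfig | None = None,
    step: float = 0.005,
) -> TwoWayGrid:
    """Joint variation of two parameters with an analytic frontier.

    The favored-strategy matrix is rasterized on a ``step`` grid over the
    two ranges (ranges' endpoints always included). The contour holds, for
    each x grid value, the y value where the incremental NMB crosses zero,
    solved in closed form; the raster step therefore affects only the
    matrix, never the frontier.
    """
    if x == y:
        raise ValueError("two-way analysis needs two distinct parameters")
    if step <= 0:
        raise ValueError(f"grid step must be positive, got {step}")
    config = config or CEAConfig()
    xr = get_param(pi, ci, x)
    yr = get_param(pi, ci, y)

    def axis(lo: float, hi: float) -> tuple[float, ...]:
        n = int(np.floor((hi - lo) / step + 1e-9))
        vals = [lo + k * step for k in range(n + 1)]
        if vals[-1] < hi - 1e-12:
            vals.append(hi)
        return tuple(vals)

    xs, ys = axis(xr.low, xr.high), axis(yr.low, yr.high)

    favored_rows: list[tuple[str, ...]] = []
    for yv in ys:
        row = []
        for xv in xs:
            pi2, ci2 = set_param(*set_param(pi, ci, x, xv), y, yv)
            res = evaluate_arms(pi2, ci2, policy)
            nmb_vns = nmb(res["vns"].expected_cost, res["vns"].expected_effectiveness, config.wtp)
            nmb_cc = nmb(res["cc"].expected_cost, res["cc"].expected_effectiveness, config.wtp)
            if nmb_cc > nmb_vns:
                row.append("cc")
            elif nmb_vns > nmb_cc:
                row.append("vns")
            else:  # exact tie: cheaper strategy
                row.append(min(res, key=lambda a: res[a].expected_cost))
        favored_rows.append(tuple(row))

    contour: list[tuple[float, float]] = []
    for xv in xs:
        pi2, ci2 = set_param(pi, ci, x, xv)
        y_star = threshold_value(y, pi2, ci2, policy, config.wtp)
        if y_star is not None:
            contour.append((xv, y_star))

    return TwoWayGrid(x, y, xs, ys, config.wtp, tuple(favored_rows), tuple(contour))


def run_scenario(
    scenario: ScenarioLabel,
    policy: EffectivenessPolicy,
    config: CEAConfig | None = None,
    path: str | None = None,
) -> CEATable:
    """Full pipeline for one scenario's probability set (costs shared)."""
    pi, ci = load_parameters(path, scenario)
    results = evaluate_arms(pi, ci, policy)
    return build_ce_table(sorted(results.items()), config)
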