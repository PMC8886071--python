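"""Seeded generators for decision problems with known ground truth.

Everything the pipeline does — tree rollback, incremental comparison,
sensitivity analysis, calibration — can be exercised on randomly generated
inputs whose correct answers are known at generation time, so the whole
package is testable without any external data. All randomness flows
through a single :func:`numpy.random.default_rng` seeded explicitly; the
same seed reproduces the same object bit-for-bit.

Degenerate features (zero-probability branches, zero terminal costs) are
injected with fixed rates so that edge cases are exercised by
construction rather than by luck.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .calibration import solve_unreported_costs
from .parameters import (
    COST_NAMES,
    PROBABILITY_NAMES,
    CostInputs,
    ParamRange,
    ProbabilityInputs,
    load_parameters,
    set_param,
    validate,
)
from .tree import (
    COMPLICATIONS,
    SEIZURE_OUTCOMES,
    ChanceNode,
    EffectivenessPolicy,
    TerminalNode,
    build_strategy_tree,
    enumerate_paths,
    evaluate,
)

__all__ = [
    "SyntheticProblem",
    "random_tree",
    "sample_parameter_set",
    "plant_and_recover",
]

log = logging.getLogger(__name__)

#: Injection rates for degenerate features.
P_ZERO_BRANCH = 0.15
P_ZERO_COST = 0.10
MAX_TERMINAL_COST = 100_000.0
RESAMPLE_CAP = 10_000


@lru_cache(maxsize=1)
def _default_ranges() -> tuple[ProbabilityInputs, CostInputs]:
    return load_parameters()


@dataclass(frozen=True)
class SyntheticProblem:
    """A random decision tree plus its enumeration-oracle ground truth.

    ``truth_effect`` is the positive-outcome probability under the strict
    policy preset (every complication disqualifies).
    """

    tree: ChanceNode | TerminalNode
    truth_cost: float
    truth_effect: float
    seed: int


def _random_node(
    rng: np.random.Generator, depth: int, max_depth: int, max_branching: int
) -> ChanceNode | TerminalNode:
    if depth >= max_depth or (depth > 0 and rng.random() < 0.35):
        cost = 0.0 if rng.random() < P_ZERO_COST else float(rng.uniform(0, MAX_TERMINAL_COST))
        return TerminalNode(
            seizure_outcome=str(rng.choice(SEIZURE_OUTCOMES)),
            complication=str(rng.choice(COMPLICATIONS)),
            cost_increment=cost,
        )
    k = int(rng.integers(2, max_branching + 1))
    probs = rng.dirichlet(np.ones(k))
    if k >= 3 and rng.random() < P_ZERO_BRANCH:
        probs[0] = 0.0
        probs /= probs.sum()
    branches = tuple(
        (float(p), _random_node(rng, depth + 1, max_depth, max_branching))
        for p in probs
    )
    return ChanceNode(label=f"synthetic-d{depth}", branches=branches)


def random_tree(seed: int, max_depth: int = 3, max_branching: int = 4) -> SyntheticProblem:
    """Generate a random tree; ground truth comes from path enumeration."""
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if max_branching < 2:
        raise ValueError("max_branching must be >= 2")
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, max_branching + 1))
    probs = rng.dirichlet(np.ones(k))
    branches = tuple(
        (float(p), _random_node(rng, 1, max_depth, max_branching)) for p in probs
    )
    tree = ChanceNode(label="synthetic-root", branches=branches)
    paths = enumerate_paths(tree)
    strict = EffectivenessPolicy.preset("strict")
    truth_cost = sum(p * c for p, c, _t in paths)
    truth_effect = sum(
        p
        for p, _c, t in paths
        if t.seizure_outcome in ("free", "reduced") and t.complication not in strict.adverse
    )
    return SyntheticProblem(tree=tree, truth_cost=truth_cost, truth_effect=truth_effect, seed=seed)


def sample_parameter_set(
    seed: int,
    pi_ranges: ProbabilityInputs | None = None,
    ci_ranges: CostInputs | None = None,
) -> tuple[ProbabilityInputs, CostInputs]:
    """Draw each parameter uniformly within its range.

    Rejection-samples (cap 10 000 attempts) until the joint invariants hold
    (per-arm outcome and complication sums); the accepted draw keeps each
    parameter's original low/high so downstream sensitivity analyses stay
    well-defined. The number of attempts is logged.
    """
    if pi_ranges is None or ci_ranges is None:
        base_pi, base_ci = _default_ranges()
        pi_ranges = pi_ranges or base_pi
        ci_ranges = ci_ranges or base_ci
    rng = np.random.default_rng(seed)
    for attempt in range(1, RESAMPLE_CAP + 1):
        pi, ci = pi_ranges, ci_ranges
        for name in PROBABILITY_NAMES + COST_NAMES:
            pr: ParamRange = (
                getattr(pi_ranges, name) if name in PROBABILITY_NAMES else getattr(ci_ranges, name)
            )
            draw = float(rng.uniform(pr.low, pr.high))
            pi, ci = set_param(pi, ci, name, ParamRange(draw, pr.low, pr.high))
        if not validate(pi, ci):
            log.debug("sample_parameter_set(seed=%d): accepted after %d draw(s)", seed, attempt)
            return pi, ci
    raise RuntimeError(
        f"ranges jointly infeasible: no valid draw in {RESAMPLE_CAP} attempts (seed {seed})"
    )


def plant_and_recover(seed: int, path: str | None = None) -> dict[str, float]:
    """Plant random unreported complication costs and recover them.

    Draws c_other_vns and c_deficit uniformly within their ranges,
    generates *unrounded* expected strategy costs through the actual tree
    evaluation, and inverts them with the calibration solver. Exact linear
    algebra: the max relative error should sit at machine precision.
    """
    pi, ci0 = load_parameters(path, "base")
    rng = np.random.default_rng(seed)
    planted_other = float(rng.uniform(ci0.c_other_vns.low, ci0.c_other_vns.high))
    planted_deficit = float(rng.uniform(ci0.c_deficit.low, ci0.c_deficit.high))
    _pi, ci = set_param(pi, ci0, "c_other_vns", planted_other)
    _pi, ci = set_param(pi, ci, "c_deficit", planted_deficit)

    policy = EffectivenessPolicy.preset("reference")
    total_vns = evaluate(build_strategy_tree("vns", pi, ci), policy).expected_cost
    total_cc = evaluate(build_strategy_tree("cc", pi, ci), policy).expected_cost
    solved = solve_unreported_costs(total_vns, total_cc, pi, ci)

    def rel(err: float, truth: float) -> float:
        return abs(err) / max(abs(truth), 1.0)

    return {
        "seed": float(seed),
        "planted_c_other_vns": planted_other,
        "planted_c_deficit": planted_deficit,
        "recovered_c_other_vns": solved.c_other_vns_solved,
        "recovered_c_deficit": solved.c_deficit_solved,
        "max_rel_error": max(
            rel(solved.c_other_vns_solved - planted_other, planted_other),
            rel(solved.c_deficit_solved - planted_deficit, planted_deficit),
        ),
    }
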