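"""One-year decision tree for each surgical strategy arm.

Each arm (VNS or CC) is a two-level tree of chance nodes: an arm-specific
complication node (explicit complications plus a residual "none" branch)
crossed independently with a seizure-outcome node (seizure freedom, >50%
reduction, residual no-improvement). Terminals carry the absolute one-year
cost of their path: index-procedure cost plus the complication's cost
increment. Complication cost increments accrue regardless of seizure
outcome; complications affect *effectiveness* only through the
:class:`EffectivenessPolicy`, which says which complications disqualify an
otherwise positive seizure outcome.

Two evaluation routes are provided and must agree: :func:`evaluate`
(recursive rollback) and :func:`enumerate_paths` (exhaustive depth-first
path enumeration), the latter serving as the independent oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Union

from .parameters import CostInputs, ProbabilityInputs

__all__ = [
    "Arm",
    "SEIZURE_OUTCOMES",
    "COMPLICATIONS",
    "ARM_COMPLICATIONS",
    "TerminalNode",
    "ChanceNode",
    "EffectivenessPolicy",
    "POLICY_PRESETS",
    "EvaluationResult",
    "TreeError",
    "residual_probability",
    "build_strategy_tree",
    "enumerate_paths",
    "evaluate",
    "classify_outcome",
]

Arm = Literal["vns", "cc"]
SEIZURE_OUTCOMES = ("free", "reduced", "no_improvement")
COMPLICATIONS = ("none", "infection", "other_vns", "deficit", "reop")
ARM_COMPLICATIONS: dict[str, tuple[str, ...]] = {
    "vns": ("infection", "other_vns"),
    "cc": ("deficit", "reop"),
}

#: Tolerance on probability conservation at a chance node.
PROB_TOL = 1e-12


class TreeError(ValueError):
    """Invalid tree structure (probability leak, cycle, bad labels)."""


@dataclass(frozen=True)
class TerminalNode:
    """A leaf outcome: seizure result, complication status, absolute cost."""

    seizure_outcome: str
    complication: str
    cost_increment: float

    def __post_init__(self) -> None:
        if self.seizure_outcome not in SEIZURE_OUTCOMES:
            raise TreeError(f"unknown seizure outcome {self.seizure_outcome!r}")
        if self.complication not in COMPLICATIONS:
            raise TreeError(f"unknown complication {self.complication!r}")


@dataclass(frozen=True)
class ChanceNode:
    label: str
    branches: tuple[tuple[float, Union["ChanceNode", TerminalNode]], ...]

    def __post_init__(self) -> None:
        total = 0.0
        for p, _child in self.branches:
            if p < -PROB_TOL:
                raise TreeError(f"{self.label}: negative branch probability {p}")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise TreeError(f"{self.label}: branch probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class EffectivenessPolicy:
    """Which complications disqualify a positive seizure outcome, per arm.

    Presets: ``strict`` counts every complication as disqualifying (the
    literal reading of the outcome definition), ``reference`` counts only
    VNS infection (the reconstruction that reproduces the reported
    effectiveness values), ``none`` counts no complication.
    """

    adverse_for_vns: frozenset[str] = frozenset()
    adverse_for_cc: frozenset[str] = frozenset()
    name: str = field(default="custom", compare=False)

    def __post_init__(self) -> None:
        bad = (self.adverse_for_vns - set(ARM_COMPLICATIONS["vns"])) | (
            self.adverse_for_cc - set(ARM_COMPLICATIONS["cc"])
        )
        if bad:
            raise TreeError(f"complications not valid for their arm: {sorted(bad)}")

    @property
    def adverse(self) -> frozenset[str]:
        return self.adverse_for_vns | self.adverse_for_cc

    @classmethod
    def preset(cls, name: str) -> "EffectivenessPolicy":
        try:
            return POLICY_PRESETS[name]
        except KeyError:
            raise KeyError(
                f"unknown policy {name!r}; expected one of {sorted(POLICY_PRESETS)}"
            ) from None


POLICY_PRESETS: dict[str, EffectivenessPolicy] = {
    "strict": EffectivenessPolicy(
        frozenset({"infection", "other_vns"}), frozenset({"deficit", "reop"}), name="strict"
    ),
    "reference": EffectivenessPolicy(frozenset({"infection"}), frozenset(), name="reference"),
    "none": EffectivenessPolicy(frozenset(), frozenset(), name="none"),
}


@dataclass(frozen=True)
class EvaluationResult:
    """Rollback output for one strategy arm."""

    expected_cost: float
    expected_effectiveness: float
    terminal_distribution: tuple[tuple[float, TerminalNode], ...]


def residual_probability(explicit: Iterable[float], label: str = "node") -> float:
    """1 minus the explicit branch probabilities; clamps tiny negatives."""
    residual = 1.0 - sum(explicit)
    if residual < -PROB_TOL:
        raise TreeError(f"{label}: explicit branch probabilities sum above 1 by {-residual}")
    return max(residual, 0.0)


def build_strategy_tree(arm: Arm, pi: ProbabilityInputs, ci: CostInputs) -> ChanceNode:
    """Assemble the two-level complication x seizure-outcome tree for one arm.

    Zero-probability complication branches are pruned, so an arm with no
    complications degenerates to the bare three-outcome seizure node.
    """
    if arm not in ARM_COMPLICATIONS:
        raise TreeError(f"unknown arm {arm!r}")
    index_cost = (ci.c_vns_index if arm == "vns" else ci.c_cc_index).base
    comp_probs = {c: getattr(pi, f"p_{c}").base for c in ARM_COMPLICATIONS[arm]}
    comp_costs = {c: getattr(ci, f"c_{c}").base for c in ARM_COMPLICATIONS[arm]}
    p_free = getattr(pi, f"p_free_{arm}").base
    p_red = getattr(pi, f"p_red_{arm}").base

    def seizure_node(complication: str, cost: float) -> ChanceNode:
        p_none = residual_probability((p_free, p_red), f"{arm}/seizure")
        branches = (
            (p_free, TerminalNode("free", complication, cost)),
            (p_red, TerminalNode("reduced", complication, cost)),
            (p_none, TerminalNode("no_improvement", complication, cost)),
        )
        return ChanceNode(f"{arm}:seizure|{complication}", branches)

    p_no_comp = residual_probability(comp_probs.values(), f"{arm}/complication")
    explicit = [
        (p, seizure_node(c, index_cost + comp_costs[c]))
        for c, p in comp_probs.items()
        if p > 0.0
    ]
    if not explicit:
        return seizure_node("none", index_cost)
    branches = tuple(explicit) + ((p_no_comp, seizure_node("none", index_cost)),)
    return ChanceNode(f"{arm}:complication", branches)


def enumerate_paths(
    tree: ChanceNode | TerminalNode,
) -> list[tuple[float, float, TerminalNode]]:
    """Exhaustive DFS over root-to-terminal paths.

    Probabilities multiply along edges; the terminal's ``cost_increment`` is
    the absolute path cost. Errors on any cycle (the structure must be a
    tree). This is the evaluation oracle: it shares no code with
    :func:`evaluate`.
    """
    out: list[tuple[float, float, TerminalNode]] = []
    on_path: set[int] = set()

    def walk(node: ChanceNode | TerminalNode, prob: float) -> None:
        if isinstance(node, TerminalNode):
            out.append((prob, node.cost_increment, node))
            return
        if id(node) in on_path:
            raise TreeError(f"cycle detected at node {node.label!r}")
        on_path.add(id(node))
        for p, child in node.branches:
            walk(child, prob * p)
        on_path.remove(id(node))

    walk(tree, 1.0)
    return out


def classify_outcome(
    t: TerminalNode, arm: Arm, policy: EffectivenessPolicy
) -> Literal["positive", "adverse"]:
    """Positive iff seizures improved and no disqualifying complication."""
    if t.complication != "none" and t.complication not in ARM_COMPLICATIONS[arm]:
        raise TreeError(f"complication {t.complication!r} not valid for arm {arm!r}")
    adverse_set = policy.adverse_for_vns if arm == "vns" else policy.adverse_for_cc
    good = t.seizure_outcome in ("free", "reduced") and t.complication not in adverse_set
    return "positive" if good else "adverse"


def evaluate(
    tree: ChanceNode | TerminalNode, policy: EffectivenessPolicy
) -> EvaluationResult:
    """Roll the tree back to expected cost and expected effectiveness.

    Effectiveness is the probability of a positive outcome: a terminal
    counts iff its seizure outcome is freedom or >50% reduction and its
    complication is not in the policy's adverse set (arm membership is
    implied by the complication label, so the union of the per-arm adverse
    sets applies).
    """
    adverse = policy.adverse
    dist: list[tuple[float, TerminalNode]] = []

    def roll(node: ChanceNode | TerminalNode, path_prob: float) -> tuple[float, float]:
        if isinstance(node, TerminalNode):
            dist.append((path_prob, node))
            good = node.seizure_outcome in ("free", "reduced") and node.complication not in adverse
            return node.cost_increment, 1.0 if good else 0.0
        cost = 0.0
        eff = 0.0
        for p, child in node.branches:
            c, e = roll(child, path_prob * p)
            cost += p * c
            eff += p * e
        return cost, eff

    cost, eff = roll(tree, 1.0)
    return EvaluationResult(
        expected_cost=cost, expected_effectiveness=eff, terminal_distribution=tuple(dist)
    )
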