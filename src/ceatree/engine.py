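"""Expected-value evaluation of decision trees.

``rollback`` folds each strategy subtree bottom-up into an expected cost and
expected effect; ``enumerate_paths`` lists every root-to-leaf path with its
product probability and payoffs, which serves as a brute-force oracle for the
rollback (the two must agree to floating-point accuracy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

from .errors import ModelError
from .expressions import evaluate
from .tree_model import (
    AnalysisSettings,
    DecisionTree,
    ParameterSet,
    TreeNode,
    resolve_branch_probabilities,
    validate_tree,
)


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected cost (US$) and effect (QALY) of one strategy."""

    strategy: str
    cost: float
    effect: float


@dataclass(frozen=True)
class PathRecord:
    """One root-to-leaf path: product probability and the leaf payoffs."""

    strategy: str
    leaf: str
    probability: float
    cost: float
    effect: float


def discount_factor(t_years: float, rate: float) -> float:
    """Present-value factor (1 + rate)^(-t) for an outcome occurring at ``t`` years."""
    if t_years < 0:
        raise ValueError("t_years must be non-negative")
    if rate <= -1:
        raise ValueError("rate must exceed -1")
    return (1.0 + rate) ** (-t_years)


def effect_scale(settings: AnalysisSettings) -> float:
    """Factor converting a terminal utility into the reported QALY outcome.

    ``utility_at_horizon`` reports the utility itself (factor 1).
    ``time_integrated`` reports the continuously discounted integral
    u * (1 - (1+r)^-H) / ln(1+r) over the horizon of H years, which reduces
    to u * H when the discount rate is zero.
    """
    if settings.effectiveness_mode == "utility_at_horizon":
        return 1.0
    horizon_years = settings.horizon_months / 12.0
    r = settings.discount_rate
    if r == 0.0:
        return horizon_years
    return (1.0 - (1.0 + r) ** (-horizon_years)) / math.log1p(r)


def _expected(node: TreeNode, env: Mapping[str, float], scale: float) -> Tuple[float, float]:
    if node.kind == "terminal":
        return evaluate(node.cost, env), evaluate(node.effect, env) * scale
    probs = resolve_branch_probabilities(node, env)
    cost = 0.0
    effect = 0.0
    for p, br in zip(probs, node.branches):
        c, e = _expected(br.node, env, scale)
        cost += p * c
        effect += p * e
    return cost, effect


def _require_valid(tree: DecisionTree, params: ParameterSet) -> None:
    report = validate_tree(tree, params)
    if not report.ok:
        raise ModelError("model failed validation:\n" + str(report))


def rollback(tree: DecisionTree, params: ParameterSet,
             settings: AnalysisSettings) -> List[StrategyOutcome]:
    """Expected cost and effect per strategy (refuses to evaluate invalid models)."""
    _require_valid(tree, params)
    env = params.base_values()
    scale = effect_scale(settings)
    return [StrategyOutcome(s.label, *_expected(s, env, scale)) for s in tree.strategies]


def enumerate_paths(tree: DecisionTree, params: ParameterSet,
                    settings: Optional[AnalysisSettings] = None) -> List[PathRecord]:
    """Every root-to-leaf path with product-of-branch probability.

    Aggregating sum(prob * payoff) per strategy reproduces :func:`rollback`.
    """
    _require_valid(tree, params)
    env = params.base_values()
    scale = 1.0 if settings is None else effect_scale(settings)
    records: List[PathRecord] = []

    def walk(strategy: str, node: TreeNode, prob: float) -> None:
        if node.kind == "terminal":
            records.append(
                PathRecord(strategy, node.label, prob,
                           evaluate(node.cost, env), evaluate(node.effect, env) * scale)
            )
            return
        for p, br in zip(resolve_branch_probabilities(node, env), node.branches):
            walk(strategy, br.node, prob * p)

    for s in tree.strategies:
        walk(s.label, s, 1.0)
    return records


def aggregate_paths(records: List[PathRecord]) -> List[StrategyOutcome]:
    """Fold path records into per-strategy expected outcomes (oracle aggregation)."""
    order: List[str] = []
    acc: Dict[str, Tuple[List[float], List[float]]] = {}
    for r in records:
        if r.strategy not in acc:
            acc[r.strategy] = ([], [])
            order.append(r.strategy)
        acc[r.strategy][0].append(r.probability * r.cost)
        acc[r.strategy][1].append(r.probability * r.effect)
    return [StrategyOutcome(s, math.fsum(acc[s][0]), math.fsum(acc[s][1])) for s in order]


@dataclass
class DecisionModel:
    """A tree plus its analysis settings; the unit that sensitivity analyses re-evaluate."""

    tree: DecisionTree
    settings: AnalysisSettings

    def evaluate(self, params: ParameterSet) -> List[StrategyOutcome]:
        return rollback(self.tree, params, self.settings)

    def outcomes(self, params: ParameterSet) -> Dict[str, StrategyOutcome]:
        return {o.strategy: o for o in self.evaluate(params)}
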