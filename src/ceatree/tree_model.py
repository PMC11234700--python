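"""Domain types for decision-tree cost-utility models.

A model is a single decision between treatment strategies.  Each strategy is
a subtree of chance nodes ending in terminal nodes that carry a cost payoff
(US$) and an effect payoff (a utility weight on the 0-1 scale).  Branch
probabilities and payoffs are arithmetic expressions over named parameters,
so the same tree structure can be re-evaluated under perturbed parameter
values for deterministic and probabilistic sensitivity analysis.

The module also builds the bundled anterior-cruciate-ligament (ACL) model:
early surgical reconstruction (ACLR) versus conservative treatment
(structured rehabilitation with optional delayed reconstruction), each arm
with its re-operation chance branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Literal, Mapping, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ExpressionError, ModelError
from .expressions import COMPLEMENT, Expr, evaluate, parameter_names

#: tolerance for chance-node probabilities summing to one
PROB_TOL = 1e-9

Kind = Literal["probability", "utility", "cost", "rate", "count"]

#: admissible (low, high) bounds per parameter kind
KIND_BOUNDS: Dict[str, Tuple[float, float]] = {
    "probability": (0.0, 1.0),
    "utility": (0.0, 1.0),
    "cost": (0.0, math.inf),
    "rate": (0.0, math.inf),
    "count": (0.0, math.inf),
}


class DistributionSpec(BaseModel):
    """Sampling distribution of a parameter for probabilistic sensitivity analysis.

    ``beta`` and ``gamma`` are parameterised by (mean, se) and fitted by the
    method of moments; ``uniform`` spans mean ± sqrt(3)·se; ``fixed`` is
    degenerate at the parameter's base value.
    """

    model_config = ConfigDict(extra="forbid")

    family: Literal["beta", "gamma", "uniform", "fixed"]
    mean: Optional[float] = None
    se: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "DistributionSpec":
        if self.family == "fixed":
            return self
        if self.mean is None or self.se is None:
            raise ValueError(f"{self.family} distribution requires mean and se")
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if self.family == "beta" and not 0.0 < self.mean < 1.0:
            raise ValueError("beta distribution requires mean in (0, 1)")
        if self.family == "gamma" and self.mean <= 0.0:
            raise ValueError("gamma distribution requires mean > 0")
        return self


class Parameter(BaseModel):
    """A named model input with base value, plausible range, and PSA distribution.

    ``low``/``high`` are the deterministic-sensitivity range (defaulting to a
    zero-width range at ``base``); ``dist`` drives probabilistic sampling.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    kind: Kind
    base: float
    low: Optional[float] = None
    high: Optional[float] = None
    dist: Optional[DistributionSpec] = None
    note: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "Parameter":
        if not self.name.isidentifier():
            raise ValueError(f"parameter name {self.name!r} is not a valid identifier")
        if self.low is None:
            self.low = self.base
        if self.high is None:
            self.high = self.base
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"parameter '{self.name}': requires low <= base <= high, "
                f"got {self.low} / {self.base} / {self.high}"
            )
        kmin, kmax = KIND_BOUNDS[self.kind]
        if self.low < kmin or self.high > kmax:
            raise ValueError(
                f"parameter '{self.name}': range [{self.low}, {self.high}] outside "
                f"{self.kind} bounds [{kmin}, {kmax}]"
            )
        return self


class ParameterSet(Mapping[str, Parameter]):
    """Immutable-by-convention collection of :class:`Parameter` keyed by name."""

    def __init__(self, parameters: Iterable[Parameter]):
        self._params: Dict[str, Parameter] = {}
        for p in parameters:
            if p.name in self._params:
                raise ModelError(f"duplicate parameter '{p.name}'")
            self._params[p.name] = p

    def __getitem__(self, name: str) -> Parameter:
        return self._params[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ParameterSet({list(self._params)})"

    @property
    def parameters(self) -> List[Parameter]:
        return list(self._params.values())

    def base_values(self) -> Dict[str, float]:
        """Environment mapping each parameter name to its base value."""
        return {name: p.base for name, p in self._params.items()}

    def with_base(self, updates: Mapping[str, float]) -> "ParameterSet":
        """A new set with base values replaced.

        Values must respect the parameter-kind bounds (probabilities and
        utilities in [0, 1], costs non-negative); the declared low/high range
        is widened if needed so the invariant low <= base <= high holds.
        """
        unknown = set(updates) - set(self._params)
        if unknown:
            raise ModelError("unknown parameter " + ", ".join(sorted(unknown)))
        out: List[Parameter] = []
        for name, p in self._params.items():
            if name not in updates:
                out.append(p)
                continue
            v = float(updates[name])
            kmin, kmax = KIND_BOUNDS[p.kind]
            if not math.isfinite(v) or v < kmin or v > kmax:
                raise ModelError(
                    f"value {v} outside {p.kind} bounds [{kmin}, {kmax}] for parameter '{name}'"
                )
            out.append(
                p.model_copy(update={"base": v, "low": min(p.low, v), "high": max(p.high, v)})
            )
        return ParameterSet(out)

    def replace(self, param: Parameter) -> "ParameterSet":
        """A new set with one parameter object replaced wholesale."""
        if param.name not in self._params:
            raise ModelError(f"unknown parameter {param.name}")
        return ParameterSet(
            [param if p.name == param.name else p for p in self._params.values()]
        )


class TreeNode(BaseModel):
    """A chance or terminal node.

    Chance nodes carry ordered branches, each with a probability expression
    (or the ``complement`` keyword on at most one branch).  Terminal nodes
    carry ``cost`` and ``effect`` payoff expressions.
    """

    model_config = ConfigDict(extra="forbid")

    label: str
    kind: Literal["chance", "terminal"]
    branches: List["Branch"] = Field(default_factory=list)
    cost: Optional[Expr] = None
    effect: Optional[Expr] = None


class Branch(BaseModel):
    model_config = ConfigDict(extra="forbid")

    prob: Expr
    node: TreeNode


TreeNode.model_rebuild()


class DecisionTree(BaseModel):
    """A single decision root whose children are the strategy subtrees."""

    model_config = ConfigDict(extra="forbid")

    label: str = "decision"
    strategies: List[TreeNode]

    @property
    def strategy_labels(self) -> List[str]:
        return [s.label for s in self.strategies]


class AnalysisSettings(BaseModel):
    """Analysis-wide options.

    ``effectiveness_mode='utility_at_horizon'`` reports the terminal utility
    itself as the QALY outcome; ``'time_integrated'`` integrates the utility
    over the horizon with continuous discounting at ``discount_rate``.
    """

    model_config = ConfigDict(extra="forbid")

    wtp: float = 12876.0
    discount_rate: float = 0.03
    horizon_months: float = 18.0
    effectiveness_mode: Literal["utility_at_horizon", "time_integrated"] = "utility_at_horizon"
    psa_draws: int = 5000
    seed: int = 2022

    @model_validator(mode="after")
    def _check(self) -> "AnalysisSettings":
        if self.wtp < 0:
            raise ValueError("wtp must be non-negative")
        if self.psa_draws < 1:
            raise ValueError("psa_draws must be at least 1")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")
        if self.discount_rate <= -1:
            raise ValueError("discount_rate must exceed -1")
        return self


@dataclass
class ValidationReport:
    """Every structural or numerical violation found in a model; empty means evaluable."""

    problems: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems

    def __str__(self) -> str:
        return "OK" if self.ok else "\n".join(f"- {p}" for p in self.problems)


def _expr_problems(expr: Expr, env: Mapping[str, float], where: str) -> List[str]:
    if isinstance(expr, (int, float)):
        return []
    try:
        missing = sorted(parameter_names(expr) - set(env))
    except ExpressionError as exc:
        return [f"{where}: {exc}"]
    return [f"unknown parameter '{n}' in {where}" for n in missing]


def resolve_branch_probabilities(node: TreeNode, env: Mapping[str, float]) -> List[float]:
    """Numeric branch probabilities of a chance node, resolving ``complement``.

    Assumes the node has already passed :func:`validate_tree`; raises
    :class:`ModelError` on violations so it is safe on unvalidated input too.
    """
    probs: List[Optional[float]] = []
    comp_idx: Optional[int] = None
    for i, br in enumerate(node.branches):
        if isinstance(br.prob, str) and br.prob.strip() == COMPLEMENT:
            if comp_idx is not None:
                raise ModelError(f"more than one complement branch at chance node '{node.label}'")
            comp_idx = i
            probs.append(None)
        else:
            probs.append(evaluate(br.prob, env))
    explicit = [p for p in probs if p is not None]
    total = math.fsum(explicit)
    if comp_idx is not None:
        probs[comp_idx] = 1.0 - total
        total = 1.0
    out = [float(p) for p in probs]  # type: ignore[arg-type]
    for p in out:
        if p < -PROB_TOL or p > 1.0 + PROB_TOL:
            raise ModelError(f"branch probability {p:.6g} outside [0, 1] at chance node '{node.label}'")
    if abs(total - 1.0) > PROB_TOL:
        raise ModelError(f"branch probabilities at chance node '{node.label}' sum to {total:.6g}")
    return [min(max(p, 0.0), 1.0) for p in out]


def _walk(node: TreeNode, env: Mapping[str, float], problems: List[str],
          seen: set, depth: int) -> None:
    if depth > 1000:
        problems.append(f"tree deeper than 1000 levels at node '{node.label}' (cycle?)")
        return
    if id(node) in seen:
        problems.append(f"node '{node.label}' appears more than once (aliased or cyclic tree)")
        return
    seen = seen | {id(node)}

    if node.kind == "terminal":
        if node.branches:
            problems.append(f"terminal node '{node.label}' has branches")
        for payoff, what in ((node.cost, "cost"), (node.effect, "effect")):
            if payoff is None:
                problems.append(f"terminal node '{node.label}' missing {what} payoff")
                continue
            errs = _expr_problems(payoff, env, f"{what} payoff of terminal '{node.label}'")
            problems.extend(errs)
            if not errs:
                try:
                    v = evaluate(payoff, env)
                    if not math.isfinite(v):
                        problems.append(f"{what} payoff of terminal '{node.label}' is not finite")
                except ExpressionError as exc:
                    problems.append(str(exc))
        return

    # chance node
    if node.cost is not None or node.effect is not None:
        problems.append(f"chance node '{node.label}' carries payoffs (only terminals may)")
    if not node.branches:
        problems.append(f"chance node '{node.label}' has no branches")
        return
    comp_count = 0
    explicit: List[float] = []
    evaluable = True
    for br in node.branches:
        if isinstance(br.prob, str) and br.prob.strip() == COMPLEMENT:
            comp_count += 1
            continue
        errs = _expr_problems(br.prob, env, f"branch probability at chance node '{node.label}'")
        problems.extend(errs)
        if errs:
            evaluable = False
            continue
        try:
            p = evaluate(br.prob, env)
        except ExpressionError as exc:
            problems.append(str(exc))
            evaluable = False
            continue
        explicit.append(p)
        if p < -PROB_TOL or p > 1.0 + PROB_TOL:
            problems.append(
                f"branch probability {p:.6g} outside [0, 1] at chance node '{node.label}'"
            )
    if comp_count > 1:
        problems.append(f"more than one complement branch at chance node '{node.label}'")
    if evaluable and comp_count <= 1:
        total = math.fsum(explicit)
        if comp_count == 1:
            comp = 1.0 - total
            if comp < -PROB_TOL or comp > 1.0 + PROB_TOL:
                problems.append(
                    f"complement probability {comp:.6g} outside [0, 1] at chance node '{node.label}'"
                )
        elif abs(total - 1.0) > PROB_TOL:
            problems.append(
                f"branch probabilities at chance node '{node.label}' sum to {total:.6g}"
            )
    for br in node.branches:
        _walk(br.node, env, problems, seen, depth + 1)


def validate_tree(tree: DecisionTree, params: ParameterSet) -> ValidationReport:
    """Collect every invariant violation; an empty report means the model is evaluable."""
    problems: List[str] = []
    if not tree.strategies:
        problems.append("decision node has no strategies")
    labels = tree.strategy_labels
    if len(set(labels)) != len(labels):
        problems.append("strategy labels are not unique")
    env = params.base_values()
    for s in tree.strategies:
        _walk(s, env, problems, set(), 0)
    return ValidationReport(problems)


# --------------------------------------------------------------------------
# Bundled ACL model structure
# --------------------------------------------------------------------------

STRATEGY_EARLY_ACLR = "Early ACLR"
STRATEGY_CONSERVATIVE = "Conservative treatment"

#: post-operative rehabilitation cost after any ACL reconstruction
_REHAB_COST = "c_rehab_visit * n_rehab_visits_week * n_rehab_weeks"

#: parameters the ACL tree references
ACL_PARAMETER_NAMES = (
    "p_meniscus_aclr",
    "p_revision_aclr",
    "p_other_aclr",
    "p_arthroscopy_conserv",
    "p_delayed_aclr",
    "u_stable_aclr",
    "u_stable_conserv",
    "du_reop_aclr",
    "du_reop_conserv",
    "c_aclr_direct",
    "c_meniscus_surgery",
    "c_other_surgery",
    "c_rehab_visit",
    "n_rehab_visits_week",
    "n_rehab_weeks",
    "c_base_aclr",
    "c_base_conserv",
)


def _terminal(label: str, cost: str, effect: str) -> TreeNode:
    return TreeNode(label=label, kind="terminal", cost=cost, effect=effect)


def build_acl_tree(params: ParameterSet) -> DecisionTree:
    """The two-strategy ACL-injury treatment tree.

    Early-ACLR arm: everyone receives the index reconstruction and
    post-operative rehabilitation; chance branches cover additional meniscus
    surgery, ACL revision, other surgery, or no further surgery.
    Conservative arm: everyone receives structured rehabilitation; chance
    branches cover meniscus arthroscopy without reconstruction, delayed ACLR
    (with its own post-operative rehabilitation), or a stable knee with
    rehabilitation alone.
    """
    missing = [n for n in ACL_PARAMETER_NAMES if n not in params]
    if missing:
        raise ModelError("unknown parameter " + ", ".join(missing))

    aclr_base = f"c_base_aclr + c_aclr_direct + {_REHAB_COST}"
    early = TreeNode(
        label=STRATEGY_EARLY_ACLR,
        kind="chance",
        branches=[
            Branch(
                prob="p_meniscus_aclr",
                node=_terminal("Meniscus surgery", f"{aclr_base} + c_meniscus_surgery",
                               "u_stable_aclr - du_reop_aclr"),
            ),
            Branch(
                prob="p_revision_aclr",
                node=_terminal("ACL revision", f"{aclr_base} + c_aclr_direct",
                               "u_stable_aclr - du_reop_aclr"),
            ),
            Branch(
                prob="p_other_aclr",
                node=_terminal("Other surgery", f"{aclr_base} + c_other_surgery",
                               "u_stable_aclr - du_reop_aclr"),
            ),
            Branch(
                prob=COMPLEMENT,
                node=_terminal("No further surgery", aclr_base, "u_stable_aclr"),
            ),
        ],
    )
    conserv = TreeNode(
        label=STRATEGY_CONSERVATIVE,
        kind="chance",
        branches=[
            Branch(
                prob="p_arthroscopy_conserv",
                node=_terminal("Meniscus arthroscopy without ACLR",
                               "c_base_conserv + c_meniscus_surgery",
                               "u_stable_conserv - du_reop_conserv"),
            ),
            Branch(
                prob="p_delayed_aclr",
                node=_terminal("Delayed ACLR",
                               f"c_base_conserv + c_aclr_direct + {_REHAB_COST}",
                               "u_stable_conserv - du_reop_conserv"),
            ),
            Branch(
                prob=COMPLEMENT,
                node=_terminal("Stable with rehabilitation alone",
                               "c_base_conserv", "u_stable_conserv"),
            ),
        ],
    )
    return DecisionTree(label="ACL injury treatment", strategies=[early, conserv])
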