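"""Deterministic sensitivity analysis: one-way, two-way, tornado, threshold.

All four analyses share one evaluation core (:func:`evaluate_output`): the
model is re-evaluated with selected parameters moved away from base, and a
scalar output — ICER, NMB difference, or the comparator's cost/effect — is
read off.  Reference and comparator roles are fixed at the base case (the
cheaper strategy is the reference) so that grids and brackets are comparable
across evaluation points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Literal, Mapping, Optional, Sequence, Tuple

import numpy as np

from .cea import Dominance, icer, nmb
from .engine import DecisionModel, StrategyOutcome
from .errors import ModelError
from .tree_model import KIND_BOUNDS, ParameterSet

OutputKind = Literal["icer", "nmb_diff", "cost", "effect"]

#: outputs where *lower* values favour the comparator (ICER below WTP)
_LOWER_FAVOURS_COMPARATOR = {"icer", "cost"}


def base_roles(model: DecisionModel, params: ParameterSet,
               reference: Optional[str] = None,
               comparator: Optional[str] = None) -> Tuple[str, str]:
    """(reference, comparator) labels, defaulting to (cheapest, dearest) at base case."""
    outcomes = model.evaluate(params)
    labels = [o.strategy for o in outcomes]
    for given in (reference, comparator):
        if given is not None and given not in labels:
            raise ModelError(f"unknown strategy '{given}'")
    ordered = sorted(outcomes, key=lambda o: (o.cost, o.strategy))
    ref = reference or ordered[0].strategy
    comp = comparator or next(o.strategy for o in reversed(ordered) if o.strategy != ref)
    if ref == comp:
        raise ModelError("reference and comparator must differ")
    return ref, comp


def _scalar_output(outcomes: Mapping[str, StrategyOutcome], output: OutputKind,
                   ref: str, comp: str, wtp: float) -> float:
    r, c = outcomes[ref], outcomes[comp]
    if output == "icer":
        v = icer(r, c)
        return float("nan") if isinstance(v, Dominance) else v
    if output == "nmb_diff":
        return nmb(c, wtp) - nmb(r, wtp)
    if output == "cost":
        return c.cost
    if output == "effect":
        return c.effect
    raise ValueError(f"unknown output '{output}'")


def evaluate_output(model: DecisionModel, params: ParameterSet, output: OutputKind,
                    reference: str, comparator: str,
                    wtp: Optional[float] = None) -> float:
    """The scalar model output at the given parameter values (single evaluation core)."""
    w = model.settings.wtp if wtp is None else wtp
    return _scalar_output(model.outcomes(params), output, reference, comparator, w)


def one_way(model: DecisionModel, params: ParameterSet, name: str,
            grid: Sequence[float], output: OutputKind = "icer",
            reference: Optional[str] = None, comparator: Optional[str] = None,
            wtp: Optional[float] = None) -> List[Tuple[float, float]]:
    """Re-evaluate the output over a grid of values of one parameter.

    Grid values must respect the parameter's kind bounds (e.g. probabilities
    in [0, 1]); all other parameters stay at base.
    """
    if name not in params:
        raise ModelError(f"unknown parameter {name}")
    ref, comp = base_roles(model, params, reference, comparator)
    return [
        (float(v), evaluate_output(model, params.with_base({name: v}), output, ref, comp, wtp))
        for v in grid
    ]


def two_way(model: DecisionModel, params: ParameterSet, name_a: str, name_b: str,
            grid_a: Sequence[float], grid_b: Sequence[float],
            output: OutputKind = "icer",
            reference: Optional[str] = None, comparator: Optional[str] = None,
            wtp: Optional[float] = None) -> np.ndarray:
    """Output matrix over the Cartesian grid; rows follow ``grid_a``, columns ``grid_b``."""
    for name in (name_a, name_b):
        if name not in params:
            raise ModelError(f"unknown parameter {name}")
    ref, comp = base_roles(model, params, reference, comparator)
    out = np.empty((len(grid_a), len(grid_b)))
    for i, va in enumerate(grid_a):
        for j, vb in enumerate(grid_b):
            trial = params.with_base({name_a: va, name_b: vb})
            out[i, j] = evaluate_output(model, trial, output, ref, comp, wtp)
    return out


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    output_low: float
    output_high: float

    @property
    def spread(self) -> float:
        return abs(self.output_high - self.output_low)


def default_range(params: ParameterSet, name: str) -> Tuple[float, float]:
    """Declared low/high range; if zero-width, ±20% of base clipped to kind bounds."""
    p = params[name]
    if p.high > p.low:
        return p.low, p.high
    kmin, kmax = KIND_BOUNDS[p.kind]
    return max(kmin, 0.8 * p.base), min(kmax, 1.2 * p.base)


def tornado(model: DecisionModel, params: ParameterSet,
            ranges: Optional[Mapping[str, Tuple[float, float]]] = None,
            output: OutputKind = "nmb_diff",
            reference: Optional[str] = None, comparator: Optional[str] = None,
            wtp: Optional[float] = None) -> List[TornadoEntry]:
    """One entry per parameter, sorted by output spread (descending, ties by name).

    Each entry's endpoints are the one-way evaluations at the parameter's low
    and high bound with everything else at base, so tornado bars are exactly
    consistent with :func:`one_way`.
    """
    if ranges is None:
        ranges = {name: default_range(params, name) for name in params}
    ref, comp = base_roles(model, params, reference, comparator)
    entries: List[TornadoEntry] = []
    for name in ranges:
        if name not in params:
            raise ModelError(f"unknown parameter {name}")
        lo, hi = ranges[name]
        base = params[name].base
        if not (lo <= base <= hi):
            raise ModelError(
                f"range [{lo}, {hi}] for parameter '{name}' does not bracket base {base}"
            )
        pts = one_way(model, params, name, [lo, hi], output, ref, comp, wtp)
        entries.append(TornadoEntry(name, lo, hi, pts[0][1], pts[1][1]))
    entries.sort(key=lambda e: (-e.spread, e.parameter))
    return entries


@dataclass(frozen=True)
class ThresholdResult:
    """Solution of output(parameter) = target by bisection.

    ``direction`` states on which side of the threshold the comparator is the
    cost-effective choice (inferred from the output's slope across the
    bracket); when ``converged`` is false, ``value_lo``/``value_hi`` hold the
    diagnostic outputs at the bracket ends and no threshold is reported.
    """

    parameter: str
    threshold: Optional[float]
    direction: Optional[Literal["below", "above"]]
    converged: bool
    iterations: int
    value_at_threshold: Optional[float]
    value_lo: float
    value_hi: float


def solve_threshold(model: DecisionModel, params: ParameterSet, name: str,
                    target: float, bracket: Tuple[float, float],
                    output: OutputKind = "icer",
                    reference: Optional[str] = None, comparator: Optional[str] = None,
                    wtp: Optional[float] = None,
                    rel_tol: float = 1e-8, max_iter: int = 200) -> ThresholdResult:
    """Bisect for the parameter value where the output crosses ``target``.

    Requires a sign change of output − target across ``bracket``; stops when
    |output − target| falls below ``rel_tol`` (relative to the target's
    magnitude) or after ``max_iter`` bisections.
    """
    if name not in params:
        raise ModelError(f"unknown parameter {name}")
    ref, comp = base_roles(model, params, reference, comparator)

    def f(x: float) -> float:
        return evaluate_output(model, params.with_base({name: x}), output, ref, comp, wtp)

    lo, hi = float(bracket[0]), float(bracket[1])
    if lo > hi:
        lo, hi = hi, lo
    v_lo, v_hi = f(lo), f(hi)
    g_lo, g_hi = v_lo - target, v_hi - target

    def direction_for(value_lo: float) -> Literal["below", "above"]:
        # side of the threshold on which the comparator is cost-effective
        favoured_low_side = (value_lo < target) == (output in _LOWER_FAVOURS_COMPARATOR)
        return "below" if favoured_low_side else "above"

    tol = rel_tol * max(1.0, abs(target))
    if abs(g_lo) <= tol or abs(g_hi) <= tol:
        theta = lo if abs(g_lo) <= abs(g_hi) else hi
        return ThresholdResult(name, theta, direction_for(v_lo), True, 0, f(theta), v_lo, v_hi)
    if math.isnan(g_lo) or math.isnan(g_hi) or g_lo * g_hi > 0:
        return ThresholdResult(name, None, None, False, 0, None, v_lo, v_hi)

    iterations = 0
    a, b, ga = lo, hi, g_lo
    mid, g_mid = a, ga
    for iterations in range(1, max_iter + 1):
        mid = 0.5 * (a + b)
        g_mid = f(mid) - target
        if abs(g_mid) <= tol:
            break
        if ga * g_mid <= 0:
            b = mid
        else:
            a, ga = mid, g_mid
    converged = abs(g_mid) <= tol
    return ThresholdResult(name, mid, direction_for(v_lo), converged, iterations,
                           g_mid + target, v_lo, v_hi)
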