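"""Incremental cost-effectiveness statistics and the willingness-to-pay decision rule.

Strategies are compared by the incremental cost-effectiveness ratio
ICER = ΔCost / ΔEffect and by net monetary benefit NMB = WTP·effect − cost.
For two strategies with a positive effect gain, picking the strategy with the
highest NMB is equivalent to comparing the ICER against the WTP threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Sequence, Union

import pandas as pd

from .engine import StrategyOutcome


class Dominance(str, Enum):
    """Qualitative ICER outcomes when the ratio is not informative."""

    DOMINANT = "dominant"        # comparator no dearer and at least as effective
    DOMINATED = "dominated"      # comparator dearer and strictly less effective
    EQUAL_EFFECT = "equal-effect"

    def mirrored(self) -> "Dominance":
        if self is Dominance.DOMINANT:
            return Dominance.DOMINATED
        if self is Dominance.DOMINATED:
            return Dominance.DOMINANT
        return self


ICERResult = Union[float, Dominance]


def icer(reference: StrategyOutcome, comparator: StrategyOutcome) -> ICERResult:
    """ICER of ``comparator`` versus ``reference`` or a dominance flag.

    Returns ΔCost/ΔEffect when the ratio is informative (both deltas positive,
    or both negative — the south-west quadrant, where the ratio is read as
    savings forgone per QALY forgone).  Otherwise returns a flag: ``dominant``
    when the comparator is no dearer and at least as effective (and not
    identical), ``dominated`` when it is dearer and strictly less effective,
    ``equal-effect`` when the effect difference is exactly zero.
    """
    for o in (reference, comparator):
        if not (math.isfinite(o.cost) and math.isfinite(o.effect)):
            raise ValueError(f"non-finite outcome for strategy '{o.strategy}'")
    dc = comparator.cost - reference.cost
    de = comparator.effect - reference.effect
    if dc <= 0 and de >= 0 and (dc < 0 or de > 0):
        return Dominance.DOMINANT
    if dc >= 0 and de < 0:
        return Dominance.DOMINATED
    if de == 0:
        return Dominance.EQUAL_EFFECT
    return dc / de


def nmb(outcome: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit WTP·effect − cost at willingness-to-pay ``wtp`` (US$/QALY)."""
    if wtp < 0:
        raise ValueError("wtp must be non-negative")
    return wtp * outcome.effect - outcome.cost


@dataclass
class CEARow:
    strategy: str
    cost: float
    effect: float
    incr_cost: Optional[float]
    incr_effect: Optional[float]
    icer: Optional[ICERResult]
    nmb: float


@dataclass
class CEATable:
    """Per-strategy costs, effects, incrementals and NMB at a stated WTP.

    Rows are sorted by cost; the reference (cheapest) strategy has empty
    incremental fields.  With more than two strategies each row is compared
    against the previous non-dominated row (a simple frontier sweep, kept
    experimental — the bundled model has exactly two strategies).
    """

    rows: List[CEARow]
    wtp: float

    @property
    def reference(self) -> str:
        return self.rows[0].strategy

    def row(self, strategy: str) -> CEARow:
        for r in self.rows:
            if r.strategy == strategy:
                return r
        raise KeyError(strategy)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "strategy": r.strategy,
                    "cost": r.cost,
                    "incr_cost": r.incr_cost,
                    "effect": r.effect,
                    "incr_effect": r.incr_effect,
                    "icer": r.icer.value if isinstance(r.icer, Dominance) else r.icer,
                    "nmb": r.nmb,
                }
            )
        return pd.DataFrame.from_records(recs)


def build_table(outcomes: Sequence[StrategyOutcome], wtp: float) -> CEATable:
    """CEA table from strategy outcomes, sorted by cost (ties: higher effect first)."""
    if not outcomes:
        raise ValueError("no strategy outcomes")
    ordered = sorted(outcomes, key=lambda o: (o.cost, -o.effect, o.strategy))
    rows: List[CEARow] = [
        CEARow(ordered[0].strategy, ordered[0].cost, ordered[0].effect,
               None, None, None, nmb(ordered[0], wtp))
    ]
    prev = ordered[0]
    for o in ordered[1:]:
        flag_or_ratio = icer(prev, o)
        rows.append(
            CEARow(o.strategy, o.cost, o.effect,
                   o.cost - prev.cost, o.effect - prev.effect,
                   flag_or_ratio, nmb(o, wtp))
        )
        if flag_or_ratio is not Dominance.DOMINATED:
            prev = o
    return CEATable(rows, wtp)


@dataclass(frozen=True)
class Decision:
    strategy: str
    tie: bool = False


def decide(table: CEATable, wtp: Optional[float] = None) -> Decision:
    """Strategy with maximal NMB; ties go to the cheaper strategy with a tie flag.

    ``wtp`` defaults to the WTP the table was built at; passing a different
    value recomputes NMB from the stored (unrounded) costs and effects.
    """
    w = table.wtp if wtp is None else wtp
    scored = [(w * r.effect - r.cost, r) for r in table.rows]
    best = max(s for s, _ in scored)
    tol = 1e-9 * max(1.0, abs(best))
    winners = [r for s, r in scored if best - s <= tol]
    winners.sort(key=lambda r: (r.cost, r.strategy))
    return Decision(winners[0].strategy, tie=len(winners) > 1)
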