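"""Incremental cost-effectiveness analysis.

Strategies are sorted by cost; strictly dominated strategies (weakly higher
cost, weakly lower effectiveness, ties broken by name order) are removed;
then extendedly dominated strategies (whose ICER against the previous
survivor exceeds the ICER of the next survivor against them) are removed
iteratively until ICERs are non-decreasing along the chain. Every strategy's
incremental cost and effect are reported against the most costly
nondominated strategy cheaper than it — the "next least costly,
nondominated strategy" convention of the published base-case table.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

NONDOMINATED = "nondominated"
REFERENCE = "reference"
STRICT = "strictly_dominated"
EXTENDED = "extendedly_dominated"


@dataclass
class FrontierRow:
    name: str
    cost: float
    effectiveness: float
    status: str
    comparator: str | None = None
    incremental_cost: float | None = None
    incremental_effect: float | None = None
    icer: float | None = None


@dataclass
class FrontierResult:
    rows: list[FrontierRow]

    def __getitem__(self, name: str) -> FrontierRow:
        for row in self.rows:
            if row.name == name:
                return row
        raise KeyError(name)

    @property
    def reference(self) -> FrontierRow:
        return next(r for r in self.rows if r.status == REFERENCE)

    def nondominated(self) -> list[FrontierRow]:
        """The efficient chain (reference included), sorted by cost."""
        return [r for r in self.rows if r.status in (REFERENCE, NONDOMINATED)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": r.name,
                    "cost": r.cost,
                    "effectiveness": r.effectiveness,
                    "incremental_cost": r.incremental_cost,
                    "incremental_effectiveness": r.incremental_effect,
                    "icer": r.icer,
                    "status": r.status,
                    "comparator": r.comparator,
                }
                for r in self.rows
            ]
        )


def incremental_analysis(pairs: list[tuple[str, float, float]]) -> FrontierResult:
    """Full incremental analysis of (name, cost, effectiveness) triples."""
    if not pairs:
        raise ValueError("at least one strategy required")
    names = [p[0] for p in pairs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names rejected")
    for name, cost, eff in pairs:
        if not (math.isfinite(cost) and math.isfinite(eff)):
            raise ValueError(f"non-finite cost/effectiveness for {name!r}")

    # stable sort: cost, then effectiveness, then name (deterministic ties)
    items = sorted(pairs, key=lambda p: (p[1], p[2], p[0]))

    strict: set[str] = set()
    for name, cost, eff in items:
        for oname, ocost, oeff in items:
            if oname == name:
                continue
            if ocost <= cost and oeff >= eff:
                if ocost < cost or oeff > eff:
                    strict.add(name)
                elif oname < name:  # exact tie: dominated by name order
                    strict.add(name)

    chain = [p for p in items if p[0] not in strict]
    extended: set[str] = set()
    while True:
        removed = False
        for i in range(1, len(chain) - 1):
            prev_, cur, nxt = chain[i - 1], chain[i], chain[i + 1]
            icer_cur = (cur[1] - prev_[1]) / (cur[2] - prev_[2])
            icer_nxt = (nxt[1] - cur[1]) / (nxt[2] - cur[2])
            if icer_nxt < icer_cur:
                extended.add(cur[0])
                chain.pop(i)
                removed = True
                break
        if not removed:
            return _build_result(items, chain, strict, extended)


def _build_result(items, chain, strict, extended) -> FrontierResult:
    frontier_names = [c[0] for c in chain]
    rows = []
    for name, cost, eff in items:
        if name in strict:
            status = STRICT
        elif name in extended:
            status = EXTENDED
        elif name == chain[0][0]:
            status = REFERENCE
        else:
            status = NONDOMINATED
        # next least costly nondominated strategy (reference has none)
        comp = None
        for cname, ccost, ceff in chain:
            if (ccost, ceff, cname) < (cost, eff, name) and cname != name:
                comp = (cname, ccost, ceff)
        row = FrontierRow(name=name, cost=cost, effectiveness=eff, status=status)
        if comp is not None:
            row.comparator = comp[0]
            row.incremental_cost = cost - comp[1]
            row.incremental_effect = eff - comp[2]
            if status == NONDOMINATED and row.incremental_effect > 0:
                row.icer = row.incremental_cost / row.incremental_effect
        rows.append(row)
    return FrontierResult(rows)


def decide_cost_effective(frontier: FrontierResult, wtp: float) -> str:
    """Highest-effectiveness nondominated strategy with ICER <= WTP.

    Falls back to the reference strategy when no step on the efficient
    chain is affordable at the threshold.
    """
    chosen = frontier.reference.name
    for row in frontier.nondominated():
        if row.status == REFERENCE:
            continue
        if row.icer is not None and row.icer <= wtp:
            chosen = row.name
        else:
            break
    return chosen
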