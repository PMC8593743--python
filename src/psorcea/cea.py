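"""Dominance classification, cost-utility frontier and ICURs.

A strategy is *strictly dominated* when another strategy costs no more and
yields no fewer QALYs (with at least one strict inequality).  *Extended
dominance* removes strategies that are never optimal at any willingness-to-
pay: after sorting the undominated set by cost, any strategy whose
incremental cost-utility ratio (ICUR) against its frontier predecessor
exceeds that of its successor is excluded, iteratively, until the frontier
ICUR sequence is strictly increasing.

ICURs versus the reference (least-cost) strategy are reported for every
strategy, dominated ones included — negative values mean the strategy is
both more expensive and less effective than the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .engine import ArmResult

FRONTIER = "frontier"
STRICTLY_DOMINATED = "strictly_dominated"
EXTENDEDLY_DOMINATED = "extendedly_dominated"


def icur(cost_a: float, qaly_a: float, cost_b: float, qaly_b: float) -> float:
    """Incremental cost-utility ratio of A versus B, AUD per QALY.

    Undefined (NaN) when the QALYs are equal; the sign is preserved, so a
    dominated comparison yields a negative ratio rather than infinity.
    """
    dq = qaly_a - qaly_b
    if dq == 0:
        return math.nan
    return (cost_a - cost_b) / dq


@dataclass
class FrontierReport:
    table: pd.DataFrame
    reference: str

    @property
    def frontier(self) -> list[str]:
        mask = self.table["status"] == FRONTIER
        return list(self.table.loc[mask].sort_values("cost")["strategy"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def classify(results: list[ArmResult]) -> FrontierReport:
    """Dominance status, frontier membership and ICURs for a set of arms."""
    if not results:
        raise ValueError("need at least one ArmResult")
    rows = [{"strategy": r.strategy.name, "cost": r.total_cost,
             "qaly": r.total_qaly} for r in results]
    df = pd.DataFrame(rows).sort_values(["cost", "qaly", "strategy"],
                                        ascending=[True, False, True])
    df = df.reset_index(drop=True)

    # strict dominance: any other point with cost <= and qaly >= (one strict)
    status = {}
    for i, a in df.iterrows():
        dominated = False
        for j, b in df.iterrows():
            if i == j:
                continue
            if (b.cost <= a.cost and b.qaly >= a.qaly
                    and (b.cost < a.cost or b.qaly > a.qaly)):
                dominated = True
                break
        status[a.strategy] = STRICTLY_DOMINATED if dominated else FRONTIER

    # extended dominance among the remaining, by increasing cost
    def frontier_names():
        return [s for s in df.strategy if status[s] == FRONTIER]

    changed = True
    while changed:
        changed = False
        names = frontier_names()
        pts = {s: (float(df.loc[df.strategy == s, "cost"].iloc[0]),
                   float(df.loc[df.strategy == s, "qaly"].iloc[0]))
               for s in names}
        for idx in range(1, len(names) - 1):
            prev, cur, nxt = names[idx - 1], names[idx], names[idx + 1]
            icur_in = _seg_icur(pts[prev], pts[cur])
            icur_out = _seg_icur(pts[cur], pts[nxt])
            if icur_in >= icur_out:
                status[cur] = EXTENDEDLY_DOMINATED
                changed = True
                break

    ref = df.iloc[0].strategy            # least cost (ties: highest QALY)
    ref_cost = float(df.iloc[0].cost)
    ref_qaly = float(df.iloc[0].qaly)
    df["status"] = df["strategy"].map(status)
    df["icur_vs_reference"] = [
        math.nan if s == ref else icur(c, q, ref_cost, ref_qaly)
        for s, c, q in zip(df.strategy, df.cost, df.qaly)
    ]

    # incremental ICURs along the frontier
    inc = {}
    fr = [s for s in df.strategy if status[s] == FRONTIER]
    for prev, cur in zip(fr, fr[1:]):
        pc = float(df.loc[df.strategy == prev, "cost"].iloc[0])
        pq = float(df.loc[df.strategy == prev, "qaly"].iloc[0])
        cc = float(df.loc[df.strategy == cur, "cost"].iloc[0])
        cq = float(df.loc[df.strategy == cur, "qaly"].iloc[0])
        inc[cur] = icur(cc, cq, pc, pq)
    df["icur_vs_next_on_frontier"] = df["strategy"].map(
        lambda s: inc.get(s, math.nan))
    return FrontierReport(table=df, reference=ref)


def _seg_icur(a: tuple[float, float], b: tuple[float, float]) -> float:
    (ca, qa), (cb, qb) = a, b
    if qb == qa:
        return math.inf
    return (cb - ca) / (qb - qa)
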