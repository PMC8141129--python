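"""Incremental cost-effectiveness analysis over one stratum's strategies.

Given each strategy's mean discounted cost and QALYs, this module sorts by
cost, removes strictly dominated strategies (another option is at least as
effective and no more expensive), removes extendedly dominated ones (those
lying above the line joining two neighbours on the cost-effectiveness plane,
i.e. breaking the increasing-ICER sequence along the frontier), computes
incremental costs, incremental QALYs and ICERs between consecutive frontier
strategies, and picks the recommended strategy at a willingness-to-pay
threshold: the most effective frontier strategy whose whole ICER chain from
the cheapest option stays at or below the threshold.  Absent ties this is
exactly the net-monetary-benefit maximizer.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .parameters import StratumKey

__all__ = ["StrategyOutcome", "IncrementalRow", "CEATable",
           "build_cea_table", "nmb", "recommend"]


@dataclass(frozen=True)
class StrategyOutcome:
    """One strategy's mean discounted (cost, QALY) pair."""

    label: str
    cost: float
    qaly: float

    def __post_init__(self) -> None:
        if self.cost < 0 or self.qaly < 0:
            raise ValidationError("cost and qaly must be >= 0")


@dataclass(frozen=True)
class IncrementalRow:
    """One strategy's line of the incremental analysis.

    ``status`` is one of ``dominated`` (strictly), ``extended_dominated``,
    ``dominant`` (weakly dominates every alternative) or ``frontier``.
    Non-dominated rows other than the cheapest carry the comparator (the
    previous frontier strategy), the cost/QALY increments and the ICER.
    """

    label: str
    cost: float
    qaly: float
    status: str
    comparator_label: str | None = None
    delta_cost: float | None = None
    delta_qaly: float | None = None
    icer: float | None = None


@dataclass(frozen=True)
class CEATable:
    stratum: StratumKey | None
    rows: tuple[IncrementalRow, ...]
    recommendation: str

    def row(self, label: str) -> IncrementalRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(f"no row labelled {label!r}")


def nmb(outcome: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit ``wtp * qaly - cost``."""
    if wtp < 0:
        raise ValidationError("wtp must be >= 0")
    return wtp * outcome.qaly - outcome.cost


def _weakly_dominates(a: StrategyOutcome, b: StrategyOutcome) -> bool:
    """a is no worse than b on both axes and strictly better on one."""
    return (a.cost <= b.cost and a.qaly >= b.qaly
            and (a.cost < b.cost or a.qaly > b.qaly))


def build_cea_table(outcomes: list[StrategyOutcome], wtp: float,
                    stratum: StratumKey | None = None) -> CEATable:
    """Full incremental analysis; see the module docstring for the algorithm."""
    if len(outcomes) < 2:
        raise ValidationError("need at least 2 strategies to compare")
    labels = [o.label for o in outcomes]
    if len(set(labels)) != len(labels):
        raise ValidationError("strategy labels must be unique")

    ordered = sorted(outcomes, key=lambda o: (o.cost, -o.qaly, o.label))
    dominated = {o.label for o in ordered
                 if any(_weakly_dominates(other, o) for other in ordered if other is not o)}

    # extended dominance: restore the increasing-ICER sequence on the remainder
    frontier = [o for o in ordered if o.label not in dominated]
    ext_dominated: set[str] = set()
    changed = True
    while changed and len(frontier) >= 3:
        changed = False
        for i in range(1, len(frontier) - 1):
            prev, cur, nxt = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_in = _icer(prev, cur)
            icer_out = _icer(cur, nxt)
            if icer_in is not None and icer_out is not None and icer_in >= icer_out:
                ext_dominated.add(cur.label)
                frontier.pop(i)
                changed = True
                break

    dominant = {o.label for o in ordered
                if all(o.cost <= other.cost and o.qaly >= other.qaly
                       for other in ordered if other is not o)}

    rows = []
    frontier_rows: list[IncrementalRow] = []
    for o in ordered:
        if o.label in dominated:
            rows.append(IncrementalRow(o.label, o.cost, o.qaly, "dominated"))
        elif o.label in ext_dominated:
            rows.append(IncrementalRow(o.label, o.cost, o.qaly, "extended_dominated"))
        else:
            idx = frontier.index(o)
            status = "dominant" if o.label in dominant else "frontier"
            if idx == 0:
                row = IncrementalRow(o.label, o.cost, o.qaly, status)
            else:
                prev = frontier[idx - 1]
                dc, dq = o.cost - prev.cost, o.qaly - prev.qaly
                row = IncrementalRow(o.label, o.cost, o.qaly, status,
                                     comparator_label=prev.label,
                                     delta_cost=dc, delta_qaly=dq,
                                     icer=dc / dq if dq > 0 else None)
            rows.append(row)
            frontier_rows.append(row)

    rec = frontier_rows[0].label
    for row in frontier_rows[1:]:
        if row.icer is None:
            # equal-cost equal-QALY tie: keep the earlier (cheaper-sorted) pick
            continue
        if row.icer <= wtp:
            rec = row.label
        else:
            break
    return CEATable(stratum=stratum, rows=tuple(rows), recommendation=rec)


def _icer(a: StrategyOutcome, b: StrategyOutcome) -> float | None:
    """ICER of b vs the cheaper a; None for a zero-QALY-gain tie."""
    dq = b.qaly - a.qaly
    if dq <= 0:
        return None
    return (b.cost - a.cost) / dq


def recommend(outcomes: list[StrategyOutcome], wtp: float) -> str:
    """Label of the strategy recommended at the given WTP threshold."""
    return build_cea_table(outcomes, wtp).recommendation
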