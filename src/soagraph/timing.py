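"""Planned and actual day arithmetic along schedule paths.

All computation uses signed whole-day offsets with 0 at the schedule's
reference timepoint.  Protocol day *labels* follow the one-based no-day-zero
convention: offset 0 renders "Day 1", offset 28 renders "Day 29", and
pre-reference offsets render "-Day n" (Table-style screening ranges such as
"-Days 28 to 1").  Labels are presentation only.

The core consistency requirement is that a visit's stored plannedTiming
equals the sum of transitionDelay values along the primary path from the
reference timepoint to that visit.  Because planned timings are node
attributes while path timing is an edge summation, the two can drift apart
in hand-authored protocols — :func:`check_timing_consistency` surfaces
exactly those inconsistencies.

Only the default start_to_start transition type participates in day
arithmetic; the other three relationship types are stored and round-tripped
but rejected by the walkers' actual-day computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, TYPE_CHECKING

from .model import Role, SoAGraph, TransitionType

if TYPE_CHECKING:  # pragma: no cover
    from .walker import WalkState


class TimingError(ValueError):
    pass


class TransitionTypeNotSupported(TimingError):
    """Raised when day arithmetic meets a non start_to_start edge."""


def day_number(offset: int) -> int:
    """Protocol day number for an internal offset (no day zero)."""
    return offset + 1 if offset >= 0 else offset


def day_label(offset: int) -> str:
    n = day_number(offset)
    return f"Day {n}" if n > 0 else f"-Day {-n}"


def offset_from_day_number(day: int) -> int:
    if day == 0:
        raise TimingError("protocol day numbering has no day zero")
    return day - 1 if day > 0 else day


@dataclass
class TimingReport:
    """Per-node comparison of stored plannedTiming against the primary-path
    delay summation."""

    per_node: dict[str, dict] = field(default_factory=dict)
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {"perNode": self.per_node, "violations": self.violations}


def primary_offsets(g: SoAGraph) -> dict[str, int]:
    """Offsets of every primary-chain node, anchored at the reference
    timepoint (offset 0); pre-reference nodes get negative offsets by
    reverse summation."""
    chain = g.primary_chain()
    refs = [i for i in chain if g.interaction.nodes[i].reference_timepoint]
    if not refs:
        raise TimingError("graph has no referenceTimepoint node on the "
                          "primary path")
    cumulative = {chain[0]: 0}
    total = 0
    for a, b in zip(chain, chain[1:]):
        edge = g.primary_edge_between(a, b)
        if edge.transition_delay is None:
            raise TimingError(f"primary edge {edge.edge_id} has no "
                              "transitionDelay")
        total += edge.transition_delay
        cumulative[b] = total
    shift = cumulative[refs[0]]
    return {node_id: c - shift for node_id, c in cumulative.items()}


def planned_day(g: SoAGraph, node_id: str) -> int:
    """Planned day offset of a primary-path node (sum of transitionDelay
    from the reference timepoint)."""
    offsets = primary_offsets(g)
    try:
        return offsets[node_id]
    except KeyError:
        label = g.node(node_id).label if _has_node(g, node_id) else node_id
        raise TimingError(f"node {label!r} is not on the primary path "
                          "from the reference timepoint") from None


def _has_node(g: SoAGraph, node_id: str) -> bool:
    try:
        g.node(node_id)
        return True
    except KeyError:
        return False


def check_timing_consistency(g: SoAGraph) -> TimingReport:
    """Compare every primary-path node's stored plannedTiming with the
    computed delay sum; nodes with null plannedTiming (boundary or
    unscheduled) are excluded."""
    offsets = primary_offsets(g)
    report = TimingReport()
    for node_id, computed in offsets.items():
        node = g.interaction.nodes[node_id]
        if node.planned_timing is None:
            continue
        delta = node.planned_timing - computed
        report.per_node[node_id] = {
            "alias": node.label,
            "plannedTiming": node.planned_timing,
            "computedSum": computed,
            "delta": delta,
        }
        if delta != 0:
            report.violations.append(node_id)
    return report


def actual_day(history: "WalkState") -> dict[tuple[str, int], int]:
    """Actual day offset per (nodeID, occurrence) from a subject's walk.

    Days accumulate the delay actually taken on each traversed edge, which
    for unscheduled interludes can differ from the planned schedule.  The
    walk must begin at instantiation_start.
    """
    steps = [s for s in history.trajectory if s.level == "interaction"]
    if not steps or steps[0].role != Role.INSTANTIATION_START:
        raise TimingError("walk history must begin at instantiation_start")
    occurrences: dict[str, int] = {}
    out: dict[tuple[str, int], int] = {}
    for step in steps:
        occ = occurrences.get(step.node_id, 0) + 1
        occurrences[step.node_id] = occ
        out[(step.node_id, occ)] = step.day
    return out


def check_window(planned: int, window: Optional[tuple[int, int]],
                 actual: int) -> bool:
    """True iff ``planned - earlier <= actual <= planned + later``; a
    missing window means (0, 0)."""
    earlier, later = window if window is not None else (0, 0)
    if earlier < 0 or later < 0:
        raise TimingError("window variances must be non-negative")
    return planned - earlier <= actual <= planned + later


def require_computable(edge_type: TransitionType) -> None:
    if edge_type != TransitionType.START_TO_START:
        raise TransitionTypeNotSupported(
            f"transitionType {edge_type.value!r} is stored and round-tripped "
            "but not implemented for day arithmetic (only start_to_start)")
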