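"""Per-subject dynamic traversal of a schedule-of-activities graph.

A walk starts at instantiation start (IS), evaluates the conditional rules
on the current node's outgoing transitions, takes exactly one available
edge per step, and ends at instantiation finish (IF) — either completing
the schedule or leaving it via an implied withdrawal route.  Along the way
the walker maintains the runtime context the rule engine reads: visit
history with actual days, per-node execution counts (repeats), completed
treatment cycles, and subject flags.

Withdrawal is the canonical *undefined* path: rather than drawing an early
exit at every point, a general guard of ``{"withdrawn": false}`` applies to
every transition whose own rule set does not mention the flag, so a subject
proceeds through the schedule until withdrawal flips the flag, at which
point only the implied Vn→IF routes remain available.

Unscheduled visits are taken "as required": the day they occur comes from
the walk policy, not from the planned schedule.  Returning from the
unscheduled node to the planned schedule resumes the target visit's planned
day when it is still reachable; if the unscheduled visit occupied (or
passed) that day, the visit is pushed by the implied edge's minimum-spacing
delay — which is how a late unscheduled visit displaces downstream visits
while an early one leaves the schedule untouched.

Cycle accounting: ``completed_cycles`` increments on arrival at a
cycle_finish node, so the rule engine's prospective index
(completed + 1) makes ``{"n_cycles": "<6"}`` admit exactly five cycles.

A node with no available transition is a *stall* — recorded as a finding on
the walk state, not raised: stalls are precisely the protocol
inconsistencies this kind of model is meant to surface.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Any, Callable, Optional

from .model import GraphLevel, NodeType, Role, SoAGraph, SoATransition
from .rules import EvaluationContext, evaluate_rule_set
from .timing import primary_offsets, require_computable

log = logging.getLogger("soagraph")

_MAX_STEPS = 10_000


class WalkError(ValueError):
    pass


@dataclass(frozen=True)
class TrajectoryStep:
    node_id: str
    label: str
    role: Role
    edge_id: Optional[str]   # edge taken to arrive (None at the start node)
    day: int
    level: str = "interaction"   # "interaction" | "activity"


@dataclass
class WalkState:
    subject_id: str
    current_node: str
    day: int = 0
    trajectory: list[TrajectoryStep] = field(default_factory=list)
    context: EvaluationContext = field(default_factory=EvaluationContext)
    status: str = "active"       # active | finished | withdrawn
    stall: Optional[str] = None

    @property
    def interaction_steps(self) -> list[TrajectoryStep]:
        return [s for s in self.trajectory if s.level == "interaction"]


@dataclass
class WalkPolicy:
    """How choices are made when more than one transition is available.

    ``greedy_primary`` prefers the protocol's main-schedule edge;
    ``scripted`` consumes ``script`` entries (edge ids or target aliases);
    ``random`` draws uniformly from the available set; ``interactive``
    delegates to ``chooser``.  ``flag_schedule`` applies timed subject-flag
    changes, e.g. ``[(10, "withdrawn", True)]``.  ``unscheduled_days`` lists
    the day offsets on which the subject requires an unscheduled visit.
    ``prefer_loops`` / ``prefer_cycles`` make required repeats happen: an
    available self-loop (activity repeat) or cycle-return edge is taken
    while its rule allows.
    """

    mode: str = "greedy_primary"
    script: list[str] = field(default_factory=list)
    flag_schedule: list[tuple[int, str, Any]] = field(default_factory=list)
    unscheduled_days: list[int] = field(default_factory=list)
    initial_flags: dict[str, Any] = field(default_factory=dict)
    prefer_loops: bool = True
    prefer_cycles: bool = True
    walk_activities: bool = True
    strict_rules: bool = False
    chooser: Optional[Callable[[list[SoATransition], WalkState],
                               SoATransition]] = None

    def __post_init__(self) -> None:
        if self.mode == "scripted" and not self.script:
            raise WalkError("scripted mode requires a script")


def start_walk(g: SoAGraph, subject_id: str = "subject-1",
               flags: Optional[dict[str, Any]] = None) -> WalkState:
    start = g.instantiation_start()
    state = WalkState(subject_id=subject_id, current_node=start.node_id)
    state.context.subject_flags["withdrawn"] = False
    if flags:
        state.context.subject_flags.update(flags)
    # anchor the walk so the reference timepoint falls on day offset 0
    # (screening studies begin at a negative offset)
    start_day = _planned_or_none(g, start.node_id)
    state.day = start_day if start_day is not None else 0
    _record_arrival(state, start, None, state.day, "interaction")
    return state


def _record_arrival(state: WalkState, node, edge_id: Optional[str],
                    day: int, level: str) -> None:
    state.trajectory.append(TrajectoryStep(node.node_id, node.label,
                                           node.role, edge_id, day, level))
    counts = state.context.node_execution_counts
    counts[node.node_id] = counts.get(node.node_id, 0) + 1
    if level == "interaction":
        state.context.interaction_history.append((node.label, day))
        if node.role == Role.CYCLE_FINISH:
            state.context.completed_cycles += 1


def _edge_allowed(edge: SoATransition, state: WalkState, *,
                  strict: bool, apply_guard: bool) -> bool:
    rule = edge.transition_rule
    if not evaluate_rule_set(rule, state.context, edge, strict=strict):
        return False
    if apply_guard and not rule.mentions("withdrawn"):
        # the implied global {"withdrawn": false} guard
        if bool(state.context.subject_flags.get("withdrawn", False)):
            return False
    return True


def _order_key(edge: SoATransition) -> tuple:
    return (not edge.primary_path, edge.priority, edge.edge_id)


def available_transitions(g: SoAGraph, state: WalkState, *,
                          level: Optional[GraphLevel] = None,
                          strict: bool = False) -> list[SoATransition]:
    """Outgoing transitions of the current node whose rules evaluate true,
    in deterministic order: primaryPath first, then priority, then edgeID.

    The implied withdrawal guard applies at the interaction level only; an
    empty result is a valid answer (a stall finding, not an error).
    """
    apply_guard = level is None
    edges = (level or g.interaction).outgoing(state.current_node)
    allowed = [e for e in edges
               if _edge_allowed(e, state, strict=strict,
                                apply_guard=apply_guard)]
    return sorted(allowed, key=_order_key)


def step(g: SoAGraph, state: WalkState, edge: SoATransition, *,
         day_override: Optional[int] = None,
         strict: bool = False) -> WalkState:
    """Take one interaction-level transition, updating day, history,
    counters and status in place."""
    if state.status != "active":
        raise WalkError(f"walk is {state.status}; no further steps allowed")
    avail = available_transitions(g, state, strict=strict)
    if edge.edge_id not in {e.edge_id for e in avail}:
        raise WalkError(f"edge {edge.edge_id} is not currently available "
                        f"from {g.node(state.current_node).label!r}")
    require_computable(edge.transition_type)
    source = g.node(edge.source)
    target = g.node(edge.target)
    if day_override is not None:
        if day_override < state.day:
            raise WalkError("cannot schedule a visit before the current day")
        day = day_override
    else:
        delay = edge.transition_delay or 0
        if source.role == Role.UNSCHEDULED and target.role == Role.REGULAR:
            # resume the planned schedule where possible; push by the
            # implied edge's minimum spacing where the day has passed
            planned = _planned_or_none(g, target.node_id)
            if planned is not None:
                delay = max(planned - state.day, delay)
        day = state.day + delay
    state.day = day
    state.current_node = target.node_id
    _record_arrival(state, target, edge.edge_id, day, "interaction")
    if target.role == Role.INSTANTIATION_FINISH:
        withdrawn = bool(state.context.subject_flags.get("withdrawn", False))
        state.status = "withdrawn" if withdrawn else "finished"
    return state


def _planned_or_none(g: SoAGraph, node_id: str) -> Optional[int]:
    try:
        return primary_offsets(g).get(node_id)
    except Exception:
        return None


# ---------------------------------------------------------------------------
# activity-level walking
# ---------------------------------------------------------------------------

def walk_activities(g: SoAGraph, state: WalkState, interaction_id: str,
                    policy: Optional[WalkPolicy] = None) -> None:
    """Execute the activity subgraph of an interaction, AS → ... → AF.

    Activities are contiguous: they run on the interaction's day (plus any
    explicit activity-edge delays).  Rule-gated branches (early exits,
    repeat self-loops) are honored; an available self-loop is taken while
    its repeat rule allows when the policy prefers loops.
    """
    policy = policy or WalkPolicy()
    sub = g.activity_subgraphs.get(interaction_id)
    if sub is None:
        return
    current = sub.find_role(Role.ACTIVITY_START)[0]
    day = state.day
    _record_arrival(state, current, None, day, "activity")
    for _ in range(_MAX_STEPS):
        if current.role == Role.ACTIVITY_FINISH:
            return
        saved = state.current_node
        state.current_node = current.node_id
        try:
            avail = available_transitions(g, state, level=sub,
                                          strict=policy.strict_rules)
        finally:
            state.current_node = saved
        if not avail:
            state.stall = (f"no available activity transition at "
                           f"{current.label!r} in visit "
                           f"{g.node(interaction_id).label!r}")
            log.warning("%s", state.stall)
            return
        chosen = avail[0]
        if policy.prefer_loops:
            loops = [e for e in avail if e.target == current.node_id]
            if loops:
                chosen = loops[0]
        require_computable(chosen.transition_type)
        day += chosen.transition_delay or 0
        current = sub.nodes[chosen.target]
        _record_arrival(state, current, chosen.edge_id, day, "activity")
    raise WalkError("activity walk exceeded the step budget; unbounded "
                    "repeat loop?")


# ---------------------------------------------------------------------------
# end-to-end simulation
# ---------------------------------------------------------------------------

def _apply_flag_schedule(state: WalkState, policy: WalkPolicy,
                         applied: set[int]) -> None:
    for i, (at_day, name, value) in enumerate(policy.flag_schedule):
        if i not in applied and state.day >= at_day:
            state.context.subject_flags[name] = value
            applied.add(i)


def _next_forward_planned(g: SoAGraph, state: WalkState,
                          avail: list[SoATransition]) -> Optional[int]:
    """Planned day of the next scheduled visit reachable from here."""
    candidates = []
    for e in avail:
        target = g.node(e.target)
        if target.role in (Role.REGULAR, Role.CYCLE_START,
                           Role.CYCLE_FINISH):
            p = _planned_or_none(g, target.node_id)
            if p is not None:
                candidates.append(p)
    return min(candidates) if candidates else None


def simulate(g: SoAGraph, policy: Optional[WalkPolicy] = None,
             seed: int = 0) -> WalkState:
    """Run a full subject walk; deterministic for a fixed seed and policy.

    Returns the terminal state: finished, withdrawn, or active-with-stall.
    """
    policy = policy or WalkPolicy()
    rng = random.Random(seed)
    state = start_walk(g, flags=policy.initial_flags)
    pending_unscheduled = sorted(policy.unscheduled_days)
    script = list(policy.script)
    applied_flags: set[int] = set()

    for _ in range(_MAX_STEPS):
        _apply_flag_schedule(state, policy, applied_flags)
        node = g.node(state.current_node)
        if policy.walk_activities and node.type == NodeType.INTERACTION:
            walk_activities(g, state, node.node_id, policy)
            if state.stall:
                return state
        if state.status != "active":
            return state
        avail = available_transitions(g, state,
                                      strict=policy.strict_rules)
        if not avail:
            state.stall = (f"no available transition at "
                           f"{node.label!r} (day {state.day})")
            log.warning("%s", state.stall)
            return state

        chosen: Optional[SoATransition] = None
        override: Optional[int] = None
        while pending_unscheduled and pending_unscheduled[0] < state.day:
            log.warning("unscheduled day %d already passed (day %d); "
                        "dropping", pending_unscheduled[0], state.day)
            pending_unscheduled.pop(0)
        if pending_unscheduled:
            d = pending_unscheduled[0]
            u_edges = [e for e in avail
                       if g.node(e.target).role == Role.UNSCHEDULED]
            next_planned = _next_forward_planned(g, state, avail)
            if u_edges and (next_planned is None or d <= next_planned):
                chosen = u_edges[0]
                override = d
                pending_unscheduled.pop(0)

        if chosen is None:
            if policy.mode == "scripted":
                if not script:
                    raise WalkError("script exhausted before reaching "
                                    "instantiation_finish")
                token = script.pop(0)
                matches = [e for e in avail
                           if e.edge_id == token or
                           g.node(e.target).label == token]
                if not matches:
                    raise WalkError(f"scripted choice {token!r} is not an "
                                    "available transition")
                chosen = matches[0]
            elif policy.mode == "random":
                chosen = rng.choice(avail)
            elif policy.mode == "interactive":
                if policy.chooser is None:
                    raise WalkError("interactive mode requires a chooser")
                chosen = policy.chooser(avail, state)
            else:   # greedy_primary
                chosen = avail[0]
                if policy.prefer_cycles and node.role == Role.CYCLE_FINISH:
                    returns = [e for e in avail
                               if g.node(e.target).role == Role.CYCLE_START]
                    if returns:
                        chosen = returns[0]
        step(g, state, chosen, day_override=override,
             strict=policy.strict_rules)
    raise WalkError("walk exceeded the step budget; unbounded loop?")


def trajectory_table(state: WalkState) -> list[dict]:
    """Flat per-step records (for the CLI's calendar CSV)."""
    return [{"level": s.level, "node": s.label, "role": s.role.value,
             "day": s.day, "dayLabel": _label(s.day), "edge": s.edge_id}
            for s in state.trajectory]


def _label(offset: int) -> str:
    from .timing import day_label
    return day_label(offset)
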