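"""Directed-property-graph model of a clinical study schedule of activities.

A schedule of activities (SoA) is modeled at two levels.  The interaction
level holds the study events a participant is involved in (visits, telephone
contacts, an "unscheduled" visit usable as required) between two boundary
nodes: instantiation start (IS) and instantiation finish (IF).  Each
interaction may own an activity subgraph — the tasks performed at that visit
— delimited by activity start (AS) and activity finish (AF) boundary nodes.
Treatment-cycle designs add cycle start / cycle finish (CS/CF) boundaries
around the repeatable block.

Edges (transitions) carry the wait time before moving from source to target
(``transition_delay``, whole days), an optional permitted variance window,
and a conditional rule set resolving to true (path selectable) or false
(path unavailable) at runtime.

Protocols only draw the explicit schedule; the permitted paths they *imply*
(withdrawing at any visit, taking the unscheduled visit and returning
forward to the planned schedule) are materialized by
:func:`expand_implied_paths`.
"""

from __future__ import annotations

import copy
import uuid
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

import networkx as nx

from .rules import EMPTY_RULE_SET, RuleClause, RuleSet

_NAMESPACE = uuid.uuid5(uuid.NAMESPACE_URL, "soagraph")


def deterministic_id(*parts: str) -> str:
    """UUID v5 derived from the given parts; stable across runs."""
    return str(uuid.uuid5(_NAMESPACE, "/".join(parts)))


def random_id() -> str:
    return str(uuid.uuid4())


class NodeType(str, Enum):
    INTERACTION = "interaction"
    ACTIVITY = "activity"


class Role(str, Enum):
    REGULAR = "regular"
    INSTANTIATION_START = "instantiation_start"
    INSTANTIATION_FINISH = "instantiation_finish"
    ACTIVITY_START = "activity_start"
    ACTIVITY_FINISH = "activity_finish"
    CYCLE_START = "cycle_start"
    CYCLE_FINISH = "cycle_finish"
    UNSCHEDULED = "unscheduled"


class TransitionType(str, Enum):
    START_TO_START = "start_to_start"
    START_TO_FINISH = "start_to_finish"
    FINISH_TO_START = "finish_to_start"
    FINISH_TO_FINISH = "finish_to_finish"


class Origin(str, Enum):
    EXPLICIT = "explicit"
    IMPLIED = "implied"


@dataclass
class SoANode:
    """An interaction (visit/contact) or activity node.

    ``planned_timing`` is a signed whole-day offset from the schedule's
    reference timepoint (offset 0); it is null for boundary and unscheduled
    nodes.  ``planned_window`` is the permitted (earlier, later) variance in
    days; ``planned_duration`` is in hours.  ``alias`` is the short
    protocol label (V1, U, IS ...) used by conditional rules, kept separate
    from the opaque ``node_id``.
    """

    node_id: str = field(default_factory=random_id)
    alias: str = ""
    type: NodeType = NodeType.INTERACTION
    subtype: Optional[str] = None
    name: str = ""
    description: Optional[str] = None
    planned_timing: Optional[int] = None
    reference_timepoint: bool = False
    planned_window: Optional[tuple[int, int]] = None
    planned_duration: Optional[int] = None
    role: Role = Role.REGULAR
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.type = NodeType(self.type)
        self.role = Role(self.role)
        if self.planned_window is not None:
            self.planned_window = (int(self.planned_window[0]),
                                   int(self.planned_window[1]))

    @property
    def label(self) -> str:
        return self.alias or self.name or self.node_id


@dataclass
class SoATransition:
    """A directed edge: the permitted move from ``source`` to ``target``.

    ``transition_delay`` is the wait in whole days before moving (V1>V2 7d).
    ``primary_path`` marks the protocol's explicit main-schedule edge; at
    most one outgoing edge per interaction carries it, which gives the
    timing consistency check a defined summation path.  ``origin`` records
    whether the edge was drawn by the protocol or added by implied-path
    expansion.  ``priority`` breaks ties when ordering available transitions
    (lower first).
    """

    source: str = ""
    target: str = ""
    edge_id: str = field(default_factory=random_id)
    transition_delay: Optional[int] = None
    transition_window: Optional[tuple[int, int]] = None
    transition_type: TransitionType = TransitionType.START_TO_START
    transition_rule: RuleSet = EMPTY_RULE_SET
    primary_path: bool = False
    origin: Origin = Origin.EXPLICIT
    priority: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.transition_type = TransitionType(self.transition_type)
        self.origin = Origin(self.origin)
        if self.transition_window is not None:
            self.transition_window = (int(self.transition_window[0]),
                                      int(self.transition_window[1]))


@dataclass
class GraphLevel:
    """One level of the model: a node dict and an edge dict (insertion
    ordered, keyed by id)."""

    nodes: dict[str, SoANode] = field(default_factory=dict)
    edges: dict[str, SoATransition] = field(default_factory=dict)

    @classmethod
    def from_lists(cls, nodes: Iterable[SoANode],
                   edges: Iterable[SoATransition]) -> "GraphLevel":
        level = cls()
        for n in nodes:
            if n.node_id in level.nodes:
                raise GraphValidationError(ValidationReport([Finding(
                    "error", n.node_id, f"duplicate nodeID {n.node_id!r} "
                    f"(alias {n.label!r})")]))
            level.nodes[n.node_id] = n
        for e in edges:
            if e.edge_id in level.edges:
                raise GraphValidationError(ValidationReport([Finding(
                    "error", e.edge_id, f"duplicate edgeID {e.edge_id!r}")]))
            level.edges[e.edge_id] = e
        return level

    def outgoing(self, node_id: str) -> list[SoATransition]:
        return [e for e in self.edges.values() if e.source == node_id]

    def find_role(self, role: Role) -> list[SoANode]:
        return [n for n in self.nodes.values() if n.role == role]

    def by_alias(self, alias: str) -> SoANode:
        for n in self.nodes.values():
            if n.alias == alias:
                return n
        raise KeyError(alias)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges.values():
            g.add_edge(e.source, e.target, key=e.edge_id)
        return g


@dataclass
class SoAGraph:
    """A full study schedule: interaction graph plus per-visit activity
    subgraphs."""

    graph_id: str = field(default_factory=random_id)
    title: str = ""
    interaction: GraphLevel = field(default_factory=GraphLevel)
    activity_subgraphs: dict[str, GraphLevel] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    # convenience -----------------------------------------------------------
    def node(self, node_id: str) -> SoANode:
        n = self.interaction.nodes.get(node_id)
        if n is not None:
            return n
        for sub in self.activity_subgraphs.values():
            if node_id in sub.nodes:
                return sub.nodes[node_id]
        raise KeyError(node_id)

    def by_alias(self, alias: str) -> SoANode:
        return self.interaction.by_alias(alias)

    def instantiation_start(self) -> SoANode:
        return self.interaction.find_role(Role.INSTANTIATION_START)[0]

    def instantiation_finish(self) -> SoANode:
        return self.interaction.find_role(Role.INSTANTIATION_FINISH)[0]

    def primary_chain(self) -> list[str]:
        """Node ids along the explicit main schedule, IS → ... → IF."""
        start = self.instantiation_start()
        chain = [start.node_id]
        seen = {start.node_id}
        current = start.node_id
        while True:
            nxt = [e for e in self.interaction.outgoing(current)
                   if e.primary_path]
            if not nxt:
                break
            current = nxt[0].target
            if current in seen:
                raise GraphValidationError(ValidationReport([Finding(
                    "error", current, "primary path contains a cycle")]))
            chain.append(current)
            seen.add(current)
        return chain

    def primary_edge_between(self, source: str,
                             target: str) -> SoATransition:
        for e in self.interaction.outgoing(source):
            if e.primary_path and e.target == target:
                return e
        raise KeyError((source, target))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Finding:
    severity: str          # "error" | "warning"
    ref: str               # offending nodeID/edgeID (or graph id)
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    def add(self, severity: str, ref: str, message: str) -> None:
        self.findings.append(Finding(severity, ref, message))

    def __str__(self) -> str:
        if self.ok:
            return "valid (no findings)"
        return "\n".join(f"[{f.severity}] {f.ref}: {f.message}"
                         for f in self.findings)


class GraphValidationError(ValueError):
    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(str(report))


def _validate_level(report: ValidationReport, level: GraphLevel,
                    where: str) -> None:
    for e in level.edges.values():
        for endpoint in (e.source, e.target):
            if endpoint not in level.nodes:
                report.add("error", e.edge_id,
                           f"{where}: edge references unknown node "
                           f"{endpoint!r}")
    for n in level.nodes.values():
        if n.planned_window is not None and (n.planned_window[0] < 0 or
                                             n.planned_window[1] < 0):
            report.add("error", n.node_id,
                       f"{where}: plannedWindow must be non-negative")
    for e in level.edges.values():
        if e.transition_window is not None and (e.transition_window[0] < 0 or
                                                e.transition_window[1] < 0):
            report.add("error", e.edge_id,
                       f"{where}: transitionWindow must be non-negative")


def validate_graph(g: SoAGraph) -> ValidationReport:
    """Structural validation; findings are data, an empty report is valid."""
    report = ValidationReport()
    inter = g.interaction
    _validate_level(report, inter, "interaction level")

    starts = inter.find_role(Role.INSTANTIATION_START)
    finishes = inter.find_role(Role.INSTANTIATION_FINISH)
    if len(starts) != 1:
        report.add("error", g.graph_id,
                   f"expected exactly one instantiation_start node, "
                   f"found {len(starts)}")
    if len(finishes) != 1:
        report.add("error", g.graph_id,
                   f"expected exactly one instantiation_finish node, "
                   f"found {len(finishes)}")

    refs = [n for n in inter.nodes.values() if n.reference_timepoint]
    if len(refs) > 1:
        report.add("error", refs[1].node_id,
                   f"at most one referenceTimepoint node allowed, "
                   f"found {len(refs)}")

    for n in inter.nodes.values():
        if n.role == Role.UNSCHEDULED and n.planned_timing is not None:
            report.add("error", n.node_id,
                       f"unscheduled node {n.label!r} must have null "
                       "plannedTiming")

    for n in inter.nodes.values():
        primaries = [e for e in inter.outgoing(n.node_id) if e.primary_path]
        if len(primaries) > 1:
            report.add("error", n.node_id,
                       f"node {n.label!r} has {len(primaries)} outgoing "
                       "primaryPath edges (at most one allowed)")

    # IF must be reachable from IS along explicit edges
    if len(starts) == 1 and len(finishes) == 1 and not report.errors:
        nxg = nx.MultiDiGraph()
        nxg.add_nodes_from(inter.nodes)
        for e in inter.edges.values():
            if e.origin == Origin.EXPLICIT:
                nxg.add_edge(e.source, e.target)
        if not nx.has_path(nxg, starts[0].node_id, finishes[0].node_id):
            report.add("error", finishes[0].node_id,
                       f"instantiation_finish {finishes[0].label!r} is not "
                       "reachable from instantiation_start along explicit "
                       "edges")

    for owner_id, sub in g.activity_subgraphs.items():
        if owner_id not in inter.nodes:
            report.add("error", owner_id,
                       "activity subgraph attached to unknown interaction "
                       f"node {owner_id!r}")
            continue
        _validate_level(report, sub, f"subgraph of "
                        f"{inter.nodes[owner_id].label!r}")
        n_as = len(sub.find_role(Role.ACTIVITY_START))
        n_af = len(sub.find_role(Role.ACTIVITY_FINISH))
        if n_as != 1 or n_af != 1:
            report.add("error", owner_id,
                       f"activity subgraph of "
                       f"{inter.nodes[owner_id].label!r} must have exactly "
                       f"one activity_start and one activity_finish "
                       f"(found {n_as}/{n_af})")
    return report


def build_graph(nodes: Iterable[SoANode], edges: Iterable[SoATransition],
                *, activity_subgraphs: Optional[dict[str, GraphLevel]] = None,
                graph_id: Optional[str] = None, title: str = "",
                metadata: Optional[dict] = None) -> SoAGraph:
    """Assemble and validate an :class:`SoAGraph`.

    Raises :class:`GraphValidationError` (carrying the report) on duplicate
    ids, dangling edge endpoints, missing IS/IF or any other structural
    error.
    """
    g = SoAGraph(graph_id=graph_id or random_id(), title=title,
                 interaction=GraphLevel.from_lists(nodes, edges),
                 activity_subgraphs=dict(activity_subgraphs or {}),
                 metadata=dict(metadata or {}))
    report = validate_graph(g)
    if report.errors:
        raise GraphValidationError(report)
    return g


# ---------------------------------------------------------------------------
# implied-path expansion
# ---------------------------------------------------------------------------

@dataclass
class ExpansionPolicy:
    """Controls which protocol-implied paths are materialized.

    ``withdrawal`` adds a Vn→IF edge from every non-boundary interaction,
    selectable only once the subject's ``withdrawn`` flag is true.
    ``unscheduled`` adds paired Vn→U / U→Vn edges for every post-reference
    primary-path visit, with auto-generated interactions_exist /
    interactions_not_exist rule pairs on each return edge so only the next
    forward visit is reachable from U, plus a rate-limited U→U self-loop
    (consecutive unscheduled visits do occur, e.g. on adjacent days).
    ``min_spacing`` is the transitionDelay placed on implied unscheduled
    edges: an unscheduled visit landing on a planned visit's day pushes that
    visit by this many days.
    """

    withdrawal: bool = True
    unscheduled: bool = True
    unscheduled_self_loop: bool = True
    unscheduled_repeat_limit: int = 12
    min_spacing: int = 1


def _has_implied_edge(level: GraphLevel, source: str, target: str) -> bool:
    return any(e.source == source and e.target == target and
               e.origin == Origin.IMPLIED for e in level.edges.values())


def expand_implied_paths(g: SoAGraph,
                         policy: Optional[ExpansionPolicy] = None
                         ) -> SoAGraph:
    """Return a new graph with all protocol-implied permitted paths added.

    Explicit nodes and edges are never removed or mutated; re-running the
    expansion adds nothing (idempotent).
    """
    policy = policy or ExpansionPolicy()
    out = copy.deepcopy(g)
    inter = out.interaction
    finish = out.instantiation_finish()
    chain = out.primary_chain()
    chain_aliases = [inter.nodes[i].alias for i in chain]

    if policy.withdrawal:
        for n in list(inter.nodes.values()):
            if n.role in (Role.INSTANTIATION_START,
                          Role.INSTANTIATION_FINISH):
                continue
            if n.type != NodeType.INTERACTION:
                continue
            if _has_implied_edge(inter, n.node_id, finish.node_id):
                continue
            edge = SoATransition(
                source=n.node_id, target=finish.node_id,
                edge_id=deterministic_id(out.graph_id, "implied",
                                         n.alias or n.node_id, "IF"),
                transition_delay=0,
                transition_rule=RuleSet((RuleClause("withdrawn", True),)),
                origin=Origin.IMPLIED)
            inter.edges[edge.edge_id] = edge

    unscheduled_nodes = inter.find_role(Role.UNSCHEDULED)
    if policy.unscheduled and unscheduled_nodes:
        u = unscheduled_nodes[0]
        # visits eligible for unscheduled interludes: regular primary-chain
        # interactions at or after the reference timepoint (protocols draw
        # the "as required" visit over the on-study period only)
        ref_seen = False
        eligible: list[SoANode] = []
        for node_id in chain:
            n = inter.nodes[node_id]
            if n.reference_timepoint:
                ref_seen = True
            if ref_seen and n.role == Role.REGULAR:
                eligible.append(n)
        for n in eligible:
            if not _has_implied_edge(inter, n.node_id, u.node_id):
                edge = SoATransition(
                    source=n.node_id, target=u.node_id,
                    edge_id=deterministic_id(out.graph_id, "implied",
                                             n.alias or n.node_id,
                                             u.alias or "U"),
                    transition_delay=policy.min_spacing,
                    origin=Origin.IMPLIED)
                inter.edges[edge.edge_id] = edge
            if not _has_implied_edge(inter, u.node_id, n.node_id):
                idx = chain_aliases.index(n.alias)
                exist = chain_aliases[:idx]
                not_exist = chain_aliases[idx:]
                rule = RuleSet((
                    RuleClause("interactions_exist", exist),
                    RuleClause("interactions_not_exist", not_exist)))
                edge = SoATransition(
                    source=u.node_id, target=n.node_id,
                    edge_id=deterministic_id(out.graph_id, "implied",
                                             u.alias or "U",
                                             n.alias or n.node_id),
                    transition_delay=policy.min_spacing,
                    transition_rule=rule,
                    origin=Origin.IMPLIED)
                inter.edges[edge.edge_id] = edge
        # forward completion: an unscheduled visit taken after the last
        # planned visit proceeds to IF (same forward-only rule-pair
        # pattern, with IF as the next forward node)
        finish_edge_id = deterministic_id(out.graph_id, "implied-forward",
                                          u.alias or "U", "IF")
        if finish_edge_id not in inter.edges:
            rule = RuleSet((
                RuleClause("interactions_exist", chain_aliases[:-1]),
                RuleClause("interactions_not_exist", chain_aliases[-1:])))
            inter.edges[finish_edge_id] = SoATransition(
                source=u.node_id, target=finish.node_id,
                edge_id=finish_edge_id,
                transition_delay=policy.min_spacing,
                transition_rule=rule, origin=Origin.IMPLIED)
        if (policy.unscheduled_self_loop and
                not _has_implied_edge(inter, u.node_id, u.node_id)):
            edge = SoATransition(
                source=u.node_id, target=u.node_id,
                edge_id=deterministic_id(out.graph_id, "implied",
                                         u.alias or "U", "self"),
                transition_delay=policy.min_spacing,
                transition_rule=RuleSet((RuleClause(
                    "maxRepeats", policy.unscheduled_repeat_limit),)),
                origin=Origin.IMPLIED,
                priority=10)
            inter.edges[edge.edge_id] = edge
    return out


# ---------------------------------------------------------------------------
# attribute-wise graph comparison (round-trip oracle)
# ---------------------------------------------------------------------------

_NODE_ATTRS = ("alias", "type", "subtype", "name", "description",
               "planned_timing", "reference_timepoint", "planned_window",
               "planned_duration", "role", "extra")
_EDGE_ATTRS = ("source", "target", "transition_delay", "transition_window",
               "transition_type", "primary_path", "origin", "priority",
               "extra")


def _diff_levels(out: list[str], a: GraphLevel, b: GraphLevel,
                 where: str) -> None:
    a_nodes, b_nodes = set(a.nodes), set(b.nodes)
    for missing in sorted(a_nodes - b_nodes):
        out.append(f"{where}: node {missing} missing from right graph")
    for extra_n in sorted(b_nodes - a_nodes):
        out.append(f"{where}: node {extra_n} only in right graph")
    for node_id in sorted(a_nodes & b_nodes):
        na, nb = a.nodes[node_id], b.nodes[node_id]
        for attr in _NODE_ATTRS:
            va, vb = getattr(na, attr), getattr(nb, attr)
            if va != vb:
                out.append(f"{where}: node {na.label} attribute {attr}: "
                           f"{va!r} != {vb!r}")
    a_edges, b_edges = set(a.edges), set(b.edges)
    for missing in sorted(a_edges - b_edges):
        out.append(f"{where}: edge {missing} missing from right graph")
    for extra_e in sorted(b_edges - a_edges):
        out.append(f"{where}: edge {extra_e} only in right graph")
    for edge_id in sorted(a_edges & b_edges):
        ea, eb = a.edges[edge_id], b.edges[edge_id]
        for attr in _EDGE_ATTRS:
            va, vb = getattr(ea, attr), getattr(eb, attr)
            if va != vb:
                out.append(f"{where}: edge {edge_id} attribute {attr}: "
                           f"{va!r} != {vb!r}")
        if ea.transition_rule.serialize() != eb.transition_rule.serialize():
            out.append(f"{where}: edge {edge_id} attribute transition_rule: "
                       f"{ea.transition_rule.serialize()!r} != "
                       f"{eb.transition_rule.serialize()!r}")


def graph_diff(a: SoAGraph, b: SoAGraph) -> list[str]:
    """Attribute-wise structural diff; empty list means lossless equality.

    Identity is by nodeID/edgeID; insertion order is not compared.
    """
    out: list[str] = []
    if a.graph_id != b.graph_id:
        out.append(f"graphID: {a.graph_id!r} != {b.graph_id!r}")
    if a.title != b.title:
        out.append(f"title: {a.title!r} != {b.title!r}")
    if a.metadata != b.metadata:
        out.append(f"metadata: {a.metadata!r} != {b.metadata!r}")
    _diff_levels(out, a.interaction, b.interaction, "interaction")
    subs_a, subs_b = set(a.activity_subgraphs), set(b.activity_subgraphs)
    for missing in sorted(subs_a - subs_b):
        out.append(f"activity subgraph {missing} missing from right graph")
    for extra_s in sorted(subs_b - subs_a):
        out.append(f"activity subgraph {extra_s} only in right graph")
    for owner in sorted(subs_a & subs_b):
        _diff_levels(out, a.activity_subgraphs[owner],
                     b.activity_subgraphs[owner], f"subgraph {owner}")
    return out


__all__ = [
    "NodeType", "Role", "TransitionType", "Origin", "SoANode",
    "SoATransition", "GraphLevel", "SoAGraph", "Finding",
    "ValidationReport", "GraphValidationError", "build_graph",
    "validate_graph", "ExpansionPolicy", "expand_implied_paths",
    "graph_diff", "deterministic_id", "random_id", "replace",
]
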