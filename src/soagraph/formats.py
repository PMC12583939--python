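"""Readers and writers: tabular SoA (CSV), native graph JSON, GraphML.

The tabular form is the square table protocols print: visits as columns
with a timing row, activities as rows with X marks.  Its timing-text
grammar is deliberately closed — "Day N", "Days A to B", "-Days A to B"
(pre-reference screening ranges) and "As required" (unscheduled) — anything
else is an error, never a guess.  Screening ranges map to plannedTiming =
earliest day with plannedWindow spanning the range, keeping the timing
consistency equation single-valued.

GraphML export targets visual editing (yEd-style): a two-level colored
layout with display labels, all model attributes carried as data keys, and
activity nodes tagged with their owning interaction.  Unknown keys found on
import are preserved as opaque metadata on the element.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import pandas as pd

from .model import (GraphLevel, NodeType, Origin, Role, SoAGraph, SoANode,
                    SoATransition, TransitionType, deterministic_id)
from .rules import parse_rule_set
from .timing import day_number, offset_from_day_number

PathLike = Union[str, Path]


class TabularError(ValueError):
    pass


class TimingTextError(TabularError):
    pass


# ---------------------------------------------------------------------------
# timing text grammar
# ---------------------------------------------------------------------------

_DAY_RE = re.compile(r"^Day\s+(\d+)$", re.IGNORECASE)
_DAYS_RE = re.compile(r"^Days\s+(\d+)\s+to\s+(\d+)$", re.IGNORECASE)
_NEG_DAYS_RE = re.compile(r"^[-–−]\s*Days?\s+(\d+)\s+to\s+(\d+)$",
                          re.IGNORECASE)
_AS_REQUIRED_RE = re.compile(r"^As\s+required$", re.IGNORECASE)


def parse_timing_text(text: str
                      ) -> tuple[Optional[int],
                                 Optional[tuple[int, int]], bool]:
    """Return (offset, window, unscheduled) for a protocol timing label."""
    s = text.strip()
    if _AS_REQUIRED_RE.match(s):
        return None, None, True
    m = _DAY_RE.match(s)
    if m:
        return offset_from_day_number(int(m.group(1))), None, False
    m = _DAYS_RE.match(s)
    if m:
        a, b = int(m.group(1)), int(m.group(2))
        if b < a:
            raise TimingTextError(f"descending day range in {text!r}")
        return offset_from_day_number(a), (0, b - a), False
    m = _NEG_DAYS_RE.match(s)
    if m:
        a, b = int(m.group(1)), int(m.group(2))   # -a .. -b, a >= b
        if a < b:
            raise TimingTextError(f"descending day range in {text!r}")
        return offset_from_day_number(-a), (0, a - b), False
    raise TimingTextError(f"unrecognized timing text {text!r}; expected "
                          "'Day N', 'Days A to B', '-Days A to B' or "
                          "'As required'")


def render_timing_text(offset: Optional[int],
                       window: Optional[tuple[int, int]],
                       unscheduled: bool) -> str:
    if unscheduled or offset is None:
        return "As required"
    n = day_number(offset)
    if window is None or window == (0, 0):
        return f"Day {n}" if n > 0 else f"-Day {-n}"
    later = window[1]
    if n > 0:
        return f"Days {n} to {n + later}"
    return f"-Days {-n} to {-(n + later)}"


# ---------------------------------------------------------------------------
# tabular SoA
# ---------------------------------------------------------------------------

@dataclass
class VisitColumn:
    visit_id: str
    phase: str = ""
    timing_text: str = ""
    offset: Optional[int] = None
    window: Optional[tuple[int, int]] = None
    unscheduled: bool = False


@dataclass
class TabularSoA:
    """Parsed protocol table: ordered visit columns plus activity rows of
    X-marks (one boolean per visit column)."""

    visit_columns: list[VisitColumn] = field(default_factory=list)
    activity_rows: list[tuple[str, list[bool]]] = field(default_factory=list)
    has_phase_row: bool = False


def read_tabular_soa(source: PathLike) -> TabularSoA:
    df = pd.read_csv(source, header=None, dtype=str,
                     keep_default_na=False, skip_blank_lines=False)
    df = df.fillna("")
    rows = [[str(c).strip() for c in row] for row in df.itertuples(index=False)]
    header: dict[str, list[str]] = {}
    activities: list[tuple[str, list[str]]] = []
    for idx, row in enumerate(rows):
        label, cells = row[0], row[1:]
        if label in ("Phase", "Visit ID", "Visit timing"):
            header[label] = cells
        elif label == "Activity" and not any(cells):
            continue   # section marker row
        else:
            if not label:
                raise TabularError(f"row {idx + 1}: activity row with an "
                                   "empty activity name")
            activities.append((label, cells))
    if "Visit ID" not in header or "Visit timing" not in header:
        raise TabularError("table must contain 'Visit ID' and "
                           "'Visit timing' rows")
    ids = [v for v in header["Visit ID"] if v]
    n = len(ids)
    if len(set(ids)) != n:
        dupes = sorted({v for v in ids if ids.count(v) > 1})
        raise TabularError(f"duplicate visit IDs: {dupes}")
    timings = header["Visit timing"][:n]
    if len([t for t in timings if t]) != n:
        raise TabularError("every visit column needs a timing entry")
    phases = (header.get("Phase", [""] * n) + [""] * n)[:n]

    table = TabularSoA(has_phase_row="Phase" in header)
    for visit_id, phase, timing in zip(ids, phases, timings):
        offset, window, unscheduled = parse_timing_text(timing)
        table.visit_columns.append(VisitColumn(
            visit_id=visit_id, phase=phase, timing_text=timing,
            offset=offset, window=window, unscheduled=unscheduled))
    for name, cells in activities:
        marks = []
        for i in range(n):
            cell = cells[i] if i < len(cells) else ""
            if cell.upper() not in ("", "X"):
                raise TabularError(f"activity {name!r}: mark must be X or "
                                   f"blank, got {cell!r}")
            marks.append(cell.upper() == "X")
        table.activity_rows.append((name, marks))
    return table


def write_tabular_soa(table: TabularSoA, path: PathLike) -> None:
    rows: list[list[str]] = []
    if table.has_phase_row:
        rows.append(["Phase"] + [c.phase for c in table.visit_columns])
    rows.append(["Visit ID"] + [c.visit_id for c in table.visit_columns])
    rows.append(["Visit timing"] + [c.timing_text
                                    for c in table.visit_columns])
    for name, marks in table.activity_rows:
        rows.append([name] + [("X" if m else "") for m in marks])
    pd.DataFrame(rows).to_csv(path, header=False, index=False)


def table_to_graph(table: TabularSoA, *, graph_id: str = "soa",
                   title: str = "") -> SoAGraph:
    """Convert a parsed protocol table to the graph model.

    Scheduled columns become the IS→V1→...→Vn→IF primary chain with delays
    derived from the timing offsets; an unscheduled column becomes a
    floating U node (its routing edges are added later by implied-path
    expansion); each X becomes an activity node in that visit's subgraph,
    between AS and AF in row order.
    """
    def nid(*parts: str) -> str:
        return deterministic_id(graph_id, *parts)

    scheduled = [c for c in table.visit_columns if not c.unscheduled]
    unscheduled = [c for c in table.visit_columns if c.unscheduled]
    if not scheduled:
        raise TabularError("table has no scheduled visit column")
    if not any(c.offset == 0 for c in scheduled):
        raise TabularError("no visit with timing 'Day 1' to serve as the "
                           "reference timepoint")
    offsets = [c.offset for c in scheduled]
    if any(b <= a for a, b in zip(offsets, offsets[1:])):
        raise TabularError("visit timings must be strictly increasing "
                           "across scheduled columns")

    def alias_for(col: VisitColumn) -> str:
        if col.unscheduled:
            return col.visit_id if col.visit_id.upper() != "U" else "U"
        return f"V{col.visit_id}" if col.visit_id.isdigit() else col.visit_id

    nodes = [SoANode(node_id=nid("IS"), alias="IS",
                     name="Instantiation start",
                     role=Role.INSTANTIATION_START)]
    for col in scheduled:
        nodes.append(SoANode(
            node_id=nid(alias_for(col)), alias=alias_for(col),
            name=f"Visit {col.visit_id}", subtype=col.phase or None,
            planned_timing=col.offset,
            reference_timepoint=(col.offset == 0),
            planned_window=col.window))
    for col in unscheduled:
        nodes.append(SoANode(
            node_id=nid(alias_for(col)), alias=alias_for(col),
            name="Unscheduled visit", subtype=col.phase or None,
            role=Role.UNSCHEDULED))
    nodes.append(SoANode(node_id=nid("IF"), alias="IF",
                         name="Instantiation finish",
                         role=Role.INSTANTIATION_FINISH))

    edges = []
    chain_aliases = (["IS"] + [alias_for(c) for c in scheduled] + ["IF"])
    chain_offsets = [offsets[0]] + offsets + [offsets[-1]]
    for (a, oa), (b, ob) in zip(zip(chain_aliases, chain_offsets),
                                zip(chain_aliases[1:], chain_offsets[1:])):
        edges.append(SoATransition(
            source=nid(a), target=nid(b),
            edge_id=nid("edge", a, b),
            transition_delay=ob - oa, primary_path=True))

    subgraphs: dict[str, GraphLevel] = {}
    for col_idx, col in enumerate(table.visit_columns):
        marked = [(name, marks) for name, marks in table.activity_rows
                  if marks[col_idx]]
        if not marked:
            continue
        visit_alias = alias_for(col)
        sub_nodes = [SoANode(node_id=nid(visit_alias, "AS"), alias="AS",
                             name="Activity start", type=NodeType.ACTIVITY,
                             role=Role.ACTIVITY_START)]
        for name, _ in marked:
            sub_nodes.append(SoANode(
                node_id=nid(visit_alias, "activity", name), alias=name,
                name=name, type=NodeType.ACTIVITY))
        sub_nodes.append(SoANode(node_id=nid(visit_alias, "AF"), alias="AF",
                                 name="Activity finish",
                                 type=NodeType.ACTIVITY,
                                 role=Role.ACTIVITY_FINISH))
        sub_edges = []
        for a, b in zip(sub_nodes, sub_nodes[1:]):
            sub_edges.append(SoATransition(
                source=a.node_id, target=b.node_id,
                edge_id=nid(visit_alias, "edge", a.alias, b.alias),
                transition_delay=0, primary_path=True))
        subgraphs[nid(visit_alias)] = GraphLevel.from_lists(sub_nodes,
                                                            sub_edges)

    from .model import build_graph
    return build_graph(nodes, edges, activity_subgraphs=subgraphs,
                       graph_id=graph_id, title=title)


# ---------------------------------------------------------------------------
# native JSON
# ---------------------------------------------------------------------------

def _node_to_dict(n: SoANode) -> dict:
    d: dict = {"nodeID": n.node_id, "alias": n.alias, "type": n.type.value,
               "name": n.name, "role": n.role.value}
    if n.subtype is not None:
        d["subtype"] = n.subtype
    if n.description is not None:
        d["description"] = n.description
    if n.planned_timing is not None:
        d["plannedTiming"] = n.planned_timing
    if n.reference_timepoint:
        d["referenceTimepoint"] = True
    if n.planned_window is not None:
        d["plannedWindow"] = list(n.planned_window)
    if n.planned_duration is not None:
        d["plannedDuration"] = n.planned_duration
    if n.extra:
        d["extra"] = n.extra
    return d


def _node_from_dict(d: dict) -> SoANode:
    window = d.get("plannedWindow")
    return SoANode(node_id=d["nodeID"], alias=d.get("alias", ""),
                   type=NodeType(d["type"]), subtype=d.get("subtype"),
                   name=d.get("name", ""), description=d.get("description"),
                   planned_timing=d.get("plannedTiming"),
                   reference_timepoint=d.get("referenceTimepoint", False),
                   planned_window=tuple(window) if window else None,
                   planned_duration=d.get("plannedDuration"),
                   role=Role(d.get("role", "regular")),
                   extra=d.get("extra", {}))


def _edge_to_dict(e: SoATransition) -> dict:
    d: dict = {"edgeID": e.edge_id, "source": e.source, "target": e.target,
               "transitionType": e.transition_type.value,
               "origin": e.origin.value}
    if e.transition_delay is not None:
        d["transitionDelay"] = e.transition_delay
    if e.transition_window is not None:
        d["transitionWindow"] = list(e.transition_window)
    if e.transition_rule.clauses:
        d["transitionRule"] = e.transition_rule.serialize()
    if e.primary_path:
        d["primaryPath"] = True
    if e.priority:
        d["priority"] = e.priority
    if e.extra:
        d["extra"] = e.extra
    return d


def _edge_from_dict(d: dict) -> SoATransition:
    window = d.get("transitionWindow")
    return SoATransition(
        edge_id=d["edgeID"], source=d["source"], target=d["target"],
        transition_delay=d.get("transitionDelay"),
        transition_window=tuple(window) if window else None,
        transition_type=TransitionType(d.get("transitionType",
                                             "start_to_start")),
        transition_rule=parse_rule_set(d.get("transitionRule", "")),
        primary_path=d.get("primaryPath", False),
        origin=Origin(d.get("origin", "explicit")),
        priority=d.get("priority", 0),
        extra=d.get("extra", {}))


def graph_to_json_dict(g: SoAGraph) -> dict:
    doc: dict = {"graphID": g.graph_id, "title": g.title,
                 "nodes": [_node_to_dict(n)
                           for n in g.interaction.nodes.values()],
                 "edges": [_edge_to_dict(e)
                           for e in g.interaction.edges.values()]}
    if g.activity_subgraphs:
        doc["activitySubgraphs"] = {
            owner: {"nodes": [_node_to_dict(n) for n in sub.nodes.values()],
                    "edges": [_edge_to_dict(e) for e in sub.edges.values()]}
            for owner, sub in g.activity_subgraphs.items()}
    if g.metadata:
        doc["metadata"] = g.metadata
    return doc


def graph_from_json_dict(doc: dict) -> SoAGraph:
    g = SoAGraph(graph_id=doc["graphID"], title=doc.get("title", ""),
                 metadata=doc.get("metadata", {}))
    for nd in doc.get("nodes", []):
        n = _node_from_dict(nd)
        g.interaction.nodes[n.node_id] = n
    for ed in doc.get("edges", []):
        e = _edge_from_dict(ed)
        g.interaction.edges[e.edge_id] = e
    for owner, sub_doc in doc.get("activitySubgraphs", {}).items():
        sub = GraphLevel()
        for nd in sub_doc.get("nodes", []):
            n = _node_from_dict(nd)
            sub.nodes[n.node_id] = n
        for ed in sub_doc.get("edges", []):
            e = _edge_from_dict(ed)
            sub.edges[e.edge_id] = e
        g.activity_subgraphs[owner] = sub
    return g


def write_graph_json(g: SoAGraph, path: PathLike) -> None:
    Path(path).write_text(json.dumps(graph_to_json_dict(g), indent=2) + "\n")


def read_graph_json(path: PathLike) -> SoAGraph:
    return graph_from_json_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

_ROLE_COLORS = {
    Role.INSTANTIATION_START: "#99CC00",
    Role.ACTIVITY_START: "#99CC00",
    Role.CYCLE_START: "#99CC00",
    Role.INSTANTIATION_FINISH: "#FF6666",
    Role.ACTIVITY_FINISH: "#FF6666",
    Role.CYCLE_FINISH: "#FF6666",
    Role.UNSCHEDULED: "#66CCFF",
}

_KNOWN_NODE_KEYS = {"alias", "type", "subtype", "name", "description",
                    "plannedTiming", "referenceTimepoint", "plannedWindow",
                    "plannedDuration", "role", "interaction",
                    "label", "color"}
_KNOWN_EDGE_KEYS = {"edgeID", "transitionDelay", "transitionWindow",
                    "transitionType", "transitionRule", "primaryPath",
                    "origin", "priority", "label"}
_PRESENTATION_KEYS = {"label", "color"}


def _window_str(w: Optional[tuple[int, int]]) -> Optional[str]:
    return None if w is None else f"{w[0]},{w[1]}"


def _window_from_str(s: str) -> tuple[int, int]:
    a, b = s.split(",")
    return (int(a), int(b))


def _node_attrs(n: SoANode, owner: Optional[str]) -> dict:
    color = _ROLE_COLORS.get(
        n.role, "#FFFF99" if n.type == NodeType.ACTIVITY else "#FFFFFF")
    attrs = {"alias": n.alias, "type": n.type.value, "name": n.name,
             "role": n.role.value, "label": n.label, "color": color,
             "referenceTimepoint": n.reference_timepoint}
    if n.subtype is not None:
        attrs["subtype"] = n.subtype
    if n.description is not None:
        attrs["description"] = n.description
    if n.planned_timing is not None:
        attrs["plannedTiming"] = n.planned_timing
    if n.planned_window is not None:
        attrs["plannedWindow"] = _window_str(n.planned_window)
    if n.planned_duration is not None:
        attrs["plannedDuration"] = n.planned_duration
    if owner is not None:
        attrs["interaction"] = owner
    for k, v in n.extra.items():
        attrs[k] = v
    return attrs


def _edge_attrs(e: SoATransition, g: SoAGraph) -> dict:
    attrs = {"edgeID": e.edge_id,
             "transitionType": e.transition_type.value,
             "origin": e.origin.value,
             "primaryPath": e.primary_path,
             "label": e.transition_rule.serialize()}
    if e.transition_delay is not None:
        attrs["transitionDelay"] = e.transition_delay
    if e.transition_window is not None:
        attrs["transitionWindow"] = _window_str(e.transition_window)
    if e.transition_rule.clauses:
        attrs["transitionRule"] = e.transition_rule.serialize()
    if e.priority:
        attrs["priority"] = e.priority
    for k, v in e.extra.items():
        attrs[k] = v
    return attrs


def graph_to_graphml(g: SoAGraph, path: PathLike) -> None:
    """Write a flat, editor-friendly GraphML file: activity nodes carry an
    ``interaction`` key naming their owning visit; display label and
    role-based fill color are included for visual editing."""
    G = nx.MultiDiGraph()
    G.graph["graphID"] = g.graph_id
    G.graph["title"] = g.title
    if g.metadata:
        G.graph["metadata"] = json.dumps(g.metadata, sort_keys=True)
    for n in g.interaction.nodes.values():
        G.add_node(n.node_id, **_node_attrs(n, None))
    for owner, sub in g.activity_subgraphs.items():
        for n in sub.nodes.values():
            G.add_node(n.node_id, **_node_attrs(n, owner))
    for e in g.interaction.edges.values():
        G.add_edge(e.source, e.target, key=e.edge_id, **_edge_attrs(e, g))
    for sub in g.activity_subgraphs.values():
        for e in sub.edges.values():
            G.add_edge(e.source, e.target, key=e.edge_id,
                       **_edge_attrs(e, g))
    nx.write_graphml(G, path)


def _node_from_attrs(node_id: str, attrs: dict) -> SoANode:
    extra = {k: v for k, v in attrs.items()
             if k not in _KNOWN_NODE_KEYS}
    window = attrs.get("plannedWindow")
    return SoANode(
        node_id=node_id, alias=attrs.get("alias", ""),
        type=NodeType(attrs.get("type", "interaction")),
        subtype=attrs.get("subtype"), name=attrs.get("name", ""),
        description=attrs.get("description"),
        planned_timing=attrs.get("plannedTiming"),
        reference_timepoint=bool(attrs.get("referenceTimepoint", False)),
        planned_window=_window_from_str(window) if window else None,
        planned_duration=attrs.get("plannedDuration"),
        role=Role(attrs.get("role", "regular")), extra=extra)


def _edge_from_attrs(source: str, target: str, attrs: dict) -> SoATransition:
    extra = {k: v for k, v in attrs.items()
             if k not in _KNOWN_EDGE_KEYS}
    window = attrs.get("transitionWindow")
    return SoATransition(
        edge_id=attrs["edgeID"], source=source, target=target,
        transition_delay=attrs.get("transitionDelay"),
        transition_window=_window_from_str(window) if window else None,
        transition_type=TransitionType(attrs.get("transitionType",
                                                 "start_to_start")),
        transition_rule=parse_rule_set(attrs.get("transitionRule", "")),
        primary_path=bool(attrs.get("primaryPath", False)),
        origin=Origin(attrs.get("origin", "explicit")),
        priority=attrs.get("priority", 0), extra=extra)


def graph_from_graphml(path: PathLike) -> SoAGraph:
    G = nx.read_graphml(path, force_multigraph=True)
    g = SoAGraph(graph_id=G.graph.get("graphID", ""),
                 title=G.graph.get("title", ""))
    if "metadata" in G.graph:
        g.metadata = json.loads(G.graph["metadata"])
    owners: dict[str, str] = {}
    for node_id, attrs in G.nodes(data=True):
        node = _node_from_attrs(node_id, attrs)
        owner = attrs.get("interaction")
        if owner is None:
            g.interaction.nodes[node_id] = node
        else:
            owners[node_id] = owner
            g.activity_subgraphs.setdefault(owner,
                                            GraphLevel()).nodes[node_id] = \
                node
    for source, target, attrs in G.edges(data=True):
        edge = _edge_from_attrs(source, target, attrs)
        owner = owners.get(source)
        if owner is not None and owners.get(target) == owner:
            g.activity_subgraphs[owner].edges[edge.edge_id] = edge
        else:
            g.interaction.edges[edge.edge_id] = edge
    return g
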