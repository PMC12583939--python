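"""Lossless bidirectional mapping between SoA graphs and FHIR R5
PlanDefinition resources.

Mapping scheme
--------------
* each interaction node → one top-level ``PlanDefinition.action`` carrying
  an ``soaTimePoint`` extension with the node attributes;
* each outgoing transition → one sub-action (``action.action``) carrying an
  ``soaTransition`` extension, with one ``action.condition`` of kind
  ``applicability`` per rule clause (expression language
  ``text/x-soa-rule``, the canonical rule dialect — translation to FHIRPath
  or CQL is downstream tooling, out of scope here);
* each activity node of a visit's subgraph → a nested action under that
  visit's action (again with ``soaTimePoint``), its own outgoing activity
  edges nested one level further;
* ``groupingBehavior = logical-group`` and ``selectionBehavior =
  exactly-one`` on every node action restrict runtime path selection to a
  single transition;
* scheduling is decoupled from task content: activity actions point at stub
  ``ActivityDefinition`` resources via ``relatedAction.targetId``
  (regenerated deterministically from the activity name, so they carry no
  round-trip information).

Delays and windows serialize as integer day values (not ISO-8601 strings)
for bit-exact round trips.  Document serialization is canonical: building
the same graph twice yields byte-identical JSON.

The shipped profile check (``schemas/soa-plan-definition.schema.json``) is a
synthetic JSON-schema reconstruction of the soaPlanDefinition profile at the
structural level, authored for this package; it is applied by a small
built-in schema interpreter.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import Any, Optional

from .model import (GraphLevel, NodeType, Origin, Role, SoAGraph, SoANode,
                    SoATransition, TransitionType, graph_diff)
from .rules import RULE_MEDIA_TYPE, RuleSet, parse_rule_set

DEFAULT_BASE_URL = "https://soagraph.example.org/fhir"


class MappingError(ValueError):
    pass


@dataclass(frozen=True)
class MappingProfile:
    """Stable conversion parameters; must match on both legs of a round
    trip."""

    extension_base_url: str = DEFAULT_BASE_URL
    rule_expression_language: str = RULE_MEDIA_TYPE
    nest_activities: bool = True

    def __post_init__(self) -> None:
        if not self.extension_base_url:
            raise MappingError("extensionBaseUrl must be non-empty")

    @property
    def time_point_url(self) -> str:
        return (f"{self.extension_base_url}/StructureDefinition/"
                "soa-time-point")

    @property
    def transition_url(self) -> str:
        return (f"{self.extension_base_url}/StructureDefinition/"
                "soa-transition")

    @property
    def metadata_url(self) -> str:
        return (f"{self.extension_base_url}/StructureDefinition/"
                "soa-graph-metadata")


DEFAULT_PROFILE = MappingProfile()


# ---------------------------------------------------------------------------
# graph -> PlanDefinition
# ---------------------------------------------------------------------------

def _sub(url: str, key: str, value: Any) -> dict:
    return {"url": url, key: value}


def _window_ext(url: str, window: tuple[int, int]) -> dict:
    return {"url": url, "extension": [
        _sub("earlier", "valueInteger", window[0]),
        _sub("later", "valueInteger", window[1]),
    ]}


def _time_point_extension(node: SoANode, profile: MappingProfile) -> dict:
    subs: list[dict] = [
        _sub("type", "valueCode", node.type.value),
        _sub("role", "valueCode", node.role.value),
        _sub("alias", "valueString", node.alias),
    ]
    if node.subtype is not None:
        subs.append(_sub("subtype", "valueString", node.subtype))
    if node.planned_timing is not None:
        subs.append(_sub("plannedTiming", "valueInteger",
                         node.planned_timing))
    if node.reference_timepoint:
        subs.append(_sub("referenceTimepoint", "valueBoolean", True))
    if node.planned_window is not None:
        subs.append(_window_ext("plannedWindow", node.planned_window))
    if node.planned_duration is not None:
        subs.append(_sub("plannedDuration", "valueQuantity",
                         {"value": node.planned_duration, "unit": "h"}))
    if node.extra:
        subs.append(_sub("extra", "valueString",
                         json.dumps(node.extra, sort_keys=True)))
    return {"url": profile.time_point_url, "extension": subs}


def _transition_extension(edge: SoATransition,
                          profile: MappingProfile) -> dict:
    subs: list[dict] = [
        _sub("source", "valueString", edge.source),
        _sub("target", "valueString", edge.target),
        _sub("transitionType", "valueCode", edge.transition_type.value),
        _sub("origin", "valueCode", edge.origin.value),
    ]
    if edge.transition_delay is not None:
        subs.append(_sub("transitionDelay", "valueInteger",
                         edge.transition_delay))
    if edge.transition_window is not None:
        subs.append(_window_ext("transitionWindow", edge.transition_window))
    if edge.primary_path:
        subs.append(_sub("primaryPath", "valueBoolean", True))
    if edge.priority:
        subs.append(_sub("priority", "valueInteger", edge.priority))
    if edge.extra:
        subs.append(_sub("extra", "valueString",
                         json.dumps(edge.extra, sort_keys=True)))
    return {"url": profile.transition_url, "extension": subs}


def _edge_action(edge: SoATransition, g: SoAGraph,
                 profile: MappingProfile) -> dict:
    action: dict = {
        "id": edge.edge_id,
        "title": f"{g.node(edge.source).label}>{g.node(edge.target).label}",
        "extension": [_transition_extension(edge, profile)],
    }
    if edge.transition_rule.clauses:
        action["condition"] = [
            {"kind": "applicability",
             "expression": {
                 "language": profile.rule_expression_language,
                 "expression": clause.serialize()}}
            for clause in edge.transition_rule.clauses]
    return action


def activity_definition_id(name: str) -> str:
    slug = re.sub(r"[^A-Za-z0-9]+", "-", name).strip("-").lower()
    return f"ad-{slug or 'activity'}"


def _node_action(node: SoANode, level: GraphLevel, g: SoAGraph,
                 profile: MappingProfile, *, nested: bool) -> dict:
    action: dict = {"id": node.node_id, "title": node.name or node.alias}
    if node.description is not None:
        action["description"] = node.description
    action["extension"] = [_time_point_extension(node, profile)]
    if nested and node.role == Role.REGULAR:
        action["relatedAction"] = [{
            "targetId": activity_definition_id(node.name or node.alias),
            "relationship": "concurrent"}]
    action["groupingBehavior"] = "logical-group"
    action["selectionBehavior"] = "exactly-one"
    children: list[dict] = [_edge_action(e, g, profile)
                            for e in level.edges.values()
                            if e.source == node.node_id]
    if not nested and profile.nest_activities:
        sub = g.activity_subgraphs.get(node.node_id)
        if sub is not None:
            children.extend(_node_action(a, sub, g, profile, nested=True)
                            for a in sub.nodes.values())
    if children:
        action["action"] = children
    return action


def to_plan_definition(g: SoAGraph,
                       profile: MappingProfile = DEFAULT_PROFILE) -> dict:
    """Serialize an SoA graph to a FHIR R5 PlanDefinition dict.

    Requires mappability (no dangling edge endpoints), not full structural
    validity: partial schedules are legitimately exchangeable.
    """
    for level in [g.interaction, *g.activity_subgraphs.values()]:
        for e in level.edges.values():
            for endpoint in (e.source, e.target):
                if endpoint not in level.nodes:
                    raise MappingError(
                        f"unmappable graph: edge {e.edge_id} references "
                        f"unknown node {endpoint!r}")
    doc: dict = {
        "resourceType": "PlanDefinition",
        "id": g.graph_id,
        "title": g.title,
        "status": "draft",
    }
    if g.metadata:
        doc["extension"] = [{
            "url": profile.metadata_url,
            "valueString": json.dumps(g.metadata, sort_keys=True)}]
    doc["action"] = [
        _node_action(n, g.interaction, g, profile, nested=False)
        for n in g.interaction.nodes.values()]
    return doc


def plan_definition_json(g: SoAGraph,
                         profile: MappingProfile = DEFAULT_PROFILE) -> str:
    """Canonical JSON text (stable key order and ID mapping)."""
    return json.dumps(to_plan_definition(g, profile), indent=2) + "\n"


# ---------------------------------------------------------------------------
# PlanDefinition -> graph
# ---------------------------------------------------------------------------

def _find_extension(element: dict, url: str) -> Optional[dict]:
    for ext in element.get("extension", []):
        if ext.get("url") == url:
            return ext
    return None


def _read_subs(ext: dict) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for sub in ext.get("extension", []):
        url = sub.get("url")
        if "extension" in sub:   # nested window
            inner = {s["url"]: s.get("valueInteger")
                     for s in sub["extension"]}
            out[url] = (inner.get("earlier", 0), inner.get("later", 0))
        else:
            value = next((v for k, v in sub.items()
                          if k.startswith("value")), None)
            out[url] = value
    return out


def _node_from_action(action: dict, profile: MappingProfile) -> SoANode:
    ext = _find_extension(action, profile.time_point_url)
    if ext is None:
        raise MappingError(
            f"action {action.get('id')!r} has no soaTimePoint extension")
    subs = _read_subs(ext)
    duration = subs.get("plannedDuration")
    return SoANode(
        node_id=action["id"],
        alias=subs.get("alias", ""),
        type=NodeType(subs["type"]),
        subtype=subs.get("subtype"),
        name=action.get("title", ""),
        description=action.get("description"),
        planned_timing=subs.get("plannedTiming"),
        reference_timepoint=bool(subs.get("referenceTimepoint", False)),
        planned_window=subs.get("plannedWindow"),
        planned_duration=(duration["value"]
                          if isinstance(duration, dict) else duration),
        role=Role(subs["role"]),
        extra=json.loads(subs["extra"]) if "extra" in subs else {},
    )


def _edge_from_action(action: dict, profile: MappingProfile,
                      source: str) -> SoATransition:
    ext = _find_extension(action, profile.transition_url)
    assert ext is not None
    subs = _read_subs(ext)
    clauses_text = []
    for cond in action.get("condition", []):
        expr = cond.get("expression", {}).get("expression")
        if expr is None:
            raise MappingError(f"sub-action {action.get('id')!r} has a "
                               "condition without an expression")
        clauses_text.append(expr)
    try:
        rule = parse_rule_set(", ".join(clauses_text))
    except Exception as exc:
        raise MappingError(f"sub-action {action.get('id')!r}: condition "
                           f"expression unparseable: {exc}") from exc
    if subs.get("source", source) != source:
        raise MappingError(f"sub-action {action.get('id')!r}: source "
                           "mismatch with enclosing action")
    return SoATransition(
        source=source,
        target=subs["target"],
        edge_id=action["id"],
        transition_delay=subs.get("transitionDelay"),
        transition_window=subs.get("transitionWindow"),
        transition_type=TransitionType(subs["transitionType"]),
        transition_rule=rule,
        primary_path=bool(subs.get("primaryPath", False)),
        origin=Origin(subs["origin"]),
        priority=subs.get("priority", 0),
        extra=json.loads(subs["extra"]) if "extra" in subs else {},
    )


def _is_transition_action(action: dict, profile: MappingProfile) -> bool:
    return _find_extension(action, profile.transition_url) is not None


def from_plan_definition(doc: dict,
                         profile: MappingProfile = DEFAULT_PROFILE
                         ) -> SoAGraph:
    """Reconstruct an SoA graph from a PlanDefinition carrying the
    soaTimePoint/soaTransition extensions."""
    if doc.get("resourceType") != "PlanDefinition":
        raise MappingError("document is not a PlanDefinition")
    g = SoAGraph(graph_id=doc.get("id", ""), title=doc.get("title", ""))
    meta_ext = _find_extension(doc, profile.metadata_url)
    if meta_ext is not None:
        g.metadata = json.loads(meta_ext["valueString"])
    for action in doc.get("action", []):
        node = _node_from_action(action, profile)
        g.interaction.nodes[node.node_id] = node
        sub_level: Optional[GraphLevel] = None
        for child in action.get("action", []):
            if _is_transition_action(child, profile):
                edge = _edge_from_action(child, profile, node.node_id)
                g.interaction.edges[edge.edge_id] = edge
            else:
                if sub_level is None:
                    sub_level = GraphLevel()
                    g.activity_subgraphs[node.node_id] = sub_level
                activity = _node_from_action(child, profile)
                sub_level.nodes[activity.node_id] = activity
                for grandchild in child.get("action", []):
                    if not _is_transition_action(grandchild, profile):
                        raise MappingError(
                            f"unexpected nested node action "
                            f"{grandchild.get('id')!r} below activity "
                            f"{activity.node_id!r}")
                    edge = _edge_from_action(grandchild, profile,
                                             activity.node_id)
                    sub_level.edges[edge.edge_id] = edge
    # dangling-target check
    for edge in g.interaction.edges.values():
        if edge.target not in g.interaction.nodes:
            raise MappingError(f"sub-action {edge.edge_id!r} targets "
                               f"unknown node {edge.target!r}")
    for owner, sub in g.activity_subgraphs.items():
        for edge in sub.edges.values():
            if edge.target not in sub.nodes:
                raise MappingError(f"sub-action {edge.edge_id!r} targets "
                                   f"unknown activity {edge.target!r}")
    return g


# ---------------------------------------------------------------------------
# round-trip diff
# ---------------------------------------------------------------------------

@dataclass
class DiffReport:
    differences: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.differences

    def __str__(self) -> str:
        return ("lossless (no differences)" if self.ok
                else "\n".join(self.differences))


def roundtrip_check(g: SoAGraph,
                    profile: MappingProfile = DEFAULT_PROFILE) -> DiffReport:
    """Serialize to PlanDefinition, parse back, and diff attribute-wise;
    an empty diff demonstrates no SoA information loss."""
    recovered = from_plan_definition(to_plan_definition(g, profile), profile)
    return DiffReport(graph_diff(g, recovered))


def diff_documents(g: SoAGraph, doc: dict,
                   profile: MappingProfile = DEFAULT_PROFILE) -> DiffReport:
    return DiffReport(graph_diff(g, from_plan_definition(doc, profile)))


# ---------------------------------------------------------------------------
# profile (structural schema) check
# ---------------------------------------------------------------------------

def _schema() -> dict:
    text = (importlib_resources.files("soagraph") / "schemas" /
            "soa-plan-definition.schema.json").read_text()
    return json.loads(text)


_TYPES = {"object": dict, "array": list, "string": str, "integer": int,
          "boolean": bool, "number": (int, float)}


def _check_schema(instance: Any, schema: dict, path: str,
                  problems: list[str]) -> None:
    # deliberately small JSON-schema subset: type/required/properties/
    # items/enum/const
    t = schema.get("type")
    if t is not None:
        expected = _TYPES[t]
        if (not isinstance(instance, expected) or
                (t == "integer" and isinstance(instance, bool))):
            problems.append(f"{path}: expected {t}, got "
                            f"{type(instance).__name__}")
            return
    if "const" in schema and instance != schema["const"]:
        problems.append(f"{path}: expected constant {schema['const']!r}")
    if "enum" in schema and instance not in schema["enum"]:
        problems.append(f"{path}: {instance!r} not one of {schema['enum']}")
    if isinstance(instance, dict):
        for req in schema.get("required", []):
            if req not in instance:
                problems.append(f"{path}: missing required member {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check_schema(instance[key], sub, f"{path}.{key}", problems)
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            _check_schema(item, schema["items"], f"{path}[{i}]", problems)


def validate_profile(doc: dict) -> list[str]:
    """Structural profile check against the shipped schema; empty list
    means the document conforms."""
    problems: list[str] = []
    _check_schema(doc, _schema(), "$", problems)
    return problems


# ---------------------------------------------------------------------------
# stub context bundle
# ---------------------------------------------------------------------------

def emit_stub_context(g: SoAGraph,
                      profile: MappingProfile = DEFAULT_PROFILE) -> dict:
    """Bundle the PlanDefinition with minimal referenced resources: a
    ResearchStudy stub and one ActivityDefinition stub per distinct
    activity name, so every relatedAction targetId resolves within the
    bundle."""
    plan = to_plan_definition(g, profile)
    entries = [{"resource": plan}]
    entries.append({"resource": {
        "resourceType": "ResearchStudy",
        "id": f"rs-{g.graph_id}",
        "status": "active",
        "title": g.title or g.graph_id,
    }})
    seen: dict[str, str] = {}
    for sub in g.activity_subgraphs.values():
        for node in sub.nodes.values():
            if node.role != Role.REGULAR:
                continue
            name = node.name or node.alias
            ad_id = activity_definition_id(name)
            if ad_id not in seen:
                seen[ad_id] = name
    for ad_id, name in seen.items():
        entries.append({"resource": {
            "resourceType": "ActivityDefinition",
            "id": ad_id,
            "status": "draft",
            "title": name,
        }})
    return {"resourceType": "Bundle", "type": "collection",
            "entry": entries}
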