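"""PlanDefinition mapping: structure, conditions, round-trip fidelity,
profile conformance and the stub context bundle."""

import copy
import json

import pytest

from soagraph import fixtures
from soagraph.fhir import (DEFAULT_PROFILE, MappingError, MappingProfile,
                           diff_documents, emit_stub_context,
                           from_plan_definition, plan_definition_json,
                           roundtrip_check, to_plan_definition,
                           validate_profile)
from soagraph.model import Role, SoAGraph, SoANode, graph_diff


def action_by_id(doc, action_id):
    for action in doc["action"]:
        if action["id"] == action_id:
            return action
    raise KeyError(action_id)


def test_nodes_become_actions_edges_become_subactions(fig2b):
    doc = to_plan_definition(fig2b)
    assert doc["resourceType"] == "PlanDefinition"
    assert len(doc["action"]) == len(fig2b.interaction.nodes)
    total_edge_actions = sum(
        1 for action in doc["action"]
        for child in action.get("action", [])
        if any(ext["url"] == DEFAULT_PROFILE.transition_url
               for ext in child.get("extension", [])))
    assert total_edge_actions == len(fig2b.interaction.edges)


def test_v2_action_carries_its_transitions_and_conditions(fig2b):
    v2 = fig2b.by_alias("V2")
    doc = to_plan_definition(fig2b)
    action = action_by_id(doc, v2.node_id)
    assert action["groupingBehavior"] == "logical-group"
    assert action["selectionBehavior"] == "exactly-one"
    targets = {}
    for child in action["action"]:
        ext = next((x for x in child["extension"]
                    if x["url"] == DEFAULT_PROFILE.transition_url), None)
        if ext is None:
            continue
        subs = {s["url"]: s for s in ext["extension"]}
        alias = fig2b.node(subs["target"]["valueString"]).alias
        targets[alias] = child
    assert set(targets) >= {"V3", "IF", "U"}
    # the withdrawal route's condition is the withdrawn-flag clause
    withdrawal_conditions = targets["IF"]["condition"]
    assert withdrawal_conditions[0]["kind"] == "applicability"
    expr = withdrawal_conditions[0]["expression"]
    assert expr["language"] == "text/x-soa-rule"
    assert json.loads(expr["expression"]) == {"withdrawn": True}


def test_single_node_graph_maps_to_single_action():
    g = SoAGraph(graph_id="solo", title="solo")
    node = SoANode(alias="IS", name="Instantiation start",
                   role=Role.INSTANTIATION_START)
    g.interaction.nodes[node.node_id] = node
    doc = to_plan_definition(g)
    assert len(doc["action"]) == 1
    assert "action" not in doc["action"][0]


def test_missing_time_point_extension_names_the_action(fig1):
    doc = to_plan_definition(fig1)
    broken = copy.deepcopy(doc)
    victim = broken["action"][2]
    victim["extension"] = []
    with pytest.raises(MappingError) as exc:
        from_plan_definition(broken)
    assert victim["id"] in str(exc.value)


def test_roundtrip_is_lossless_for_worked_examples(fig1, fig2b, fig4):
    for g in (fig1, fig2b, fig4, fixtures.example_fig3(),
              fixtures.example_fig8_cycles(5),
              fixtures.example_blood_pressure_repeat()):
        diff = roundtrip_check(g)
        assert diff.ok, f"{g.graph_id}: {diff.differences[:3]}"


def test_roundtrip_is_lossless_for_generated_corpus(corpus28):
    assert len(corpus28) >= 25
    for g in corpus28:
        diff = roundtrip_check(g)
        assert diff.ok, f"{g.graph_id}: {diff.differences[:3]}"


def test_node_attributes_survive_roundtrip():
    g = fixtures.generate_random_soa(fixtures.GeneratorParams(
        n_visits=4, has_unscheduled=True, n_cycles=2, seed=42))
    node = next(n for n in g.interaction.nodes.values()
                if n.role == Role.REGULAR)
    node.planned_duration = 24
    node.description = "overnight stay"
    node.extra = {"sponsorNote": "fasting"}
    recovered = from_plan_definition(to_plan_definition(g))
    back = recovered.interaction.nodes[node.node_id]
    assert back.planned_duration == 24
    assert back.description == "overnight stay"
    assert back.extra == {"sponsorNote": "fasting"}


def test_mutated_document_diff_names_edge_and_attribute(fig1):
    doc = to_plan_definition(fig1)
    mutated = copy.deepcopy(doc)
    edge_id = None
    for action in mutated["action"]:
        for child in action.get("action", []):
            for ext in child.get("extension", []):
                if ext["url"] == DEFAULT_PROFILE.transition_url:
                    subs = [s for s in ext["extension"]
                            if s["url"] != "transitionDelay"]
                    if len(subs) != len(ext["extension"]):
                        ext["extension"] = subs
                        edge_id = child["id"]
                        break
            if edge_id:
                break
        if edge_id:
            break
    assert edge_id is not None
    diff = diff_documents(fig1, mutated)
    assert not diff.ok
    assert any(edge_id in d and "transition_delay" in d
               for d in diff.differences)


def test_serialization_is_canonical(fig2b):
    assert plan_definition_json(fig2b) == plan_definition_json(
        fixtures.example_fig2b())


def test_profile_schema_accepts_fixtures_and_rejects_breakage(fig1,
                                                              corpus28):
    for g in [fig1, *corpus28[:6]]:
        assert validate_profile(to_plan_definition(g)) == []
    broken = to_plan_definition(fig1)
    broken = copy.deepcopy(broken)
    broken["action"][0].pop("selectionBehavior")
    problems = validate_profile(broken)
    assert any("selectionBehavior" in p for p in problems)


def test_profile_url_must_match_on_both_legs(fig1):
    other = MappingProfile(extension_base_url="https://elsewhere.org/fhir")
    doc = to_plan_definition(fig1, other)
    with pytest.raises(MappingError):
        from_plan_definition(doc)  # default profile: extensions not found
    assert graph_diff(fig1, from_plan_definition(doc, other)) == []


def test_stub_bundle_covers_every_related_action_target(fig1):
    bundle = emit_stub_context(fig1)
    resources = [entry["resource"] for entry in bundle["entry"]]
    kinds = [r["resourceType"] for r in resources]
    assert kinds.count("PlanDefinition") == 1
    assert kinds.count("ResearchStudy") == 1
    activity_names = {n.name for sub in fig1.activity_subgraphs.values()
                      for n in sub.nodes.values()
                      if n.role == Role.REGULAR}
    ad_ids = {r["id"] for r in resources
              if r["resourceType"] == "ActivityDefinition"}
    assert len(ad_ids) == len(activity_names)

    # reference-resolution oracle: every relatedAction targetId resolves
    def targets(actions):
        for action in actions:
            for rel in action.get("relatedAction", []):
                yield rel["targetId"]
            yield from targets(action.get("action", []))

    plan = resources[0]
    referenced = set(targets(plan["action"]))
    assert referenced and referenced <= ad_ids


def test_stub_bundle_without_activities():
    g = fixtures.example_fig4()   # no activity subgraphs
    bundle = emit_stub_context(g)
    kinds = sorted(e["resource"]["resourceType"] for e in bundle["entry"])
    assert kinds == ["PlanDefinition", "ResearchStudy"]
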