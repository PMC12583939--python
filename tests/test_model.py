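"""Graph construction, structural validation and implied-path expansion."""

import networkx as nx
import pytest

from soagraph.model import (ExpansionPolicy, GraphValidationError, Origin,
                            Role, SoAGraph, SoANode, SoATransition,
                            build_graph, expand_implied_paths, graph_diff,
                            validate_graph)


def n(alias, role=Role.REGULAR, **kw):
    return SoANode(node_id=f"n-{alias}", alias=alias, name=alias,
                   role=role, **kw)


def e(src, tgt, **kw):
    kw.setdefault("transition_delay", 1)
    return SoATransition(source=f"n-{src}", target=f"n-{tgt}",
                         edge_id=f"e-{src}-{tgt}", **kw)


def chain_graph(*aliases, graph_id="test"):
    nodes = [n("IS", Role.INSTANTIATION_START)]
    nodes += [n(a, reference_timepoint=(i == 0),
                planned_timing=i) for i, a in enumerate(aliases)]
    nodes += [n("IF", Role.INSTANTIATION_FINISH)]
    labels = ["IS", *aliases, "IF"]
    edges = [e(a, b, primary_path=True,
               transition_delay=(0 if b == "IF" or a == "IS" else 1))
             for a, b in zip(labels, labels[1:])]
    return build_graph(nodes, edges, graph_id=graph_id)


def test_minimal_chain_builds():
    g = chain_graph("V1")
    assert len(g.interaction.nodes) == 3
    assert validate_graph(g).ok
    assert [g.interaction.nodes[i].alias for i in g.primary_chain()] == \
        ["IS", "V1", "IF"]


def test_dangling_edge_reports_offending_edge():
    nodes = [n("IS", Role.INSTANTIATION_START), n("V1"),
             n("IF", Role.INSTANTIATION_FINISH)]
    edges = [e("IS", "V1"), e("V1", "VX")]
    with pytest.raises(GraphValidationError) as exc:
        build_graph(nodes, edges)
    assert "e-V1-VX" in str(exc.value)


def test_duplicate_node_id_rejected():
    nodes = [n("IS", Role.INSTANTIATION_START), n("V1"), n("V1"),
             n("IF", Role.INSTANTIATION_FINISH)]
    with pytest.raises(GraphValidationError):
        build_graph(nodes, [e("IS", "V1"), e("V1", "IF")])


def test_missing_instantiation_boundaries_rejected():
    with pytest.raises(GraphValidationError) as exc:
        build_graph([n("V1"), n("V2")], [e("V1", "V2")])
    assert "instantiation_start" in str(exc.value)


def test_two_reference_timepoints_is_a_finding():
    g = chain_graph("V1", "V2")
    g.interaction.nodes["n-V2"].reference_timepoint = True
    report = validate_graph(g)
    assert len([f for f in report.findings
                if "referenceTimepoint" in f.message]) == 1


def test_unreachable_finish_matches_path_enumeration_oracle():
    """validate_graph flags an unreachable IF exactly when exhaustive
    path enumeration finds no IS→IF path over explicit edges."""
    nodes = [n("IS", Role.INSTANTIATION_START), n("V1"), n("V2"),
             n("IF", Role.INSTANTIATION_FINISH)]
    edges = [e("IS", "V1"), e("IF", "V2")]   # IF only has an OUTgoing edge
    g = SoAGraph(graph_id="t")
    for node in nodes:
        g.interaction.nodes[node.node_id] = node
    for edge in edges:
        g.interaction.edges[edge.edge_id] = edge
    nxg = nx.DiGraph([(ed.source, ed.target)
                      for ed in g.interaction.edges.values()])
    nxg.add_nodes_from(g.interaction.nodes)
    oracle_reaches = any(path[-1] == "n-IF" for path in
                         nx.all_simple_paths(nxg, "n-IS", "n-IF"))
    findings = [f for f in validate_graph(g).findings
                if "not reachable" in f.message]
    assert not oracle_reaches
    assert len(findings) == 1 and findings[0].ref == "n-IF"


def test_unscheduled_node_must_have_null_timing():
    g = chain_graph("V1")
    bad = SoANode(node_id="n-U", alias="U", role=Role.UNSCHEDULED,
                  planned_timing=5)
    g.interaction.nodes["n-U"] = bad
    assert any("plannedTiming" in f.message
               for f in validate_graph(g).findings)


# ---------------------------------------------------------------------------
# implied-path expansion
# ---------------------------------------------------------------------------

def test_expansion_adds_withdrawal_and_unscheduled_routes(fig1, fig2b):
    finish = fig2b.instantiation_finish().node_id
    for alias in ("V1", "V2", "V3", "V4", "V5", "V6"):
        node = fig2b.by_alias(alias)
        to_if = [ed for ed in fig2b.interaction.outgoing(node.node_id)
                 if ed.target == finish and ed.origin == Origin.IMPLIED]
        assert len(to_if) == 1, f"{alias} should gain a withdrawal edge"
        assert to_if[0].transition_rule.mentions("withdrawn")
    u = fig2b.by_alias("U").node_id
    paired = {fig2b.node(ed.target).alias
              for ed in fig2b.interaction.outgoing(u)
              if ed.target != u and ed.target != finish}
    # unscheduled interludes are drawn over the on-study period only
    assert paired == {"V2", "V3", "V4", "V5", "V6"}


def test_expansion_preserves_explicit_elements(fig1, fig2b):
    for node_id, node in fig1.interaction.nodes.items():
        assert fig2b.interaction.nodes[node_id] == node
    for edge_id in fig1.interaction.edges:
        assert edge_id in fig2b.interaction.edges


def test_expansion_is_idempotent(fig2b):
    assert graph_diff(fig2b, expand_implied_paths(fig2b)) == []


def test_unscheduled_return_rules_partition_primary_chain(fig2b):
    chain = [fig2b.interaction.nodes[i].alias
             for i in fig2b.primary_chain()]
    u = fig2b.by_alias("U").node_id
    returns = [ed for ed in fig2b.interaction.outgoing(u)
               if ed.transition_rule.mentions("interactions_exist")]
    assert returns
    for ed in returns:
        by_fn = {c.function: list(c.argument)
                 for c in ed.transition_rule.clauses}
        exist = by_fn["interactions_exist"]
        not_exist = by_fn["interactions_not_exist"]
        assert exist + not_exist == chain         # ordered partition
        assert not set(exist) & set(not_exist)


def test_generated_u_to_v3_rule_text(fig2b):
    u = fig2b.by_alias("U").node_id
    v3 = fig2b.by_alias("V3").node_id
    edge = [ed for ed in fig2b.interaction.outgoing(u)
            if ed.target == v3][0]
    assert edge.transition_rule.serialize() == (
        '{"interactions_exist": ["IS", "V1", "V2"]}, '
        '{"interactions_not_exist": ["V3", "V4", "V5", "V6", "IF"]}')


def test_every_node_on_a_start_finish_path_after_expansion(fig2b):
    """Exhaustive simple-path enumeration: post-expansion, every
    interaction node lies on at least one IS→IF path."""
    nxg = nx.DiGraph()
    nxg.add_nodes_from(fig2b.interaction.nodes)
    nxg.add_edges_from((ed.source, ed.target)
                       for ed in fig2b.interaction.edges.values())
    on_path = set()
    for path in nx.all_simple_paths(nxg,
                                    fig2b.instantiation_start().node_id,
                                    fig2b.instantiation_finish().node_id):
        on_path.update(path)
    assert on_path == set(fig2b.interaction.nodes)


def test_expansion_policy_can_disable_unscheduled(fig1):
    g = expand_implied_paths(fig1, ExpansionPolicy(unscheduled=False))
    u = g.by_alias("U").node_id
    finish = g.instantiation_finish().node_id
    # only the withdrawal route remains; no routing to/from the schedule
    assert all(ed.target == finish for ed in g.interaction.outgoing(u))
    assert not [ed for ed in g.interaction.edges.values()
                if ed.target == u]


def test_graph_diff_reports_attribute_changes(fig1):
    import copy
    other = copy.deepcopy(fig1)
    node_id = other.by_alias("V3").node_id
    other.interaction.nodes[node_id].planned_timing = 99
    diff = graph_diff(fig1, other)
    assert len(diff) == 1
    assert "planned_timing" in diff[0] and "V3" in diff[0]
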