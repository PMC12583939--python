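"""Deterministic construction of worked examples and seeded random SoAs.

The worked examples reconstruct the study designs this model is usually
demonstrated on:

* ``example_fig1`` — a six-visit study with one unscheduled visit and
  per-visit activity subgraphs, built from its protocol table
  (``TABLE1_CSV``).  The table elides two mid-study columns; they are
  reconstructed here as weekly visits (Day 14 and Day 21), which is the
  documented interpolation, not a printed value.
* ``example_fig2b`` — the same study with all implied permitted paths
  materialized (withdrawal routes, unscheduled-visit routes).
* ``example_fig4`` — a post-reference weekly chain V1(Day 1) ... V5(Day 28)
  used for actual-day arithmetic with unscheduled interludes; paired with
  :func:`fig4_policy`, a walk inserting unscheduled visits on Days 8, 27
  and 28 pushes V5 from Day 28 to Day 29 while the Day-8 interlude leaves
  the schedule untouched.
* ``example_blood_pressure_repeat`` — a single activity with a repeat
  self-loop carrying ``{"maxRepeats": 4}`` ("repeat 3x": four total
  executions).
* ``example_fig8_cycles`` — the treatment-cycle template (CS/CF boundary
  nodes, a rule-limited return edge), each visit defined once.

``generate_random_soa`` produces structurally valid graphs whose planned
timings are derived from their delays, so the timing consistency equation
holds by construction; ``corpus`` assembles a mixed-design set (linear,
unscheduled, conditional, cyclic) for round-trip testing.
"""

from __future__ import annotations

import io
import random
import uuid
from dataclasses import dataclass

from .formats import read_tabular_soa, table_to_graph
from .model import (ExpansionPolicy, GraphLevel, NodeType, Role, SoAGraph,
                    SoANode, SoATransition, build_graph, deterministic_id,
                    expand_implied_paths)
from .rules import RuleClause, RuleSet, parse_rule_set
from .walker import WalkPolicy

#: protocol table of the six-visit example study (visit 4/5 timings are
#: reconstructed as weekly; the source table elides those columns)
TABLE1_CSV = """\
Phase,Screening,Study period,Study period,Study period,Study period,Study period,Unscheduled
Visit ID,1,2,3,4,5,6,U
Visit timing,-Days 28 to 1,Day 1,Day 7,Day 14,Day 21,Day 28,As required
Demographics,X,,,,,,
Medical history,X,,,,,,
Inclusion and exclusion criteria,X,,X,,,,
Vital signs,X,X,X,X,X,X,X
Procedure,X,X,,,,,
Concomitant medication,X,X,X,X,X,X,X
AE and SAE,X,X,X,X,X,X,X
"""


def example_table1():
    """The example protocol table, parsed."""
    return read_tabular_soa(io.StringIO(TABLE1_CSV))


def example_fig1() -> SoAGraph:
    """Six planned visits, one floating unscheduled visit, activity
    subgraphs per visit."""
    return table_to_graph(example_table1(), graph_id="fig1",
                          title="Example study (6 planned visits + U)")


def example_fig2a() -> SoAGraph:
    """The explicit schedule only — identical to :func:`example_fig1`."""
    return example_fig1()


def example_fig2b() -> SoAGraph:
    """All implied permitted paths added: withdrawal routes Vn→IF and
    unscheduled routes Vn→U / U→Vn with forward-only return rules."""
    return expand_implied_paths(example_fig2a())


def example_fig3() -> SoAGraph:
    """A single-visit study whose activity sequence has formal early-exit
    paths: if inclusion/exclusion criteria are not met, the visit finishes
    early (edge to AF guarded by {"if_criteria_met": false})."""
    gid = "fig3"

    def nid(*parts: str) -> str:
        return deterministic_id(gid, *parts)

    nodes = [
        SoANode(node_id=nid("IS"), alias="IS", name="Instantiation start",
                role=Role.INSTANTIATION_START),
        SoANode(node_id=nid("V1"), alias="V1", name="Visit 1",
                planned_timing=0, reference_timepoint=True),
        SoANode(node_id=nid("IF"), alias="IF", name="Instantiation finish",
                role=Role.INSTANTIATION_FINISH),
    ]
    edges = [
        SoATransition(source=nid("IS"), target=nid("V1"),
                      edge_id=nid("edge", "IS", "V1"),
                      transition_delay=0, primary_path=True),
        SoATransition(source=nid("V1"), target=nid("IF"),
                      edge_id=nid("edge", "V1", "IF"),
                      transition_delay=0, primary_path=True),
    ]
    a = {name: SoANode(node_id=nid("V1", "activity", name), alias=name,
                       name=name, type=NodeType.ACTIVITY)
         for name in ("Demographics", "Inclusion and exclusion criteria",
                      "Vital signs", "Procedure")}
    sub_nodes = ([SoANode(node_id=nid("V1", "AS"), alias="AS",
                          name="Activity start", type=NodeType.ACTIVITY,
                          role=Role.ACTIVITY_START)] +
                 list(a.values()) +
                 [SoANode(node_id=nid("V1", "AF"), alias="AF",
                          name="Activity finish", type=NodeType.ACTIVITY,
                          role=Role.ACTIVITY_FINISH)])
    crit = a["Inclusion and exclusion criteria"]
    sub_edges = [
        SoATransition(source=nid("V1", "AS"),
                      target=a["Demographics"].node_id,
                      edge_id=nid("V1", "edge", "AS", "Demographics"),
                      transition_delay=0, primary_path=True),
        SoATransition(source=a["Demographics"].node_id,
                      target=crit.node_id,
                      edge_id=nid("V1", "edge", "Demographics", "criteria"),
                      transition_delay=0, primary_path=True),
        # criteria met: proceed with the visit
        SoATransition(source=crit.node_id, target=a["Vital signs"].node_id,
                      edge_id=nid("V1", "edge", "criteria", "Vital signs"),
                      transition_delay=0, primary_path=True,
                      transition_rule=parse_rule_set(
                          '{"if_criteria_met": true}')),
        # criteria not met: finish the visit early
        SoATransition(source=crit.node_id, target=nid("V1", "AF"),
                      edge_id=nid("V1", "edge", "criteria", "AF"),
                      transition_delay=0,
                      transition_rule=parse_rule_set(
                          '{"if_criteria_met": false}')),
        SoATransition(source=a["Vital signs"].node_id,
                      target=a["Procedure"].node_id,
                      edge_id=nid("V1", "edge", "Vital signs", "Procedure"),
                      transition_delay=0, primary_path=True),
        SoATransition(source=a["Procedure"].node_id, target=nid("V1", "AF"),
                      edge_id=nid("V1", "edge", "Procedure", "AF"),
                      transition_delay=0, primary_path=True),
    ]
    subgraphs = {nid("V1"): GraphLevel.from_lists(sub_nodes, sub_edges)}
    return build_graph(nodes, edges, activity_subgraphs=subgraphs,
                       graph_id=gid, title="Early-exit activity example")


def example_fig4() -> SoAGraph:
    """Weekly five-visit chain for actual-day arithmetic: V1 on Day 1
    (reference) through V5 on Day 28, with an unscheduled visit; implied
    paths expanded."""
    gid = "fig4"

    def nid(*parts: str) -> str:
        return deterministic_id(gid, *parts)

    plan = [("V1", 0), ("V2", 6), ("V3", 13), ("V4", 20), ("V5", 27)]
    nodes = [SoANode(node_id=nid("IS"), alias="IS",
                     name="Instantiation start",
                     role=Role.INSTANTIATION_START)]
    for alias, offset in plan:
        nodes.append(SoANode(node_id=nid(alias), alias=alias,
                             name=f"Visit {alias[1:]}",
                             planned_timing=offset,
                             reference_timepoint=(offset == 0)))
    nodes.append(SoANode(node_id=nid("U"), alias="U",
                         name="Unscheduled visit", role=Role.UNSCHEDULED))
    nodes.append(SoANode(node_id=nid("IF"), alias="IF",
                         name="Instantiation finish",
                         role=Role.INSTANTIATION_FINISH))
    chain = ["IS"] + [alias for alias, _ in plan] + ["IF"]
    offsets = [0] + [o for _, o in plan] + [27]
    edges = [SoATransition(source=nid(a), target=nid(b),
                           edge_id=nid("edge", a, b),
                           transition_delay=ob - oa, primary_path=True)
             for (a, oa), (b, ob) in zip(zip(chain, offsets),
                                         zip(chain[1:], offsets[1:]))]
    g = build_graph(nodes, edges, graph_id=gid,
                    title="Weekly schedule with unscheduled interludes")
    return expand_implied_paths(g)


def fig4_policy() -> WalkPolicy:
    """Insert unscheduled visits on Day 8, Day 27 and Day 28 (offsets 7,
    26, 27)."""
    return WalkPolicy(unscheduled_days=[7, 26, 27])


def example_blood_pressure_repeat() -> SoAGraph:
    """Repeat blood pressure measurement 3x: the activity's self-loop
    carries {"maxRepeats": 4}, i.e. four total executions."""
    gid = "bp-repeat"

    def nid(*parts: str) -> str:
        return deterministic_id(gid, *parts)

    nodes = [
        SoANode(node_id=nid("IS"), alias="IS", name="Instantiation start",
                role=Role.INSTANTIATION_START),
        SoANode(node_id=nid("V1"), alias="V1", name="Visit 1",
                planned_timing=0, reference_timepoint=True),
        SoANode(node_id=nid("IF"), alias="IF", name="Instantiation finish",
                role=Role.INSTANTIATION_FINISH),
    ]
    edges = [
        SoATransition(source=nid("IS"), target=nid("V1"),
                      edge_id=nid("edge", "IS", "V1"), transition_delay=0,
                      primary_path=True),
        SoATransition(source=nid("V1"), target=nid("IF"),
                      edge_id=nid("edge", "V1", "IF"), transition_delay=0,
                      primary_path=True),
    ]
    bp = SoANode(node_id=nid("V1", "activity", "Blood pressure"),
                 alias="Blood pressure", name="Blood pressure measurement",
                 type=NodeType.ACTIVITY)
    sub_nodes = [
        SoANode(node_id=nid("V1", "AS"), alias="AS", name="Activity start",
                type=NodeType.ACTIVITY, role=Role.ACTIVITY_START),
        bp,
        SoANode(node_id=nid("V1", "AF"), alias="AF", name="Activity finish",
                type=NodeType.ACTIVITY, role=Role.ACTIVITY_FINISH),
    ]
    sub_edges = [
        SoATransition(source=nid("V1", "AS"), target=bp.node_id,
                      edge_id=nid("V1", "edge", "AS", "BP"),
                      transition_delay=0, primary_path=True),
        SoATransition(source=bp.node_id, target=bp.node_id,
                      edge_id=nid("V1", "edge", "BP", "self"),
                      transition_delay=0,
                      transition_rule=parse_rule_set('{"maxRepeats": 4}')),
        SoATransition(source=bp.node_id, target=nid("V1", "AF"),
                      edge_id=nid("V1", "edge", "BP", "AF"),
                      transition_delay=0, primary_path=True),
    ]
    subgraphs = {nid("V1"): GraphLevel.from_lists(sub_nodes, sub_edges)}
    return build_graph(nodes, edges, activity_subgraphs=subgraphs,
                       graph_id=gid, title="Blood pressure repeat example")


def example_fig8_cycles(max_cycles: int = 5,
                        cycle_length: int = 21) -> SoAGraph:
    """Treatment-cycle template: IS → V1 → CS → Dosing → Review → CF, with
    a return edge CF→CS carrying {"n_cycles": "<max_cycles+1>"} so exactly
    ``max_cycles`` cycles complete, then CF → IF.  With ``max_cycles`` 0
    the return edge is omitted and the template degenerates to a linear
    study (the cycle block runs once)."""
    gid = f"fig8-{max_cycles}"

    def nid(*parts: str) -> str:
        return deterministic_id(gid, *parts)

    review_offset = cycle_length - 1
    nodes = [
        SoANode(node_id=nid("IS"), alias="IS", name="Instantiation start",
                role=Role.INSTANTIATION_START),
        SoANode(node_id=nid("V1"), alias="V1", name="Enrollment visit",
                planned_timing=0, reference_timepoint=True),
        SoANode(node_id=nid("CS"), alias="CS", name="Cycle start",
                planned_timing=0, role=Role.CYCLE_START),
        SoANode(node_id=nid("D1"), alias="D1", name="Dosing",
                planned_timing=0),
        SoANode(node_id=nid("R1"), alias="R1", name="Cycle review",
                planned_timing=review_offset),
        SoANode(node_id=nid("CF"), alias="CF", name="Cycle finish",
                planned_timing=review_offset, role=Role.CYCLE_FINISH),
        SoANode(node_id=nid("IF"), alias="IF", name="Instantiation finish",
                role=Role.INSTANTIATION_FINISH),
    ]
    chain = ["IS", "V1", "CS", "D1", "R1", "CF", "IF"]
    delays = [0, 0, 0, review_offset, 0, 0]
    edges = [SoATransition(source=nid(a), target=nid(b),
                           edge_id=nid("edge", a, b), transition_delay=d,
                           primary_path=True)
             for a, b, d in zip(chain, chain[1:], delays)]
    if max_cycles > 0:
        edges.append(SoATransition(
            source=nid("CF"), target=nid("CS"),
            edge_id=nid("edge", "CF", "CS"), transition_delay=1,
            transition_rule=RuleSet((RuleClause(
                "n_cycles", f"<{max_cycles + 1}"),))))
    return build_graph(nodes, edges, graph_id=gid,
                       title=f"Cycle template (max {max_cycles} cycles)")


# ---------------------------------------------------------------------------
# randomized generation
# ---------------------------------------------------------------------------

_ACTIVITY_POOL = ("Vital signs", "Blood draw", "ECG", "Physical exam",
                  "Concomitant medication", "AE review", "Questionnaire",
                  "Dispense study drug")
_SUBTYPE_POOL = ("clinic visit", "telephone call", None)


@dataclass
class GeneratorParams:
    """Knobs of the random SoA generator; generation is a pure function of
    these plus the seed."""

    n_visits: int = 5
    has_unscheduled: bool = False
    n_conditional_activities: int = 0
    n_cycles: int = 0          # 0 = no cycle block
    delay_range: tuple[int, int] = (1, 14)
    window_range: tuple[int, int] = (0, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_visits < 1 or self.n_conditional_activities < 0 \
                or self.n_cycles < 0:
            raise ValueError("generator counts must be non-negative "
                             "(n_visits >= 1)")


def generate_random_soa(params: GeneratorParams) -> SoAGraph:
    """A valid random SoA whose plannedTiming values are accumulated from
    its delays (timing-consistent by construction)."""
    rng = random.Random(params.seed)

    def rid() -> str:
        return str(uuid.UUID(int=rng.getrandbits(128), version=4))

    gid = f"random-{params.seed}"
    nodes = [SoANode(node_id=rid(), alias="IS", name="Instantiation start",
                     role=Role.INSTANTIATION_START)]
    offset = 0
    for i in range(1, params.n_visits + 1):
        window = None
        if rng.random() < 0.5:
            w = rng.randint(*params.window_range)
            window = (rng.randint(0, w), w) if w else (0, 0)
        nodes.append(SoANode(
            node_id=rid(), alias=f"V{i}", name=f"Visit {i}",
            subtype=rng.choice(_SUBTYPE_POOL),
            planned_timing=offset, reference_timepoint=(i == 1),
            planned_window=window))
        offset += rng.randint(*params.delay_range)
    visit_nodes = nodes[1:]

    cycle_nodes: list[SoANode] = []
    if params.n_cycles > 0:
        cs = SoANode(node_id=rid(), alias="CS", name="Cycle start",
                     planned_timing=offset, role=Role.CYCLE_START)
        body = SoANode(node_id=rid(), alias="C1", name="Cycle dosing",
                       planned_timing=offset)
        cf_offset = offset + rng.randint(*params.delay_range)
        cf = SoANode(node_id=rid(), alias="CF", name="Cycle finish",
                     planned_timing=cf_offset, role=Role.CYCLE_FINISH)
        cycle_nodes = [cs, body, cf]
        nodes.extend(cycle_nodes)
        offset = cf_offset

    u_node = None
    if params.has_unscheduled:
        u_node = SoANode(node_id=rid(), alias="U",
                         name="Unscheduled visit", role=Role.UNSCHEDULED)
        nodes.append(u_node)

    finish = SoANode(node_id=rid(), alias="IF",
                     name="Instantiation finish",
                     role=Role.INSTANTIATION_FINISH)
    nodes.append(finish)

    chain = ([nodes[0]] + visit_nodes + cycle_nodes + [finish])
    edges = []
    for a, b in zip(chain, chain[1:]):
        delay = ((b.planned_timing or 0) - (a.planned_timing or 0)
                 if a.planned_timing is not None and
                 b.planned_timing is not None else 0)
        window = None
        if rng.random() < 0.3:
            w = rng.randint(*params.window_range)
            window = (0, w)
        edges.append(SoATransition(
            source=a.node_id, target=b.node_id, edge_id=rid(),
            transition_delay=delay, transition_window=window,
            primary_path=True))
    if params.n_cycles > 0:
        edges.append(SoATransition(
            source=cycle_nodes[-1].node_id, target=cycle_nodes[0].node_id,
            edge_id=rid(), transition_delay=1,
            transition_rule=RuleSet((RuleClause(
                "n_cycles", f"<{params.n_cycles + 1}"),))))

    subgraphs: dict[str, GraphLevel] = {}
    conditional_left = params.n_conditional_activities
    for visit in visit_nodes:
        names = rng.sample(_ACTIVITY_POOL, rng.randint(1, 3))
        sub_nodes = [SoANode(node_id=rid(), alias="AS",
                             name="Activity start", type=NodeType.ACTIVITY,
                             role=Role.ACTIVITY_START)]
        for name in names:
            sub_nodes.append(SoANode(node_id=rid(), alias=name, name=name,
                                     type=NodeType.ACTIVITY))
        sub_nodes.append(SoANode(node_id=rid(), alias="AF",
                                 name="Activity finish",
                                 type=NodeType.ACTIVITY,
                                 role=Role.ACTIVITY_FINISH))
        sub_edges = []
        for a, b in zip(sub_nodes, sub_nodes[1:]):
            rule = RuleSet()
            if conditional_left > 0 and b.role == Role.REGULAR:
                flag = f"flag_{conditional_left}"
                rule = RuleSet((RuleClause(flag, True),))
                sub_edges.append(SoATransition(
                    source=a.node_id, target=sub_nodes[-1].node_id,
                    edge_id=rid(), transition_delay=0,
                    transition_rule=RuleSet((RuleClause(flag, False),))))
                conditional_left -= 1
            sub_edges.append(SoATransition(
                source=a.node_id, target=b.node_id, edge_id=rid(),
                transition_delay=0, primary_path=True,
                transition_rule=rule))
        subgraphs[visit.node_id] = GraphLevel.from_lists(sub_nodes,
                                                         sub_edges)

    g = build_graph(nodes, edges, activity_subgraphs=subgraphs,
                    graph_id=gid,
                    title=f"Random SoA (seed {params.seed})")
    if params.has_unscheduled:
        g = expand_implied_paths(g, ExpansionPolicy())
    return g


def corpus(seed: int = 0, n_per_class: int = 7) -> list[SoAGraph]:
    """A mixed-design corpus: linear, unscheduled, conditional and cyclic
    SoAs (``4 * n_per_class`` graphs) for round-trip and property suites."""
    graphs = []
    for i in range(n_per_class):
        base = seed * 1009 + i
        graphs.append(generate_random_soa(GeneratorParams(
            n_visits=3 + i, seed=base)))
        graphs.append(generate_random_soa(GeneratorParams(
            n_visits=3 + i, has_unscheduled=True, seed=base + 101)))
        graphs.append(generate_random_soa(GeneratorParams(
            n_visits=3 + i, n_conditional_activities=1 + i % 3,
            seed=base + 202)))
        graphs.append(generate_random_soa(GeneratorParams(
            n_visits=2 + i, n_cycles=1 + i % 4,
            has_unscheduled=(i % 2 == 0), seed=base + 303)))
    return graphs
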