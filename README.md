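# soagraph

Clinical-study **schedules of activities (SoAs)** as directed property
graphs, with a conditional-rule engine, per-subject schedule walking,
timing consistency checking, and **lossless round-trips to FHIR R5
PlanDefinition** resources.

A protocol's SoA is usually printed as a square table: visits as columns
with timings, activities as rows with X marks. That form cannot express
what real studies need — repeat treatment cycles (ubiquitous in oncology),
conditional branching, unscheduled "as required" visits, or the
participant's right to withdraw at any point. `soagraph` is for study
builders, protocol digitization teams and clinical-informatics engineers
who need all of those scheduling semantics in one machine-readable model
that can travel over standard FHIR resources.

## The model

An SoA is a two-level directed graph:

* **Interactions** (visits, telephone contacts) between boundary nodes
  *instantiation start/finish* (IS/IF); each interaction may own an
  **activity** subgraph (its tasks) between *activity start/finish*
  (AS/AF). Cycle designs mark the repeatable block with *cycle
  start/finish* (CS/CF).
* Nodes carry `plannedTiming` — a signed day offset from the schedule's
  **reference timepoint** t₀ (protocol "Day 1") — plus windows, durations
  and roles. Edges (**transitions**) carry `transitionDelay` (the wait in
  days before moving source → target), a permitted variance window, and a
  **transitionRule**.
* The key timing invariant links the two:

  ```
  plannedTiming(Vn) = Σ transitionDelay   over the primary path from t₀ to Vn
  ```

  `check_timing_consistency` verifies it and pinpoints hand-authored
  protocol inconsistencies; a subject's *actual* days are the cumulative
  delays along the path actually taken, which unscheduled visits can shift.

* Rules are conjunctions of single-pair conditions that resolve to
  true (path selectable) / false (path unavailable) at runtime:

  ```
  {"interactions_exist": ["IS", "V1", "V2"]}, {"interactions_not_exist": ["V3", "V4", "V5", "V6", "IF"]}
  ```

  Built-ins cover visit-history guards (the pair above makes unscheduled
  returns forward-only), repeat caps (`{"maxRepeats": 4}` = "repeat 3x"),
  and cycle limits (`{"n_cycles": "<6"}` = at most five cycles); any other
  name is an open-vocabulary subject flag (`{"consentObtained": true}`).

`expand_implied_paths` materializes what protocols leave implicit:
withdrawal routes from every visit and forward-only routes through the
unscheduled visit. The walker then traverses one subject's schedule,
evaluating rules against their visit history, execution counts, completed
cycles and flags.

For exchange, nodes map to `PlanDefinition.action` and edges to
`PlanDefinition.action.action`, with two extensions (`soaTimePoint`,
`soaTransition`) carrying the graph attributes, one `action.condition` per
rule clause, and `groupingBehavior`/`selectionBehavior` restricting runtime
selection to exactly one path. The mapping is bidirectional and lossless.

## Worked example

A weekly five-visit schedule (V1 on Day 1 … V5 on Day 28) walked with
unscheduled visits required on Days 8, 27 and 28:

```python
from soagraph import fixtures, simulate, actual_day, day_label
from soagraph.walker import WalkPolicy

g = fixtures.example_fig4()
state = simulate(g, WalkPolicy(unscheduled_days=[7, 26, 27]))
for s in state.interaction_steps:
    print(f"{s.label:>3}  {day_label(s.day)}")
print("status:", state.status)
```

prints

```
 IS  Day 1
 V1  Day 1
 V2  Day 7
  U  Day 8
 V3  Day 14
 V4  Day 21
  U  Day 27
  U  Day 28
 V5  Day 29
 IF  Day 29
status: finished
```

The Day-8 unscheduled visit slots between V2 and V3 and leaves the plan
untouched; the Day-27/Day-28 pair occupies V5's planned day, so V5 is
pushed to Day 29 — the actual days come from the delays actually
traversed, not from the planned timings alone.

The same graphs round-trip through FHIR:

```bash
soagraph fixtures --name fig2b -o fig2b.json
soagraph roundtrip fig2b.json        # → "lossless (no differences)"
soagraph to-fhir fig2b.json -o fig2b.plan.json
soagraph simulate fig2b.json
```

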