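# Methods

## Model

A schedule of activities (SoA) is represented as a two-level directed
property graph. The interaction level holds study events (visits,
contacts) between a single *instantiation start* (IS) and *instantiation
finish* (IF) node; each interaction may own an ordered activity subgraph
delimited by *activity start/finish* (AS/AF). Repeatable treatment blocks
are delimited by *cycle start/finish* (CS/CF). Node and edge identities
are opaque ids (UUIDs); the short protocol labels (V1, U, IS …) live in a
separate `alias` field so conditional rules and printed examples stay
legible while round-trip equality is defined over ids. Fixture ids are
UUIDv5 values derived from graph id + alias, so fixture construction is
reproducible; the random generator draws ids from its seeded RNG.

Assumptions: one IS and one IF per graph; at most one reference timepoint;
at most one outgoing primary-path edge per interaction (the `primaryPath`
flag marks the protocol's explicit main schedule — protocols leave path
identity implicit, but the timing consistency check needs a defined
summation path); unscheduled nodes have no planned timing. Activity
subgraphs are stored hierarchically (one per interaction) rather than in a
single flat graph: that mirrors the visual containment of the drawn model
and maps directly onto nested FHIR actions.

## Day arithmetic

All computation uses signed whole-day offsets with 0 at the reference
timepoint. Protocol day *labels* use the one-based no-day-zero
convention: offset 0 ↔ "Day 1", offset 28 ↔ "Day 29", offset −28 ↔
"−Day 28". Labels are presentation only; nothing computes on them.
Tabular screening ranges like "−Days 28 to 1" map to `plannedTiming` =
the earliest day (offset −28) with `plannedWindow` spanning the range
(0, 27) — anchoring at the earliest day keeps the consistency equation
single-valued. Windows default to (0, 0) when absent; `plannedDuration`
(hours) never affects day arithmetic. No calendar/date-time arithmetic is
attempted (no time zones or business days).

Of the four transition timing relationships, only the default
`start_to_start` participates in day arithmetic; the other three are
stored, validated and round-tripped but raise if a walk traverses them.
The vocabulary exists in the model, but no worked semantics are defined
for the non-default values, and inventing them silently would corrupt
actual-day results.

## Conditional rules

Rules are ordered conjunctions of single-pair `{"function": argument}`
clauses; an empty rule set is vacuously true. Multiple clauses on one
edge are ANDed — a multi-condition requirement is a list of conditions
that must all hold, and disjunction is expressed structurally by parallel
edges. No OR syntax is provided deliberately.

* `interactions_exist` / `interactions_not_exist` test the subject's visit
  history by alias.
* `maxRepeats n` is true while the governing edge's *target* node has been
  executed fewer than `n` times, so a "repeat 3×" instruction is
  `{"maxRepeats": 4}` on a self-loop — four total executions.
* `n_cycles` supports `<, <=, =, ==, >, >=` (bare integers mean equality)
  against the *prospective* cycle index, `completedCycles + 1`. The
  walker increments `completedCycles` on arrival at a cycle-finish node;
  with the prospective comparison this makes `{"n_cycles": "<6"}` admit
  exactly five completed cycles, which is the intended reading of
  "limit the number of cycles to a max of 5".
* Any other function name is an open-vocabulary subject-flag equality.
  This is what lets protocol authors write `consentObtained`,
  `record_AE`, `continue_to_OLE`, `studyPhase` … without registration.
  The strings `"true"`/`"false"` (any case) coerce to booleans on both
  sides; other strings compare literally.

The parser accepts single, double and typographic quotes — protocol
documents mix all three, occasionally within one token — and
canonicalizes to double quotes. Parsing is loss-free up to that
canonicalization. In strict mode a flag absent from the context raises;
in lenient mode (the walker default) the clause evaluates false with a
logged warning, which is the safer runtime behavior for open-vocabulary
flags.

## Implied-path expansion

Protocols draw only the explicit schedule. `expand_implied_paths` adds,
idempotently and without touching explicit elements:

* **Withdrawal routes** Vn→IF from every non-boundary interaction. The
  edge carries `{"withdrawn": true}`, and the walker applies the
  complementary global guard `{"withdrawn": false}` to every edge whose
  own rule set does not mention the flag. A withdrawn subject therefore
  sees exactly one available route (the exit), and a non-withdrawn
  subject never takes it. Realizing the guard at walk time, rather than
  rewriting every rule set, keeps the authored graph clean.
* **Unscheduled routes** Vn→U and U→Vn for every regular primary-chain
  visit at or after the reference timepoint (the "as required" visit
  spans the on-study period only; pre-reference screening is excluded).
  Each return edge U→Vn carries the generated forward-only rule pair:
  `interactions_exist` = chain aliases strictly before Vn,
  `interactions_not_exist` = Vn through IF. The two lists partition the
  primary chain, so exactly the next forward visit is reachable.
* **Forward completion** U→IF with the same rule-pair pattern (every
  planned visit visited, IF not), so an unscheduled visit taken after the
  last planned visit can close the schedule instead of stalling.
* **A U→U self-loop**, rate-limited by `{"maxRepeats": 12}` (default),
  because consecutive unscheduled visits on adjacent days do occur and
  are needed to reproduce the worked timing example. The cap keeps every
  loop in the expanded graph rule-bounded. The self-loop gets ordering
  priority 10 so deterministic selection prefers scheduled returns.

## Walking and actual days

The walker keeps the runtime context the rule engine reads: visit history
with actual days, per-node execution counts, completed cycles, subject
flags (with `withdrawn` initialized false). Available transitions are
ordered deterministically — primary path first, then priority, then edge
id — making greedy walks reproducible; `simulate` is a pure function of
graph, policy and seed. Walks are anchored so the reference timepoint
falls on offset 0 (a screening study starts at a negative offset).

Unscheduled visits occur on the days the policy requests, not on planned
days: entering U records the requested day, and returning U→Vn resumes
Vn's planned day when it is still in the future, otherwise pushes it by
the implied edge's minimum spacing (1 day by default). This is the
mechanism by which an early unscheduled visit leaves the schedule intact
while one occupying a planned day displaces that visit and everything
downstream.

A node with no available transition is a *stall*: recorded on the walk
state with full context, never raised. Stalls are findings — they are
exactly the protocol inconsistencies this style of model is meant to
surface. The per-walk step budget (10,000) only guards against truly
unbounded authored loops.

Activity subgraphs execute contiguously on the interaction's day. The
activity walker prefers an available self-loop (repeats are protocol
requirements, not options) and otherwise follows the same ordered
selection; at the interaction level a walk preferring cycles takes the
cycle-return edge while its rule allows.

## FHIR mapping

Interaction nodes map to `PlanDefinition.action`, transitions to
`action.action`, activity nodes to actions nested under their visit's
action. Two extensions, `soaTimePoint` (on node actions) and
`soaTransition` (on edge sub-actions), carry the graph attributes under
their model names (`plannedTiming`, `transitionDelay`, …) with integer
day values — not ISO-8601 durations — for bit-exact round trips. Each
rule clause becomes one `action.condition` of kind `applicability` with
expression language `text/x-soa-rule` holding the canonical clause text;
translating that dialect to FHIRPath or CQL is downstream tooling and out
of scope. `groupingBehavior = logical-group` and `selectionBehavior =
exactly-one` restrict runtime selection to a single path. Scheduling is
decoupled from task content: activity actions reference stub
`ActivityDefinition` resources (one per distinct activity name) via
`relatedAction.targetId`; `emit_stub_context` bundles those with a
`ResearchStudy` stub so every reference resolves bundle-internally.

FHIR documents are plain JSON dictionaries built in deterministic order,
so serializing the same graph twice is byte-identical. Only FHIR R5
(5.0.0) is targeted; no R4 back-port. Live FHIR-server load/recover
testing is out of scope by design (no network dependency); the round-trip
suite plus a dry serialization/profile check substitutes. The shipped
profile schema (`schemas/soa-plan-definition.schema.json`) is a
**synthetic structural reconstruction** of the profile at JSON-schema
level, authored for this package, and is applied by a small built-in
schema interpreter; it is not a normative StructureDefinition.
`to_plan_definition` requires mappability (no dangling references) rather
than full structural validity, so partial schedules remain exchangeable.

## Tabular and GraphML interop

The tabular reader implements a closed timing-text grammar — `Day N`,
`Days A to B`, `-Days A to B`, `As required` — and errors on anything
else rather than guessing. Table footnote conditions are outside the
grammar; conditions are authored on the graph. Conversion builds the
IS→V1→…→Vn→IF chain with delays derived from the offsets (consistent by
construction) and one activity subgraph per marked column; the
unscheduled column becomes a floating U node routed later by expansion.
Graph→table conversion is deliberately absent (the table is lossy).

GraphML export is flat and editor-friendly: every model attribute is a
data key, activity nodes carry an `interaction` key naming their owner,
and display labels plus role-based fill colors (green starts, red
finishes, yellow activities, blue unscheduled) are written for visual
editing. Presentation keys are regenerated on write and ignored on read;
unknown foreign keys are preserved as opaque per-element metadata and
survive all three serializations.

## Synthetic data

`generate_random_soa` emulates the structural variety of real protocols:
chains of 1–10+ visits with random delays (default 1–14 days) and windows
(0–3 days), optional unscheduled visit (with full expansion), optional
conditional activity branches (the early-exit pattern), and optional
cycle blocks with rule-limited returns. Planned timings are accumulated
from the drawn delays, so generated graphs satisfy the consistency
equation by construction — which is what makes the zero-violation
property a meaningful conservation check and single-delay perturbation a
meaningful detection check. `corpus` assembles 28 graphs (7 per design
class: linear, unscheduled, conditional, cyclic), which is the
round-trip corpus size used by the acceptance checks.

What the generator does **not** emulate: real protocols' footnote
semantics, arm-specific sub-schedules, amendment histories, or
free-text timing idioms beyond the closed grammar. Passing tests
demonstrate that the model and its serializations are faithful over the
generated design space, not that arbitrary real protocols parse.

The worked-example fixtures reconstruct their sources where those are
partial: the example table elides two mid-study columns, reconstructed
as weekly visits (Day 14, Day 21); the unscheduled-interlude timing
example is reconstructed as a post-reference weekly chain V1(Day 1) …
V5(Day 28) with a one-day minimum spacing on implied unscheduled edges,
the only reading consistent with its stated Day 28 → Day 29 shift.

## Problem sizes

The default test run exercises: the full 28-graph corpus for round trips;
100 generator seeds for validity/consistency; exhaustive truth tables for
rule sets of up to 4 clauses; 1,000 seeded randomized walks for the
safety property; 20 random chains against the path-sum oracle. The whole
suite completes in a few seconds on one CPU.

## Limitations

* The rejected node-level `repeatAllowed` control mechanism is documented
  here for completeness but intentionally not implemented: node-scoped
  permissions cannot express route restrictions after an unscheduled
  visit, which is precisely what edge rules with history guards do.
* Rules are exchanged as `text/x-soa-rule` expressions; a FHIR consumer
  needs the (deferred) FHIRPath/CQL translation layer to execute them.
* Activity subgraphs support early-exit and repeat patterns; unscheduled
  *activities* inside a visit are not modeled (no in-scope example
  defines their semantics).
* Single-subject walks only; no cohort-level statistics.
* In-memory model only; no graph database backend.
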