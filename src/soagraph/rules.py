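"""Conditional-scheduling rule syntax: parsing and runtime evaluation.

Every transition (edge) in a schedule-of-activities graph may carry a set of
conditions that must resolve to a single true/false at runtime — true means
the path can be selected, false means it is unavailable.  Conditions are
written as a comma-separated sequence of single-pair objects::

    {"interactions_exist": ["IS", "V1", "V2"]}, {"withdrawn": false}

Built-in functions
------------------
``interactions_exist``
    True when every listed interaction alias appears in the subject's visit
    history.
``interactions_not_exist``
    True when none of the listed aliases appears in the history.
``maxRepeats``
    True while the total execution count of the edge's *target* node is
    strictly below the argument.  A "repeat 3x" requirement is written as
    ``{"maxRepeats": 4}`` on a self-loop: four total executions.
``n_cycles``
    Comparison against the *prospective* cycle index (completed cycles + 1),
    so ``{"n_cycles": "<6"}`` caps a study at five completed cycles.

Any other function name is an open-vocabulary *subject flag* and evaluates
as equality against the runtime context (``{"consentObtained": true}``,
``{"studyPhase": "onStudy"}`` ...).  The string literals ``"true"`` and
``"false"`` (any case) are coerced to booleans on both sides.

Multiple clauses on one edge are conjoined (AND): every condition must hold
for the path to be selectable.  Disjunction is expressed structurally, by
parallel edges.  An empty rule set is vacuously true.

The parser accepts single, double and typographic quotes (protocol documents
mix all three, sometimes within one token) and canonicalizes to double
quotes on serialization.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Any, Optional

log = logging.getLogger("soagraph")

#: functions with registered argument types; everything else is a flag clause
BUILTIN_LIST_FUNCTIONS = ("interactions_exist", "interactions_not_exist")
BUILTIN_INT_FUNCTIONS = ("maxRepeats",)
BUILTIN_COMPARISON_FUNCTIONS = ("n_cycles",)

#: media-type label under which canonical rule text travels (e.g. inside
#: FHIR PlanDefinition action conditions)
RULE_MEDIA_TYPE = "text/x-soa-rule"

_COMPARISON_RE = re.compile(r"^(<=|>=|==|<|>|=)\s*(-?\d+)$")
_INT_RE = re.compile(r"^-?\d+$")

# typographic quotes seen in protocol text, normalized before scanning
_QUOTE_TRANSLATION = str.maketrans({"‘": "'", "’": "'",
                                    "“": '"', "”": '"'})
_QUOTES = "'\""


class RuleError(ValueError):
    """Base class for rule syntax / evaluation problems."""


class RuleSyntaxError(RuleError):
    """Malformed rule text."""


class RuleEvaluationError(RuleError):
    """A clause could not be evaluated against the runtime context."""


@dataclass(frozen=True)
class RuleClause:
    """One ``{"function": argument}`` condition."""

    function: str
    argument: Any

    def __post_init__(self) -> None:
        if not self.function:
            raise RuleSyntaxError("clause function name must be non-empty")
        object.__setattr__(self, "argument", _coerce_argument(self.function,
                                                             self.argument))

    def serialize(self) -> str:
        arg: Any = self.argument
        if isinstance(arg, tuple):
            arg = list(arg)
        return json.dumps({self.function: arg})


@dataclass(frozen=True)
class RuleSet:
    """Ordered conjunction of clauses carried by one transition."""

    clauses: tuple[RuleClause, ...] = ()

    def __bool__(self) -> bool:
        return bool(self.clauses)

    @property
    def is_empty(self) -> bool:
        return not self.clauses

    def serialize(self) -> str:
        """Canonical text form: double quotes, ``", "``-separated clauses."""
        return ", ".join(c.serialize() for c in self.clauses)

    def mentions(self, function: str) -> bool:
        return any(c.function == function for c in self.clauses)


EMPTY_RULE_SET = RuleSet()


@dataclass
class EvaluationContext:
    """Runtime state a subject's walk exposes to the rule engine.

    ``interaction_history`` holds ``(alias, day_offset)`` pairs in visit
    order; ``node_execution_counts`` is keyed by nodeID and counts every
    execution including repeats; ``completed_cycles`` counts finished
    treatment cycles; ``subject_flags`` is the open-vocabulary flag store
    (withdrawn, consentObtained, if_criteria_met, studyPhase, ...).
    """

    interaction_history: list[tuple[str, int]] = field(default_factory=list)
    node_execution_counts: dict[str, int] = field(default_factory=dict)
    completed_cycles: int = 0
    subject_flags: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if self.completed_cycles < 0:
            raise RuleEvaluationError("completed_cycles must be >= 0")
        if any(v < 0 for v in self.node_execution_counts.values()):
            raise RuleEvaluationError("execution counts must be >= 0")
        days = [d for _, d in self.interaction_history]
        if any(b < a for a, b in zip(days, days[1:])):
            raise RuleEvaluationError("history days must be non-decreasing")

    @property
    def history_aliases(self) -> list[str]:
        return [alias for alias, _ in self.interaction_history]


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _coerce_argument(function: str, raw: Any) -> Any:
    """Check/normalize an argument against the function's expected type."""
    if function in BUILTIN_LIST_FUNCTIONS:
        if not isinstance(raw, (list, tuple)) or not all(
                isinstance(x, str) for x in raw):
            raise RuleSyntaxError(
                f"{function} requires a list of interaction aliases, "
                f"got {raw!r}")
        return tuple(raw)
    if function in BUILTIN_INT_FUNCTIONS:
        if isinstance(raw, bool) or not isinstance(raw, int):
            if isinstance(raw, str) and _INT_RE.match(raw.strip()):
                return int(raw)
            raise RuleSyntaxError(f"{function} requires an integer, "
                                  f"got {raw!r}")
        return raw
    if function in BUILTIN_COMPARISON_FUNCTIONS:
        if isinstance(raw, int) and not isinstance(raw, bool):
            return raw
        if isinstance(raw, str) and _COMPARISON_RE.match(raw.strip()):
            return raw.strip()
        raise RuleSyntaxError(
            f"{function} requires an integer or a comparison string "
            f"like '<6', got {raw!r}")
    # open-vocabulary flag clause
    if isinstance(raw, str):
        low = raw.strip().lower()
        if low == "true":
            return True
        if low == "false":
            return False
    if isinstance(raw, list):
        return tuple(raw)
    return raw


def _skip_ws(s: str, i: int) -> int:
    while i < len(s) and s[i].isspace():
        i += 1
    return i


def _scan_string(s: str, i: int) -> tuple[str, int]:
    # opening quote at s[i]; any quote character terminates (protocol text
    # sometimes mixes quote styles within a single token)
    i += 1
    start = i
    while i < len(s) and s[i] not in _QUOTES:
        i += 1
    if i >= len(s):
        raise RuleSyntaxError(f"unterminated string starting at {start - 1}")
    return s[start:i], i + 1


def _scan_bare(s: str, i: int) -> tuple[str, int]:
    start = i
    while i < len(s) and s[i] not in ",}]:" and not s[i].isspace():
        i += 1
    if i == start:
        raise RuleSyntaxError(f"expected a value at position {start}")
    return s[start:i], i


def _bare_to_value(tok: str) -> Any:
    low = tok.lower()
    if low == "true":
        return True
    if low == "false":
        return False
    if _INT_RE.match(tok):
        return int(tok)
    return tok


def _scan_value(s: str, i: int) -> tuple[Any, int]:
    i = _skip_ws(s, i)
    if i >= len(s):
        raise RuleSyntaxError("unexpected end of rule text")
    ch = s[i]
    if ch == "[":
        items: list[Any] = []
        i = _skip_ws(s, i + 1)
        while i < len(s) and s[i] != "]":
            if s[i] in _QUOTES:
                item, i = _scan_string(s, i)
            else:
                tok, i = _scan_bare(s, i)
                item = tok
            items.append(item)
            i = _skip_ws(s, i)
            if i < len(s) and s[i] == ",":
                i = _skip_ws(s, i + 1)
        if i >= len(s):
            raise RuleSyntaxError("unterminated list")
        return items, i + 1
    if ch in _QUOTES:
        return _scan_string(s, i)
    tok, i = _scan_bare(s, i)
    return _bare_to_value(tok), i


def _scan_clause(s: str, i: int) -> tuple[RuleClause, int]:
    assert s[i] == "{"
    i = _skip_ws(s, i + 1)
    if i >= len(s):
        raise RuleSyntaxError("unterminated clause")
    if s[i] in _QUOTES:
        key, i = _scan_string(s, i)
    else:
        key, i = _scan_bare(s, i)
    i = _skip_ws(s, i)
    if i >= len(s) or s[i] != ":":
        raise RuleSyntaxError(f"expected ':' after function name {key!r}")
    value, i = _scan_value(s, i + 1)
    i = _skip_ws(s, i)
    if i < len(s) and s[i] == ",":
        raise RuleSyntaxError(
            f"clause {key!r}: multi-key objects are not allowed; write one "
            "condition per {...} object")
    if i >= len(s) or s[i] != "}":
        raise RuleSyntaxError(f"clause {key!r}: expected '}}'")
    return RuleClause(key, value), i + 1


def parse_rule_set(text: Optional[str]) -> RuleSet:
    """Parse rule text into a :class:`RuleSet`.

    Accepts the empty string (→ empty, vacuously-true rule set), trailing
    commas, and any mixture of straight and typographic quotes.
    """
    if text is None:
        return EMPTY_RULE_SET
    s = text.translate(_QUOTE_TRANSLATION)
    clauses: list[RuleClause] = []
    i = _skip_ws(s, 0)
    while i < len(s):
        if s[i] != "{":
            raise RuleSyntaxError(
                f"expected '{{' at position {i}, got {s[i]!r}")
        clause, i = _scan_clause(s, i)
        clauses.append(clause)
        i = _skip_ws(s, i)
        if i < len(s):
            if s[i] != ",":
                raise RuleSyntaxError(
                    f"expected ',' between clauses at position {i}")
            i = _skip_ws(s, i + 1)  # trailing comma permitted
    return RuleSet(tuple(clauses))


def serialize_rule_set(rs: RuleSet) -> str:
    return rs.serialize()


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _flag_value(v: Any) -> Any:
    if isinstance(v, str):
        low = v.strip().lower()
        if low == "true":
            return True
        if low == "false":
            return False
    return v


def _compare(op: str, lhs: int, rhs: int) -> bool:
    if op == "<":
        return lhs < rhs
    if op == "<=":
        return lhs <= rhs
    if op in ("=", "=="):
        return lhs == rhs
    if op == ">":
        return lhs > rhs
    if op == ">=":
        return lhs >= rhs
    raise RuleEvaluationError(f"unsupported comparison operator {op!r}")


def evaluate_clause(clause: RuleClause, ctx: EvaluationContext,
                    edge: Any = None, *, strict: bool = True) -> bool:
    """Resolve one clause to true/false against the runtime context.

    ``edge`` is the transition carrying the clause; it is needed for
    ``maxRepeats`` (whose count is taken from the edge's target node).
    In strict mode a flag missing from the context raises
    :class:`RuleEvaluationError`; in lenient mode it evaluates false with a
    logged warning.
    """
    fn, arg = clause.function, clause.argument
    if fn == "interactions_exist":
        history = set(ctx.history_aliases)
        return all(alias in history for alias in arg)
    if fn == "interactions_not_exist":
        history = set(ctx.history_aliases)
        return not any(alias in history for alias in arg)
    if fn == "maxRepeats":
        if edge is None:
            raise RuleEvaluationError(
                "maxRepeats requires the governing edge to identify its "
                "target node")
        count = ctx.node_execution_counts.get(edge.target, 0)
        return count < arg
    if fn == "n_cycles":
        prospective = ctx.completed_cycles + 1
        if isinstance(arg, int):
            return prospective == arg
        m = _COMPARISON_RE.match(arg)
        assert m is not None  # guaranteed by parse-time coercion
        return _compare(m.group(1), prospective, int(m.group(2)))
    # flag clause
    if fn not in ctx.subject_flags:
        if strict:
            raise RuleEvaluationError(
                f"flag {fn!r} is not present in the evaluation context")
        log.warning("flag %r missing from context; clause evaluates false",
                    fn)
        return False
    return _flag_value(ctx.subject_flags[fn]) == _flag_value(arg)


def evaluate_rule_set(rs: RuleSet, ctx: EvaluationContext,
                      edge: Any = None, *, strict: bool = True) -> bool:
    """Conjunction of all clause results; an empty rule set is true."""
    return all(evaluate_clause(c, ctx, edge, strict=strict)
               for c in rs.clauses)
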