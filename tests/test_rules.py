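"""Rule syntax parsing and truth-table evaluation semantics."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soagraph.rules import (EvaluationContext, RuleClause,
                            RuleEvaluationError, RuleSet, RuleSyntaxError,
                            evaluate_clause, evaluate_rule_set,
                            parse_rule_set)


class FakeEdge:
    def __init__(self, target="node-t"):
        self.target = target


def ctx(history=(), counts=None, cycles=0, flags=None):
    return EvaluationContext(
        interaction_history=[(a, i) for i, a in enumerate(history)],
        node_execution_counts=dict(counts or {}),
        completed_cycles=cycles,
        subject_flags=dict(flags or {}))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text, expected", [
    # forward-only unscheduled-return rule pair, straight quotes
    ("{'interactions_exist': ['IS','V1','V2']}, "
     "{'interactions_not_exist': ['V3','V4','V5','V6','IF']}",
     [("interactions_exist", ("IS", "V1", "V2")),
      ("interactions_not_exist", ("V3", "V4", "V5", "V6", "IF"))]),
    # typographic quotes and a mismatched-quote token, as protocol
    # documents print them
    ("{‘interactions_exist’: [‘IS’, ‘V1’,’V2’]}, "
     "{‘interactions_not_exist’: [‘V3’, ‘V4’, ‘V5’, ‘V6\", ‘IF’]}",
     [("interactions_exist", ("IS", "V1", "V2")),
      ("interactions_not_exist", ("V3", "V4", "V5", "V6", "IF"))]),
    # multi-condition genetic-testing example with trailing comma;
    # quoted "true" coerces to boolean
    ('{"studyPhase":"onStudy"}, {"sampleObtained":"true"}, '
     '{"geneticTestingConsent":"true"},',
     [("studyPhase", "onStudy"), ("sampleObtained", True),
      ("geneticTestingConsent", True)]),
    ('{"maxRepeats":4}', [("maxRepeats", 4)]),
    ('{"n_cycles": "<6"}', [("n_cycles", "<6")]),
    ('{"withdrawn": false}', [("withdrawn", False)]),
    ("", []),
    ("   ", []),
])
def test_parse_rule_text(text, expected):
    rs = parse_rule_set(text)
    assert [(c.function, c.argument) for c in rs.clauses] == expected


@pytest.mark.parametrize("bad", [
    "{'a': 1",                       # unterminated
    "{'a': 1, 'b': 2}",              # multi-key object
    "'a': 1",                        # no braces
    "{'a' 1}",                       # missing colon
    "{'maxRepeats': 'many'}",        # wrong argument type
    "{'n_cycles': '~6'}",            # unknown comparison operator
    "{'interactions_exist': 3}",     # list function with scalar
    "{: 1}",                         # empty function name
])
def test_parse_errors(bad):
    with pytest.raises(RuleSyntaxError):
        parse_rule_set(bad)


def test_canonical_serialization_uses_double_quotes():
    rs = parse_rule_set("{'interactions_exist': ['IS','V1']}")
    assert rs.serialize() == '{"interactions_exist": ["IS", "V1"]}'


_arguments = st.one_of(
    st.booleans(),
    st.integers(-50, 50),
    st.text(alphabet="abcXYZ_ ", min_size=1, max_size=8).map(str.strip)
    .filter(lambda s: s and s.lower() not in ("true", "false")),
    st.lists(st.text(alphabet="ABCV123", min_size=1, max_size=4),
             max_size=4))
_flag_clauses = st.builds(
    RuleClause,
    function=st.text(alphabet="abcdefgh_", min_size=1, max_size=10),
    argument=_arguments)
_builtin_clauses = st.one_of(
    st.builds(RuleClause, st.just("interactions_exist"),
              st.lists(st.sampled_from(["IS", "V1", "V2", "V3", "IF"]),
                       max_size=4)),
    st.builds(RuleClause, st.just("maxRepeats"), st.integers(0, 9)),
    st.builds(RuleClause, st.just("n_cycles"),
              st.sampled_from(["<6", "<=5", "=3", ">1", ">=2", 4])))


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.one_of(_flag_clauses, _builtin_clauses), max_size=5))
def test_parse_serialize_roundtrip(clauses):
    rs = RuleSet(tuple(clauses))
    assert parse_rule_set(rs.serialize()) == rs


# ---------------------------------------------------------------------------
# clause semantics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("aliases, history, expected", [
    (("IS", "V1", "V2"), ("IS", "V1", "V2"), True),
    (("IS", "V1", "V2"), ("IS", "V1", "V2", "U"), True),
    (("IS", "V1", "V2"), ("IS", "V1"), False),
    ((), (), True),                      # vacuous truth
])
def test_interactions_exist(aliases, history, expected):
    clause = RuleClause("interactions_exist", list(aliases))
    assert evaluate_clause(clause, ctx(history)) is expected


@pytest.mark.parametrize("aliases, history, expected", [
    (("V3", "V4", "V5", "V6", "IF"), ("IS", "V1", "V2"), True),
    (("V3", "V4", "V5", "V6", "IF"), ("IS", "V1", "V2", "V3"), False),
    ((), ("IS",), True),
])
def test_interactions_not_exist(aliases, history, expected):
    clause = RuleClause("interactions_not_exist", list(aliases))
    assert evaluate_clause(clause, ctx(history)) is expected


def test_max_repeats_against_counting_oracle():
    """maxRepeats n is true exactly while the target's execution count is
    below n (enumerated counts 0..5 against the < comparison)."""
    clause = RuleClause("maxRepeats", 4)
    edge = FakeEdge("bp")
    for count in range(6):
        expected = count < 4
        got = evaluate_clause(clause, ctx(counts={"bp": count}), edge)
        assert got is expected, count
    assert evaluate_clause(clause, ctx(counts={"bp": 4}), edge) is False


@pytest.mark.parametrize("arg, completed, expected", [
    ("<6", 4, True), ("<6", 5, False),       # "max of 5 cycles" pairing
    ("<=5", 4, True), ("<=5", 5, False),
    ("=3", 2, True), ("=3", 3, False),
    (">2", 2, True), (">2", 1, False),
    (">=3", 2, True), (">=3", 1, False),
    (4, 3, True), (4, 4, False),             # bare integer = equality
])
def test_n_cycles_prospective_comparison(arg, completed, expected):
    """n_cycles compares against the prospective index completed+1."""
    clause = RuleClause("n_cycles", arg)
    assert evaluate_clause(clause, ctx(cycles=completed)) is expected


def test_flag_clause_string_coercion():
    clause = RuleClause("sampleObtained", "true")
    assert clause.argument is True
    assert evaluate_clause(clause, ctx(flags={"sampleObtained": "TRUE"}))
    assert not evaluate_clause(clause, ctx(flags={"sampleObtained": False}))
    phase = RuleClause("studyPhase", "onStudy")
    assert evaluate_clause(phase, ctx(flags={"studyPhase": "onStudy"}))
    assert not evaluate_clause(phase, ctx(flags={"studyPhase": "followUp"}))


def test_missing_flag_strict_vs_lenient():
    clause = RuleClause("consentObtained", True)
    with pytest.raises(RuleEvaluationError):
        evaluate_clause(clause, ctx(), strict=True)
    assert evaluate_clause(clause, ctx(), strict=False) is False


# ---------------------------------------------------------------------------
# rule-set evaluation = AND fold
# ---------------------------------------------------------------------------

def test_empty_rule_set_is_true():
    assert evaluate_rule_set(RuleSet(), ctx()) is True


def test_multi_condition_conjunction():
    rs = parse_rule_set('{"studyPhase":"onStudy"}, '
                        '{"sampleObtained":"true"}, '
                        '{"geneticTestingConsent":"true"}')
    all_met = ctx(flags={"studyPhase": "onStudy", "sampleObtained": True,
                         "geneticTestingConsent": True})
    assert evaluate_rule_set(rs, all_met) is True
    one_false = ctx(flags={"studyPhase": "onStudy", "sampleObtained": True,
                           "geneticTestingConsent": False})
    assert evaluate_rule_set(rs, one_false) is False


@pytest.mark.parametrize("n_clauses", [1, 2, 3, 4])
def test_rule_set_matches_truth_table_oracle(n_clauses):
    """For every truth assignment to n flag clauses, the rule-set result
    equals the brute-force AND of the individual clause results."""
    flags = [f"f{i}" for i in range(n_clauses)]
    rs = RuleSet(tuple(RuleClause(f, True) for f in flags))
    for assignment in itertools.product([False, True], repeat=n_clauses):
        context = ctx(flags=dict(zip(flags, assignment)))
        clause_values = [evaluate_clause(c, context) for c in rs.clauses]
        oracle = all(clause_values)
        assert evaluate_rule_set(rs, context) is oracle


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.tuples(st.sampled_from("abcd"), st.booleans()),
                min_size=1, max_size=4),
       st.dictionaries(st.sampled_from("abcd"), st.booleans()))
def test_adding_a_clause_is_monotone(pairs, flags):
    """Appending a clause can never turn a false rule set true."""
    context = ctx(flags=flags)
    rs = RuleSet(tuple(RuleClause(f, v) for f, v in pairs))
    shorter = RuleSet(rs.clauses[:-1])
    if not evaluate_rule_set(shorter, context, strict=False):
        assert not evaluate_rule_set(rs, context, strict=False)
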