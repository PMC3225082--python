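"""Rule base, conjunctive matching, forward chaining, and the rule DSL."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import (
    cartesian_match_body,
    naive_forward_chain,
    random_graph,
    random_rule,
    sparql_match_body,
)
from evipath.kg import (
    Binding,
    KnowledgeGraph,
    Triple,
    TriplePattern,
    Variable,
    literal,
    wo,
)
from evipath.rules import (
    PAPER,
    RECONSTRUCTED,
    Rule,
    RuleSyntaxError,
    default_rules,
    format_rules,
    forward_chain,
    match_body,
    parse_rules,
)

PRINTED_RULE_1 = """[Rule 1: (?QueryCompound WO:isSimiliarTo ?CompoundID),
(?CompoundID WO:isActiveIn ?Bioassay),
(?Bioassay WO:isAssociatedWith ?Disease)
-> (?QueryCompound WO:mightHasDisease ?Disease)]"""


class TestDefaultRules:
    def test_registry_has_eight_rules(self):
        assert len(default_rules()) == 8

    def test_exactly_rules_1_to_3_carry_paper_provenance(self):
        tags = {r.id: r.provenance_tag for r in default_rules()}
        assert {rid for rid, tag in tags.items() if tag == PAPER} \
            == {"rule1", "rule2", "rule3"}
        assert all(tag == RECONSTRUCTED for rid, tag in tags.items()
                   if rid not in ("rule1", "rule2", "rule3"))

    def test_published_rule_bodies_are_verbatim(self):
        by_id = {r.id: r for r in default_rules()}
        r1 = by_id["rule1"]
        assert [p.predicate for p in r1.body] == [
            wo("isSimilarTo"), wo("isActiveIn"), wo("isAssociatedWith")]
        assert r1.head[0].predicate == wo("mightHasDisease")
        r2 = by_id["rule2"]
        assert [p.predicate for p in r2.body] == [
            wo("isContainedIn"), wo("hasGene"), wo("isAssociatedWith")]
        # rules 2 and 3 start at the similar compound, unanchored, as printed
        assert r2.head[0].subject == Variable("CompoundID")
        r3 = by_id["rule3"]
        assert [p.predicate for p in r3.body] == [
            wo("isActiveIn"), wo("hasGene"), wo("isAssociatedWith")]
        assert r3.head[0].subject == Variable("CompoundID")

    def test_all_rules_are_range_restricted(self):
        for r in default_rules():
            body_vars = r.body_variables()
            for pat in r.head:
                assert pat.variables() <= body_vars


class TestMatchBody:
    def test_empty_graph_yields_nothing(self, rulebase):
        g = KnowledgeGraph()
        for rule in rulebase:
            assert match_body(g, rule.body) == set()

    def test_literature_body_on_table3_yields_two_bindings(self, table3):
        rule6 = next(r for r in default_rules() if r.id == "rule6")
        got = match_body(table3, rule6.body)
        assert got == {
            Binding({"Gene": wo("HTR1B"), "CompoundID": wo("cid9681"),
                     "Disease": wo("Autistic_Disorder")}),
            Binding({"Gene": wo("HTR1B"), "CompoundID": wo("cid11865408"),
                     "Disease": wo("Autistic_Disorder")}),
        }

    def test_result_independent_of_pattern_order(self, table3, rulebase):
        rng = random.Random(0)
        for rule in rulebase:
            reference = match_body(table3, rule.body)
            for _ in range(3):
                perm = list(rule.body)
                rng.shuffle(perm)
                assert match_body(table3, perm) == reference

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_equals_cartesian_enumeration(self, seed):
        rng = random.Random(seed)
        g = random_graph(rng, rng.randint(0, 15))
        rule = random_rule(rng, "r")
        assert match_body(g, rule.body) == cartesian_match_body(g, rule.body)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_equals_sparql_engine_on_larger_graphs(self, seed):
        rng = random.Random(seed)
        g = random_graph(rng, rng.randint(50, 300))
        rule = random_rule(rng, "r")
        assert match_body(g, rule.body) == sparql_match_body(g, rule.body)


class TestForwardChain:
    def test_no_rules_is_identity(self, table3):
        res = forward_chain(table3, [])
        assert res.graph == table3 and res.paths == frozenset()

    def test_table3_inference_outcome(self, table3, rulebase):
        res = forward_chain(table3, rulebase)
        might = wo("mightHasDisease")
        inferred = {t for t in res.inferred_triples() if t.predicate == might}
        diseases = {t.object for t in inferred}
        assert diseases == {wo("Autistic_Disorder"), wo("Lymphoma")}
        autistic = [p for p in res.paths
                    if p.inferred[0].object == wo("Autistic_Disorder")]
        assert len(autistic) == 2
        compounds = {p.binding["CompoundID"] for p in autistic}
        assert compounds == {wo("cid9681"), wo("cid11865408")}
        # the assay chain fires the verbatim unanchored rule and its
        # query-anchored reconstruction, one path each
        lymphoma = sorted(p.rule_id for p in res.paths
                          if p.inferred[0].object == wo("Lymphoma"))
        assert lymphoma == ["rule3", "rule5"]

    def test_paper_rules_alone_on_table3(self, table3):
        # verbatim rules 1-3: only the assay chain (rule3) can fire on the
        # printed statements -- there are no journal nodes for rule 2
        papers = [r for r in default_rules() if r.provenance_tag == PAPER]
        res = forward_chain(table3, papers)
        assert {p.rule_id for p in res.paths} == {"rule3"}
        [path] = res.paths
        assert path.inferred == (
            Triple(wo("cid5486180"), wo("mightHasDisease"), wo("Lymphoma")),)

    def test_path_soundness(self, table3, rulebase):
        res = forward_chain(table3, rulebase)
        by_id = {r.id: r for r in rulebase}
        for path in res.paths:
            rule = by_id[path.rule_id]
            assert tuple(p.ground(path.binding) for p in rule.body) \
                == path.grounded_body
            for t in path.grounded_body:
                assert t in res.graph

    def test_idempotence_and_monotonicity(self, table3, rulebase):
        res = forward_chain(table3, rulebase)
        again = forward_chain(res.graph, rulebase)
        assert again.graph == res.graph
        assert again.paths == res.paths
        # adding an unrelated input triple never removes paths
        bigger = table3.copy().add(
            Triple(wo("cid999"), wo("hasName"), literal("inert")))
        res2 = forward_chain(bigger, rulebase)
        assert res.paths <= res2.paths

    def test_confluence_under_rule_order_permutation(self, table3, rulebase):
        rng = random.Random(1)
        reference = forward_chain(table3, rulebase)
        for _ in range(5):
            perm = list(rulebase)
            rng.shuffle(perm)
            shuffled_bodies = [
                Rule(r.id, tuple(sorted(r.body, key=lambda p: rng.random())),
                     r.head, r.provenance_tag) for r in perm]
            res = forward_chain(table3, shuffled_bodies)
            assert res.graph == reference.graph
            assert {(p.rule_id, p.binding) for p in res.paths} \
                == {(p.rule_id, p.binding) for p in reference.paths}

    def test_removing_inferred_triples_recovers_input(self, table3, rulebase):
        res = forward_chain(table3, rulebase)
        recovered = KnowledgeGraph(
            res.graph.triples() - res.inferred_triples())
        assert recovered == table3

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_equals_naive_fixpoint_enumerator(self, seed):
        rng = random.Random(seed)
        g = random_graph(rng, rng.randint(0, 12))
        rules = [random_rule(rng, f"r{i}")
                 for i in range(rng.randint(1, 4))]
        res = forward_chain(g, rules)
        oracle_triples, oracle_firings = naive_forward_chain(g, rules)
        assert res.graph.triples() == oracle_triples
        assert {(p.rule_id, p.binding) for p in res.paths} == oracle_firings

    def test_iteration_cap_raises_diagnostic(self):
        # a rule that keeps renaming nodes cannot grow forever over a closed
        # vocabulary, so build an genuinely unbounded head via fresh IRIs is
        # impossible by construction; instead verify the cap parameter works
        g = KnowledgeGraph().add(Triple(wo("a"), wo("p"), wo("b")))
        rule = Rule("loop", (TriplePattern(Variable("x"), wo("p"),
                                           Variable("y")),),
                    (TriplePattern(Variable("y"), wo("p"), Variable("x")),))
        with pytest.raises(RuntimeError, match="fixpoint"):
            forward_chain(g, [rule], max_rounds=0)


class TestRuleDsl:
    def test_printed_rule_text_parses(self):
        [r1] = parse_rules(PRINTED_RULE_1)
        assert r1.id == "Rule 1"
        assert len(r1.body) == 3 and len(r1.head) == 1
        # the published misspelling normalizes to the canonical predicate
        assert r1.body[0].predicate == wo("isSimilarTo")
        assert r1.head[0].predicate == wo("mightHasDisease")

    def test_empty_file_parses_to_no_rules(self):
        assert parse_rules("") == []
        assert parse_rules("# just a comment\n") == []

    def test_write_parse_write_is_stable(self, rulebase):
        text = format_rules(rulebase)
        again = parse_rules(text)
        assert format_rules(again) == text
        assert [r.id for r in again] == [r.id for r in rulebase]
        assert [r.provenance_tag for r in again] \
            == [r.provenance_tag for r in rulebase]

    def test_syntax_error_carries_line(self):
        with pytest.raises(RuleSyntaxError, match="line 2"):
            parse_rules("# fine\n[oops: (?a wo:p ?b) -> ]")

    def test_range_restriction_violation_names_variable(self):
        bad = "[r: (?a wo:isSimilarTo ?b) -> (?a wo:mightHasDisease ?c)]"
        with pytest.raises(RuleSyntaxError, match=r"\?c"):
            parse_rules(bad)

    def test_predicate_variable_in_body_rejected(self):
        with pytest.raises(RuleSyntaxError, match="predicate"):
            parse_rules("[r: (?a ?p ?b) -> (?a wo:mightHasDisease ?b)]")
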