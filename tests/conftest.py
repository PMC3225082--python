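"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the implementation's code paths: pattern
matching is checked against full-scan / cartesian enumeration and against
rdflib's SPARQL engine; forward chaining against a repeat-until-stable
brute-force enumerator built on those.
"""

from __future__ import annotations

import io
import random
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import pytest
import rdflib

from evipath import ingest as ing
from evipath import synthetic as syn
from evipath.kg import (
    Binding,
    KnowledgeGraph,
    Term,
    Triple,
    TriplePattern,
    Variable,
    literal,
    wo,
)
from evipath.rules import Rule, default_rules

# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def table3():
    return syn.table3_fixture()


@pytest.fixture(scope="session")
def rulebase():
    return default_rules()


@pytest.fixture(scope="session")
def methysergide_graph():
    m = syn.methysergide_fixture()
    rs = ing.parse_wendi_xml(m.wendi_xml)
    return ing.to_triples(
        rs,
        ing.load_lexicon(io.StringIO(m.gene_lexicon), "gene"),
        ing.load_lexicon(io.StringIO(m.disease_lexicon), "disease"),
        ing.load_lexicon(io.StringIO(m.go_lexicon), "go_term"),
        ing.load_go_annotation(io.StringIO(m.go_annotation)),
        ing.load_gene_disease_matrix(io.StringIO(m.gene_disease_matrix)),
    )


def ingest_bundle(bundle: syn.GeneratedBundle) -> KnowledgeGraph:
    rs = ing.parse_wendi_xml(bundle.wendi_xml)
    return ing.to_triples(
        rs,
        ing.load_lexicon(io.StringIO(bundle.gene_lexicon), "gene"),
        ing.load_lexicon(io.StringIO(bundle.disease_lexicon), "disease"),
        ing.load_lexicon(io.StringIO(bundle.go_lexicon), "go_term"),
        ing.load_go_annotation(io.StringIO(bundle.go_annotation)),
        ing.load_gene_disease_matrix(io.StringIO(bundle.gene_disease_matrix)),
    )


# ---------------------------------------------------------------------------
# random graphs and rules over a small closed vocabulary

NODES = [wo(f"N{i}") for i in range(6)]
PREDS = [wo(f"P{i}") for i in range(3)]
LITS = [literal("alpha"), literal("beta")]
TERMS = NODES + LITS
VARS = ["x", "y", "z"]


def random_graph(rng: random.Random, n_triples: int) -> KnowledgeGraph:
    g = KnowledgeGraph()
    for _ in range(n_triples):
        g.add(Triple(rng.choice(NODES), rng.choice(PREDS),
                     rng.choice(TERMS)))
    return g


def random_pattern(rng: random.Random, ground_predicate: bool = False
                   ) -> TriplePattern:
    def pos(allow_var=True, pool=TERMS):
        if allow_var and rng.random() < 0.5:
            return Variable(rng.choice(VARS))
        return rng.choice(pool)

    pred = rng.choice(PREDS) if ground_predicate or rng.random() < 0.8 \
        else Variable(rng.choice(VARS))
    return TriplePattern(pos(pool=NODES), pred, pos())


def random_rule(rng: random.Random, rule_id: str) -> Rule:
    body = tuple(random_pattern(rng, ground_predicate=True)
                 for _ in range(rng.randint(1, 3)))
    body_vars = sorted(set().union(*(p.variables() for p in body)))
    # head subject must ground to an IRI: reuse a body *subject* variable
    # (body subjects are always IRIs) or a ground node
    subj_vars = sorted({p.subject.name for p in body
                        if isinstance(p.subject, Variable)})
    subj = Variable(rng.choice(subj_vars)) \
        if subj_vars and rng.random() < 0.7 else rng.choice(NODES)
    obj = Variable(rng.choice(body_vars)) \
        if body_vars and rng.random() < 0.7 else rng.choice(TERMS)
    head = TriplePattern(subj, rng.choice(PREDS), obj)
    return Rule(rule_id, body, (head,))


# ---------------------------------------------------------------------------
# oracles

def naive_match(graph: KnowledgeGraph, pattern: TriplePattern) -> Set[Binding]:
    """Full scan over every triple (no indexes, no joins)."""
    out: Set[Binding] = set()
    for t in graph:
        assignment: Dict[str, Term] = {}
        ok = True
        for p, g in zip(pattern.positions(),
                        (t.subject, t.predicate, t.object)):
            if isinstance(p, Variable):
                if assignment.get(p.name, g) != g:
                    ok = False
                    break
                assignment[p.name] = g
            elif p != g:
                ok = False
                break
        if ok:
            out.add(Binding(assignment))
    return out


def cartesian_match_body(graph: KnowledgeGraph,
                         body: Sequence[TriplePattern]) -> Set[Binding]:
    """Exhaustive enumeration over all assignments of body variables to
    graph/vocabulary terms -- exponential, for tiny graphs only."""
    variables = sorted(set().union(*(p.variables() for p in body)))
    universe = set(TERMS) | set(PREDS)
    for t in graph:
        universe.update((t.subject, t.predicate, t.object))
    candidates = sorted(universe, key=lambda x: (x.kind, x.value))
    out: Set[Binding] = set()

    def rec(i: int, assignment: Dict[str, Term]) -> None:
        if i == len(variables):
            b = Binding(assignment)
            for pat in body:
                g = pat.substitute(b)
                try:
                    t = g.ground(b)
                except Exception:
                    return
                if t not in graph:
                    return
            out.add(b)
            return
        for term in candidates:
            assignment[variables[i]] = term
            rec(i + 1, assignment)
        del assignment[variables[i]]

    rec(0, {})
    return out


def naive_forward_chain(graph: KnowledgeGraph, rules: Sequence[Rule],
                        matcher=cartesian_match_body
                        ) -> Tuple[Set[Triple], Set[Tuple[str, Binding]]]:
    """Repeat-until-no-change enumerator; returns (final triple set,
    set of (rule id, body binding) firings on the final graph)."""
    g = graph.copy()
    while True:
        before = len(g)
        for rule in rules:
            for b in matcher(g, rule.body):
                for pat in rule.head:
                    g.add(pat.ground(b))
        if len(g) == before:
            break
    firings = {(rule.id, b) for rule in rules for b in matcher(g, rule.body)}
    return g.triples(), firings


# -- rdflib SPARQL oracle ---------------------------------------------------

def _rdf_term(term):
    if term.is_literal:
        dt = rdflib.URIRef(term.datatype) if term.datatype else None
        return rdflib.Literal(term.value, datatype=dt)
    return rdflib.URIRef(term.value)


def to_rdflib_graph(graph: KnowledgeGraph) -> rdflib.Graph:
    g = rdflib.Graph()
    for t in graph:
        g.add((_rdf_term(t.subject), _rdf_term(t.predicate),
               _rdf_term(t.object)))
    return g


def sparql_match_body(graph: KnowledgeGraph,
                      body: Sequence[TriplePattern]) -> Set[Binding]:
    """Evaluate the body as a SPARQL basic graph pattern with rdflib."""
    rg = to_rdflib_graph(graph)
    variables = sorted(set().union(*(p.variables() for p in body)))

    def token(p) -> str:
        if isinstance(p, Variable):
            return f"?{p.name}"
        return _rdf_term(p).n3()

    where = " . ".join(
        " ".join(token(x) for x in pat.positions()) for pat in body)
    if not variables:  # ground body: SELECT returns no rows, use ASK
        ok = bool(rg.query(f"ASK {{ {where} }}").askAnswer)
        return {Binding({})} if ok else set()
    select = " ".join(f"?{v}" for v in variables)
    out: Set[Binding] = set()
    for row in rg.query(f"SELECT {select} WHERE {{ {where} }}"):
        assignment = {}
        for v in variables:
            node = row[v]
            if isinstance(node, rdflib.Literal):
                dt = str(node.datatype) if node.datatype else None
                assignment[v] = literal(str(node), dt)
            else:
                assignment[v] = Term("iri", str(node))
        out.add(Binding(assignment))
    return out


def sparql_property_counts(graph: KnowledgeGraph) -> Dict[str, int]:
    """The published disease-ranking aggregate, run verbatim on rdflib."""
    rg = to_rdflib_graph(graph)
    query = """
        PREFIX wo: <http://wendi.example.org/wo#>
        SELECT ?dis (COUNT(?p) AS ?pc)
        WHERE { ?dis a wo:Disease ; ?p ?o }
        GROUP BY ?dis ORDER BY DESC(?pc)
    """
    return {str(row.dis).rsplit("#", 1)[-1]: int(row.pc)
            for row in rg.query(query)}
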