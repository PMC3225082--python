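"""Stepwise construction and execution of conjunctive graph queries.

Each step constrains ``(subject class, property, object)`` where the object
is another entity class, an exact literal, or a literal-contains filter.
Classes shared across steps bind to the same variable, so a two-step
query "compound contained in article" + "article title contains X" joins
on the article.  Compilation yields ordinary triple patterns (one
``rdf:type`` pattern per class variable plus one per step) and substring
filters; execution is a conjunctive join followed by filter application,
with distinct, deterministically ordered rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import yaml

from .kg import (
    CE_ONTOLOGY,
    KnowledgeGraph,
    Ontology,
    RDF_TYPE,
    Term,
    TriplePattern,
    Variable,
    canonical_predicate,
    wo,
)
from .rules import match_body

__all__ = [
    "ObjectClass", "ObjectLiteral", "ObjectContains", "QueryStep",
    "QuerySpec", "ContainsFilter", "CompiledQuery",
    "add_step", "compile_spec", "execute", "spec_from_yaml",
]


@dataclass(frozen=True)
class ObjectClass:
    name: str


@dataclass(frozen=True)
class ObjectLiteral:
    value: str


@dataclass(frozen=True)
class ObjectContains:
    substring: str
    case_sensitive: bool = True


ObjectConstraint = Union[ObjectClass, ObjectLiteral, ObjectContains]


@dataclass(frozen=True)
class QueryStep:
    subject_class: str
    property: str
    object: ObjectConstraint


@dataclass(frozen=True)
class QuerySpec:
    steps: Tuple[QueryStep, ...] = ()
    ontology: Ontology = CE_ONTOLOGY


@dataclass(frozen=True)
class ContainsFilter:
    variable: str
    substring: str
    case_sensitive: bool = True

    def accepts(self, term: Term) -> bool:
        if not term.is_literal:
            return False
        if self.case_sensitive:
            return self.substring in term.value
        return self.substring.lower() in term.value.lower()


@dataclass(frozen=True)
class CompiledQuery:
    patterns: Tuple[TriplePattern, ...]
    filters: Tuple[ContainsFilter, ...]


def _known_class(name: str, ontology: Ontology) -> None:
    if wo(name) not in ontology.classes:
        known = sorted(c.local for c in ontology.classes)
        raise ValueError(f"unknown class {name!r}; known classes: {known}")


def add_step(spec: QuerySpec, subject_class: str, property: str,
             object_constraint: ObjectConstraint) -> QuerySpec:
    """Return a spec grown by one step; rejects undeclared names."""
    ontology = spec.ontology
    _known_class(subject_class, ontology)
    prop = canonical_predicate(wo(property))
    if not ontology.is_declared(prop):
        raise ValueError(f"undeclared property {property!r}")
    if isinstance(object_constraint, ObjectClass):
        _known_class(object_constraint.name, ontology)
    step = QueryStep(subject_class, prop.local, object_constraint)
    return replace(spec, steps=spec.steps + (step,))


def _class_variables(spec: QuerySpec) -> Dict[str, Variable]:
    """Deterministic variable per class, by first appearance: the class
    initial (lowercased) plus a per-letter ordinal, e.g. ?c1, ?j1."""
    variables: Dict[str, Variable] = {}
    counters: Dict[str, int] = {}
    def assign(cls: str) -> None:
        if cls in variables:
            return
        letter = cls[0].lower()
        counters[letter] = counters.get(letter, 0) + 1
        variables[cls] = Variable(f"{letter}{counters[letter]}")
    for step in spec.steps:
        assign(step.subject_class)
        if isinstance(step.object, ObjectClass):
            assign(step.object.name)
    return variables


def compile_spec(spec: QuerySpec) -> CompiledQuery:
    """Compile to triple patterns plus literal-contains filters.

    Emits one ``rdf:type`` pattern per distinct class variable and one
    pattern per step; contains-constraints bind a fresh literal variable
    (?v1, ?v2, ...) and become substring filters on it.
    """
    if not spec.steps:
        raise ValueError("query spec has no steps")
    class_vars = _class_variables(spec)
    patterns: List[TriplePattern] = [
        TriplePattern(var, RDF_TYPE, wo(cls))
        for cls, var in class_vars.items()
    ]
    filters: List[ContainsFilter] = []
    lit_count = 0
    for step in spec.steps:
        subject = class_vars[step.subject_class]
        prop = wo(step.property)
        obj = step.object
        if isinstance(obj, ObjectClass):
            patterns.append(TriplePattern(subject, prop, class_vars[obj.name]))
        elif isinstance(obj, ObjectLiteral):
            patterns.append(TriplePattern(subject, prop,
                                          Term("literal", obj.value)))
        else:
            lit_count += 1
            var = Variable(f"v{lit_count}")
            patterns.append(TriplePattern(subject, prop, var))
            filters.append(ContainsFilter(var.name, obj.substring,
                                          obj.case_sensitive))
    return CompiledQuery(tuple(patterns), tuple(filters))


def execute(spec: QuerySpec, graph: KnowledgeGraph) -> List[Dict[str, Term]]:
    """Distinct result rows, sorted by binding values."""
    compiled = compile_spec(spec)
    rows = match_body(graph, compiled.patterns)
    kept = [b for b in rows
            if all(f.accepts(b[f.variable]) for f in compiled.filters)]
    distinct = sorted(
        {b for b in kept},
        key=lambda b: tuple((k, v.value) for k, v in b.items()))
    return [b.as_dict() for b in distinct]


# --------------------------------------------------------------------------
# YAML step lists, e.g.:
#   steps:
#     - subject: ChemicalCompound
#       property: isContainedIn
#       object: {class: JournalArticle}
#     - subject: JournalArticle
#       property: hasTitle
#       object: {contains: "5-HT"}

def spec_from_yaml(text: str, ontology: Ontology = CE_ONTOLOGY) -> QuerySpec:
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "steps" not in data:
        raise ValueError("query YAML must be a mapping with a 'steps' list")
    spec = QuerySpec(ontology=ontology)
    for i, raw in enumerate(data["steps"], start=1):
        try:
            obj = raw["object"]
            if "class" in obj:
                constraint: ObjectConstraint = ObjectClass(obj["class"])
            elif "literal" in obj:
                constraint = ObjectLiteral(obj["literal"])
            elif "contains" in obj:
                constraint = ObjectContains(
                    obj["contains"], obj.get("case_sensitive", True))
            else:
                raise KeyError("object needs class/literal/contains")
            spec = add_step(spec, raw["subject"], raw["property"], constraint)
        except KeyError as exc:
            raise ValueError(f"query YAML step {i}: missing {exc}") from exc
    return spec
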