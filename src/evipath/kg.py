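"""Ontology-typed triple graph for chemogenomic evidence.

The in-memory model is a set of subject-predicate-object statements
(:class:`Triple`) over :class:`Term` nodes, with a small fixed ontology of
entity classes (ChemicalCompound, BioAssay, JournalArticle, Gene, Disease)
and object/data properties with domain/range declarations.  The graph has
strict set semantics: adding a statement twice is a no-op.

Serialization to and from N-Triples and Turtle is delegated to :mod:`rdflib`;
the container, pattern matcher and validator here are independent of it.
Blank nodes are deliberately unsupported -- every entity gets a deterministic
IRI in the project namespace -- which makes write/read round trips exact
set equalities.

All graph-producing operations mutate the receiving graph in place and
return it (like :mod:`networkx`); use :meth:`KnowledgeGraph.copy` when a
value-style snapshot is needed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Set, Tuple, Union

import rdflib

__all__ = [
    "WO", "RDF_NS", "XSD_NS", "DEFAULT_NAMESPACES",
    "Term", "Variable", "Triple", "TriplePattern", "Binding",
    "iri", "wo", "literal", "decimal_literal", "RDF_TYPE",
    "Ontology", "PropertySignature", "LITERAL_RANGE", "CE_ONTOLOGY", "CLASSES",
    "KnowledgeGraph", "add_triple", "match", "validate",
    "Violation", "ValidationReport",
    "write_graph", "read_graph", "GraphSyntaxError", "MalformedTermError",
]

#: Project namespace ("wo" prefix).  The source system never published a
#: full IRI for its vocabulary, so the base is an implementation constant.
WO = "http://wendi.example.org/wo#"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
XSD_NS = "http://www.w3.org/2001/XMLSchema#"

DEFAULT_NAMESPACES: Dict[str, str] = {"wo": WO, "rdf": RDF_NS, "xsd": XSD_NS}


class MalformedTermError(ValueError):
    """A term violates its invariants (empty IRI, unknown prefix, ...)."""


class GraphSyntaxError(ValueError):
    """A serialized graph document failed to parse; carries line info."""


@dataclass(frozen=True)
class Term:
    """A node: either an IRI or a literal.

    For IRIs ``value`` always holds the absolute IRI; ``prefix`` is only a
    serialization hint and is ignored by equality.  For literals ``value``
    is the lexical form and ``datatype`` an optional absolute datatype IRI
    (plain literals and ``xsd:string`` are normalized to ``datatype=None``).
    """

    kind: str  # "iri" | "literal"
    value: str
    datatype: Optional[str] = None
    prefix: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("iri", "literal"):
            raise MalformedTermError(f"unknown term kind {self.kind!r}")
        if self.kind == "iri":
            if not self.value:
                raise MalformedTermError("IRI term with empty value")
            if self.datatype is not None:
                raise MalformedTermError("IRI term cannot carry a datatype")

    @property
    def is_iri(self) -> bool:
        return self.kind == "iri"

    @property
    def is_literal(self) -> bool:
        return self.kind == "literal"

    @property
    def local(self) -> str:
        """Local name of an IRI (text after the last '#' or '/'); literals
        return their lexical form.  Used for display and result JSON."""
        if self.is_literal:
            return self.value
        return re.split(r"[#/]", self.value)[-1]

    def curie(self, namespaces: Optional[Dict[str, str]] = None) -> str:
        """Compact prefixed form when a namespace matches, else the IRI."""
        if self.is_literal:
            out = json.dumps(self.value)
            if self.datatype:
                out += "^^" + Term("iri", self.datatype).curie(namespaces)
            return out
        for pfx, base in (namespaces or DEFAULT_NAMESPACES).items():
            if self.value.startswith(base):
                return f"{pfx}:{self.value[len(base):]}"
        return f"<{self.value}>"

    def __repr__(self) -> str:  # compact, test-failure friendly
        return self.curie()


@dataclass(frozen=True)
class Variable:
    """A pattern variable; rendered ``?name``."""

    name: str

    def __post_init__(self) -> None:
        if not self.name or self.name.startswith("?"):
            raise MalformedTermError(f"bad variable name {self.name!r}")

    def __repr__(self) -> str:
        return f"?{self.name}"


PatternTerm = Union[Term, Variable]


def iri(ref: str, namespaces: Optional[Dict[str, str]] = None) -> Term:
    """Build an IRI term from an absolute IRI, ``<iri>``, or a CURIE.

    Prefixes are resolved case-insensitively against ``namespaces`` (default
    project map), so the source system's ``WO:`` spelling is accepted.
    """
    namespaces = namespaces or DEFAULT_NAMESPACES
    if ref.startswith("<") and ref.endswith(">"):
        return Term("iri", ref[1:-1])
    if "://" in ref:
        return Term("iri", ref)
    if ":" in ref:
        pfx, local = ref.split(":", 1)
        lowered = {k.lower(): v for k, v in namespaces.items()}
        base = lowered.get(pfx.lower())
        if base is None:
            raise MalformedTermError(f"unknown namespace prefix {pfx!r} in {ref!r}")
        return Term("iri", base + local, prefix=pfx.lower())
    raise MalformedTermError(f"cannot interpret IRI reference {ref!r}")


def wo(local: str) -> Term:
    """IRI term in the project namespace."""
    if not local:
        raise MalformedTermError("empty local name in project namespace")
    return Term("iri", WO + local, prefix="wo")


def literal(value: str, datatype: Optional[str] = None) -> Term:
    if datatype == XSD_NS + "string":
        datatype = None
    return Term("literal", value, datatype=datatype)


def decimal_literal(lexical: str) -> Term:
    """Tanimoto similarities etc.: an ``xsd:decimal`` keeping its printed
    lexical form (``"0.774"`` stays ``"0.774"``)."""
    return Term("literal", lexical, datatype=XSD_NS + "decimal")


RDF_TYPE = Term("iri", RDF_NS + "type", prefix="rdf")


@dataclass(frozen=True)
class Triple:
    """One statement.  Subject and predicate must be IRIs."""

    subject: Term
    predicate: Term
    object: Term

    def __post_init__(self) -> None:
        for role, term in (("subject", self.subject), ("predicate", self.predicate)):
            if not isinstance(term, Term) or not term.is_iri:
                raise MalformedTermError(f"triple {role} must be an IRI term, got {term!r}")
        if not isinstance(self.object, Term):
            raise MalformedTermError(f"triple object must be a Term, got {self.object!r}")

    def __repr__(self) -> str:
        return f"({self.subject!r} {self.predicate!r} {self.object!r})"


@dataclass(frozen=True)
class TriplePattern:
    """A triple with variables allowed in any position."""

    subject: PatternTerm
    predicate: PatternTerm
    object: PatternTerm

    def positions(self) -> Tuple[PatternTerm, PatternTerm, PatternTerm]:
        return (self.subject, self.predicate, self.object)

    def variables(self) -> Set[str]:
        return {p.name for p in self.positions() if isinstance(p, Variable)}

    def substitute(self, binding: "Binding") -> "TriplePattern":
        def sub(p: PatternTerm) -> PatternTerm:
            if isinstance(p, Variable) and p.name in binding:
                return binding[p.name]
            return p

        return TriplePattern(sub(self.subject), sub(self.predicate), sub(self.object))

    def ground(self, binding: "Binding") -> Triple:
        """Instantiate to a Triple; raises if any variable is left unbound."""
        pat = self.substitute(binding)
        for p in pat.positions():
            if isinstance(p, Variable):
                raise ValueError(f"unbound variable ?{p.name} when grounding {self!r}")
        assert isinstance(pat.subject, Term) and isinstance(pat.predicate, Term)
        assert isinstance(pat.object, Term)
        return Triple(pat.subject, pat.predicate, pat.object)

    def __repr__(self) -> str:
        return f"({self.subject!r} {self.predicate!r} {self.object!r})"


class Binding:
    """An immutable variable assignment (variable name -> ground Term)."""

    __slots__ = ("_items", "_hash")

    def __init__(self, mapping: Union[Dict[str, Term], Iterable[Tuple[str, Term]]] = ()):
        if isinstance(mapping, dict):
            items = tuple(sorted(mapping.items()))
        else:
            items = tuple(sorted(mapping))
        self._items: Tuple[Tuple[str, Term], ...] = items
        self._hash = hash(items)

    def __getitem__(self, var: str) -> Term:
        for k, v in self._items:
            if k == var:
                return v
        raise KeyError(var)

    def get(self, var: str, default: Optional[Term] = None) -> Optional[Term]:
        try:
            return self[var]
        except KeyError:
            return default

    def __contains__(self, var: str) -> bool:
        return any(k == var for k, _ in self._items)

    def __iter__(self) -> Iterator[str]:
        return (k for k, _ in self._items)

    def items(self) -> Tuple[Tuple[str, Term], ...]:
        return self._items

    def as_dict(self) -> Dict[str, Term]:
        return dict(self._items)

    def extended(self, var: str, value: Term) -> Optional["Binding"]:
        """Binding with ``var=value`` added; None on conflicting rebind."""
        existing = self.get(var)
        if existing is not None:
            return self if existing == value else None
        return Binding(self._items + ((var, value),))

    def restricted(self, variables: Iterable[str]) -> "Binding":
        keep = set(variables)
        return Binding(tuple((k, v) for k, v in self._items if k in keep))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Binding) and self._items == other._items

    def __hash__(self) -> int:
        return self._hash

    def __len__(self) -> int:
        return len(self._items)

    def __repr__(self) -> str:
        inner = ", ".join(f"?{k}→{v!r}" for k, v in self._items)
        return "{" + inner + "}"


# --------------------------------------------------------------------------
# Ontology

#: Sentinel range meaning "a literal value", e.g. names, titles, similarities.
LITERAL_RANGE = "literal"


@dataclass(frozen=True)
class PropertySignature:
    domains: FrozenSet[Term]
    ranges: Union[FrozenSet[Term], str]  # class set or LITERAL_RANGE


@dataclass(frozen=True)
class Ontology:
    """Entity classes plus property domain/range declarations."""

    classes: FrozenSet[Term]
    properties: Dict[Term, PropertySignature]

    def is_declared(self, predicate: Term) -> bool:
        return predicate == RDF_TYPE or predicate in self.properties


def _sig(domains: Iterable[str], ranges: Union[Iterable[str], str]) -> PropertySignature:
    dom = frozenset(wo(c) for c in domains)
    if ranges == LITERAL_RANGE:
        return PropertySignature(dom, LITERAL_RANGE)
    return PropertySignature(dom, frozenset(wo(c) for c in ranges))


CLASSES = ("ChemicalCompound", "BioAssay", "JournalArticle", "Gene", "Disease")

#: The project ontology: five entity classes, and every property emitted by
#: the ingest pipeline or referenced by the inference rules.  ``hasGenes``/
#: ``hasDiseases`` are accepted read-time aliases of hasGene/hasDisease (the
#: rules are the executable surface, and they use the singular forms).
CE_ONTOLOGY = Ontology(
    classes=frozenset(wo(c) for c in CLASSES),
    properties={
        wo("isSimilarTo"): _sig(["ChemicalCompound"], ["ChemicalCompound"]),
        wo("isActiveIn"): _sig(["ChemicalCompound"], ["BioAssay"]),
        wo("isContainedIn"): _sig(["ChemicalCompound"], ["JournalArticle"]),
        wo("hasGene"): _sig(
            ["BioAssay", "JournalArticle", "ChemicalCompound"], ["Gene"]
        ),
        wo("hasDisease"): _sig(
            ["BioAssay", "JournalArticle", "ChemicalCompound"], ["Disease"]
        ),
        # gene-disease association; assays reach diseases through it too when
        # a disease term occurs in an assay description without a gene link.
        wo("isAssociatedWith"): _sig(["Gene", "BioAssay"], ["Disease"]),
        wo("hasSimilarity"): _sig(["ChemicalCompound"], LITERAL_RANGE),
        wo("hasName"): _sig(["ChemicalCompound", "BioAssay"], LITERAL_RANGE),
        wo("hasTitle"): _sig(["JournalArticle"], LITERAL_RANGE),
        wo("isrelatedTo"): _sig(["Gene"], ["ChemicalCompound"]),
        wo("isInferredFrom"): _sig(
            ["Gene", "Disease", "JournalArticle"], LITERAL_RANGE
        ),
        wo("mightHasDisease"): _sig(["ChemicalCompound"], ["Disease"]),
    },
)

#: Read-time predicate aliases -> canonical predicate (printed variants).
PREDICATE_ALIASES: Dict[str, str] = {
    "hasGenes": "hasGene",
    "hasDiseases": "hasDisease",
    "isSimiliarTo": "isSimilarTo",  # misprint in the published Rule 1
}


def canonical_predicate(term: Term) -> Term:
    """Map alias predicates in the project namespace to canonical form."""
    if term.is_iri and term.value.startswith(WO):
        local = term.value[len(WO):]
        if local in PREDICATE_ALIASES:
            return wo(PREDICATE_ALIASES[local])
    return term


# --------------------------------------------------------------------------
# Graph

class KnowledgeGraph:
    """A set of triples with a prefix->namespace map.

    Mutation contract: ``add`` / ``add_triple`` / ``update`` mutate in place
    and return the graph.  Equality compares triple sets only.
    """

    def __init__(self, triples: Iterable[Triple] = (),
                 namespaces: Optional[Dict[str, str]] = None):
        self.namespaces: Dict[str, str] = dict(namespaces or DEFAULT_NAMESPACES)
        if "wo" not in self.namespaces or "rdf" not in self.namespaces:
            raise MalformedTermError("namespace map must bind 'wo' and 'rdf'")
        self._triples: Set[Triple] = set()
        self._by_predicate: Dict[Term, Set[Triple]] = {}
        self._by_subject: Dict[Term, Set[Triple]] = {}
        for t in triples:
            self.add(t)

    # -- mutation ----------------------------------------------------------
    def add(self, t: Triple) -> "KnowledgeGraph":
        if not isinstance(t, Triple):
            raise MalformedTermError(f"not a Triple: {t!r}")
        self._check_resolvable(t)
        if t not in self._triples:
            self._triples.add(t)
            self._by_predicate.setdefault(t.predicate, set()).add(t)
            self._by_subject.setdefault(t.subject, set()).add(t)
        return self

    def update(self, triples: Iterable[Triple]) -> "KnowledgeGraph":
        for t in triples:
            self.add(t)
        return self

    def _check_resolvable(self, t: Triple) -> None:
        for term in (t.subject, t.predicate, t.object):
            if term.is_iri and term.prefix is not None \
                    and term.prefix not in self.namespaces:
                raise MalformedTermError(
                    f"term {term.value!r} carries prefix {term.prefix!r} "
                    f"not bound in the graph's namespace map")

    # -- access ------------------------------------------------------------
    def __contains__(self, t: Triple) -> bool:
        return t in self._triples

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self._triples)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, KnowledgeGraph) and self._triples == other._triples

    def __hash__(self):  # mutable container
        raise TypeError("KnowledgeGraph is unhashable")

    def copy(self) -> "KnowledgeGraph":
        return KnowledgeGraph(self._triples, self.namespaces)

    def triples(self) -> FrozenSet[Triple]:
        return frozenset(self._triples)

    def with_predicate(self, predicate: Term) -> Set[Triple]:
        return set(self._by_predicate.get(predicate, ()))

    def with_subject(self, subject: Term) -> Set[Triple]:
        return set(self._by_subject.get(subject, ()))

    def types_of(self, node: Term) -> Set[Term]:
        return {t.object for t in self._by_subject.get(node, ())
                if t.predicate == RDF_TYPE}

    def objects(self, subject: Term, predicate: Term) -> Set[Term]:
        return {t.object for t in self._by_subject.get(subject, ())
                if t.predicate == predicate}

    def __repr__(self) -> str:
        return f"<KnowledgeGraph with {len(self)} triples>"


def add_triple(graph: KnowledgeGraph, t: Triple) -> KnowledgeGraph:
    """Add ``t`` to ``graph`` (set semantics; in-place, returns graph)."""
    return graph.add(t)


def match(graph: KnowledgeGraph, pattern: TriplePattern) -> Set[Binding]:
    """All bindings sigma with sigma(pattern) in graph.

    Complete and sound against a full scan; uses the predicate index when
    the predicate is ground.
    """
    if isinstance(pattern.predicate, Term):
        candidates: Iterable[Triple] = graph.with_predicate(pattern.predicate)
    elif isinstance(pattern.subject, Term):
        candidates = graph.with_subject(pattern.subject)
    else:
        candidates = graph
    out: Set[Binding] = set()
    for t in candidates:
        b = unify(pattern, t)
        if b is not None:
            out.add(b)
    return out


def unify(pattern: TriplePattern, t: Triple, seed: Optional[Binding] = None
          ) -> Optional[Binding]:
    """Unify a pattern with a ground triple, extending ``seed``."""
    b = seed if seed is not None else Binding()
    for p, g in zip(pattern.positions(), (t.subject, t.predicate, t.object)):
        if isinstance(p, Variable):
            nxt = b.extended(p.name, g)
            if nxt is None:
                return None
            b = nxt
        elif p != g:
            return None
    return b


# --------------------------------------------------------------------------
# Validation

@dataclass(frozen=True)
class Violation:
    triple: Optional[Triple]
    kind: str  # undeclared_predicate | domain | range | multiple_types
    message: str


@dataclass
class ValidationReport:
    violations: List[Violation]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def __iter__(self) -> Iterator[Violation]:
        return iter(self.violations)


def validate(graph: KnowledgeGraph, ontology: Ontology = CE_ONTOLOGY
             ) -> ValidationReport:
    """Per-triple domain/range conformance report.

    A triple is flagged when its predicate is undeclared, when its subject's
    declared rdf:type is outside the property's domain, when its object is a
    literal where a class is required (or vice versa), or when a typed
    object falls outside the declared range.  Untyped nodes are not flagged
    (nothing contradicts the declaration).  Nodes carrying more than one
    ontology class are reported once as ``multiple_types``.
    """
    violations: List[Violation] = []
    multi_seen: Set[Term] = set()
    for t in sorted(graph, key=lambda x: (x.subject.value, x.predicate.value,
                                          x.object.value)):
        if t.predicate == RDF_TYPE:
            continue
        pred = canonical_predicate(t.predicate)
        sig = ontology.properties.get(pred)
        if sig is None:
            violations.append(Violation(
                t, "undeclared_predicate",
                f"predicate {t.predicate.curie()} is not declared"))
            continue
        stypes = graph.types_of(t.subject) & ontology.classes
        if len(stypes) > 1 and t.subject not in multi_seen:
            multi_seen.add(t.subject)
            violations.append(Violation(
                None, "multiple_types",
                f"node {t.subject.curie()} has multiple ontology classes: "
                + ", ".join(sorted(c.curie() for c in stypes))))
        if stypes and not (stypes & sig.domains):
            violations.append(Violation(
                t, "domain",
                f"subject {t.subject.curie()} of {pred.curie()} is typed "
                + "/".join(sorted(c.curie() for c in stypes))
                + ", outside the declared domain"))
        if sig.ranges == LITERAL_RANGE:
            if not t.object.is_literal:
                violations.append(Violation(
                    t, "range",
                    f"{pred.curie()} expects a literal object, got IRI "
                    f"{t.object.curie()}"))
        else:
            if t.object.is_literal:
                violations.append(Violation(
                    t, "range",
                    f"{pred.curie()} expects a resource object, got literal "
                    f"{t.object.value!r}"))
            else:
                otypes = graph.types_of(t.object) & ontology.classes
                if otypes and not (otypes & sig.ranges):
                    violations.append(Violation(
                        t, "range",
                        f"object {t.object.curie()} of {pred.curie()} is typed "
                        + "/".join(sorted(c.curie() for c in otypes))
                        + ", outside the declared range"))
    return ValidationReport(violations)


# --------------------------------------------------------------------------
# Serialization (rdflib-backed)

_FORMATS = {"ntriples": "nt", "turtle": "turtle"}


def _to_rdflib(graph: KnowledgeGraph) -> rdflib.Graph:
    g = rdflib.Graph()
    for pfx, base in graph.namespaces.items():
        g.bind(pfx, rdflib.Namespace(base))
    for t in graph:
        g.add((_term_to_rdflib(t.subject), _term_to_rdflib(t.predicate),
               _term_to_rdflib(t.object)))
    return g


def _term_to_rdflib(term: Term):
    if term.is_iri:
        return rdflib.URIRef(term.value)
    dt = rdflib.URIRef(term.datatype) if term.datatype else None
    return rdflib.Literal(term.value, datatype=dt)


def _term_from_rdflib(node) -> Term:
    if isinstance(node, rdflib.URIRef):
        s = str(node)
        prefix = None
        for pfx, base in DEFAULT_NAMESPACES.items():
            if s.startswith(base):
                prefix = pfx
                break
        return Term("iri", s, prefix=prefix)
    if isinstance(node, rdflib.Literal):
        dt = str(node.datatype) if node.datatype else None
        return literal(str(node), dt)
    raise GraphSyntaxError(
        f"blank node {node!r} encountered; blank nodes are unsupported")


def write_graph(graph: KnowledgeGraph, format: str = "ntriples") -> str:
    """Serialize to N-Triples or Turtle text."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; use 'ntriples' or 'turtle'")
    return _to_rdflib(graph).serialize(format=_FORMATS[format])


def read_graph(text: str, format: str = "ntriples") -> KnowledgeGraph:
    """Parse N-Triples or Turtle text into a KnowledgeGraph.

    Raises :class:`GraphSyntaxError` (with the parser's line information
    where available) on malformed input or on blank nodes.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; use 'ntriples' or 'turtle'")
    g = rdflib.Graph()
    try:
        g.parse(data=text, format=_FORMATS[format])
    except Exception as exc:  # rdflib raises several parser exception types
        raise GraphSyntaxError(f"parse failure ({format}): {exc}") from exc
    out = KnowledgeGraph()
    for s, p, o in g:
        out.add(Triple(_term_from_rdflib(s), _term_from_rdflib(p),
                       _term_from_rdflib(o)))
    return out
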