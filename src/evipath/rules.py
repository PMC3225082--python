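"""Forward-chaining rule engine with evidence-path provenance.

A :class:`Rule` rewrites a conjunction of triple patterns (the body) into
one or more head patterns.  Rules are *range restricted*: every head
variable must occur in the body, so every inference is ground.  Running
:func:`forward_chain` materializes the graph to fixpoint and records one
:class:`EvidencePath` per rule firing -- the rule id, the full body-variable
binding and the grounded body triples.  Two firings with different bindings
are distinct evidence paths even when they infer the same head triple;
this multiplicity is exactly what the downstream ranking counts.

The default rule base has eight rules.  Rules 1-3 are transcribed verbatim
from the published system (``provenance_tag="paper"``); the remaining five
were never printed and are reconstructions covering the other evidence
channels (``provenance_tag="reconstructed"``): direct curated
compound-disease records, query-anchored assay and target chains, and
literature co-occurrence.  Note that published Rules 2 and 3 start at an
arbitrary compound without an isSimilarTo link; this is kept verbatim (the
input graphs only ever contain the query compound's similar compounds), and
the reconstructed literature rule follows the same unanchored style because
the worked-example data encodes literature evidence as
``gene isrelatedTo compound`` without journal nodes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

from .kg import (
    Binding,
    KnowledgeGraph,
    MalformedTermError,
    Term,
    Triple,
    TriplePattern,
    Variable,
    canonical_predicate,
    iri,
    literal,
    match,
)

__all__ = [
    "Rule", "EvidencePath", "InferenceResult", "RuleSyntaxError",
    "match_body", "forward_chain", "default_rules",
    "load_rules", "parse_rules", "format_rules",
]

PAPER = "paper"
RECONSTRUCTED = "reconstructed"


class RuleSyntaxError(ValueError):
    """Rule-file syntax or safety error; message carries the line number."""


@dataclass(frozen=True)
class Rule:
    """A declarative body -> head rewrite over triple patterns."""

    id: str
    body: Tuple[TriplePattern, ...]
    head: Tuple[TriplePattern, ...]
    provenance_tag: str = RECONSTRUCTED

    def __post_init__(self) -> None:
        if not self.body:
            raise RuleSyntaxError(f"rule {self.id!r}: empty body")
        if not self.head:
            raise RuleSyntaxError(f"rule {self.id!r}: empty head")
        for pat in self.body:
            if isinstance(pat.predicate, Variable):
                raise RuleSyntaxError(
                    f"rule {self.id!r}: body pattern {pat!r} has a predicate "
                    "variable; rule-body predicates must be ground")
        body_vars = self.body_variables()
        for pat in self.head:
            unbound = pat.variables() - body_vars
            if unbound:
                name = sorted(unbound)[0]
                raise RuleSyntaxError(
                    f"rule {self.id!r}: head variable ?{name} does not occur "
                    "in the body (range restriction)")
        if self.provenance_tag not in (PAPER, RECONSTRUCTED):
            raise RuleSyntaxError(
                f"rule {self.id!r}: unknown provenance tag "
                f"{self.provenance_tag!r}")

    def body_variables(self) -> Set[str]:
        out: Set[str] = set()
        for pat in self.body:
            out |= pat.variables()
        return out


@dataclass(frozen=True)
class EvidencePath:
    """One grounded rule firing.

    Identity is (rule_id, binding over the body variables): the grounded
    body and head are functions of those two, so dataclass equality
    coincides with the path-identity contract.
    """

    rule_id: str
    binding: Binding
    grounded_body: Tuple[Triple, ...]
    inferred: Tuple[Triple, ...]

    def triples(self) -> Tuple[Triple, ...]:
        return self.grounded_body + self.inferred


@dataclass
class InferenceResult:
    """Materialized graph (input plus inferences) and all evidence paths."""

    graph: KnowledgeGraph
    paths: FrozenSet[EvidencePath]

    def inferred_triples(self) -> Set[Triple]:
        out: Set[Triple] = set()
        for p in self.paths:
            out.update(p.inferred)
        return out


def match_body(graph: KnowledgeGraph, body: Sequence[TriplePattern]
               ) -> Set[Binding]:
    """All total assignments satisfying every body pattern (conjunctive join).

    The result is independent of pattern order; patterns are joined
    left-to-right, extending partial bindings pattern by pattern.
    """
    partial: List[Binding] = [Binding()]
    for pat in body:
        nxt: List[Binding] = []
        for b in partial:
            sub = pat.substitute(b)
            for extension in match(graph, sub):
                merged = b
                ok = True
                for var, val in extension.items():
                    res = merged.extended(var, val)
                    if res is None:
                        ok = False
                        break
                    merged = res
                if ok:
                    nxt.append(merged)
        partial = nxt
        if not partial:
            return set()
    all_vars: Set[str] = set()
    for pat in body:
        all_vars |= pat.variables()
    return {b.restricted(all_vars) for b in partial}


def forward_chain(graph: KnowledgeGraph, rules: Sequence[Rule],
                  max_rounds: int = 1000) -> InferenceResult:
    """Naive fixpoint: re-evaluate every rule until nothing new fires.

    The input graph is not mutated.  On the default rule base a single
    round suffices (the head vocabulary ``mightHasDisease`` feeds no body),
    but inferred triples are re-matched each round so chained rule sets are
    handled too; ``max_rounds`` guards non-terminating reconstructions.
    """
    work = graph.copy()
    fired: Dict[Tuple[str, Binding], EvidencePath] = {}
    for _ in range(max_rounds):
        changed = False
        for rule in rules:
            for binding in match_body(work, rule.body):
                key = (rule.id, binding)
                if key in fired:
                    continue
                grounded_body = tuple(p.ground(binding) for p in rule.body)
                inferred = tuple(p.ground(binding) for p in rule.head)
                path = EvidencePath(rule.id, binding, grounded_body, inferred)
                fired[key] = path
                for t in inferred:
                    work.add(t)
                changed = True
        if not changed:
            return InferenceResult(work, frozenset(fired.values()))
    raise RuntimeError(
        f"forward chaining did not reach a fixpoint within {max_rounds} "
        "rounds; the rule set likely derives an unbounded chain")


# --------------------------------------------------------------------------
# Default rule base

def _v(name: str) -> Variable:
    return Variable(name)


def _pat(s, p, o) -> TriplePattern:
    def conv(x):
        if isinstance(x, (Variable, Term)):
            return x
        if isinstance(x, str) and x.startswith("?"):
            return Variable(x[1:])
        return iri(x)
    return TriplePattern(conv(s), conv(p), conv(o))


def default_rules() -> List[Rule]:
    """The eight-rule base.

    rule1-rule3 are the published rules, verbatim (the misprint
    ``isSimiliarTo`` in the published Rule 1 normalizes to isSimilarTo).
    rule4-rule8 reconstruct the unpublished evidence channels:

    - rule4: similar compound with a directly curated disease record.
    - rule5: query-anchored assay chain (isSimilarTo o isActiveIn o
      hasGene o isAssociatedWith).
    - rule6: literature co-occurrence as encoded in the data
      (gene isrelatedTo compound), unanchored like published Rules 2-3.
    - rule7: query-anchored screening-target chain (compound hasGene).
    - rule8: article carrying a disease term directly.
    """
    Q, C, B, G, D, J = ("?QueryCompound", "?CompoundID", "?Bioassay",
                        "?Gene", "?Disease", "?Journal")
    might = "wo:mightHasDisease"
    r = [
        Rule("rule1", (
            _pat(Q, "wo:isSimilarTo", C),
            _pat(C, "wo:isActiveIn", B),
            _pat(B, "wo:isAssociatedWith", D),
        ), (_pat(Q, might, D),), PAPER),
        Rule("rule2", (
            _pat(C, "wo:isContainedIn", J),
            _pat(J, "wo:hasGene", G),
            _pat(G, "wo:isAssociatedWith", D),
        ), (_pat(C, might, D),), PAPER),
        Rule("rule3", (
            _pat(C, "wo:isActiveIn", B),
            _pat(B, "wo:hasGene", G),
            _pat(G, "wo:isAssociatedWith", D),
        ), (_pat(C, might, D),), PAPER),
        Rule("rule4", (
            _pat(Q, "wo:isSimilarTo", C),
            _pat(C, "wo:hasDisease", D),
        ), (_pat(Q, might, D),), RECONSTRUCTED),
        Rule("rule5", (
            _pat(Q, "wo:isSimilarTo", C),
            _pat(C, "wo:isActiveIn", B),
            _pat(B, "wo:hasGene", G),
            _pat(G, "wo:isAssociatedWith", D),
        ), (_pat(Q, might, D),), RECONSTRUCTED),
        Rule("rule6", (
            _pat(G, "wo:isrelatedTo", C),
            _pat(G, "wo:isAssociatedWith", D),
        ), (_pat(C, might, D),), RECONSTRUCTED),
        Rule("rule7", (
            _pat(Q, "wo:isSimilarTo", C),
            _pat(C, "wo:hasGene", G),
            _pat(G, "wo:isAssociatedWith", D),
        ), (_pat(Q, might, D),), RECONSTRUCTED),
        Rule("rule8", (
            _pat(Q, "wo:isSimilarTo", C),
            _pat(C, "wo:isContainedIn", J),
            _pat(J, "wo:hasDisease", D),
        ), (_pat(Q, might, D),), RECONSTRUCTED),
    ]
    return r


# --------------------------------------------------------------------------
# Rule DSL
#
#   # comment
#   [rule1 {paper}: (?QueryCompound wo:isSimilarTo ?CompoundID),
#                   (?CompoundID wo:isActiveIn ?Bioassay)
#                   -> (?QueryCompound wo:mightHasDisease ?Bioassay)]
#
# mirroring the published bracketed syntax; the {tag} annotation is
# optional and defaults to "reconstructed".  Prefixes resolve
# case-insensitively, and printed predicate variants (isSimiliarTo,
# hasGenes, hasDiseases) normalize to canonical form.

_PATTERN_RE = re.compile(r"\(([^()]*)\)")
_TERM_RE = re.compile(r"""\?(?P<var>[A-Za-z_][\w-]*)
                          |"(?P<lit>(?:[^"\\]|\\.)*)"
                          |<(?P<full>[^<>\s]+)>
                          |(?P<curie>[A-Za-z_][\w.-]*:[\w.-]+)
                       """, re.X)


def _parse_pattern(text: str, line: int) -> TriplePattern:
    parts: List = []
    pos = 0
    while pos < len(text):
        if text[pos].isspace() or text[pos] == ",":
            pos += 1
            continue
        m = _TERM_RE.match(text, pos)
        if not m:
            raise RuleSyntaxError(
                f"line {line}: cannot read term at {text[pos:pos+20]!r}")
        if m.group("var") is not None:
            parts.append(Variable(m.group("var")))
        elif m.group("lit") is not None:
            parts.append(literal(m.group("lit").replace('\\"', '"')
                                 .replace("\\\\", "\\")))
        elif m.group("full") is not None:
            parts.append(Term("iri", m.group("full")))
        else:
            try:
                parts.append(iri(m.group("curie")))
            except MalformedTermError as exc:
                raise RuleSyntaxError(f"line {line}: {exc}") from exc
        pos = m.end()
    if len(parts) != 3:
        raise RuleSyntaxError(
            f"line {line}: pattern ({text.strip()}) has {len(parts)} terms, "
            "expected 3")
    subj, pred, obj = parts
    if isinstance(pred, Term):
        pred = canonical_predicate(pred)
    return TriplePattern(subj, pred, obj)


def parse_rules(text: str) -> List[Rule]:
    """Parse a rule file; raises :class:`RuleSyntaxError` with line info."""
    rules: List[Rule] = []
    # strip comments, keep a char->line map via per-line scan
    depth = 0
    buf: List[str] = []
    start_line = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0]
        if not line.strip() and depth == 0:
            continue
        if depth == 0:
            stripped = line.lstrip()
            if not stripped:
                continue
            if not stripped.startswith("["):
                raise RuleSyntaxError(
                    f"line {lineno}: expected '[' starting a rule, got "
                    f"{stripped[:20]!r}")
            start_line = lineno
        buf.append(line)
        depth += line.count("[") - line.count("]")
        if depth < 0:
            raise RuleSyntaxError(f"line {lineno}: unbalanced ']'")
        if depth == 0:
            rules.append(_parse_rule_block(" ".join(buf), start_line))
            buf = []
    if depth != 0:
        raise RuleSyntaxError(f"line {start_line}: unterminated rule block")
    return rules


def _parse_rule_block(block: str, line: int) -> Rule:
    block = block.strip()
    assert block.startswith("[") and block.endswith("]")
    inner = block[1:-1]
    if ":" not in inner:
        raise RuleSyntaxError(f"line {line}: missing ':' after rule id")
    head_part, _, rest = inner.partition(":")
    rule_id = head_part.strip()
    tag = RECONSTRUCTED
    m = re.match(r"^(.*?)\{\s*(\w+)\s*\}$", rule_id)
    if m:
        rule_id, tag = m.group(1).strip(), m.group(2)
    if not rule_id:
        raise RuleSyntaxError(f"line {line}: empty rule id")
    if "->" not in rest:
        raise RuleSyntaxError(f"line {line}: rule {rule_id!r} missing '->'")
    body_text, _, head_text = rest.partition("->")
    body = tuple(_parse_pattern(p, line) for p in _PATTERN_RE.findall(body_text))
    head = tuple(_parse_pattern(p, line) for p in _PATTERN_RE.findall(head_text))
    if not body:
        raise RuleSyntaxError(f"line {line}: rule {rule_id!r} has no body patterns")
    if not head:
        raise RuleSyntaxError(f"line {line}: rule {rule_id!r} has no head patterns")
    try:
        return Rule(rule_id, body, head, tag)
    except RuleSyntaxError as exc:
        raise RuleSyntaxError(f"line {line}: {exc}") from exc


def load_rules(text: str) -> List[Rule]:
    """Alias of :func:`parse_rules` (the operation's contract name)."""
    return parse_rules(text)


def _format_term(t) -> str:
    if isinstance(t, Variable):
        return f"?{t.name}"
    if t.is_literal:
        return '"' + t.value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    return t.curie()


def _format_pattern(p: TriplePattern) -> str:
    return "(" + " ".join(_format_term(x) for x in p.positions()) + ")"


def format_rules(rules: Iterable[Rule]) -> str:
    """Canonical text for a rule list; ``parse_rules`` round-trips it."""
    blocks = []
    for r in rules:
        body = ",\n    ".join(_format_pattern(p) for p in r.body)
        head = ", ".join(_format_pattern(p) for p in r.head)
        blocks.append(f"[{r.id} {{{r.provenance_tag}}}:\n    {body}\n    -> {head}]")
    return "\n\n".join(blocks) + ("\n" if blocks else "")
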