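"""Cluster, rank and filter inferred evidence paths by disease.

Two rank metrics are exposed.  ``path_count`` (the default) scores a
disease by the number of distinct evidence paths inferring it -- the
stated intent of the original ranking.  ``property_count`` reproduces the
system's published aggregate query literally: it counts the statements
whose subject is the disease node in the materialized graph (including
typing and provenance statements).  The two can legitimately disagree:
several paths that share one gene-disease statement collapse under the
graph's set semantics, so property_count under-counts path multiplicity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Set

from ._schema import load_packaged_schema, validate_instance
from .kg import KnowledgeGraph, Term, wo
from .rules import EvidencePath, InferenceResult

__all__ = [
    "DiseaseCluster", "RankedAssociation", "FACETS", "METRICS",
    "cluster_by_disease", "rank", "facet_filter",
    "to_result_json", "build_result", "validate_result",
]

METRICS = ("path_count", "property_count")
FACETS = ("disease", "compound", "assay", "gene", "journal", "gene_family")

MIGHT_HAS_DISEASE = wo("mightHasDisease")


@dataclass(frozen=True)
class DiseaseCluster:
    disease: Term
    paths: FrozenSet[EvidencePath]

    def __post_init__(self) -> None:
        if not self.paths:
            raise ValueError(f"empty cluster for {self.disease!r}")


@dataclass(frozen=True)
class RankedAssociation:
    disease: Term
    score: float
    metric: str
    rank: int
    paths: FrozenSet[EvidencePath]


def _path_disease(path: EvidencePath) -> Term:
    diseases = {t.object for t in path.inferred
                if t.predicate == MIGHT_HAS_DISEASE}
    if len(diseases) != 1:
        raise ValueError(
            f"path {path.rule_id}/{path.binding!r} infers "
            f"{len(diseases)} diseases; clustering expects exactly one")
    return diseases.pop()


def cluster_by_disease(result: InferenceResult) -> List[DiseaseCluster]:
    """Partition evidence paths by their inferred disease (sorted by IRI)."""
    buckets: Dict[Term, Set[EvidencePath]] = {}
    for path in result.paths:
        buckets.setdefault(_path_disease(path), set()).add(path)
    return [DiseaseCluster(d, frozenset(paths))
            for d, paths in sorted(buckets.items(), key=lambda kv: kv[0].value)]


def rank(clusters: Iterable[DiseaseCluster], metric: str = "path_count", *,
         graph: Optional[KnowledgeGraph] = None) -> List[RankedAssociation]:
    """Score and order clusters, descending; ties break on disease IRI.

    ``property_count`` needs the materialized ``graph`` (it counts the
    disease node's statements there).  Ranks are 1..N without gaps.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; use one of {METRICS}")
    clusters = list(clusters)
    if metric == "property_count" and graph is None:
        raise ValueError("property_count needs graph= (the materialized graph)")

    def score(c: DiseaseCluster) -> float:
        if metric == "path_count":
            return float(len(c.paths))
        return float(len(graph.with_subject(c.disease)))

    ordered = sorted(clusters, key=lambda c: (-score(c), c.disease.value))
    return [RankedAssociation(c.disease, score(c), metric, i + 1,
                              frozenset(c.paths))
            for i, c in enumerate(ordered)]


# --------------------------------------------------------------------------
# Facets

_P = {name: wo(name) for name in (
    "isSimilarTo", "isActiveIn", "isContainedIn", "isrelatedTo", "hasGene",
    "hasDisease", "hasTitle", "isAssociatedWith", "mightHasDisease")}


def path_facet_values(path: EvidencePath, facet: str) -> Set[Term]:
    """Terms playing ``facet``'s role in the path's grounded triples."""
    out: Set[Term] = set()
    for t in path.triples():
        p = t.predicate
        if facet == "compound":
            if p in (_P["isSimilarTo"], _P["isrelatedTo"]):
                out.add(t.object)
            if p in (_P["isSimilarTo"], _P["isActiveIn"], _P["isContainedIn"],
                     _P["mightHasDisease"], _P["hasDisease"]):
                out.add(t.subject)
        elif facet == "assay":
            if p == _P["isActiveIn"]:
                out.add(t.object)
        elif facet in ("gene", "gene_family"):
            if p == _P["hasGene"]:
                out.add(t.object)
            if p == _P["isrelatedTo"]:
                out.add(t.subject)
            if p == _P["isAssociatedWith"]:
                out.add(t.subject)  # may be an assay; family lookup ignores it
        elif facet == "journal":
            if p == _P["isContainedIn"]:
                out.add(t.object)
            if p == _P["hasTitle"]:
                out.add(t.subject)
        elif facet == "disease":
            if p in (_P["mightHasDisease"], _P["hasDisease"],
                     _P["isAssociatedWith"]):
                out.add(t.object)
    return out


def facet_filter(paths: Iterable[EvidencePath], facet: str, value: Term, *,
                 gene_families: Optional[Dict[str, str]] = None
                 ) -> Set[EvidencePath]:
    """Paths whose ``facet`` role contains ``value``; filters compose by
    intersection.  The ``gene_family`` facet needs a gene-id -> family map
    (no family data exists in the core model) and matches paths whose gene
    belongs to the requested family.
    """
    if facet not in FACETS:
        raise ValueError(f"unknown facet {facet!r}; use one of {FACETS}")
    if facet == "gene_family":
        if gene_families is None:
            raise ValueError(
                "the gene_family facet is unavailable without a "
                "gene-to-family mapping")
        wanted = {wo(g) for g, fam in gene_families.items()
                  if fam == value.local}
        return {p for p in paths
                if path_facet_values(p, "gene") & wanted}
    return {p for p in paths if value in path_facet_values(p, facet)}


# --------------------------------------------------------------------------
# Result JSON

def _path_entry(path: EvidencePath, graph: Optional[KnowledgeGraph]) -> dict:
    compound = _primary_compound(path)
    similarity = None
    provenance: List[str] = []
    if graph is not None:
        if compound is not None:
            sims = graph.objects(compound, wo("hasSimilarity"))
            if sims:
                similarity = float(sorted(s.value for s in sims)[0])
        for node in _path_nodes(path):
            for lit in graph.objects(node, wo("isInferredFrom")):
                provenance.append(lit.value)
    entry = {
        "rule": path.rule_id,
        "similar_compound": compound.local if compound else "",
        "similarity": similarity,
    }
    genes = sorted(t.local for t in path_facet_values(path, "gene"))
    assays = sorted(t.local for t in path_facet_values(path, "assay"))
    journals = sorted(t.local for t in path_facet_values(path, "journal"))
    if genes:
        entry["gene"] = genes[0]
    if assays:
        entry["bioassay"] = assays[0]
    if journals:
        entry["article"] = journals[0]
    entry["provenance"] = sorted(set(provenance))
    return entry


def _primary_compound(path: EvidencePath) -> Optional[Term]:
    for pred in ("isSimilarTo", "isrelatedTo"):
        for t in path.grounded_body:
            if t.predicate == _P[pred]:
                return t.object
    for t in path.inferred:
        if t.predicate == MIGHT_HAS_DISEASE:
            return t.subject
    return None


def _path_nodes(path: EvidencePath) -> Set[Term]:
    out: Set[Term] = set()
    for t in path.triples():
        out.add(t.subject)
        if t.object.is_iri:
            out.add(t.object)
    return out


def build_result(ranked: Iterable[RankedAssociation], *,
                 graph: Optional[KnowledgeGraph] = None) -> List[dict]:
    """Result document as a Python list (ordered by rank; stable fields)."""
    out = []
    for assoc in sorted(ranked, key=lambda a: a.rank):
        paths = sorted(
            assoc.paths,
            key=lambda p: (p.rule_id, tuple((k, v.value)
                                            for k, v in p.binding.items())))
        out.append({
            "disease": assoc.disease.local,
            "score": assoc.score,
            "metric": assoc.metric,
            "rank": assoc.rank,
            "paths": [_path_entry(p, graph) for p in paths],
        })
    return out


def to_result_json(ranked: Iterable[RankedAssociation], *,
                   graph: Optional[KnowledgeGraph] = None) -> str:
    """Serialize a ranking to the shipped result-JSON schema.

    ``graph`` (the materialized graph) supplies similarity literals and
    isInferredFrom provenance; without it those fields are null/empty.
    """
    doc = build_result(ranked, graph=graph)
    validate_result(doc)
    return json.dumps(doc, indent=2) + "\n"


def validate_result(doc) -> None:
    """Raise :class:`evipath._schema.SchemaError` if non-conformant."""
    validate_instance(doc, load_packaged_schema("result.schema.json"))
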