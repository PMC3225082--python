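"""Parse aggregated chemogenomic XML and side tables into ontology triples.

The input document (dialect defined by the shipped ``wendi.xsd`` schema)
describes one query compound and its similar compounds, grouped into four
evidence channels: ``ActiveBioassay`` (activity in a screening assay),
``CTD`` (curated compound-disease records), ``Chembl`` (screening target
genes) and ``Literature`` (article co-occurrence).  Side tables are plain
TSV: gene / disease / GO-term lexicons (surface term -> entity id), a
GO-term -> gene annotation, and a gene-disease association matrix with
optional PubMed provenance.

Free text (assay descriptions, article titles and abstracts) is annotated
by dictionary lookup: by default case-insensitive substring matching (the
behaviour of a plain SQL ``position`` call), with an optional
word-boundary mode that suppresses matches embedded inside longer words.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Set, Tuple, Union

import pandas as pd
from lxml import etree

from .kg import (
    KnowledgeGraph,
    RDF_TYPE,
    Triple,
    decimal_literal,
    literal,
    wo,
)

__all__ = [
    "GROUP_NAMES", "Record", "WendiRecordSet",
    "BioassayPayload", "CtdDiseasePayload", "ChemblPayload", "LiteraturePayload",
    "Lexicon", "GoAnnotation", "GeneDiseaseMatrix",
    "parse_wendi_xml", "WendiSchemaError",
    "load_lexicon", "load_go_annotation", "load_gene_disease_matrix",
    "extract_terms", "go_terms_to_genes", "genes_to_diseases", "to_triples",
]

GROUP_NAMES = ("ActiveBioassay", "CTD", "Chembl", "Literature")


class WendiSchemaError(ValueError):
    """Input XML fails the shipped schema; message names element and line."""


@dataclass(frozen=True)
class BioassayPayload:
    assay_id: str
    description: str


@dataclass(frozen=True)
class CtdDiseasePayload:
    disease_id: str
    provenance: Optional[str] = None


@dataclass(frozen=True)
class ChemblPayload:
    gene_id: str


@dataclass(frozen=True)
class LiteraturePayload:
    article_id: str
    title: str
    abstract: str = ""


Payload = Union[BioassayPayload, CtdDiseasePayload, ChemblPayload,
                LiteraturePayload]

_PAYLOAD_GROUP = {
    BioassayPayload: "ActiveBioassay",
    CtdDiseasePayload: "CTD",
    ChemblPayload: "Chembl",
    LiteraturePayload: "Literature",
}


@dataclass(frozen=True)
class Record:
    """One similar-compound evidence record."""

    similar_compound: str
    similarity: str  # lexical decimal in [0, 1], kept as printed
    payload: Payload
    compound_name: Optional[str] = None

    def __post_init__(self) -> None:
        value = float(self.similarity)
        if not 0.0 <= value <= 1.0:
            raise ValueError(
                f"similarity {self.similarity!r} outside [0, 1] for "
                f"{self.similar_compound}")

    @property
    def group(self) -> str:
        return _PAYLOAD_GROUP[type(self.payload)]


@dataclass
class WendiRecordSet:
    """Parsed document: query compound plus the four record groups."""

    query_id: str
    smiles: str
    groups: Dict[str, List[Record]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in GROUP_NAMES:
            self.groups.setdefault(name, [])
        unknown = set(self.groups) - set(GROUP_NAMES)
        if unknown:
            raise ValueError(f"unknown record groups: {sorted(unknown)}")

    def records(self) -> List[Record]:
        return [r for name in GROUP_NAMES for r in self.groups[name]]


# --------------------------------------------------------------------------
# XML parsing

def _load_xsd() -> etree.XMLSchema:
    text = resources.files("evipath").joinpath("schemas", "wendi.xsd") \
        .read_bytes()
    return etree.XMLSchema(etree.parse(io.BytesIO(text)))


def parse_wendi_xml(document: str) -> WendiRecordSet:
    """Parse and schema-validate an evidence document.

    Raises :class:`WendiSchemaError` naming the offending element and line
    when the document does not conform.
    """
    try:
        tree = etree.parse(io.BytesIO(document.encode("utf-8")))
    except etree.XMLSyntaxError as exc:
        raise WendiSchemaError(f"not well-formed XML: {exc}") from exc
    schema = _load_xsd()
    if not schema.validate(tree):
        err = schema.error_log[0]
        raise WendiSchemaError(
            f"schema violation at line {err.line}: {err.message}")
    root = tree.getroot()
    rs = WendiRecordSet(query_id=root.get("query-id"),
                        smiles=root.get("smiles", ""))
    for group_el in root.findall("group"):
        name = group_el.get("name")
        for rec_el in group_el.findall("record"):
            payload = _parse_payload(name, rec_el)
            rs.groups[name].append(Record(
                similar_compound=rec_el.get("compound"),
                similarity=rec_el.get("similarity"),
                payload=payload,
                compound_name=rec_el.get("name"),
            ))
    return rs


_GROUP_PAYLOAD_TAG = {"ActiveBioassay": "bioassay", "CTD": "disease",
                      "Chembl": "target", "Literature": "article"}


def _parse_payload(group: str, rec_el: etree._Element) -> Payload:
    expected = _GROUP_PAYLOAD_TAG[group]
    el = rec_el.find(expected)
    if el is None:
        child = rec_el[0] if len(rec_el) else rec_el
        raise WendiSchemaError(
            f"schema violation at line {child.sourceline}: record in group "
            f"{group!r} must carry a <{expected}> element")
    if group == "ActiveBioassay":
        return BioassayPayload(el.get("id"), el.get("description", ""))
    if group == "CTD":
        return CtdDiseasePayload(el.get("id"), el.get("provenance"))
    if group == "Chembl":
        return ChemblPayload(el.get("gene"))
    return LiteraturePayload(el.get("pmid"), el.get("title", ""),
                             el.get("abstract", ""))


# --------------------------------------------------------------------------
# Side tables

@dataclass(frozen=True)
class Lexicon:
    """Surface term -> entity id dictionary of a single entity kind."""

    entries: Tuple[Tuple[str, str], ...]  # (surface term, entity id)
    entity_kind: str  # gene | disease | go_term

    def __post_init__(self) -> None:
        if self.entity_kind not in ("gene", "disease", "go_term"):
            raise ValueError(f"unknown lexicon kind {self.entity_kind!r}")
        for surface, _ in self.entries:
            if not surface:
                raise ValueError("empty surface term in lexicon")


@dataclass(frozen=True)
class GoAnnotation:
    mapping: Dict[str, frozenset]  # GO-term id -> gene ids

    def __post_init__(self) -> None:
        for term, genes in self.mapping.items():
            if not genes:
                raise ValueError(f"GO term {term!r} maps to no genes")


@dataclass(frozen=True)
class GeneDiseaseMatrix:
    """(gene, disease, optional provenance) association rows."""

    associations: FrozenSetRows = ()

    def rows_for(self, genes: Set[str]) -> List[Tuple[str, str, Optional[str]]]:
        return [row for row in self.associations if row[0] in genes]


FrozenSetRows = Tuple[Tuple[str, str, Optional[str]], ...]


def _read_tsv(source) -> pd.DataFrame:
    if isinstance(source, str) and "\t" in source or \
            isinstance(source, str) and "\n" in source:
        return pd.read_csv(io.StringIO(source), sep="\t", dtype=str,
                           keep_default_na=False)
    return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)


def load_lexicon(source, entity_kind: str) -> Lexicon:
    """Load a 2-column TSV (``term``, ``entity_id``) lexicon."""
    df = _read_tsv(source)
    return Lexicon(tuple(zip(df["term"], df["entity_id"])), entity_kind)


def load_go_annotation(source) -> GoAnnotation:
    """Load a 2-column TSV (``go_id``, ``gene_id``); rows aggregate per term."""
    df = _read_tsv(source)
    mapping: Dict[str, set] = {}
    for go_id, gene in zip(df["go_id"], df["gene_id"]):
        mapping.setdefault(go_id, set()).add(gene)
    return GoAnnotation({k: frozenset(v) for k, v in mapping.items()})


def load_gene_disease_matrix(source) -> GeneDiseaseMatrix:
    """Load a 2-3 column TSV (``gene_id``, ``disease_id``[, ``provenance``])."""
    df = _read_tsv(source)
    prov = df["provenance"] if "provenance" in df.columns else [""] * len(df)
    rows = tuple(
        (g, d, (p or None))
        for g, d, p in zip(df["gene_id"], df["disease_id"], prov)
    )
    return GeneDiseaseMatrix(rows)


# --------------------------------------------------------------------------
# Annotation operations

def extract_terms(text: str, lexicon: Lexicon, *, case_sensitive: bool = False,
                  word_boundary: bool = False) -> List[Tuple[str, int]]:
    """Dictionary matches in ``text``: (entity id, first-match offset).

    Every lexicon surface term occurring as a substring is reported (no
    longest-match suppression; overlapping terms all match).  Order is by
    offset, then entity id -- deterministic for a fixed lexicon.
    """
    if not text:
        return []
    hits: List[Tuple[int, str]] = []
    haystack = text if case_sensitive else text.lower()
    for surface, entity in lexicon.entries:
        needle = surface if case_sensitive else surface.lower()
        if word_boundary:
            flags = 0 if case_sensitive else re.IGNORECASE
            m = re.search(r"(?<!\w)" + re.escape(surface) + r"(?!\w)", text,
                          flags)
            if m:
                hits.append((m.start(), entity))
        else:
            offset = haystack.find(needle)
            if offset >= 0:
                hits.append((offset, entity))
    hits.sort(key=lambda h: (h[0], h[1]))
    return [(entity, offset) for offset, entity in hits]


def go_terms_to_genes(terms: Set[str], ann: GoAnnotation) -> Set[str]:
    """Union of annotated gene sets; unknown GO terms contribute nothing."""
    out: Set[str] = set()
    for term in terms:
        out |= ann.mapping.get(term, frozenset())
    return out


def genes_to_diseases(genes: Set[str], matrix: GeneDiseaseMatrix
                      ) -> Set[Tuple[str, str, Optional[str]]]:
    """Matrix rows whose gene is in the input set."""
    return set(matrix.rows_for(set(genes)))


# --------------------------------------------------------------------------
# Triple emission

def to_triples(records: WendiRecordSet, gene_lex: Lexicon,
               disease_lex: Lexicon, go_lex: Lexicon, ann: GoAnnotation,
               matrix: GeneDiseaseMatrix, *, word_boundary: bool = False
               ) -> KnowledgeGraph:
    """Emit the ontology-conformant evidence graph for a record set.

    Every record yields the similarity backbone (query isSimilarTo C,
    C hasSimilarity s, typing) plus channel triples:

    - ActiveBioassay: activity edge, assay name, assay->gene links found by
      the gene lexicon or via GO terms and the GO annotation, gene->disease
      rows from the association matrix, and a direct assay-disease edge
      (``isAssociatedWith``) when a disease term occurs in the description.
    - CTD: a direct compound hasDisease edge.
    - Chembl: compound hasGene plus matrix expansion.
    - Literature: compound isContainedIn article, title, gene isrelatedTo
      compound for text co-occurrences (with pubmed provenance), matrix
      expansion, and article hasDisease for disease-term co-occurrences.

    PubMed provenance attaches to the mentioning entity via isInferredFrom,
    e.g. ``HTR1B isInferredFrom "pubmedid8743744"``.
    """
    g = KnowledgeGraph()
    query = wo(records.query_id)
    g.add(Triple(query, RDF_TYPE, wo("ChemicalCompound")))
    kw = dict(word_boundary=word_boundary)

    def emit_gene_diseases(gene_ids: Iterable[str]) -> None:
        for gene, disease, prov in sorted(
                genes_to_diseases(set(gene_ids), matrix),
                key=lambda r: (r[0], r[1], r[2] or "")):
            g.add(Triple(wo(gene), wo("isAssociatedWith"), wo(disease)))
            g.add(Triple(wo(disease), RDF_TYPE, wo("Disease")))
            if prov:
                g.add(Triple(wo(disease), wo("isInferredFrom"), literal(prov)))

    for record in records.records():
        comp = wo(record.similar_compound)
        g.add(Triple(query, wo("isSimilarTo"), comp))
        g.add(Triple(comp, wo("hasSimilarity"),
                     decimal_literal(record.similarity)))
        g.add(Triple(comp, RDF_TYPE, wo("ChemicalCompound")))
        if record.compound_name:
            g.add(Triple(comp, wo("hasName"), literal(record.compound_name)))
        payload = record.payload
        if isinstance(payload, BioassayPayload):
            assay = wo(payload.assay_id)
            g.add(Triple(comp, wo("isActiveIn"), assay))
            g.add(Triple(assay, RDF_TYPE, wo("BioAssay")))
            if payload.description:
                g.add(Triple(assay, wo("hasName"),
                             literal(payload.description)))
            genes = {e for e, _ in extract_terms(payload.description,
                                                 gene_lex, **kw)}
            go_terms = {e for e, _ in extract_terms(payload.description,
                                                    go_lex, **kw)}
            genes |= go_terms_to_genes(go_terms, ann)
            for gene in sorted(genes):
                g.add(Triple(assay, wo("hasGene"), wo(gene)))
                g.add(Triple(wo(gene), RDF_TYPE, wo("Gene")))
            emit_gene_diseases(genes)
            for disease, _ in extract_terms(payload.description, disease_lex,
                                            **kw):
                g.add(Triple(assay, wo("isAssociatedWith"), wo(disease)))
                g.add(Triple(wo(disease), RDF_TYPE, wo("Disease")))
        elif isinstance(payload, CtdDiseasePayload):
            disease = wo(payload.disease_id)
            g.add(Triple(comp, wo("hasDisease"), disease))
            g.add(Triple(disease, RDF_TYPE, wo("Disease")))
            if payload.provenance:
                g.add(Triple(disease, wo("isInferredFrom"),
                             literal(payload.provenance)))
        elif isinstance(payload, ChemblPayload):
            g.add(Triple(comp, wo("hasGene"), wo(payload.gene_id)))
            g.add(Triple(wo(payload.gene_id), RDF_TYPE, wo("Gene")))
            emit_gene_diseases({payload.gene_id})
        else:
            article = wo("pmid" + payload.article_id)
            pubref = literal("pubmedid" + payload.article_id)
            g.add(Triple(comp, wo("isContainedIn"), article))
            g.add(Triple(article, RDF_TYPE, wo("JournalArticle")))
            if payload.title:
                g.add(Triple(article, wo("hasTitle"), literal(payload.title)))
            text = payload.title + "\n" + payload.abstract
            genes = {e for e, _ in extract_terms(text, gene_lex, **kw)}
            for gene in sorted(genes):
                g.add(Triple(wo(gene), wo("isrelatedTo"), comp))
                g.add(Triple(wo(gene), RDF_TYPE, wo("Gene")))
                g.add(Triple(wo(gene), wo("isInferredFrom"), pubref))
            emit_gene_diseases(genes)
            for disease, _ in extract_terms(text, disease_lex, **kw):
                g.add(Triple(article, wo("hasDisease"), wo(disease)))
                g.add(Triple(wo(disease), RDF_TYPE, wo("Disease")))
    return g
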