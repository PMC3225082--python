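"""Synthetic evidence documents with known ground truth, plus exact
fixtures for the published worked examples.

The generator emits one query compound and a configurable number of
similar compounds whose records realize *planted* compound-disease
associations through chosen evidence channels:

- ``literature``: each planted path is an article whose title mentions a
  gene that the association matrix links to the disease (fires the
  literature co-occurrence rule once per path);
- ``bioassay``: an assay whose description carries the gene term -- or,
  in GO mode, a GO-term name that the GO annotation maps to the gene --
  (fires both the unanchored and the query-anchored assay-chain rules,
  i.e. two evidence paths per planted record);
- ``ctd``: a curated compound-disease record (fires the direct rule once);
- ``chembl``: a screening-target record (fires the target-chain rule once).

Decoy records are similar compounds whose payloads complete no rule body
(term-free descriptions, matrix-less target genes).  The returned
:class:`GroundTruth` is the generator's own bookkeeping -- expected
evidence-path counts per rule and disease, record counts per group, and
the exact expected triple set -- computed by direct construction,
independently of the ingest pipeline it is used to check.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from lxml import etree

from .kg import KnowledgeGraph, RDF_TYPE, Triple, decimal_literal, literal, wo

__all__ = [
    "CHANNELS", "PlantedAssociation", "GeneratorConfig", "GroundTruth",
    "GeneratedBundle", "InfeasibleConfigError", "generate",
    "table3_fixture", "table4_fixture", "TABLE4_TITLES",
    "methysergide_fixture",
]

CHANNELS = ("bioassay", "literature", "ctd", "chembl")

#: Rules fired per planted record, by channel (see module docstring).
CHANNEL_RULES: Dict[str, Tuple[str, ...]] = {
    "bioassay": ("rule3", "rule5"),
    "literature": ("rule6",),
    "ctd": ("rule4",),
    "chembl": ("rule7",),
}


class InfeasibleConfigError(ValueError):
    """The entity pools cannot host the requested plants."""


@dataclass(frozen=True)
class PlantedAssociation:
    """A disease to plant, with (channel, multiplicity) evidence."""

    disease: str
    channels: Tuple[Tuple[str, int], ...]

    def __post_init__(self) -> None:
        for channel, multiplicity in self.channels:
            if channel not in CHANNELS:
                raise InfeasibleConfigError(
                    f"unknown channel {channel!r}; use one of {CHANNELS}")
            if multiplicity < 1:
                raise InfeasibleConfigError(
                    f"multiplicity {multiplicity} for {self.disease}/{channel} "
                    "must be >= 1")


def _default_planted() -> Tuple[PlantedAssociation, ...]:
    # Mirrors the worked example's shape: one disease supported by two
    # literature paths, a second by one assay record.
    return (
        PlantedAssociation("Disease_01", (("literature", 2),)),
        PlantedAssociation("Disease_02", (("bioassay", 1),)),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    n_similar_compounds: int = 12
    n_bioassays: int = 6
    n_genes: int = 10
    n_diseases: int = 6
    n_articles: int = 8
    planted: Tuple[PlantedAssociation, ...] = field(
        default_factory=_default_planted)
    similarity_range: Tuple[float, float] = (0.7, 1.0)
    decoy_fraction: float = 0.25
    extra_decoys: int = 0
    seed: int = 0
    bioassay_via_go: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.similarity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise InfeasibleConfigError(
                f"similarity_range {self.similarity_range} must lie in (0, 1]")
        if not 0.0 <= self.decoy_fraction < 1.0:
            raise InfeasibleConfigError(
                f"decoy_fraction {self.decoy_fraction} must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Generator bookkeeping for recovery checks."""

    path_counts: Dict[str, Dict[str, int]]  # disease -> rule id -> paths
    record_counts: Dict[str, int]           # group -> records
    triple_count: int                       # expected ingest output size
    expected_triples: Set[Tuple[str, str, str]]  # curie-style bookkeeping
    planted_order: List[str]                # by total path count desc, lex

    def total_paths(self, disease: str) -> int:
        return sum(self.path_counts.get(disease, {}).values())

    def to_json_dict(self) -> dict:
        return {
            "path_counts": self.path_counts,
            "record_counts": self.record_counts,
            "triple_count": self.triple_count,
            "planted_order": self.planted_order,
        }


@dataclass
class GeneratedBundle:
    """All generated artifacts as plain text."""

    wendi_xml: str
    gene_lexicon: str
    disease_lexicon: str
    go_lexicon: str
    go_annotation: str
    gene_disease_matrix: str
    ground_truth: GroundTruth


# --------------------------------------------------------------------------

def generate(config: GeneratorConfig) -> GeneratedBundle:
    """Deterministically generate a document + side tables for ``config``."""
    rng = random.Random(config.seed)
    plants = [(p.disease, ch, mult)
              for p in config.planted for ch, mult in p.channels]
    n_planted_records = sum(m for _, _, m in plants)
    n_decoys = int(round(config.decoy_fraction * n_planted_records)) \
        + config.extra_decoys
    n_records = n_planted_records + n_decoys

    if n_records > config.n_similar_compounds:
        raise InfeasibleConfigError(
            f"{n_records} records (planted {n_planted_records} + decoys "
            f"{n_decoys}) need n_similar_compounds >= {n_records}, "
            f"got {config.n_similar_compounds}")
    diseases_used = [p.disease for p in config.planted]
    if len(set(diseases_used)) != len(diseases_used):
        raise InfeasibleConfigError("planted diseases must be distinct")
    if len(diseases_used) > config.n_diseases:
        raise InfeasibleConfigError(
            f"{len(diseases_used)} planted diseases exceed n_diseases="
            f"{config.n_diseases}")
    gene_plants = [pl for pl in plants if pl[1] != "ctd"]
    n_chembl_decoys = len([i for i in range(n_decoys) if i % 3 == 2])
    if len(gene_plants) + n_chembl_decoys > config.n_genes:
        raise InfeasibleConfigError(
            f"{len(gene_plants)} gene-mediated plants plus {n_chembl_decoys} "
            f"target decoys need n_genes >= "
            f"{len(gene_plants) + n_chembl_decoys}, got {config.n_genes}")
    n_lit_records = sum(m for _, ch, m in plants if ch == "literature") \
        + len([i for i in range(n_decoys) if i % 3 == 1])
    if n_lit_records > config.n_articles:
        raise InfeasibleConfigError(
            f"{n_lit_records} article records need n_articles >= "
            f"{n_lit_records}, got {config.n_articles}")
    n_assay_records = sum(m for _, ch, m in plants if ch == "bioassay") \
        + len([i for i in range(n_decoys) if i % 3 == 0])
    if n_assay_records > config.n_bioassays:
        raise InfeasibleConfigError(
            f"{n_assay_records} assay records need n_bioassays >= "
            f"{n_assay_records}, got {config.n_bioassays}")

    # entity pools (fixed-width ids: no accidental substring matches)
    genes = [f"GEN{i:02d}" for i in range(1, config.n_genes + 1)]
    diseases = sorted(set(diseases_used)) + [
        f"Disease_{i:02d}" for i in range(1, config.n_diseases + 1)]
    seen: Set[str] = set()
    diseases = [d for d in diseases if not (d in seen or seen.add(d))]
    diseases = diseases[:max(config.n_diseases, len(diseases_used))]
    go_terms = [(f"GO:00{i:05d}", f"synthetic process {i:02d}")
                for i in range(1, config.n_bioassays + 1)]

    gene_iter = iter(genes)
    compound_counter = iter(range(1, config.n_similar_compounds + 1))
    assay_counter = iter(range(1, config.n_bioassays + 1))
    article_counter = iter(range(1, config.n_articles + 1))
    go_iter = iter(go_terms)

    matrix_rows: List[Tuple[str, str, str]] = []
    go_ann_rows: List[Tuple[str, str]] = []
    records: List[dict] = []  # group, attrs, payload tag + attrs
    path_counts: Dict[str, Dict[str, int]] = {}

    def next_compound(ctd: bool = False) -> str:
        k = next(compound_counter)
        return f"{'ctdcid' if ctd else 'cid'}{5000000 + k}"

    def similarity() -> str:
        lo, hi = config.similarity_range
        return f"{rng.uniform(lo, hi):.3f}"

    for disease, channel, multiplicity in plants:
        gene = next(gene_iter) if channel != "ctd" else None
        prov = f"pubmedid{9500000 + rng.randrange(400000)}" \
            if channel == "literature" else ""
        if gene is not None:
            matrix_rows.append((gene, disease, prov))
        for _ in range(multiplicity):
            comp = next_compound(ctd=(channel == "ctd"))
            sim = similarity()
            if channel == "bioassay":
                aid = f"aid{400 + next(assay_counter)}"
                if config.bioassay_via_go:
                    go_id, go_surface = next(go_iter)
                    go_ann_rows.append((go_id, gene))
                    desc = f"cell-based screen of the {go_surface} response"
                else:
                    desc = f"inhibition screen against {gene} activity"
                records.append(dict(group="ActiveBioassay", compound=comp,
                                    similarity=sim, tag="bioassay",
                                    attrs={"id": aid, "description": desc}))
            elif channel == "literature":
                pmid = str(8000000 + next(article_counter))
                title = f"Modulation of {gene} signalling by analogue {comp}"
                records.append(dict(group="Literature", compound=comp,
                                    similarity=sim, tag="article",
                                    attrs={"pmid": pmid, "title": title,
                                           "abstract": f"We report activity "
                                           f"of {comp} at {gene}."}))
            elif channel == "ctd":
                records.append(dict(group="CTD", compound=comp,
                                    similarity=sim, tag="disease",
                                    attrs={"id": disease}))
            else:  # chembl
                records.append(dict(group="Chembl", compound=comp,
                                    similarity=sim, tag="target",
                                    attrs={"gene": gene}))
        counts = path_counts.setdefault(disease, {})
        for rule_id in CHANNEL_RULES[channel]:
            counts[rule_id] = counts.get(rule_id, 0) + multiplicity

    for i in range(n_decoys):
        comp = next_compound()
        sim = similarity()
        kind = i % 3
        if kind == 0:
            aid = f"aid{400 + next(assay_counter)}"
            records.append(dict(group="ActiveBioassay", compound=comp,
                                similarity=sim, tag="bioassay",
                                attrs={"id": aid,
                                       "description": "buffer-only counter "
                                       "screen, no annotated target"}))
        elif kind == 1:
            pmid = str(8000000 + next(article_counter))
            records.append(dict(group="Literature", compound=comp,
                                similarity=sim, tag="article",
                                attrs={"pmid": pmid,
                                       "title": "Notes on assay "
                                       "reproducibility and solvents",
                                       "abstract": ""}))
        else:
            decoy_gene = next(gene_iter)  # deliberately absent from matrix
            records.append(dict(group="Chembl", compound=comp,
                                similarity=sim, tag="target",
                                attrs={"gene": decoy_gene}))

    xml_text = _records_to_xml(records)
    go_surfaces = {go_id: surface for go_id, surface in go_terms}
    bookkeeping = _expected_triples(records, matrix_rows, go_ann_rows,
                                    genes, go_surfaces)
    record_counts = {g: len([r for r in records if r["group"] == g])
                     for g in ("ActiveBioassay", "CTD", "Chembl", "Literature")}
    totals = {d: sum(c.values()) for d, c in path_counts.items()}
    planted_order = sorted(totals, key=lambda d: (-totals[d], d))
    ground_truth = GroundTruth(
        path_counts=path_counts,
        record_counts=record_counts,
        triple_count=len(bookkeeping),
        expected_triples=bookkeeping,
        planted_order=planted_order,
    )

    gene_lex = _tsv(("term", "entity_id"), [(g, g) for g in genes])
    disease_lex = _tsv(("term", "entity_id"),
                       [(d.replace("_", " "), d) for d in diseases])
    go_lex = _tsv(("term", "entity_id"), [(s, i) for i, s in go_terms])
    go_ann = _tsv(("go_id", "gene_id"), go_ann_rows)
    matrix = _tsv(("gene_id", "disease_id", "provenance"), matrix_rows)
    return GeneratedBundle(xml_text, gene_lex, disease_lex, go_lex, go_ann,
                           matrix, ground_truth)


def _tsv(header: Sequence[str], rows: Sequence[Sequence[str]]) -> str:
    lines = ["\t".join(header)]
    lines += ["\t".join(str(x) for x in row) for row in rows]
    return "\n".join(lines) + "\n"


def _records_to_xml(records: List[dict]) -> str:
    root = etree.Element("wendi", {"query-id": "querycmpd",
                                   "smiles": "CC(=O)Oc1ccccc1C(=O)O"})
    for group_name in ("ActiveBioassay", "CTD", "Chembl", "Literature"):
        group_records = [r for r in records if r["group"] == group_name]
        if not group_records:
            continue
        group_el = etree.SubElement(root, "group", {"name": group_name})
        for r in group_records:
            rec_el = etree.SubElement(group_el, "record",
                                      {"compound": r["compound"],
                                       "similarity": r["similarity"]})
            etree.SubElement(rec_el, r["tag"],
                             {k: v for k, v in r["attrs"].items()
                              if v is not None})
    return etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


def _expected_triples(records: List[dict],
                      matrix_rows: List[Tuple[str, str, str]],
                      go_ann_rows: List[Tuple[str, str]],
                      gene_pool: List[str],
                      go_surfaces: Dict[str, str]
                      ) -> Set[Tuple[str, str, str]]:
    """Directly constructed expectation of the ingest output (curie text).

    Gene detection is a plain substring scan over the full gene pool and
    the GO surface forms; the fixed-width id scheme guarantees no
    accidental matches.
    """
    matrix: Dict[str, List[Tuple[str, str]]] = {}
    for gene, disease, prov in matrix_rows:
        matrix.setdefault(gene, []).append((disease, prov))
    go_genes: Dict[str, Set[str]] = {}
    for go_id, gene in go_ann_rows:
        go_genes.setdefault(go_id, set()).add(gene)

    out: Set[Tuple[str, str, str]] = set()
    out.add(("wo:querycmpd", "rdf:type", "wo:ChemicalCompound"))

    def gene_expansion(gene: str) -> None:
        out.add((f"wo:{gene}", "rdf:type", "wo:Gene"))
        for disease, prov in matrix.get(gene, []):
            out.add((f"wo:{gene}", "wo:isAssociatedWith", f"wo:{disease}"))
            out.add((f"wo:{disease}", "rdf:type", "wo:Disease"))
            if prov:
                out.add((f"wo:{disease}", "wo:isInferredFrom", f'"{prov}"'))

    for r in records:
        comp = f"wo:{r['compound']}"
        out.add(("wo:querycmpd", "wo:isSimilarTo", comp))
        out.add((comp, "wo:hasSimilarity", f'"{r["similarity"]}"'))
        out.add((comp, "rdf:type", "wo:ChemicalCompound"))
        attrs = r["attrs"]
        if r["tag"] == "bioassay":
            assay = f"wo:{attrs['id']}"
            out.add((comp, "wo:isActiveIn", assay))
            out.add((assay, "rdf:type", "wo:BioAssay"))
            out.add((assay, "wo:hasName", f'"{attrs["description"]}"'))
            found = {g for g in gene_pool if g in attrs["description"]}
            for go_id, surface in go_surfaces.items():
                if surface in attrs["description"]:
                    found |= go_genes.get(go_id, set())
            for gene in found:
                out.add((assay, "wo:hasGene", f"wo:{gene}"))
                gene_expansion(gene)
        elif r["tag"] == "disease":
            out.add((comp, "wo:hasDisease", f"wo:{attrs['id']}"))
            out.add((f"wo:{attrs['id']}", "rdf:type", "wo:Disease"))
        elif r["tag"] == "target":
            out.add((comp, "wo:hasGene", f"wo:{attrs['gene']}"))
            gene_expansion(attrs["gene"])
        else:  # article
            article = f"wo:pmid{attrs['pmid']}"
            out.add((comp, "wo:isContainedIn", article))
            out.add((article, "rdf:type", "wo:JournalArticle"))
            out.add((article, "wo:hasTitle", f'"{attrs["title"]}"'))
            text = attrs["title"] + "\n" + attrs.get("abstract", "")
            for gene in [g for g in gene_pool if g in text]:
                out.add((f"wo:{gene}", "wo:isrelatedTo", comp))
                out.add((f"wo:{gene}", "wo:isInferredFrom",
                         f'"pubmedid{attrs["pmid"]}"'))
                gene_expansion(gene)
    return out


def triple_to_curie(t: Triple) -> Tuple[str, str, str]:
    """Graph triple -> the bookkeeping curie/quoted-literal encoding."""
    def enc(term) -> str:
        if term.is_literal:
            return f'"{term.value}"'
        return term.curie()
    return (enc(t.subject), enc(t.predicate), enc(t.object))


# --------------------------------------------------------------------------
# Worked-example fixtures

def table3_fixture() -> KnowledgeGraph:
    """The published worked example's three statement blocks, verbatim.

    Entity ids are reproduced exactly as printed, including the source
    tags (``ctdcid9681`` as similar compound vs the bare ``cid9681`` the
    literature link points at).  The gene-disease associations are stored
    gene -> disease, the direction the ontology and every rule declare.
    """
    g = KnowledgeGraph()
    T = Triple
    cc, ba, gene, dis = (wo("ChemicalCompound"), wo("BioAssay"), wo("Gene"),
                         wo("Disease"))
    # block 1: Methysergide itself, literature link via HTR1B
    g.add(T(wo("ctdcid9681"), RDF_TYPE, cc))
    g.add(T(wo("querycmpd"), wo("isSimilarTo"), wo("ctdcid9681")))
    g.add(T(wo("ctdcid9681"), wo("hasSimilarity"), decimal_literal("1.000")))
    g.add(T(wo("ctdcid9681"), wo("hasName"), literal("Methysergide")))
    g.add(T(wo("HTR1B"), RDF_TYPE, gene))
    g.add(T(wo("HTR1B"), wo("isrelatedTo"), wo("cid9681")))
    g.add(T(wo("HTR1B"), wo("isInferredFrom"), literal("pubmedid8743744")))
    g.add(T(wo("Autistic_Disorder"), RDF_TYPE, dis))
    g.add(T(wo("HTR1B"), wo("isAssociatedWith"), wo("Autistic_Disorder")))
    g.add(T(wo("Autistic_Disorder"), wo("isInferredFrom"),
            literal("pubmedid19038234")))
    # block 2: Metergoline, second literature path via the same gene
    g.add(T(wo("ctdcid11865408"), RDF_TYPE, cc))
    g.add(T(wo("querycmpd"), wo("isSimilarTo"), wo("ctdcid11865408")))
    g.add(T(wo("ctdcid11865408"), wo("hasSimilarity"),
            decimal_literal("0.774")))
    g.add(T(wo("ctdcid11865408"), wo("hasName"), literal("Metergoline")))
    g.add(T(wo("HTR1B"), wo("isrelatedTo"), wo("cid11865408")))
    g.add(T(wo("HTR1B"), wo("isInferredFrom"), literal("pubmedid1330643")))
    # block 3: assay chain to Lymphoma via CYP1A2
    g.add(T(wo("cid5486180"), RDF_TYPE, cc))
    g.add(T(wo("querycmpd"), wo("isSimilarTo"), wo("cid5486180")))
    g.add(T(wo("cid5486180"), wo("hasSimilarity"), decimal_literal("0.929")))
    g.add(T(wo("cid5486180"), wo("isActiveIn"), wo("aid410")))
    g.add(T(wo("aid410"), RDF_TYPE, ba))
    g.add(T(wo("aid410"), wo("hasName"), literal("p450-cyp1a2")))
    g.add(T(wo("CYP1A2"), RDF_TYPE, gene))
    g.add(T(wo("aid410"), wo("hasGene"), wo("CYP1A2")))
    g.add(T(wo("CYP1A2"), wo("isAssociatedWith"), wo("Lymphoma")))
    g.add(T(wo("Lymphoma"), RDF_TYPE, dis))
    return g


TABLE4_TITLES = (
    "First Pharmacophoric Hypothesis for 5-HT7 Antagonism",
    "Novel, Potent, and Selective 5-HT3 Receptor Antagonists Based on the "
    "Arylpiperazine Skeleton: Synthesis, Structure, Biological Activity, and "
    "Comparative Molecular Field Analysis Studies",
    "Synthesis of 2-Piperazinylbenzothiazole and 2-Piperazinylbenzoxazole "
    "Derivatives with 5-HT3 Antagonist and 5-HT4 Agonist Properties",
    "Novel and Highly Potent 5-HT3 Receptor Agonists Based on a "
    "Pyrroloquinoxaline Structure",
)

_DISTRACTOR_TITLES = (
    "Dopamine D2 Receptor Binding of Ergoline Derivatives",
    "Muscarinic Acetylcholine Receptor Ligands from Natural Products",
)


def table4_fixture() -> KnowledgeGraph:
    """Articles carrying the four published serotonin-receptor titles,
    each linked from a compound, plus two distractor articles."""
    g = KnowledgeGraph()
    titles = list(TABLE4_TITLES) + list(_DISTRACTOR_TITLES)
    for i, title in enumerate(titles, start=1):
        comp = wo(f"cid{7000000 + i}")
        article = wo(f"pmid{9100000 + i}")
        g.add(Triple(comp, RDF_TYPE, wo("ChemicalCompound")))
        g.add(Triple(article, RDF_TYPE, wo("JournalArticle")))
        g.add(Triple(comp, wo("isContainedIn"), article))
        g.add(Triple(article, wo("hasTitle"), literal(title)))
    return g


@dataclass(frozen=True)
class MethysergideFixture:
    """Input-side reconstruction of the worked example (consistent ids)."""

    wendi_xml: str
    gene_lexicon: str
    disease_lexicon: str
    go_lexicon: str
    go_annotation: str
    gene_disease_matrix: str


def methysergide_fixture() -> MethysergideFixture:
    xml = """<?xml version="1.0" encoding="UTF-8"?>
<wendi query-id="querycmpd" smiles="CCC(CO)NC(=O)C1CN(C)C2CC3=CN(C)C4=CC=CC(=C34)C2=C1">
  <group name="ActiveBioassay">
    <record compound="cid5486180" similarity="0.929">
      <bioassay id="aid410" description="p450-cyp1a2"/>
    </record>
  </group>
  <group name="Literature">
    <record compound="ctdcid9681" similarity="1.000" name="Methysergide">
      <article pmid="8743744"
               title="Methysergide binding at the serotonin receptor gene HTR1B"
               abstract="Co-occurrence of the compound with HTR1B."/>
    </record>
    <record compound="ctdcid11865408" similarity="0.774" name="Metergoline">
      <article pmid="1330643"
               title="Metergoline and HTR1B mediated serotonin responses"
               abstract=""/>
    </record>
  </group>
</wendi>
"""
    gene_lex = _tsv(("term", "entity_id"),
                    [("HTR1B", "HTR1B"), ("CYP1A2", "CYP1A2")])
    disease_lex = _tsv(("term", "entity_id"),
                       [("Autistic Disorder", "Autistic_Disorder"),
                        ("Lymphoma", "Lymphoma")])
    go_lex = _tsv(("term", "entity_id"),
                  [("oxidoreductase activity", "GO:0016491")])
    go_ann = _tsv(("go_id", "gene_id"), [("GO:0016491", "CYP1A2")])
    matrix = _tsv(("gene_id", "disease_id", "provenance"),
                  [("HTR1B", "Autistic_Disorder", "pubmedid19038234"),
                   ("CYP1A2", "Lymphoma", "")])
    return MethysergideFixture(xml, gene_lex, disease_lex, go_lex, go_ann,
                               matrix)
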