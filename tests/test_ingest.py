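"""Document parsing, dictionary annotation, and triple emission."""

import io
import random
import string

import pytest
from hypothesis import given, settings, strategies as st

from conftest import ingest_bundle
from evipath import synthetic as syn
from evipath.ingest import (
    GeneDiseaseMatrix,
    GoAnnotation,
    Lexicon,
    WendiSchemaError,
    extract_terms,
    genes_to_diseases,
    go_terms_to_genes,
    load_gene_disease_matrix,
    load_lexicon,
    parse_wendi_xml,
)
from evipath.ingest import to_triples
from evipath.kg import CE_ONTOLOGY, RDF_TYPE, Triple, literal, validate, wo
from evipath.synthetic import triple_to_curie


class TestParseWendiXml:
    def test_empty_document_keeps_query_compound(self):
        rs = parse_wendi_xml(
            '<wendi query-id="querycmpd" smiles="CCO"/>')
        assert rs.query_id == "querycmpd"
        assert all(rs.groups[g] == [] for g in rs.groups)

    def test_methysergide_fixture_recovers_three_records(self):
        rs = parse_wendi_xml(syn.methysergide_fixture().wendi_xml)
        lits = rs.groups["Literature"]
        assert [(r.similar_compound, r.similarity) for r in lits] \
            == [("ctdcid9681", "1.000"), ("ctdcid11865408", "0.774")]
        [assay] = rs.groups["ActiveBioassay"]
        assert assay.similar_compound == "cid5486180"
        assert assay.similarity == "0.929"
        assert assay.payload.assay_id == "aid410"

    def test_schema_violation_reports_line(self):
        bad = ('<wendi query-id="q">\n  <group name="NoSuchGroup">\n'
               '  </group>\n</wendi>')
        with pytest.raises(WendiSchemaError, match="line 2"):
            parse_wendi_xml(bad)

    def test_out_of_range_similarity_rejected(self):
        bad = ('<wendi query-id="q"><group name="CTD">'
               '<record compound="cid1" similarity="1.2">'
               '<disease id="D"/></record></group></wendi>')
        with pytest.raises(WendiSchemaError):
            parse_wendi_xml(bad)

    def test_payload_group_mismatch_rejected(self):
        bad = ('<wendi query-id="q"><group name="CTD">'
               '<record compound="cid1" similarity="0.9">'
               '<bioassay id="aid1"/></record></group></wendi>')
        with pytest.raises(WendiSchemaError, match="CTD"):
            parse_wendi_xml(bad)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_generator_documents_round_trip(self, seed):
        rng = random.Random(seed)
        cfg = syn.GeneratorConfig(
            seed=seed,
            planted=(syn.PlantedAssociation(
                "Disease_01",
                ((rng.choice(syn.CHANNELS), rng.randint(1, 3)),)),),
        )
        bundle = syn.generate(cfg)
        rs = parse_wendi_xml(bundle.wendi_xml)
        assert {g: len(v) for g, v in rs.groups.items()} \
            == bundle.ground_truth.record_counts


GENE_LEX = Lexicon((("CYP1A2", "CYP1A2"), ("HTR1B", "HTR1B"),
                    ("CAT", "CAT")), "gene")


class TestExtractTerms:
    def test_empty_text(self):
        assert extract_terms("", GENE_LEX) == []

    def test_case_insensitive_substring_finds_gene_in_assay_name(self):
        assert extract_terms("p450-cyp1a2", GENE_LEX) == [("CYP1A2", 5)]

    def test_word_boundary_mode_suppresses_embedded_matches(self):
        text = "concatenate the CAT assay"
        loose = dict(extract_terms(text, GENE_LEX))
        strict = dict(extract_terms(text, GENE_LEX, word_boundary=True))
        assert loose == {"CAT": 3}   # embedded hit, first offset
        assert strict == {"CAT": 16}  # token hit only

    def test_overlapping_terms_all_reported(self):
        lex = Lexicon((("HTR1", "HTR1"), ("HTR1B", "HTR1B")), "gene")
        got = extract_terms("binding at HTR1B", lex)
        assert got == [("HTR1", 11), ("HTR1B", 11)]

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_equals_naive_scan(self, seed):
        rng = random.Random(seed)
        vocab = ["ABC1", "XYZ2", "LONGGENE3", "Q4"]
        lex = Lexicon(tuple((v, v) for v in vocab), "gene")
        words = [rng.choice(vocab + ["filler", "noise", "q4x"])
                 for _ in range(rng.randint(0, 12))]
        text = " ".join(words)
        for cs in (False, True):
            got = extract_terms(text, lex, case_sensitive=cs)
            hay = text if cs else text.lower()
            expected = sorted(
                ((hay.find(v if cs else v.lower()), v) for v in vocab
                 if (v if cs else v.lower()) in hay),
                key=lambda h: (h[0], h[1]))
            assert got == [(v, off) for off, v in expected]


class TestMappings:
    ANN = GoAnnotation({"GO:1": frozenset({"A", "B"}),
                        "GO:2": frozenset({"B", "C"})})

    def test_go_union_without_duplicates(self):
        assert go_terms_to_genes(set(), self.ANN) == set()
        assert go_terms_to_genes({"GO:1", "GO:2"}, self.ANN) \
            == {"A", "B", "C"}
        assert go_terms_to_genes({"GO:unknown"}, self.ANN) == set()

    def test_genes_to_diseases_is_a_row_filter(self):
        matrix = GeneDiseaseMatrix((
            ("HTR1B", "Autistic_Disorder", "pubmedid19038234"),
            ("CYP1A2", "Lymphoma", None),
            ("BRCA1", "Breast_Neoplasms", None)))
        assert genes_to_diseases(set(), matrix) == set()
        assert genes_to_diseases({"HTR1B"}, matrix) \
            == {("HTR1B", "Autistic_Disorder", "pubmedid19038234")}
        got = genes_to_diseases({"HTR1B", "CYP1A2"}, matrix)
        assert got == {r for r in matrix.associations if r[0] != "BRCA1"}

    def test_tsv_loaders(self):
        lex = load_lexicon(io.StringIO("term\tentity_id\nHTR1B\tHTR1B\n"),
                           "gene")
        assert lex.entries == (("HTR1B", "HTR1B"),)
        mat = load_gene_disease_matrix(io.StringIO(
            "gene_id\tdisease_id\tprovenance\nG\tD\t\n"))
        assert mat.associations == (("G", "D", None),)


class TestToTriples:
    def test_empty_record_set_yields_query_typing_only(self):
        rs = parse_wendi_xml('<wendi query-id="querycmpd"/>')
        g = to_triples(rs, GENE_LEX,
                       Lexicon((), "disease"), Lexicon((), "go_term"),
                       GoAnnotation({}), GeneDiseaseMatrix(()))
        assert g.triples() == frozenset(
            {Triple(wo("querycmpd"), RDF_TYPE, wo("ChemicalCompound"))})

    def test_methysergide_graph_reproduces_worked_example_chains(
            self, methysergide_graph):
        g = methysergide_graph
        # literature chains
        assert Triple(wo("querycmpd"), wo("isSimilarTo"),
                      wo("ctdcid9681")) in g
        assert Triple(wo("HTR1B"), wo("isrelatedTo"), wo("ctdcid9681")) in g
        assert Triple(wo("HTR1B"), wo("isInferredFrom"),
                      literal("pubmedid8743744")) in g
        assert Triple(wo("HTR1B"), wo("isAssociatedWith"),
                      wo("Autistic_Disorder")) in g
        # assay chain
        assert Triple(wo("cid5486180"), wo("isActiveIn"), wo("aid410")) in g
        assert Triple(wo("aid410"), wo("hasGene"), wo("CYP1A2")) in g
        assert Triple(wo("CYP1A2"), wo("isAssociatedWith"),
                      wo("Lymphoma")) in g
        sims = {t.object.value for t in g
                if t.predicate == wo("hasSimilarity")}
        assert sims == {"1.000", "0.774", "0.929"}

    def test_output_validates_against_ontology(self, methysergide_graph):
        assert validate(methysergide_graph, CE_ONTOLOGY).ok

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_generator_triples_match_bookkeeping(self, seed):
        cfg = syn.GeneratorConfig(seed=seed,
                                  bioassay_via_go=bool(seed % 2))
        bundle = syn.generate(cfg)
        g = ingest_bundle(bundle)
        assert {triple_to_curie(t) for t in g} \
            == bundle.ground_truth.expected_triples
        assert len(g) == bundle.ground_truth.triple_count
        assert validate(g, CE_ONTOLOGY).ok

    def test_every_record_reachable_from_query_compound(
            self, methysergide_graph):
        # breadth-first over the emitted edges, ignoring direction for the
        # gene->compound literature links
        g = methysergide_graph
        adjacency = {}
        for t in g:
            if t.object.is_iri:
                adjacency.setdefault(t.subject, set()).add(t.object)
                adjacency.setdefault(t.object, set()).add(t.subject)
        seen, frontier = {wo("querycmpd")}, [wo("querycmpd")]
        while frontier:
            node = frontier.pop()
            for nxt in adjacency.get(node, ()):
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
        for comp in ("ctdcid9681", "ctdcid11865408", "cid5486180"):
            assert wo(comp) in seen
        assert wo("aid410") in seen and wo("pmid8743744") in seen
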