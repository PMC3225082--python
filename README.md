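# evipath

Infer, cluster and rank **compound–disease evidence paths** over an
ontology-typed chemogenomic knowledge graph.

## The problem

When a new or poorly characterized chemical compound comes in, most of
what can be said about it is indirect: it resembles known compounds, those
compounds are active in screening assays, the assays are annotated with
genes, the genes are associated with diseases, and the whole chain may
also be traced through the literature or curated compound–disease
databases. `evipath` turns such aggregated evidence about one *query
compound* into a typed RDF-style triple graph, forward-chains a small
declarative rule base to infer new `mightHasDisease` links, records every
rule firing as an **evidence path** with full provenance, and ranks the
candidate diseases by the amount of independent evidence supporting them.
It is aimed at cheminformaticians doing early drug-discovery triage.

## The model

The graph vocabulary has five entity classes — `ChemicalCompound`,
`BioAssay`, `JournalArticle`, `Gene`, `Disease` — and a dozen properties
with declared domains/ranges (`isSimilarTo`, `isActiveIn`,
`isContainedIn`, `hasGene`, `hasDisease`, `isAssociatedWith`,
`hasSimilarity`, `isrelatedTo`, `isInferredFrom`, `mightHasDisease`, …).
Everything lives in one project namespace bound to the prefix `wo:`
(base IRI `http://wendi.example.org/wo#`).

Inference rules are range-restricted rewrites of triple-pattern
conjunctions, e.g. the assay channel:

```
[rule1: (?QueryCompound wo:isSimilarTo ?CompoundID),
        (?CompoundID wo:isActiveIn ?Bioassay),
        (?Bioassay wo:isAssociatedWith ?Disease)
        -> (?QueryCompound wo:mightHasDisease ?Disease)]
```

The default registry has 8 rules: three published verbatim
(`provenance_tag="paper"`) and five reconstructions of the remaining
evidence channels (`provenance_tag="reconstructed"`) — curated
compound–disease records, query-anchored assay and screening-target
chains, literature gene co-occurrence, and article-borne disease terms.
Forward chaining runs to fixpoint; each firing is kept as an
`EvidencePath` (rule id + variable binding + grounded body triples), and
two firings with different bindings count as two paths even when they
infer the same triple — multiplicity *is* the evidence signal.

Paths are clustered by disease and ranked either by `path_count`
(number of distinct evidence paths, the default) or by `property_count`
(the number of statements on the disease node in the materialized graph,
the literal historical aggregate, which under-counts paths that share
statements). Facet filters (disease / compound / assay / gene / journal,
optionally gene family) compose by intersection.

## Worked example

The repository ships the worked example of a serotonin-antagonist query
compound (Methysergide) as an exact fixture:

```python
from evipath import (synthetic, default_rules, forward_chain,
                     cluster_by_disease, rank, to_result_json)

graph = synthetic.table3_fixture()          # 26 statements, 3 similar compounds
result = forward_chain(graph, default_rules())
ranked = rank(cluster_by_disease(result), "path_count")
print(to_result_json(ranked, graph=result.graph))
```

prints

```json
[
  {
    "disease": "Autistic_Disorder",
    "score": 2.0,
    "metric": "path_count",
    "rank": 1,
    "paths": [
      {"rule": "rule6", "similar_compound": "cid11865408", "similarity": null,
       "gene": "HTR1B",
       "provenance": ["pubmedid1330643", "pubmedid19038234", "pubmedid8743744"]},
      {"rule": "rule6", "similar_compound": "cid9681", "similarity": null,
       "gene": "HTR1B",
       "provenance": ["pubmedid1330643", "pubmedid19038234", "pubmedid8743744"]}
    ]
  },
  {
    "disease": "Lymphoma",
    "score": 2.0,
    "metric": "path_count",
    "rank": 2,
    "paths": [
      {"rule": "rule3", "similar_compound": "cid5486180", "similarity": 0.929,
       "gene": "CYP1A2", "bioassay": "aid410", "provenance": []},
      {"rule": "rule5", "similar_compound": "cid5486180", "similarity": 0.929,
       "gene": "CYP1A2", "bioassay": "aid410", "provenance": []}
    ]
  }
]
```

Reading: two distinct similar compounds (the query compound itself and a
0.774-similar analogue) each co-occur in an article with the gene HTR1B,
which is matrix-linked to autistic disorder — two independent literature
evidence paths, so `Autistic_Disorder` ranks first. The lymphoma link
runs through one 0.929-similar compound active in assay `aid410`
(a p450-cyp1a2 screen); it is matched by both the verbatim unanchored
assay rule and its query-anchored reconstruction, and the tie against
the autism cluster is broken lexicographically.

## Command line

```
evipath generate --seed 3 --out-dir data/           # synthetic input + ground truth
evipath run --xml data/wendi.xml \
    --genes data/gene_lexicon.tsv --diseases data/disease_lexicon.tsv \
    --go data/go_lexicon.tsv --go-ann data/go_annotation.tsv \
    --matrix data/gene_disease_matrix.tsv --out-dir out/
evipath filter --paths out/paths.json --facet disease --value Disease_01
evipath query --graph out/graph.nt --spec query.yaml
```

`run` writes `graph.nt` (ingested triples), `result.nt` (materialized
graph), `paths.json` (evidence paths) and `ranked.json`; running the
stages individually (`ingest`, `infer`, `rank`) over the intermediate
files produces byte-identical output.

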