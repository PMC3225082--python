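# Methods

## Data model

The knowledge graph is a *set* of subject–predicate–object statements
over IRI and literal terms. Set semantics is load-bearing: re-asserting a
statement is a no-op, which is exactly why the two ranking metrics can
disagree (below). Blank nodes are not supported anywhere; every entity is
minted a deterministic IRI in the single project namespace
(`wo:` → `http://wendi.example.org/wo#`, a constant of this
implementation — the original system never published its namespace IRI).
This makes serialization round trips exact set equalities, which the
tests exploit.

The ontology declares five classes and the property domain/range table.
Two normalization decisions:

- **Predicate aliases.** The historical materials use both `hasGenes` and
  `hasGene` (similarly `hasDiseases`), and one printed rule spells
  `isSimiliarTo`. The executable rules are the authority, so the singular
  forms are canonical and the variants are accepted as read-time aliases
  by the validator and the rule parser.
- **Similarity as a typed literal.** Tanimoto similarity is attached to
  the similar compound as an `xsd:decimal` literal via `hasSimilarity`,
  keeping the printed lexical form (`"0.774"` stays `"0.774"`). The
  worked example's compact Turtle notation reads, literally, as attaching
  all three similarity values to the query compound; attaching each to
  its similar compound is the only reading consistent with one value per
  compound, and is what every downstream consumer needs.
- **Association direction.** Gene–disease associations are stored
  gene → disease (`isAssociatedWith`), the direction the property table
  and all rules declare. One worked-example block prints the reverse
  (disease as Turtle subject); it is treated as a notation slip.

Graph operations mutate in place and return the graph (the networkx
convention); `copy()` gives value snapshots, and equality compares triple
sets only.

## Ingest

Input is a schema-validated XML document (one query compound, similar
compounds with similarities in [0,1], four record groups) plus plain TSV
side tables: gene/disease/GO-term lexicons, a GO→gene annotation, and a
gene–disease matrix with optional PubMed provenance.

Term spotting in free text (assay descriptions, titles, abstracts) is
dictionary lookup by **case-insensitive substring**, the behaviour of a
plain SQL `position` call. That is deliberately permissive — a gene
symbol like `CAT` matches inside "concatenate" — so a word-boundary mode
is available behind a flag; the default stays permissive because the
historical pipeline's recall characteristics depend on it, and both modes
are tested. All matching lexicon terms are reported (no longest-match
suppression), each with its first offset, ordered by offset then id.

Emission per record: the similarity backbone (`isSimilarTo`,
`hasSimilarity`, typing), then channel triples. Assays reach genes via
lexicon hits or via GO terms expanded through the annotation; article
records emit `gene isrelatedTo compound` with
`gene isInferredFrom "pubmedid…"` provenance, matching the printed
encoding of literature evidence (no journal→gene statements are minted).
The gene–disease matrix expansion is applied to genes found through
*every* channel — the matrix is channel-agnostic, and the screening-target
rule would otherwise be dead code. Two additional emissions keep the
published rule vocabulary live: an assay description carrying a disease
term with no gene intermediary yields `assay isAssociatedWith disease`
(the vocabulary the published assay rule matches), and an article
carrying a disease term yields `article hasDisease disease`. Output is
always ontology-conformant (validated in tests and defensively in the
CLI).

## Rule base and inference

Rules are range-restricted (every head variable occurs in the body) and
body predicates are ground, so all inferences are ground triples.
`forward_chain` is naive fixpoint iteration: re-evaluate every rule until
no new firing appears. On the default rule base one round suffices
because the head vocabulary (`mightHasDisease`) feeds no body, but
inferred triples are re-matched every round so chained rule sets work,
with an iteration cap as a guard against non-terminating custom rules.
The conjunctive body matcher joins patterns left-to-right over a
predicate index; results are independent of body order and rule order
(tested by permutation), and the engine is checked for exact path-set
equality against brute-force enumeration and against an independent
SPARQL engine on random graphs.

Evidence-path identity is `(rule id, body-variable binding)`. Distinct
bindings are distinct paths even when they infer the same head triple —
this is the multiplicity the ranking counts.

Of the eight default rules, three are published verbatim and five are
reconstructions (the original count is known, the texts are not); the
`provenance_tag` field keeps the distinction machine-readable. Design
notes on the reconstructions:

- The published literature rule routes through journal nodes
  (`isContainedIn` / `hasGene`), but the printed data encodes literature
  evidence as `gene isrelatedTo compound`. The reconstructed literature
  rule (`rule6`) therefore matches the `isrelatedTo` encoding, and is
  *unanchored* (it starts at the similar compound without an
  `isSimilarTo` premise) exactly like the published rules 2 and 3 —
  input graphs only ever contain the query compound's neighbourhood, so
  anchoring is redundant there, and the printed worked example's
  literature links point at compound ids that an anchored join could not
  reach. Consequently literature- and assay-channel inferences name the
  similar compound in the head, as the published rule heads do.
- The assay chain is covered twice by design: verbatim `rule3`
  (unanchored) and its query-anchored reconstruction `rule5`. On the
  worked example both fire on the single lymphoma chain, so that cluster
  shows two paths and ties the autism cluster 2–2; the deterministic
  lexicographic tie-break still puts `Autistic_Disorder` first. This
  double-counting is the honest consequence of keeping the published
  rule verbatim *and* reconstructing its anchored sibling; consumers who
  want one-path-per-chain semantics can pass a custom rule file.

## Ranking

`path_count` scores a disease cluster by its number of evidence paths —
the stated intent of the original ranking. `property_count` implements
the historical aggregate query literally: count the statements whose
subject is the disease node in the materialized graph, `rdf:type` and
provenance included (whether the original authors meant to exclude
housekeeping predicates is unknowable, so nothing is excluded; the
implementation is cross-checked against the verbatim SPARQL aggregate run
on rdflib). The two metrics legitimately diverge when paths share
statements — on the worked example the lymphoma cluster has two paths but
a single chain, so `property_count` sees 1 where `path_count` sees 2; a
regression test pins this. Ties break lexicographically on the disease
IRI; ranks are 1..N without gaps.

## Synthetic data

The generator emulates the input side of the system: one query compound,
similar compounds with similarities drawn uniformly from a configurable
range, and *planted* compound–disease associations realized through the
four evidence channels with chosen multiplicity. Defaults mirror the
worked example's scale — a dozen similar compounds, two planted diseases
(literature multiplicity 2, assay multiplicity 1), similarities in
[0.7, 1.0], and a 25 % decoy fraction (decoy records complete no rule
body: term-free assay descriptions and titles, target genes absent from
the matrix). Entity ids mimic the field's shapes (`cidNNN`/`ctdcidNNN`,
`aidNNN`, gene-symbol-like tokens, Title_Case diseases) and are fixed
width, so naive substring spotting cannot produce accidental hits. Each
plant consumes its own gene/assay/article, which keeps plants
non-interacting and makes the expected per-rule path counts exact:
literature, curated and target plants yield one path per record
(`rule6`/`rule4`/`rule7`), assay plants yield two (`rule3` + `rule5`).
The returned ground truth (per-rule path counts, record counts, and the
full expected triple set) is computed by direct construction, not by
running the ingest pipeline it checks.

What the generator does **not** emulate: real chemistry (SMILES are
placeholders), real literature text (titles are templates around planted
tokens), lexicon ambiguity, or conflicting/duplicated source records.
Passing the recovery suite therefore demonstrates correctness of the
graph construction, inference and ranking machinery under clean planted
signal — not robustness to the noise of real aggregated sources.

## Numerical and procedural choices

- Similarities are parsed and re-serialized by lexical form; `xsd:string`
  literals normalize to plain literals on read.
- Result JSON field order is fixed
  (`disease, score, metric, rank, paths[...]`) and validated against the
  shipped schema by a small structural JSON validator.
- Query-builder variables are deterministic (`?c1`, `?j1`, … by class
  first-appearance; `?v1`, … for literal filters); literal `contains`
  filtering is case-sensitive by default because the motivating title
  query relies on the exact token `"5-HT"` (a case-insensitive flag
  exists). Result rows are de-duplicated and sorted.
- Degenerate inputs: an empty document yields a graph with only the query
  compound's typing; empty rule files and empty rankings are valid; the
  `gene_family` facet is unavailable (not an error) until a gene→family
  table is supplied.
- Problem sizes in the default test/acceptance runs — random graphs up to
  300 triples with up to 8 rules, 50 generator configurations, 100
  round-trip graphs — were chosen so the exhaustive oracles stay exact
  while the whole suite completes in seconds.

## Known limitations

- Ranking treats evidence paths as exchangeable counts; no independence
  weighting or significance model (paths sharing a gene or article are
  not down-weighted).
- Dictionary matching is not entity recognition; it has no
  disambiguation and, in default mode, no tokenization.
- The five reconstructed rules are informed guesses at unpublished
  channels; they are flagged as such and replaceable via the rule DSL.
- The XML dialect is this project's own (schema shipped); it models the
  shape of the upstream aggregator's output, not its exact format.
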